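"""Synthetic mid-IR spectra with the band structure of gypsum plant groups.

The generator emulates the three ecological groups as they appear in leaf
ATR-FTIR spectra:

* **wide gypsophiles** — dominated by inorganic bands: gypsum O-H stretches
  at 3522/3400 cm^-1 and S-O bends at 669/597 cm^-1, broad sulphate
  absorption near 1110 cm^-1, and frequently calcium oxalate (1615, 1312,
  780 cm^-1).  Replicate intensities vary more than in the other groups.
* **narrow gypsum endemisms** — organic-dominated spectra carrying oxalate
  bands but no gypsum.
* **gypsovags** — the least inorganic content; stronger ester (C=O near
  1735 cm^-1) and CH2 stretching; a small fraction of samples carry
  oxalate, mirroring the one oxalate-bearing gypsovag species.

Each spectrum is a sum of Gaussian bands on a linear baseline plus iid
Gaussian noise.  Per-band amplitudes are drawn lognormally around the
profile means (so they are positive), scaled by a per-sample multiplier
whose spread is wider for wide gypsophiles.

An elemental table is generated alongside, linearly coupled to the drawn
band areas (S to sulphate bands, Ca to gypsum+oxalate+carbonate, Ash to
all inorganics, N to amide, C decreasing in Ash) with K deliberately drawn
independently of the spectrum.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .spectra_io import (
    ANALYTE_COLUMNS,
    ElementalTable,
    Group,
    Spectrum,
    SpectrumSet,
    default_grid,
)

__all__ = [
    "BandReference",
    "GroupProfile",
    "SyntheticConfig",
    "make_band_library",
    "default_profiles",
    "lepidium_like_profile",
    "simulate_spectrum",
    "simulate_dataset",
]

GAUSS_AREA = math.sqrt(2.0 * math.pi)  # unit-amplitude, unit-sigma Gaussian


@dataclasses.dataclass(frozen=True)
class BandReference:
    """One reference absorption band: position, vibrational mode, compound.

    ``center`` is the band position in cm^-1; for bands quoted as a range
    the span is carried in ``band_range`` and ``center`` is its midpoint.
    """

    center: float
    assignment: str
    characterisation: str
    band_range: tuple[float, float] | None = None
    diagnostic_of: str | None = None

    def __post_init__(self) -> None:
        if not (370.0 <= self.center <= 4000.0):
            raise ValueError(f"band center {self.center} outside 370-4000")
        if self.band_range is not None and not (
                self.band_range[0] < self.band_range[1]):
            raise ValueError("band range low must be < high")

    def distance_to(self, wavenumber: float) -> float:
        """cm^-1 from a wavenumber to this band (0 inside a range)."""
        if self.band_range is not None:
            lo, hi = self.band_range
            if lo <= wavenumber <= hi:
                return 0.0
            return min(abs(wavenumber - lo), abs(wavenumber - hi))
        return abs(wavenumber - self.center)


def make_band_library() -> list[BandReference]:
    """Reference library of the main mid-IR bands of gypsum plant leaves."""

    def b(center, assignment, characterisation, rng=None, diag=None):
        return BandReference(center, assignment, characterisation,
                             band_range=rng, diagnostic_of=diag)

    return [
        b(3522, "O-H stretching", "gypsum", diag="gypsum"),
        b(3400, "O-H stretching", "gypsum", diag="gypsum"),
        b(3340, "O-H stretching", "cellulose"),
        b(2920, "antisymmetric CH2 stretching", "fats, wax, lipids",
          diag="alkane"),
        b(2850, "symmetric CH2 stretching", "fats, wax, lipids",
          diag="alkane"),
        b(1730, "C=O stretch of COOR", "esters", rng=(1720, 1740),
          diag="ester"),
        b(1708.5, "C=O stretch of COOH", "carboxylic acids",
          rng=(1707, 1710)),
        b(1686, "C=O stretch", "aromatic ester", diag="aromatic_ester"),
        b(1653, "C=O of amide I", "proteinaceous origin", diag="amide"),
        b(1615, "C-O stretching", "calcium oxalate", diag="oxalate"),
        b(1610, "aromatic C=C stretching / asymmetric C-O stretch in COO-",
          "lignin and other aromatics, or carboxylates", rng=(1600, 1650)),
        b(1550, "N-H in plane (amide II)", "proteinaceous origin",
          diag="amide"),
        b(1510, "aromatic C=C stretching", "lignin/phenolic backbone",
          rng=(1505, 1515), diag="lignin"),
        b(1430, "C-O stretching", "calcium carbonate", rng=(1410, 1450),
          diag="carbonate"),
        b(1426, "symmetric C-O stretch from COO- / OH deformation (COOH)",
          "carboxylate/carboxylic structures"),
        b(1371, "C-H deformations", "phenolic (lignin) and aliphatic structures"),
        b(1315, "C-O stretching", "calcium oxalate", diag="oxalate"),
        b(1312, "C-O stretching", "calcium oxalate", diag="oxalate"),
        b(1265, "C-O stretching of phenolic OH and/or arylmethylethers",
          "lignin backbone", diag="lignin"),
        b(1252.5, "C-O-C stretching / C-N stretching",
          "esters; amide III", rng=(1240, 1265)),
        b(1110, "S-O stretching", "sulphates", rng=(1080, 1140),
          diag="sulphate_other"),
        b(1050, "P-O stretching", "phosphates", rng=(1000, 1100)),
        b(1025, "Si-O stretching", "silicates", rng=(950, 1100)),
        b(1050, "combination of C-O stretching and O-H deformation",
          "polysaccharides", rng=(1030, 1080), diag="polysaccharide"),
        b(874, "C-O in plane bending", "calcium carbonate", diag="carbonate"),
        b(835, "aromatic CH out of plane", "lignin", diag="lignin"),
        b(780, "COO bending", "calcium oxalate", diag="oxalate"),
        b(720, "CH2 wag", "long chain (>C4) alkanes", diag="alkane"),
        b(715, "C-O in plane bending", "calcium carbonate", diag="carbonate"),
        b(645, "S-O bending", "sulphates", rng=(610, 680),
          diag="sulphate_other"),
        b(669, "S-O bending", "gypsum", diag="gypsum"),
        b(597, "S-O bending", "gypsum", diag="gypsum"),
    ]


# ---------------------------------------------------------------------------
# Generator bands: (center cm^-1, sigma cm^-1) used to synthesise spectra.
# Sharp mineral bands get sigma ~10, broad O-H stretches ~40.

GENERATOR_BANDS: dict[str, tuple[float, float]] = {
    "oh_cellulose": (3340.0, 40.0),
    "gypsum_oh_3522": (3522.0, 15.0),
    "gypsum_oh_3400": (3400.0, 15.0),
    "ch2_asym": (2920.0, 12.0),
    "ch2_sym": (2850.0, 12.0),
    "ester": (1735.0, 12.0),
    "aromatic_ester": (1686.0, 10.0),
    "amide_i": (1653.0, 14.0),
    "oxalate_1615": (1615.0, 10.0),
    "broad_1600": (1600.0, 35.0),
    "amide_ii": (1550.0, 14.0),
    "lignin": (1510.0, 12.0),
    "carbonate_1430": (1430.0, 14.0),
    "carboxylate": (1426.0, 14.0),
    "ch_deform": (1371.0, 10.0),
    "oxalate_1312": (1312.0, 10.0),
    "lignin_co": (1265.0, 12.0),
    "sulphate": (1110.0, 25.0),
    "polysaccharide": (1050.0, 30.0),
    "carbonate_874": (874.0, 6.0),
    "aromatic_ch": (835.0, 8.0),
    "oxalate_780": (780.0, 8.0),
    "alkane_wag": (720.0, 6.0),
    "carbonate_715": (715.0, 5.0),
    "gypsum_so_669": (669.0, 10.0),
    "gypsum_so_597": (597.0, 10.0),
}

GYPSUM_BANDS = ("gypsum_oh_3522", "gypsum_oh_3400",
                "gypsum_so_669", "gypsum_so_597")
OXALATE_BANDS = ("oxalate_1615", "oxalate_1312", "oxalate_780")
CARBONATE_BANDS = ("carbonate_1430", "carbonate_874", "carbonate_715")
AMIDE_BANDS = ("amide_i", "amide_ii")


@dataclasses.dataclass
class GroupProfile:
    """Mean band amplitudes (and their CVs) for one ecological group.

    ``band_amplitudes`` maps generator band names to (mean amplitude,
    coefficient of variation); missing bands are absent from the group.
    ``sample_cv`` is the spread of the per-sample lognormal intensity
    multiplier (replicate-to-replicate variability).
    """

    group: Group
    band_amplitudes: Mapping[str, tuple[float, float]]
    sample_cv: float = 0.10
    band_width_sigma: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {k: s for k, (_, s) in GENERATOR_BANDS.items()})

    def __post_init__(self) -> None:
        for name, (mean, cv) in self.band_amplitudes.items():
            if name not in GENERATOR_BANDS:
                raise ValueError(f"unknown generator band {name!r}")
            if mean < 0 or cv < 0:
                raise ValueError(f"negative amplitude/CV for {name!r}")


# Shared organic backbone of a leaf spectrum (amplitude, CV).
_ORGANIC_BASE = {
    "oh_cellulose": (0.25, 0.15),
    "ch2_asym": (0.16, 0.15),
    "ch2_sym": (0.11, 0.15),
    "amide_i": (0.22, 0.12),
    "amide_ii": (0.13, 0.12),
    "lignin": (0.08, 0.20),
    "carboxylate": (0.08, 0.20),
    "ch_deform": (0.05, 0.20),
    "lignin_co": (0.06, 0.20),
    "polysaccharide": (0.30, 0.15),
    "aromatic_ch": (0.03, 0.25),
    "alkane_wag": (0.03, 0.25),
}

#: Oxalate band amplitudes given to the overlap fraction of gypsovags.
OVERLAP_OXALATE = {
    "oxalate_1615": (0.12, 0.25),
    "oxalate_1312": (0.10, 0.25),
    "oxalate_780": (0.06, 0.25),
}


def default_profiles() -> dict[Group, GroupProfile]:
    """The three default group profiles (gypsum only in wide gypsophiles)."""
    gypsovag = dict(_ORGANIC_BASE)
    gypsovag.update({
        "ester": (0.20, 0.15),
        "sulphate": (0.02, 0.30),  # trace only
    })

    narrow = dict(_ORGANIC_BASE)
    narrow.update({
        "ester": (0.12, 0.20),
        "ch2_asym": (0.12, 0.20),
        "ch2_sym": (0.08, 0.20),
        "amide_i": (0.24, 0.12),
        "sulphate": (0.03, 0.30),
        "oxalate_1615": (0.18, 0.25),
        "oxalate_1312": (0.15, 0.25),
        "oxalate_780": (0.08, 0.25),
    })

    wide = dict(_ORGANIC_BASE)
    wide.update({
        "oh_cellulose": (0.12, 0.30),
        "ch2_asym": (0.10, 0.30),
        "ch2_sym": (0.07, 0.30),
        "ester": (0.06, 0.30),
        "amide_i": (0.18, 0.25),
        "amide_ii": (0.10, 0.25),
        "polysaccharide": (0.25, 0.25),
        "gypsum_oh_3522": (0.35, 0.30),
        "gypsum_oh_3400": (0.40, 0.30),
        "gypsum_so_669": (0.25, 0.30),
        "gypsum_so_597": (0.28, 0.30),
        "sulphate": (0.15, 0.30),
        "oxalate_1615": (0.12, 0.60),
        "oxalate_1312": (0.10, 0.60),
        "oxalate_780": (0.05, 0.60),
    })

    return {
        Group.GYPSOVAG: GroupProfile(Group.GYPSOVAG, gypsovag,
                                     sample_cv=0.10),
        Group.NARROW_ENDEMISM: GroupProfile(Group.NARROW_ENDEMISM, narrow,
                                            sample_cv=0.10),
        Group.WIDE_GYPSOPHILE: GroupProfile(Group.WIDE_GYPSOPHILE, wide,
                                            sample_cv=0.25),
    }


def lepidium_like_profile() -> GroupProfile:
    """Optional wide-gypsophile variant without gypsum bands.

    Models the one gypsophile whose spectrum lacks clear gypsum but shows
    the strongest amide bands and a broad ~1600 cm^-1 sulphate/carboxylate
    absorption.  Off by default so the three default classes stay cleanly
    separable.
    """
    amps = dict(_ORGANIC_BASE)
    amps.update({
        "ester": (0.06, 0.30),
        "amide_i": (0.30, 0.15),
        "amide_ii": (0.18, 0.15),
        "broad_1600": (0.25, 0.25),
        "sulphate": (0.10, 0.30),
    })
    return GroupProfile(Group.WIDE_GYPSOPHILE, amps, sample_cv=0.25)


# ---------------------------------------------------------------------------
# Configuration


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    Defaults reproduce the 44-case design: 17 gypsovags, 12 narrow
    endemisms, 15 wide gypsophiles on the canonical 1882-point grid, with
    an overlap fraction of 3/17 of gypsovag samples carrying oxalate (one
    species' replicates).  Elemental coupling coefficients are documented
    constants of the generator.
    """

    group_sizes: dict[Group, int] = dataclasses.field(
        default_factory=lambda: {
            Group.GYPSOVAG: 17,
            Group.NARROW_ENDEMISM: 12,
            Group.WIDE_GYPSOPHILE: 15,
        })
    noise_sd: float = 0.01            # absorbance units, iid per grid point
    baseline: tuple[float, float] = (0.02, 0.01)  # offset, slope across range
    seed: int = 0
    grid: np.ndarray = dataclasses.field(default_factory=default_grid)
    overlap_fraction: float = 3.0 / 17.0
    element_noise_cv: float = 0.04    # relative noise on coupled analytes
    include_lepidium_variant: bool = False

    # Linear coupling coefficients from band areas (absorbance*cm^-1)
    # to analyte concentrations.  K is drawn independently by design.
    alpha_s: float = 0.055        # S (%) per unit sulphate-family area
    alpha_ca: float = 0.09        # Ca (%) per unit gypsum+oxalate+carbonate
    alpha_ash: float = 0.30       # Ash (%) per unit total inorganic area
    ash_baseline: float = 2.0     # organic-ash floor (%)
    alpha_n: float = 2.2          # N (mg/g) per unit amide area
    c_intercept: float = 48.0     # C (%) at zero ash
    c_ash_slope: float = 0.55     # C decrease per Ash %
    na_baseline: float = 0.8      # Na (mg/g)
    alpha_na: float = 0.04
    mg_baseline: float = 2.0      # Mg (mg/g)
    alpha_mg_ox: float = 0.08
    alpha_mg_gyp: float = 0.02
    p_baseline: float = 1.2       # P (mg/g)
    alpha_p: float = 0.12
    k_mean: float = 12.0          # K (mg/g), lognormal, spectrum-independent
    k_cv: float = 0.30

    def __post_init__(self) -> None:
        self.group_sizes = {Group.coerce(g): int(n)
                            for g, n in self.group_sizes.items()}
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0, 1]")
        self.grid = np.asarray(self.grid, dtype=float)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        """Load a flat key:value YAML config; unknown keys are an error."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "baseline" in raw:
            raw["baseline"] = tuple(raw["baseline"])
        if "group_sizes" in raw:
            raw["group_sizes"] = {Group.coerce(k): v
                                  for k, v in raw["group_sizes"].items()}
        return cls(**raw)


# ---------------------------------------------------------------------------
# Simulation


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean lognormal multiplier with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    s2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2), size=size)


def _draw_amplitudes(profile: GroupProfile, rng: np.random.Generator,
                     extra: Mapping[str, tuple[float, float]] | None = None,
                     ) -> dict[str, float]:
    amps = dict(profile.band_amplitudes)
    if extra:
        amps.update(extra)
    scale = _lognormal_factor(rng, profile.sample_cv)
    return {name: mean * _lognormal_factor(rng, cv) * scale
            for name, (mean, cv) in amps.items()}


def _render(grid: np.ndarray, amplitudes: Mapping[str, float],
            baseline: tuple[float, float], noise_sd: float,
            rng: np.random.Generator,
            widths: Mapping[str, float]) -> np.ndarray:
    span = grid.max() - grid.min()
    values = baseline[0] + baseline[1] * (grid - grid.min()) / span
    for name, amp in amplitudes.items():
        center, _ = GENERATOR_BANDS[name]
        sigma = widths.get(name, GENERATOR_BANDS[name][1])
        values = values + amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=grid.size)
    return values


def simulate_spectrum(profile: GroupProfile, config: SyntheticConfig,
                      rng: np.random.Generator,
                      sample_id: str = "synthetic",
                      species_code: str = "",
                      replicate: int = 1,
                      extra_bands: Mapping[str, tuple[float, float]] | None = None,
                      ) -> Spectrum:
    """Draw one synthetic spectrum from a group profile.

    Absorbance = linear baseline + sum of Gaussian bands with lognormally
    drawn amplitudes + iid Gaussian noise.  Reproducible for a fixed rng
    state.
    """
    if config.grid.size == 0:
        raise ValueError("empty wavenumber grid")
    amps = _draw_amplitudes(profile, rng, extra=extra_bands)
    values = _render(config.grid, amps, config.baseline, config.noise_sd,
                     rng, profile.band_width_sigma)
    return Spectrum(sample_id=sample_id, wavenumbers=config.grid,
                    absorbances=values, species_code=species_code,
                    group=profile.group, replicate=replicate)


_SPECIES = {
    Group.GYPSOVAG: ["Ls", "Ro", "Sl", "Tp", "Tt"],
    Group.NARROW_ENDEMISM: ["Ch", "Hm", "Tu", "Tl"],
    Group.WIDE_GYPSOPHILE: ["Hs", "Lu", "Hf", "Gs", "Ot"],
}

_PREFIX = {
    Group.GYPSOVAG: "gv",
    Group.NARROW_ENDEMISM: "ne",
    Group.WIDE_GYPSOPHILE: "wg",
}


def _band_area(name: str, amplitude: float,
               widths: Mapping[str, float]) -> float:
    sigma = widths.get(name, GENERATOR_BANDS[name][1])
    return amplitude * sigma * GAUSS_AREA


def simulate_dataset(config: SyntheticConfig | None = None,
                     ) -> tuple[SpectrumSet, ElementalTable]:
    """Simulate the full study: spectra plus a coupled elemental table.

    Returns one :class:`Spectrum` per sample (default 17 gypsovags, 12
    narrow endemisms, 15 wide gypsophiles) and an :class:`ElementalTable`
    whose analytes are linear in the drawn band areas (S in sulphate-family
    area, Ca in gypsum+oxalate+carbonate, Ash in all inorganics, N in
    amide, C affinely decreasing in Ash) except K, which is drawn
    independently of the spectrum.  The per-sample summed band areas used
    for the coupling are attached to the returned table as
    ``table.band_areas`` (generator diagnostics).
    """
    if config is None:
        config = SyntheticConfig()
    total = sum(config.group_sizes.values())
    if total < 2:
        raise ValueError("need at least 2 samples in total")
    rng = np.random.default_rng(config.seed)
    profiles = default_profiles()

    spectra: list[Spectrum] = []
    area_rows: list[dict[str, float]] = []
    elem_rows: list[dict[str, float]] = []
    ids: list[str] = []

    for group in (Group.GYPSOVAG, Group.NARROW_ENDEMISM,
                  Group.WIDE_GYPSOPHILE):
        n = config.group_sizes.get(group, 0)
        profile = profiles[group]
        species = _SPECIES[group]
        n_overlap = (int(round(config.overlap_fraction * n))
                     if group is Group.GYPSOVAG else 0)
        variant = (lepidium_like_profile()
                   if config.include_lepidium_variant else None)
        for i in range(n):
            sample_id = f"{_PREFIX[group]}{i + 1:02d}"
            sp_code = species[i % len(species)]
            replicate = i // len(species) + 1
            prof_i = profile
            extra = None
            if group is Group.GYPSOVAG and i < n_overlap:
                extra = OVERLAP_OXALATE  # the oxalate-bearing gypsovag
            if (variant is not None and group is Group.WIDE_GYPSOPHILE
                    and sp_code == "Lu"):
                prof_i = variant
            amps = _draw_amplitudes(prof_i, rng, extra=extra)
            values = _render(config.grid, amps, config.baseline,
                             config.noise_sd, rng,
                             prof_i.band_width_sigma)
            spectra.append(Spectrum(
                sample_id=sample_id, wavenumbers=config.grid,
                absorbances=values, species_code=sp_code, group=group,
                replicate=replicate))
            widths = prof_i.band_width_sigma
            areas = {
                "gypsum": sum(_band_area(b, amps.get(b, 0.0), widths)
                              for b in GYPSUM_BANDS),
                "oxalate": sum(_band_area(b, amps.get(b, 0.0), widths)
                               for b in OXALATE_BANDS),
                "carbonate": sum(_band_area(b, amps.get(b, 0.0), widths)
                                 for b in CARBONATE_BANDS),
                "sulphate_other": _band_area(
                    "sulphate", amps.get("sulphate", 0.0), widths),
                "amide": sum(_band_area(b, amps.get(b, 0.0), widths)
                             for b in AMIDE_BANDS),
            }
            areas["total_inorganic"] = (areas["gypsum"] + areas["oxalate"]
                                        + areas["carbonate"]
                                        + areas["sulphate_other"])
            area_rows.append(areas)
            ids.append(sample_id)

    # Elemental coupling: noise is relative (element_noise_cv) and applied
    # multiplicatively so noiseless runs reproduce the linear maps exactly.
    def noisy(x: float) -> float:
        if config.element_noise_cv == 0:
            return x
        return max(0.0, x * (1.0 + rng.normal(0.0, config.element_noise_cv)))

    for areas in area_rows:
        s_pct = noisy(config.alpha_s
                      * (areas["gypsum"] + areas["sulphate_other"]))
        ca_pct = noisy(config.alpha_ca * (areas["gypsum"] + areas["oxalate"]
                                          + areas["carbonate"]))
        ash_pct = noisy(config.ash_baseline
                        + config.alpha_ash * areas["total_inorganic"])
        n_mg = noisy(config.alpha_n * areas["amide"])
        c_pct = noisy(config.c_intercept - config.c_ash_slope * ash_pct)
        na_mg = noisy(config.na_baseline
                      + config.alpha_na * areas["total_inorganic"])
        mg_mg = noisy(config.mg_baseline
                      + config.alpha_mg_ox * areas["oxalate"]
                      + config.alpha_mg_gyp * areas["gypsum"])
        p_mg = noisy(config.p_baseline + config.alpha_p * areas["amide"])
        k_mg = config.k_mean * _lognormal_factor(rng, config.k_cv)
        elem_rows.append({
            "C (%)": c_pct,
            "N (mg/g)": n_mg,
            "C/N": (c_pct * 10.0) / n_mg if n_mg > 0 else 0.0,
            "Na (mg/g)": na_mg,
            "K (mg/g)": k_mg,
            "Ca (%)": ca_pct,
            "Mg (mg/g)": mg_mg,
            "P (mg/g)": p_mg,
            "S (%)": s_pct,
            "Ash (%)": ash_pct,
        })

    table = ElementalTable(pd.DataFrame(elem_rows, index=pd.Index(
        ids, name="sample_id"), columns=list(ANALYTE_COLUMNS)))
    table.band_areas = pd.DataFrame(area_rows, index=table.data.index)
    return SpectrumSet(spectra), table
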