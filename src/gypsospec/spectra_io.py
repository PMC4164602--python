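"""Core data model and file IO for mid-infrared absorbance spectra.

A :class:`Spectrum` is one sample's absorbance trace on a wavenumber grid,
plus identity metadata (sample id, species code, ecological group,
replicate).  A :class:`SpectrumSet` is an ordered collection of spectra,
typically sharing a common grid, and an :class:`ElementalTable` carries the
per-sample elemental composition used for PLS calibration.

Spectra are stored with wavenumbers descending (4000 -> 370 cm^-1, the
plotting convention in mid-IR spectroscopy); readers accept either order
and normalise.  The canonical grid has 1882 evenly spaced points spanning
4000-370 cm^-1, matching the input layer of the group classifier.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Spectrum",
    "SpectrumSet",
    "ElementalTable",
    "default_grid",
    "read_spectra_table",
    "write_spectra_table",
    "read_metadata",
    "write_metadata",
    "read_elemental_table",
    "regrid",
    "ANALYTE_COLUMNS",
]

#: Wavenumber range of the acquisition window, cm^-1.
WAVENUMBER_MAX = 4000.0
WAVENUMBER_MIN = 370.0

#: Number of points on the canonical grid (the classifier's input width).
DEFAULT_GRID_POINTS = 1882

#: Analyte columns of an elemental table, in reporting order.
ANALYTE_COLUMNS = (
    "C (%)",
    "N (mg/g)",
    "C/N",
    "Na (mg/g)",
    "K (mg/g)",
    "Ca (%)",
    "Mg (mg/g)",
    "P (mg/g)",
    "S (%)",
    "Ash (%)",
)

WAVENUMBER_COLUMN = "wavenumber_cm-1"


class Group(str, enum.Enum):
    """Ecological affinity of a plant to gypsum soils."""

    GYPSOVAG = "gypsovag"
    NARROW_ENDEMISM = "narrow_endemism"
    WIDE_GYPSOPHILE = "wide_gypsophile"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def coerce(cls, value: "Group | str") -> "Group":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise ValueError(
                f"unknown group label {value!r}; expected one of "
                f"{[g.value for g in cls]}"
            ) from None


#: The three modelled groups, in confusion-matrix order.
CLASS_ORDER = (Group.GYPSOVAG, Group.NARROW_ENDEMISM, Group.WIDE_GYPSOPHILE)


def default_grid(n_points: int = DEFAULT_GRID_POINTS,
                 high: float = WAVENUMBER_MAX,
                 low: float = WAVENUMBER_MIN) -> np.ndarray:
    """Return the canonical descending wavenumber grid.

    1882 evenly spaced points over 4000-370 cm^-1 (spacing ~1.93 cm^-1).
    """
    return np.linspace(high, low, n_points)


@dataclasses.dataclass
class Spectrum:
    """One sample's absorbance trace plus identity metadata.

    Wavenumbers must be strictly monotonic and the same length as the
    absorbances; all values must be finite.  Wavenumbers given ascending
    are flipped to the descending storage convention.
    """

    sample_id: str
    wavenumbers: np.ndarray
    absorbances: np.ndarray
    species_code: str = ""
    group: Group = Group.UNKNOWN
    replicate: int = 1

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        self.group = Group.coerce(self.group)
        if self.wavenumbers.ndim != 1 or self.absorbances.ndim != 1:
            raise ValueError("wavenumbers and absorbances must be 1-D")
        if self.wavenumbers.size != self.absorbances.size:
            raise ValueError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.absorbances.size} absorbances"
            )
        if self.wavenumbers.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not (np.isfinite(self.wavenumbers).all()
                and np.isfinite(self.absorbances).all()):
            raise ValueError("non-finite values in spectrum")
        dw = np.diff(self.wavenumbers)
        if np.all(dw > 0):  # ascending input: normalise to descending
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.absorbances = self.absorbances[::-1].copy()
        elif not np.all(dw < 0):
            raise ValueError("wavenumbers must be strictly monotonic")
        if int(self.replicate) < 1:
            raise ValueError("replicate must be >= 1")
        self.replicate = int(self.replicate)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_values(self, absorbances: np.ndarray, **meta) -> "Spectrum":
        """Copy of this spectrum with new absorbances (same grid/metadata)."""
        kw = dict(
            sample_id=self.sample_id,
            wavenumbers=self.wavenumbers.copy(),
            absorbances=np.asarray(absorbances, dtype=float),
            species_code=self.species_code,
            group=self.group,
            replicate=self.replicate,
        )
        kw.update(meta)
        return Spectrum(**kw)


class SpectrumSet:
    """Ordered collection of spectra with unique sample ids.

    If every member shares the same wavenumber grid, :attr:`grid` holds it;
    otherwise :attr:`grid` is ``None`` and matrix-producing operations
    refuse to run.
    """

    def __init__(self, spectra: Iterable[Spectrum]):
        self.spectra: list[Spectrum] = list(spectra)
        ids = [s.sample_id for s in self.spectra]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate sample_id(s): {sorted(dupes)}")

    @property
    def grid(self) -> np.ndarray | None:
        if not self.spectra:
            return None
        g = self.spectra[0].wavenumbers
        for s in self.spectra[1:]:
            if s.wavenumbers.size != g.size or not np.array_equal(
                    s.wavenumbers, g):
                return None
        return g

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]

    @property
    def groups(self) -> list[Group]:
        return [s.group for s in self.spectra]

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, key: int | str) -> Spectrum:
        if isinstance(key, str):
            for s in self.spectra:
                if s.sample_id == key:
                    return s
            raise KeyError(key)
        return self.spectra[key]

    def to_matrix(self) -> np.ndarray:
        """Samples x grid-points absorbance matrix (common grid required)."""
        if self.grid is None:
            raise ValueError("spectra do not share a common grid")
        return np.vstack([s.absorbances for s in self.spectra])


class ElementalTable:
    """Per-sample elemental composition (the ten reported analytes).

    Thin wrapper over a DataFrame indexed by sample_id with the columns of
    :data:`ANALYTE_COLUMNS`.  Concentrations must be non-negative.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in ANALYTE_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"missing analyte column(s): {missing}")
        df = data.loc[:, list(ANALYTE_COLUMNS)].astype(float)
        if df.index.has_duplicates:
            raise ValueError("duplicate sample_id in elemental table")
        if (df.values < 0).any():
            raise ValueError("negative concentration in elemental table")
        df.index.name = "sample_id"
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def analyte(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def aligned_to(self, sample_ids: Sequence[str]) -> "ElementalTable":
        """Rows reordered to match ``sample_ids`` (must all be present)."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValueError(f"elemental table lacks sample(s): {missing}")
        return ElementalTable(self.data.loc[list(sample_ids)])

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# File IO


def _read_wide_csv(path: Path) -> SpectrumSet:
    df = pd.read_csv(path)
    if WAVENUMBER_COLUMN not in df.columns:
        raise ValueError(
            f"{path}: expected a '{WAVENUMBER_COLUMN}' column, "
            f"got {list(df.columns)[:5]}"
        )
    # pandas silently mangles duplicate headers; check the raw header line
    with open(path) as fh:
        raw_header = [c.strip().strip('"') for c in
                      fh.readline().rstrip("\n").split(",")]
    dupes = {c for c in raw_header if raw_header.count(c) > 1}
    if dupes:
        raise ValueError(
            f"{path}: duplicate sample column name(s): {sorted(dupes)}")
    sample_cols = [c for c in df.columns if c != WAVENUMBER_COLUMN]
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(
            f"{path}: unparseable numeric cell(s): {exc}") from None
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: unparseable or missing numeric cell(s)")
    wn = df[WAVENUMBER_COLUMN].to_numpy(dtype=float)
    spectra = [
        Spectrum(sample_id=c, wavenumbers=wn,
                 absorbances=df[c].to_numpy(dtype=float))
        for c in sample_cols
    ]
    return SpectrumSet(spectra)


def _read_two_column_dir(path: Path) -> SpectrumSet:
    files = sorted(p for p in path.iterdir() if p.suffix in {".csv", ".txt"})
    if not files:
        raise ValueError(f"{path}: no .csv/.txt spectrum files")
    spectra = []
    for f in files:
        df = pd.read_csv(f, header=None, comment="#")
        if df.shape[1] != 2:
            raise ValueError(f"{f}: expected exactly 2 columns")
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError(f"{f}: unparseable numeric cell(s)")
        spectra.append(
            Spectrum(sample_id=f.stem, wavenumbers=arr[:, 0],
                     absorbances=arr[:, 1]))
    return SpectrumSet(spectra)


def read_spectra_table(path: str | Path, dialect: str = "wide_csv",
                       metadata: str | Path | None = None) -> SpectrumSet:
    """Read spectra from disk.

    Parameters
    ----------
    path
        CSV file (``wide_csv``: one ``wavenumber_cm-1`` column plus one
        column per sample) or directory of two-column per-sample files
        (``two_column_dir``).
    dialect
        ``"wide_csv"`` or ``"two_column_dir"``.
    metadata
        Optional sidecar CSV with columns sample_id, species_code, group,
        replicate; applied to the returned set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "wide_csv":
        sset = _read_wide_csv(path)
    elif dialect == "two_column_dir":
        sset = _read_two_column_dir(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if metadata is not None:
        apply_metadata(sset, read_metadata(metadata))
    return sset


def write_spectra_table(sset: SpectrumSet, path: str | Path,
                        float_format: str = "%.8g") -> None:
    """Write a common-grid SpectrumSet as a wide CSV.

    Values round-trip through :func:`read_spectra_table` to within the
    print precision of ``float_format``.
    """
    if len(sset) == 0:
        raise ValueError("refusing to write an empty SpectrumSet")
    grid = sset.grid
    if grid is None:
        raise ValueError("spectra do not share a common grid")
    df = pd.DataFrame({WAVENUMBER_COLUMN: grid})
    for s in sset:
        df[s.sample_id] = s.absorbances
    df.to_csv(path, index=False, float_format=float_format)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sidecar metadata CSV (sample_id, species_code, group, replicate)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "species_code": str})
    required = {"sample_id", "species_code", "group", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata column(s) {sorted(missing)}")
    return df.set_index("sample_id")


def write_metadata(sset: SpectrumSet, path: str | Path) -> None:
    pd.DataFrame({
        "sample_id": [s.sample_id for s in sset],
        "species_code": [s.species_code for s in sset],
        "group": [s.group.value for s in sset],
        "replicate": [s.replicate for s in sset],
    }).to_csv(path, index=False)


def apply_metadata(sset: SpectrumSet, meta: pd.DataFrame) -> None:
    """Attach sidecar metadata to matching spectra in place."""
    for s in sset:
        if s.sample_id in meta.index:
            row = meta.loc[s.sample_id]
            s.species_code = str(row["species_code"])
            s.group = Group.coerce(row["group"])
            s.replicate = int(row["replicate"])


def read_elemental_table(path: str | Path) -> ElementalTable:
    """Read an elemental composition CSV (sample_id + the ten analytes)."""
    df = pd.read_csv(path, index_col="sample_id")
    return ElementalTable(df)


def regrid(spectrum: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto a new wavenumber grid.

    The new grid must lie within the spectrum's range: extrapolation is an
    error.  Metadata is preserved.  Regridding onto the spectrum's own grid
    is the identity.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = spectrum.wavenumbers.min(), spectrum.wavenumbers.max()
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(
            f"requested grid [{grid.min()}, {grid.max()}] extends outside "
            f"the spectrum's range [{lo}, {hi}]"
        )
    # np.interp wants ascending abscissae; storage is descending.
    asc_wn = spectrum.wavenumbers[::-1]
    asc_ab = spectrum.absorbances[::-1]
    values = np.interp(grid, asc_wn, asc_ab)
    return Spectrum(
        sample_id=spectrum.sample_id,
        wavenumbers=grid,
        absorbances=values,
        species_code=spectrum.species_code,
        group=spectrum.group,
        replicate=spectrum.replicate,
    )
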