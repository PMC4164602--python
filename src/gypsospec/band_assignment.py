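"""Peak detection and assignment against the reference band library.

Peaks are local maxima of the absorbance trace (scipy's peak finder with
prominence and separation thresholds); each is matched to the nearest
reference band within a tolerance (default 8 cm^-1, about twice the
acquisition resolution).  Compound-level feature flags then summarise the
group-diagnostic evidence: gypsum requires both an O-H stretch match
(3522/3400) and an S-O bend match (669/597), which keeps broad water
bands from counting as gypsum; oxalate requires two of its three bands
(1615, 1312/1315, 780); and so on.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .spectra_io import Spectrum
from .synthetic_data import BandReference, make_band_library

__all__ = [
    "Peak",
    "PeakAssignment",
    "FeatureFlags",
    "detect_peaks",
    "assign_peaks",
    "summarise_features",
]


@dataclasses.dataclass(frozen=True)
class Peak:
    position: float  # cm^-1
    height: float    # absorbance


@dataclasses.dataclass(frozen=True)
class PeakAssignment:
    """A detected peak and the reference band it matched, if any."""

    peak_position: float
    peak_height: float
    matched_band: BandReference | None = None
    distance: float | None = None

    def __post_init__(self) -> None:
        if self.matched_band is None and self.distance is not None:
            raise ValueError("unmatched peak cannot carry a distance")


@dataclasses.dataclass
class FeatureFlags:
    """Compound-level presence flags with their peak evidence."""

    gypsum_present: bool = False
    oxalate_present: bool = False
    ester_present: bool = False
    amide_present: bool = False
    carbonate_present: bool = False
    evidence: dict = dataclasses.field(default_factory=dict)


def detect_peaks(spectrum: Spectrum, min_prominence: float = 0.01,
                 min_separation: float = 10.0) -> list[Peak]:
    """Local maxima with at least the given prominence and separation.

    Returned sorted by wavenumber descending (the storage convention).
    """
    values = spectrum.absorbances
    step = float(np.mean(np.abs(np.diff(spectrum.wavenumbers))))
    distance = max(1, int(round(min_separation / step)))
    idx, _ = find_peaks(values, prominence=min_prominence, distance=distance)
    peaks = [Peak(position=float(spectrum.wavenumbers[i]),
                  height=float(values[i])) for i in idx]
    return sorted(peaks, key=lambda p: -p.position)


def assign_peaks(peaks: Sequence[Peak],
                 library: Sequence[BandReference] | None = None,
                 tolerance: float = 8.0) -> list[PeakAssignment]:
    """Match each peak to the nearest reference band within tolerance.

    A band range matches if the peak falls inside it or within tolerance
    of its nearer edge.  Bands may be reused by several peaks.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if library is None:
        library = make_band_library()
    if not library:
        raise ValueError("empty band library")
    assignments = []
    for peak in peaks:
        best, best_d = None, None
        for band in library:
            d = band.distance_to(peak.position)
            if d <= tolerance and (best_d is None or d < best_d):
                best, best_d = band, d
        assignments.append(PeakAssignment(
            peak_position=peak.position, peak_height=peak.height,
            matched_band=best, distance=best_d))
    return assignments


def _matches(assignments: Sequence[PeakAssignment],
             centers: Sequence[float], tol: float = 8.0
             ) -> list[PeakAssignment]:
    out = []
    for a in assignments:
        if a.matched_band is None:
            continue
        if any(abs(a.matched_band.center - c) <= tol for c in centers):
            out.append(a)
    return out


def _range_matches(assignments: Sequence[PeakAssignment],
                   low: float, high: float) -> list[PeakAssignment]:
    return [a for a in assignments if a.matched_band is not None
            and low <= a.peak_position <= high]


def summarise_features(assignments: Sequence[PeakAssignment]
                       ) -> FeatureFlags:
    """Roll peak assignments up into compound presence flags.

    * gypsum: at least one O-H match (3522/3400) AND one S-O match
      (669/597);
    * oxalate: at least two of {1615, 1312/1315, 780};
    * ester: a match in 1740-1720;
    * amide: 1653 or 1550;
    * carbonate: at least two of {1450-1410, 874, 715}.
    """
    flags = FeatureFlags()

    oh = _matches(assignments, [3522, 3400], tol=5)
    so = _matches(assignments, [669, 597], tol=5)
    if oh and so:
        flags.gypsum_present = True
        flags.evidence["gypsum"] = oh + so

    ox_groups = [_matches(assignments, [1615], tol=5),
                 _matches(assignments, [1312, 1315], tol=5),
                 _matches(assignments, [780], tol=5)]
    hit = [g for g in ox_groups if g]
    if len(hit) >= 2:
        flags.oxalate_present = True
        flags.evidence["oxalate"] = [a for g in hit for a in g]

    ester = _range_matches(assignments, 1720 - 8, 1740 + 8)
    ester = [a for a in ester if a.matched_band.characterisation == "esters"]
    if ester:
        flags.ester_present = True
        flags.evidence["ester"] = ester

    amide = _matches(assignments, [1653, 1550], tol=5)
    if amide:
        flags.amide_present = True
        flags.evidence["amide"] = amide

    carb_groups = [_range_matches(assignments, 1410, 1450),
                   _matches(assignments, [874], tol=5),
                   _matches(assignments, [715], tol=5)]
    carb_groups[0] = [a for a in carb_groups[0]
                      if a.matched_band.characterisation == "calcium carbonate"]
    hit = [g for g in carb_groups if g]
    if len(hit) >= 2:
        flags.carbonate_present = True
        flags.evidence["carbonate"] = [a for g in hit for a in g]

    return flags
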