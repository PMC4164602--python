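"""Two-stage spectral preprocessing for the group classifier.

Stage 1 ("flattening"): subtract from each point the mean of a moving
window centred on it (width 101 by default, i.e. 50 points to either
side), which zeroes flat regions and broad baselines while keeping sharp
band structure.  Stage 2: divide each derived spectrum by its maximum
absolute value, normalising it into [-1, 1].
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .spectra_io import Spectrum, SpectrumSet

__all__ = [
    "PreprocessConfig",
    "moving_average",
    "detrend",
    "normalize_maxabs",
    "preprocess_set",
]


@dataclasses.dataclass
class PreprocessConfig:
    """Settings for the two preprocessing stages.

    ``window_width`` must be odd (a centred window).  ``edge_policy``
    "shrink" truncates the window at the spectrum ends; "reflect" pads by
    mirroring.  ``normalize`` toggles the max-abs stage.
    """

    window_width: int = 101
    edge_policy: str = "shrink"
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.window_width % 2 == 0 or self.window_width < 3:
            raise ValueError(
                f"window_width must be odd and >= 3, got {self.window_width}")
        if self.edge_policy not in ("shrink", "reflect"):
            raise ValueError(f"unknown edge_policy {self.edge_policy!r}")


def moving_average(values, window_width: int = 101,
                   edge_policy: str = "shrink") -> np.ndarray:
    """Centred moving mean of a sequence.

    Under "shrink" the window is truncated at the edges (the mean is over
    however many points fall inside); under "reflect" the sequence is
    mirror-padded by half a window first, which requires the sequence to
    be at least as long as the window.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be 1-D")
    if window_width % 2 == 0 or window_width < 1:
        raise ValueError(f"window_width must be odd, got {window_width}")
    n = values.size
    half = window_width // 2
    kernel = np.ones(window_width)
    if edge_policy == "shrink":
        if n < 1:
            raise ValueError("empty sequence")
        sums = np.convolve(values, kernel, mode="same")
        counts = np.convolve(np.ones(n), kernel, mode="same")
        return sums / counts
    if edge_policy == "reflect":
        if n < window_width:
            raise ValueError(
                f"sequence of length {n} shorter than window {window_width}")
        padded = np.pad(values, half, mode="reflect")
        return np.convolve(padded, kernel, mode="valid") / window_width
    raise ValueError(f"unknown edge_policy {edge_policy!r}")


def detrend(spectrum: Spectrum, config: PreprocessConfig | None = None
            ) -> Spectrum:
    """Subtract the moving-window mean from a spectrum ("flattening").

    Constant spectra map to zero; additive offsets are removed entirely.
    Grid and metadata are unchanged.
    """
    if config is None:
        config = PreprocessConfig()
    avg = moving_average(spectrum.absorbances, config.window_width,
                         config.edge_policy)
    return spectrum.with_values(spectrum.absorbances - avg)


def normalize_maxabs(values) -> np.ndarray:
    """Divide a sequence by its maximum absolute value.

    The result lies in [-1, 1] with at least one element of magnitude
    exactly 1, except for an all-zero input, which is returned unchanged.
    """
    values = np.asarray(values, dtype=float)
    peak = np.max(np.abs(values)) if values.size else 0.0
    if peak == 0.0:
        return values.copy()
    return values / peak


def preprocess_set(sset: SpectrumSet, config: PreprocessConfig | None = None
                   ) -> tuple[np.ndarray, list[str]]:
    """Preprocess every spectrum of a common-grid set into a matrix.

    Row i is ``normalize_maxabs(detrend(spectrum i))``; row order follows
    the set order and the returned sample_ids.
    """
    if config is None:
        config = PreprocessConfig()
    if sset.grid is None:
        raise ValueError("spectra do not share a common grid")
    rows = []
    for s in sset:
        flattened = detrend(s, config).absorbances
        rows.append(normalize_maxabs(flattened) if config.normalize
                    else flattened)
    return np.vstack(rows), sset.sample_ids
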