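"""Classification metrics: confusion matrix, per-output-node errors, and
the random-output baseline.

The confusion matrix follows the convention rows = observed group,
columns = predicted group.  Per-node MAE and RMSE measure, over all
cases, the error between a network's output at one node and the 0/1
target for that node.  Purely random outputs uniform on [0, 1] give a
node RMSE of sqrt(1/3) ~ 0.577, so any useful model should sit well
below that; the baseline simulator makes the comparison concrete.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .spectra_io import CLASS_ORDER, Group

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "node_errors",
    "random_baseline_rmse",
]


@dataclasses.dataclass
class ConfusionMatrix:
    """Counts of observed (rows) vs predicted (columns) group labels."""

    groups: tuple[Group, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.groups)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square in the group count")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    def row_totals(self) -> np.ndarray:
        """Observed group sizes."""
        return self.counts.sum(axis=1)

    def to_frame(self):
        import pandas as pd
        names = [g.value for g in self.groups]
        return pd.DataFrame(self.counts, index=pd.Index(names, name="observed"),
                            columns=pd.Index(names, name="predicted"))


def confusion_matrix(observed: Sequence, predicted: Sequence,
                     groups: tuple[Group, ...] = CLASS_ORDER
                     ) -> ConfusionMatrix:
    """Tally (observed, predicted) label pairs into a confusion matrix."""
    if len(observed) != len(predicted):
        raise ValueError(
            f"{len(observed)} observed vs {len(predicted)} predicted labels")
    index = {g: k for k, g in enumerate(groups)}
    counts = np.zeros((len(groups), len(groups)), dtype=int)
    for obs, pred in zip(observed, predicted):
        obs = Group.coerce(obs)
        pred = Group.coerce(pred)
        if obs not in index or pred not in index:
            raise ValueError(f"label {obs} or {pred} not in {groups}")
        counts[index[obs], index[pred]] += 1
    return ConfusionMatrix(groups=groups, counts=counts)


def node_errors(outputs: np.ndarray, targets: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-node MAE and RMSE of outputs against one-hot 0/1 targets."""
    outputs = np.asarray(outputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if outputs.shape != targets.shape:
        raise ValueError(
            f"shape mismatch: outputs {outputs.shape} vs targets "
            f"{targets.shape}")
    if not np.isin(targets, (0.0, 1.0)).all() \
            or not np.all(targets.sum(axis=1) == 1):
        raise ValueError("targets must be one-hot rows of {0,1}")
    err = outputs - targets
    mae = np.mean(np.abs(err), axis=0)
    rmse = np.sqrt(np.mean(err ** 2, axis=0))
    return mae, rmse


def random_baseline_rmse(n_cases: int, group_proportions: Sequence[float],
                         seed: int = 0) -> np.ndarray:
    """Per-node RMSE of uniform-random outputs against sampled targets.

    Targets are one-hot rows drawn with the given class proportions;
    outputs are iid uniform on [0, 1].  The expected node RMSE is
    sqrt(1/3) regardless of the proportions, since E[(U - b)^2] = 1/3 for
    b in {0, 1}.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    props = np.asarray(group_proportions, dtype=float)
    props = props / props.sum()
    rng = np.random.default_rng(seed)
    k = props.size
    classes = rng.choice(k, size=n_cases, p=props)
    targets = np.zeros((n_cases, k))
    targets[np.arange(n_cases), classes] = 1.0
    outputs = rng.uniform(0.0, 1.0, size=(n_cases, k))
    err = outputs - targets
    return np.sqrt(np.mean(err ** 2, axis=0))
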