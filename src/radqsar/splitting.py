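"""Kennard-Stone representative subset selection and train/test splitting.

The Kennard-Stone algorithm picks a subset with maximal coverage of
descriptor space: seed with the globally most distant pair, then repeatedly
add the candidate whose minimum Euclidean distance to the already-selected
points is largest (maximin). Applied here to choose the *training* set, so
the training compounds span the descriptor space and the remainder forms the
test set. Distances are computed on the autoscaled full descriptor matrix so
large-magnitude descriptors (surface area, polarizability) do not dominate
bond lengths.

Ties at any step are broken by lowest row index, making the split fully
deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data import DataSet, DescriptorTable, autoscale
from .errors import DegenerateInputError, RadqsarError, SplitError

__all__ = ["SplitResult", "pairwise_distances", "kennard_stone_select",
           "split_dataset"]


@dataclass(frozen=True)
class SplitResult:
    """Outcome of a Kennard-Stone split.

    ``selection_order`` records the order in which training compounds were
    picked (the first two being the most distant pair)."""

    train_ids: list[str]
    test_ids: list[str]
    selection_order: list[str]
    distance_metric: str = "euclidean on autoscaled descriptors"

    def to_dict(self) -> dict:
        return {"train": self.train_ids, "test": self.test_ids,
                "order": self.selection_order, "metric": self.distance_metric}


def pairwise_distances(X: np.ndarray) -> np.ndarray:
    """Symmetric n x n Euclidean distance matrix with zero diagonal."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DegenerateInputError("need a 2-D matrix with at least 2 rows")
    if not np.isfinite(X).all():
        raise RadqsarError("non-finite values in descriptor matrix")
    return squareform(pdist(X, metric="euclidean"))


def kennard_stone_select(X: np.ndarray, k: int) -> list[int]:
    """Return ``k`` row indices chosen by the Kennard-Stone maximin rule.

    The first two indices are a globally most-distant pair; each subsequent
    pick maximizes its minimum distance to the points already selected. Ties
    are broken toward the lowest row index (for the seed pair, lexicographic
    on (i, j)), so the output is deterministic.
    """
    dist = pairwise_distances(X)
    n = dist.shape[0]
    if not 2 <= k <= n:
        raise RadqsarError(f"k must be in [2, {n}], got {k}")

    # seed: lexicographically first pair attaining the maximum distance
    iu = np.triu_indices(n, k=1)
    flat = dist[iu]
    best = np.flatnonzero(flat == flat.max())[0]
    selected = [int(iu[0][best]), int(iu[1][best])]

    min_dist = np.minimum(dist[selected[0]], dist[selected[1]])
    chosen = np.zeros(n, dtype=bool)
    chosen[selected] = True
    while len(selected) < k:
        masked = np.where(chosen, -np.inf, min_dist)
        nxt = int(np.argmax(masked))  # argmax returns the first (lowest) index
        selected.append(nxt)
        chosen[nxt] = True
        min_dist = np.minimum(min_dist, dist[nxt])
    return selected


def train_size(n: int, fraction: float) -> int:
    """Round-to-nearest train count with ties resolved upward."""
    return int(math.floor(fraction * n + 0.5))


def split_dataset(ds: DataSet, fraction: float = 0.8) -> SplitResult:
    """Split a dataset into Kennard-Stone training compounds (a ``fraction``
    share, rounded to nearest with ties upward) and the remaining test set.

    For the canonical 15-compound table at fraction 0.8 this yields a 12/3
    split. A test set of size 1 is allowed with a warning; an empty test or
    a training set smaller than 2 raises :class:`SplitError`.
    """
    if not 0.0 < fraction < 1.0:
        raise SplitError(f"fraction must be in (0, 1), got {fraction}")
    n = ds.n_compounds
    k = train_size(n, fraction)
    if k < 2:
        raise SplitError(f"training set of size {k} is unusable (need >= 2)")
    if k >= n:
        raise SplitError(f"fraction {fraction} leaves an empty test set for n={n}")
    if n - k == 1:
        warnings.warn("test set has a single compound; test statistics will "
                      "be fragile", UserWarning, stacklevel=2)

    scaled, _ = autoscale(ds.descriptors)
    order = kennard_stone_select(scaled.values, k)
    ids = ds.compound_ids
    train = sorted((ids[i] for i in order), key=ids.index)
    test = [c for c in ids if c not in set(train)]
    return SplitResult(train_ids=train, test_ids=test,
                       selection_order=[ids[i] for i in order])


def apply_split(ds: DataSet, split: SplitResult) -> tuple[DataSet, DataSet]:
    """Materialize (train, test) datasets from a :class:`SplitResult`."""
    return ds.subset(split.train_ids), ds.subset(split.test_ids)
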