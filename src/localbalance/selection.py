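"""Per-class nearest-neighbour training-subset selection.

This is the heart of the local-balanced model: for one test sample, rank all
labeled training samples by plain Euclidean distance in the full feature
space, then take the ``n_low`` nearest ``Low`` samples and, *independently*,
the ``n_hi`` nearest ``Hi`` samples.  Because the two per-class counts are
independent tunable parameters, the training subset is balanced (or
deliberately ratioed) even when the farthest included neighbour of one class
lies much farther from the test sample than that of the other class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_io import GROUP_HI, GROUP_LOW, DataError, LabeledDataset


@dataclass(frozen=True)
class GroupSizes:
    """The tunable pair of per-class training-subset sizes."""

    n_low: int
    n_hi: int

    def __post_init__(self) -> None:
        if self.n_low < 1 or self.n_hi < 1:
            raise ValueError(f"group sizes must be >= 1, got ({self.n_low}, {self.n_hi})")


@dataclass
class DistanceVector:
    """Euclidean distances from one test sample to every training sample."""

    test_id: str
    train_ids: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.shape != (len(self.train_ids),):
            raise ValueError("distances and train_ids must align")
        if self.test_id in self.train_ids:
            raise ValueError(f"test sample {self.test_id!r} appears among training samples")
        if np.any(self.distances < 0):
            raise ValueError("distances must be nonnegative")


@dataclass
class BalancedSubset:
    """The selected per-class nearest training samples for one test sample.

    ``low_ids`` / ``hi_ids`` are ordered nearest-first.  ``clamped`` is True
    when a class held fewer training samples than requested, in which case the
    whole class was taken (the clamped limit, where the local-balanced model
    coincides with the global base model).
    """

    low_ids: list[str]
    hi_ids: list[str]
    requested: GroupSizes
    clamped: bool

    @property
    def ids(self) -> list[str]:
        return self.low_ids + self.hi_ids


def euclidean_distances_to(x: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Distances from one point ``x`` to each row of ``X`` in full feature space."""
    diff = X - np.asarray(x, dtype=float)[None, :]
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def distances_to_test(ds: LabeledDataset, test_id: str) -> DistanceVector:
    """Distances from ``test_id`` to every *other* sample in the dataset.

    The test sample itself is excluded, so the result can directly feed
    leave-one-out subset selection.
    """
    i = ds.matrix.row_index(test_id)  # raises KeyError for unknown ids
    if ds.n_samples < 2:
        raise DataError("need at least one sample besides the test sample")
    mask = np.ones(ds.n_samples, dtype=bool)
    mask[i] = False
    dist = euclidean_distances_to(ds.X[i], ds.X[mask])
    train_ids = [s for j, s in enumerate(ds.sample_ids) if j != i]
    return DistanceVector(test_id, train_ids, dist)


def select_balanced_subset(
    dv: DistanceVector,
    labels: Mapping[str, str],
    sizes: GroupSizes,
    warn_on_clamp: bool = True,
) -> BalancedSubset:
    """Select the ``n_low`` nearest Low and ``n_hi`` nearest Hi training samples.

    Ties at equal distance are broken by the input (storage) order of the
    training samples, which makes selection deterministic.  Oversized requests
    clamp to the class size with a warning rather than erroring, so "use the
    whole class" is expressible as a large size.
    """
    per_class: dict[str, list[int]] = {GROUP_LOW: [], GROUP_HI: []}
    for j, sid in enumerate(dv.train_ids):
        lbl = labels[sid]
        if lbl not in per_class:
            raise DataError(f"sample {sid!r} has label {lbl!r}, expected Low/Hi")
        per_class[lbl].append(j)
    for grp, idx in per_class.items():
        if not idx:
            raise DataError(f"no training samples in class {grp!r} for test {dv.test_id!r}")

    def nearest(idx: list[int], k: int) -> list[str]:
        d = dv.distances[idx]
        order = np.argsort(d, kind="stable")  # stable => ties by input order
        return [dv.train_ids[idx[o]] for o in order[:k]]

    n_low_avail = len(per_class[GROUP_LOW])
    n_hi_avail = len(per_class[GROUP_HI])
    clamped = sizes.n_low > n_low_avail or sizes.n_hi > n_hi_avail
    if clamped and warn_on_clamp:
        warnings.warn(
            f"requested sizes ({sizes.n_low}, {sizes.n_hi}) exceed available "
            f"({n_low_avail}, {n_hi_avail}); clamping to the full class",
            stacklevel=2,
        )
    low_ids = nearest(per_class[GROUP_LOW], min(sizes.n_low, n_low_avail))
    hi_ids = nearest(per_class[GROUP_HI], min(sizes.n_hi, n_hi_avail))
    return BalancedSubset(low_ids, hi_ids, sizes, clamped)


def select_for_test_point(
    train: LabeledDataset,
    x_test: np.ndarray,
    test_id: str,
    sizes: GroupSizes,
    warn_on_clamp: bool = True,
) -> tuple[DistanceVector, BalancedSubset]:
    """Distance + selection for an external test point against a training set."""
    if test_id in train.sample_ids:
        raise DataError(f"test sample {test_id!r} overlaps the training set")
    dist = euclidean_distances_to(x_test, train.X)
    dv = DistanceVector(test_id, list(train.sample_ids), dist)
    labels = dict(zip(train.sample_ids, train.labels))
    return dv, select_balanced_subset(dv, labels, sizes, warn_on_clamp=warn_on_clamp)
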