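"""Pairwise feature-ratio expansion.

Expanding a feature table with every non-redundant pairwise ratio ``f_i/f_j``
(i < j) turns relationships *between* features into features of their own.
Because a per-sample multiplicative intensity drift multiplies numerator and
denominator alike, every ratio feature is exactly invariant to it — which is
why the expansion helps classifiers whose scoring treats features
independently on signal-shape problems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import FeatureMatrix, LabeledDataset


@dataclass(frozen=True)
class RatioExpansion:
    """Plan for one expansion: source ids, expanded ids, and the epsilon used
    to guard zero denominators."""

    source_feature_ids: tuple[str, ...]
    expanded_feature_ids: tuple[str, ...]
    epsilon: float


def default_epsilon(X: np.ndarray) -> float:
    """1e-9 x the median absolute nonzero value (1e-9 if everything is zero)."""
    nz = np.abs(X[X != 0])
    if nz.size == 0:
        return 1e-9
    return 1e-9 * float(np.median(nz))


def plan_ratio_expansion(feature_ids: list[str], epsilon: float) -> RatioExpansion:
    p = len(feature_ids)
    expanded = list(feature_ids)
    for i in range(p):
        for j in range(i + 1, p):
            expanded.append(f"{feature_ids[i]}/{feature_ids[j]}")
    return RatioExpansion(tuple(feature_ids), tuple(expanded), epsilon)


def build_ratio_features(ds: LabeledDataset, epsilon: float | None = None) -> LabeledDataset:
    """Append all non-redundant pairwise ratios to a feature table.

    The output keeps the ``p`` original features in input order, followed by
    ``value_i / value_j`` for every pair ``i < j`` in lexicographic (i, j)
    order — ``p + p(p-1)/2`` features in total.  Denominator entries with
    magnitude below ``epsilon`` are replaced by a sign-preserving ``epsilon``
    before dividing (MS tables contain exact zeros).  A single-feature table
    is returned unchanged.
    """
    p = ds.matrix.n_features
    if p <= 1:
        return ds
    if epsilon is None:
        epsilon = default_epsilon(ds.X)
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")

    plan = plan_ratio_expansion(list(ds.feature_ids), epsilon)
    X = ds.X
    denom = np.where(np.abs(X) < epsilon, np.where(X < 0, -epsilon, epsilon), X)
    iu, ju = np.triu_indices(p, k=1)  # row-major: lexicographic (i, j)
    ratios = X[:, iu] / denom[:, ju]
    out = np.concatenate([X, ratios], axis=1)
    fm = FeatureMatrix(out, list(ds.sample_ids), list(plan.expanded_feature_ids))
    raw = None if ds.raw_labels is None else ds.raw_labels.copy()
    return LabeledDataset(fm, ds.labels.copy(), raw)
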