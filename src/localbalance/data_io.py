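"""Loading, orientation, labeling and preprocessing of two-class feature tables.

The canonical in-memory orientation is samples-in-rows / features-in-columns.
Class labels are normalized to the two group names ``"Low"`` and ``"Hi"``;
by convention ``Low`` is the minority / target class in imbalanced problems.

Preprocessing implemented here mirrors what practitioners routinely apply to
mass-spectrometry feature tables before classification:

* total-signal normalization per sample (rows summing to 100 % or to 1.0),
* per-column z-scoring (mean 0, sample standard deviation 1, ``ddof=1``),
* removal of features that are zero in every sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

GROUP_LOW = "Low"
GROUP_HI = "Hi"
GROUPS = (GROUP_LOW, GROUP_HI)


class DataError(ValueError):
    """Raised for malformed or contract-violating input data."""


class ConfigError(ValueError):
    """Raised for invalid user configuration (missing columns, bad mappings...)."""


@dataclass
class FeatureMatrix:
    """A numeric samples x features table with stable identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Feature values; must be finite (no NaN / inf).
    sample_ids : sequence of str
        Unique, ordered sample identifiers (one per row).
    feature_ids : sequence of str
        Unique, ordered feature identifiers (one per column).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise DataError("feature matrix must be 2-dimensional")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise DataError(f"{n} rows but {len(self.sample_ids)} sample ids")
        if p != len(self.feature_ids):
            raise DataError(f"{p} columns but {len(self.feature_ids)} feature ids")
        if len(set(self.sample_ids)) != n:
            raise DataError("sample ids must be unique")
        if len(set(self.feature_ids)) != p:
            raise DataError("feature ids must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                "non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, feature {self.feature_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def row_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None


@dataclass
class LabeledDataset:
    """A :class:`FeatureMatrix` plus one class label per sample.

    ``labels`` normally holds the two canonical group names (:data:`GROUP_LOW`,
    :data:`GROUP_HI`).  Loaders keep the original class names in ``raw_labels``
    so multi-class sources can be binarized downstream with
    :func:`binarize_by_target`.
    """

    matrix: FeatureMatrix
    labels: np.ndarray
    raw_labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (self.matrix.n_samples,):
            raise DataError("labels must be one per sample")
        if self.raw_labels is not None:
            self.raw_labels = np.asarray(self.raw_labels, dtype=object)
            if self.raw_labels.shape != self.labels.shape:
                raise DataError("raw_labels must be one per sample")

    # -- convenience accessors -------------------------------------------------
    @property
    def X(self) -> np.ndarray:
        return self.matrix.values

    @property
    def y(self) -> np.ndarray:
        return self.labels

    @property
    def sample_ids(self) -> list[str]:
        return self.matrix.sample_ids

    @property
    def feature_ids(self) -> list[str]:
        return self.matrix.feature_ids

    @property
    def n_samples(self) -> int:
        return self.matrix.n_samples

    @property
    def classes(self) -> list[str]:
        seen: list[str] = []
        for lbl in self.labels:
            if lbl not in seen:
                seen.append(lbl)
        return seen

    def is_binary(self) -> bool:
        cls = set(self.labels)
        return cls == set(GROUPS)

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lbl in self.labels:
            out[lbl] = out.get(lbl, 0) + 1
        return out

    def label_of(self, sample_id: str) -> str:
        return self.labels[self.matrix.row_index(sample_id)]

    def subset_rows(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = list(indices)
        fm = FeatureMatrix(
            self.X[idx],
            [self.sample_ids[i] for i in idx],
            list(self.feature_ids),
        )
        raw = None if self.raw_labels is None else self.raw_labels[idx]
        return LabeledDataset(fm, self.labels[idx], raw)


def require_binary(ds: LabeledDataset) -> None:
    """Ensure the dataset carries exactly the two canonical groups, both non-empty."""
    counts = ds.class_counts()
    if set(counts) != set(GROUPS):
        raise DataError(
            f"classification requires the two groups {GROUPS}; got classes "
            f"{sorted(map(str, counts))}. Map labels first (binarize_by_target "
            "or an explicit label mapping)."
        )
    if min(counts.values()) == 0:  # pragma: no cover - counts never store zeros
        raise DataError("both groups must be non-empty")


@dataclass(frozen=True)
class PreprocessSpec:
    """Preprocessing recipe applied before distance computation and training.

    Order of application: drop_zero_features -> normalize_total -> scale.
    ``strict_scaling`` computes column statistics on training samples only
    (a leakage-free variant); the default computes them once over the whole
    matrix, which matches how instrument data sets are usually scaled as a
    single block before classification.
    """

    scale: bool = False
    normalize_total: str = "none"  # none | percent100 | unit1
    drop_zero_features: bool = False
    strict_scaling: bool = False

    def __post_init__(self) -> None:
        if self.normalize_total not in ("none", "percent100", "unit1"):
            raise ConfigError(
                f"normalize_total must be none|percent100|unit1, got {self.normalize_total!r}"
            )


# ---------------------------------------------------------------------------
# label mapping
# ---------------------------------------------------------------------------

def map_labels(ds: LabeledDataset, mapping: Mapping[str, str] | None = None) -> LabeledDataset:
    """Map raw class names onto the canonical ``Low`` / ``Hi`` groups.

    With ``mapping=None`` the dataset must carry exactly two raw classes; the
    lexicographically smaller name becomes ``Low``. Raw labels are retained.
    """
    raw = ds.raw_labels if ds.raw_labels is not None else ds.labels
    raw_classes = sorted({str(v) for v in raw})
    if mapping is None:
        if len(raw_classes) != 2:
            raise ConfigError(
                f"automatic label mapping needs exactly 2 classes, found {len(raw_classes)}: "
                f"{raw_classes}; use binarize_by_target or an explicit mapping"
            )
        mapping = {raw_classes[0]: GROUP_LOW, raw_classes[1]: GROUP_HI}
    missing = [c for c in raw_classes if c not in mapping]
    if missing:
        raise ConfigError(f"label mapping lacks classes {missing}")
    bad = [v for v in mapping.values() if v not in GROUPS]
    if bad:
        raise ConfigError(f"label mapping targets must be in {GROUPS}, got {bad}")
    labels = np.array([mapping[str(v)] for v in raw], dtype=object)
    return LabeledDataset(ds.matrix, labels, np.asarray(raw, dtype=object))


def binarize_by_target(ds: LabeledDataset, target: str) -> LabeledDataset:
    """One-vs-rest binarization: ``target`` becomes the ``Low`` (target/minority)
    group, every other raw class becomes ``Hi``. Raw labels are retained."""
    raw = ds.raw_labels if ds.raw_labels is not None else ds.labels
    raw = np.asarray([str(v) for v in raw], dtype=object)
    if str(target) not in set(raw):
        raise ConfigError(f"target class {target!r} absent from labels {sorted(set(raw))}")
    labels = np.where(raw == str(target), GROUP_LOW, GROUP_HI)
    return LabeledDataset(ds.matrix, labels.astype(object), raw)


# ---------------------------------------------------------------------------
# loaders / writers
# ---------------------------------------------------------------------------

def _dataset_from_frame(
    df: pd.DataFrame,
    label_column: str,
    label_map: Mapping[str, str] | None,
    auto_map: bool,
) -> LabeledDataset:
    if label_column not in df.columns:
        raise ConfigError(
            f"label column {label_column!r} not found; columns are {list(df.columns)[:10]}..."
        )
    raw_labels = df[label_column].astype(str).to_numpy(dtype=object)
    feats = df.drop(columns=[label_column])

    # A leading non-numeric column (other than the labels) is taken as sample ids.
    sample_ids: list[str]
    if feats.shape[1] and not pd.api.types.is_numeric_dtype(feats.iloc[:, 0]):
        first = feats.columns[0]
        ids = feats[first].astype(str)
        if ids.is_unique:
            sample_ids = ids.tolist()
            feats = feats.drop(columns=[first])
        else:
            raise DataError(f"leading id column {first!r} contains duplicates")
    else:
        sample_ids = [f"s{i + 1:04d}" for i in range(len(feats))]

    if feats.isna().any().any():
        r, c = np.argwhere(feats.isna().to_numpy())[0]
        raise DataError(
            f"missing value at sample {sample_ids[r]!r}, column {feats.columns[c]!r}; "
            "imputation is not performed"
        )
    for col in feats.columns:
        if not pd.api.types.is_numeric_dtype(feats[col]):
            coerced = pd.to_numeric(feats[col], errors="coerce")
            bad_rows = np.flatnonzero(coerced.isna().to_numpy())
            if len(bad_rows):
                raise DataError(
                    f"non-numeric value {feats[col].iloc[bad_rows[0]]!r} at sample "
                    f"{sample_ids[bad_rows[0]]!r}, column {col!r}"
                )
            feats[col] = coerced

    fm = FeatureMatrix(feats.to_numpy(dtype=float), sample_ids, [str(c) for c in feats.columns])
    ds = LabeledDataset(fm, raw_labels, raw_labels.copy())
    n_classes = len(set(raw_labels))
    if label_map is not None:
        return map_labels(ds, label_map)
    if auto_map and n_classes == 2:
        return map_labels(ds, None)
    return ds


def read_delimited(
    path: str | Path,
    label_column: str,
    delimiter: str = ",",
    label_map: Mapping[str, str] | None = None,
    auto_map: bool = True,
) -> LabeledDataset:
    """Read a delimited (CSV/TSV) feature table with a header row.

    Samples are rows. The ``label_column`` holds the class; an optional leading
    non-numeric column supplies sample ids, otherwise ids ``s0001...`` are
    synthesized.  Two-class files are mapped to ``Low``/``Hi`` automatically
    (lexicographic order) unless an explicit ``label_map`` is given; files with
    more classes keep their raw labels for later binarization.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such file: {path}")
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    return _dataset_from_frame(df, label_column, label_map, auto_map)


def read_arff(
    path: str | Path,
    label_attribute: str,
    label_map: Mapping[str, str] | None = None,
    auto_map: bool = True,
) -> LabeledDataset:
    """Read a dense ARFF file (the distribution format of several UCI tables)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such file: {path}")
    try:
        data, meta = scipy_arff.loadarff(str(path))
    except NotImplementedError as exc:  # sparse ARFF dialect
        raise DataError(f"unsupported ARFF dialect in {path}: {exc}") from exc
    df = pd.DataFrame(data)
    # byte-string nominal attributes -> str
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].map(lambda v: v.decode() if isinstance(v, bytes) else v)
    if label_attribute not in df.columns:
        raise ConfigError(
            f"label attribute {label_attribute!r} not in ARFF attributes {list(df.columns)[:10]}..."
        )
    return _dataset_from_frame(df, label_attribute, label_map, auto_map)


def write_delimited(
    ds: LabeledDataset,
    path: str | Path,
    label_column: str = "class",
    delimiter: str = ",",
    id_column: str = "sample_id",
) -> None:
    """Write a dataset back to delimited text (round-trips with read_delimited)."""
    df = pd.DataFrame(ds.X, columns=ds.feature_ids)
    df.insert(0, id_column, ds.sample_ids)
    df[label_column] = [str(v) for v in ds.labels]
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def normalize_total(ds: LabeledDataset, mode: str) -> LabeledDataset:
    """Normalize each sample's total signal to a constant.

    ``percent100`` rescales every row to sum to 100 (relative-abundance
    percentages); ``unit1`` rescales to sum to 1.0 (total-ion-count
    normalization).  Multiplicative per-sample intensity drift cancels exactly
    under either mode.
    """
    if mode not in ("percent100", "unit1"):
        raise ConfigError(f"mode must be percent100|unit1, got {mode!r}")
    target = 100.0 if mode == "percent100" else 1.0
    sums = ds.X.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if len(zero):
        raise DataError(f"sample {ds.sample_ids[zero[0]]!r} has zero total signal")
    fm = FeatureMatrix(ds.X * (target / sums)[:, None], list(ds.sample_ids), list(ds.feature_ids))
    return LabeledDataset(fm, ds.labels.copy(), None if ds.raw_labels is None else ds.raw_labels.copy())


def column_scale_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and sample standard deviation (ddof=1)."""
    return X.mean(axis=0), X.std(axis=0, ddof=1)


def scale_columns(
    ds: LabeledDataset,
    stats_rows: Sequence[int] | None = None,
) -> LabeledDataset:
    """Z-score each column to mean 0, sd 1 (sample sd, ``ddof=1``).

    Constant (zero-variance) columns are dropped with a warning — z-scoring is
    undefined there and keeping them would leave distances ill-conditioned.
    ``stats_rows`` restricts the statistics to a subset of rows (the training
    samples, for the leakage-free variant); the transform still applies to all
    rows.
    """
    if ds.n_samples < 2:
        raise DataError("scaling needs at least 2 samples")
    ref = ds.X if stats_rows is None else ds.X[list(stats_rows)]
    if ref.shape[0] < 2:
        raise DataError("scaling statistics need at least 2 reference samples")
    mean, sd = column_scale_stats(ref)
    keep = sd > 0
    if not np.all(keep):
        dropped = [ds.feature_ids[j] for j in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropping {len(dropped)} constant column(s) during scaling: {dropped[:5]}...",
            stacklevel=2,
        )
    scaled = (ds.X[:, keep] - mean[keep]) / sd[keep]
    fm = FeatureMatrix(scaled, list(ds.sample_ids), [f for f, k in zip(ds.feature_ids, keep) if k])
    return LabeledDataset(fm, ds.labels.copy(), None if ds.raw_labels is None else ds.raw_labels.copy())


def drop_zero_features(ds: LabeledDataset) -> LabeledDataset:
    """Remove features with no signal (zero in every sample)."""
    keep = np.any(ds.X != 0, axis=0)
    if np.all(keep):
        return ds
    fm = FeatureMatrix(
        ds.X[:, keep], list(ds.sample_ids), [f for f, k in zip(ds.feature_ids, keep) if k]
    )
    return LabeledDataset(fm, ds.labels.copy(), None if ds.raw_labels is None else ds.raw_labels.copy())


def apply_preprocess(
    ds: LabeledDataset,
    spec: PreprocessSpec,
    stats_rows: Sequence[int] | None = None,
) -> LabeledDataset:
    """Apply a :class:`PreprocessSpec` (drop zeros -> normalize -> scale).

    ``stats_rows`` is honoured only when ``spec.strict_scaling`` is set.
    """
    out = ds
    if spec.drop_zero_features:
        out = drop_zero_features(out)
    if spec.normalize_total != "none":
        out = normalize_total(out, spec.normalize_total)
    if spec.scale:
        out = scale_columns(out, stats_rows if spec.strict_scaling else None)
    return out
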