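"""The local-balanced model: one freshly trained base classifier per test sample.

For every sample to be classified, a bespoke training set is assembled from
the nearest labeled neighbours of each class (:mod:`localbalance.selection`),
a base classifier is trained on that subset alone, and only that one sample
is classified.  The per-class subset sizes are the method's only tuned
parameters; they are chosen by maximizing leave-one-out AUC on training data.

The default base classifier is a soft-margin RBF-kernel SVM with cost 1 and
kernel width gamma = 1/n_features — the stock defaults of the classical SVM
implementations — with hyperparameters deliberately left untouched so that
runs with and without the local-balanced wrapper compare like for like.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.svm import SVC

from .data_io import (
    GROUP_HI,
    GROUP_LOW,
    DataError,
    LabeledDataset,
    require_binary,
)
from .metrics import auc as _auc
from .selection import (
    BalancedSubset,
    DistanceVector,
    GroupSizes,
    distances_to_test,
    select_for_test_point,
)

__all__ = [
    "GroupSizes",
    "BaseClassifierSpec",
    "SvmRbfClassifier",
    "LocalPrediction",
    "make_base_classifier",
    "fit_predict_one",
    "run_loo",
    "run_train_test",
    "run_base_loo",
    "run_base_train_test",
    "optimize_group_sizes",
    "default_size_grid",
]


# ---------------------------------------------------------------------------
# base classifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaseClassifierSpec:
    """Declarative description of a pluggable base classifier.

    ``name`` selects an entry in the registry (currently ``"svm"``); other
    learners can be plugged in by registering a factory that returns an object
    with ``fit(X, y)``, ``predict_label(X)`` and ``score_hi(X)`` — the score
    must be continuous and oriented so larger means more ``Hi``-like.
    """

    name: str = "svm"
    hyperparameters: tuple = ()  # sorted (key, value) pairs; dataclass-hashable
    produces_score: bool = True

    @staticmethod
    def make(name: str = "svm", **hyper) -> "BaseClassifierSpec":
        return BaseClassifierSpec(name, tuple(sorted(hyper.items())))

    def as_dict(self) -> dict:
        return dict(self.hyperparameters)


class SvmRbfClassifier:
    """RBF-kernel soft-margin SVM base classifier.

    Parameters
    ----------
    C : float
        Soft-margin cost (default 1.0).
    gamma : str or float
        Kernel width; ``"auto"`` means 1/n_features, the classical default.
    score_mode : {"probability", "decision"}
        Continuous score used for AUC: Platt-calibrated class probabilities
        (default) or raw decision values.  Hard label predictions never go
        through probabilities.
    random_state : int
        Seeds the internal probability-calibration folds so fits are
        reproducible and depend only on the training matrix.
    """

    def __init__(
        self,
        C: float = 1.0,
        gamma: str | float = "auto",
        score_mode: str = "probability",
        random_state: int = 0,
    ) -> None:
        if score_mode not in ("probability", "decision"):
            raise ValueError(f"score_mode must be probability|decision, got {score_mode!r}")
        self.C = C
        self.gamma = gamma
        self.score_mode = score_mode
        self.random_state = random_state
        self._svc: SVC | None = None

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "SvmRbfClassifier":
        y = np.asarray(y, dtype=object)
        self._svc = SVC(
            C=self.C,
            kernel="rbf",
            gamma=self.gamma,
            probability=self.score_mode == "probability",
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            # libsvm's built-in Platt calibration still handles the tiny
            # per-class subsets local models produce; the suggested
            # CalibratedClassifierCV replacement needs >= 5 samples per class.
            warnings.filterwarnings("ignore", category=FutureWarning)
            self._svc.fit(np.asarray(X, dtype=float), y)
        return self

    def _require_fit(self) -> SVC:
        if self._svc is None:
            raise RuntimeError("classifier is not fitted")
        return self._svc

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        return self._require_fit().predict(np.atleast_2d(np.asarray(X, dtype=float)))

    def score_hi(self, X: np.ndarray) -> np.ndarray:
        """Continuous score, larger = more Hi-like."""
        svc = self._require_fit()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.score_mode == "probability":
            col = int(np.flatnonzero(svc.classes_ == GROUP_HI)[0])
            return svc.predict_proba(X)[:, col]
        dec = svc.decision_function(X)
        # decision_function is positive toward classes_[1]
        sign = 1.0 if svc.classes_[1] == GROUP_HI else -1.0
        return sign * dec


_REGISTRY: dict[str, Callable[..., object]] = {"svm": SvmRbfClassifier}


def register_base_classifier(name: str, factory: Callable[..., object]) -> None:
    """Register an additional base-classifier factory (extension point)."""
    _REGISTRY[name] = factory


def make_base_classifier(spec: BaseClassifierSpec, random_state: int = 0):
    if spec.name not in _REGISTRY:
        raise DataError(f"unknown base classifier {spec.name!r}; known: {sorted(_REGISTRY)}")
    return _REGISTRY[spec.name](random_state=random_state, **spec.as_dict())


# ---------------------------------------------------------------------------
# per-sample prediction
# ---------------------------------------------------------------------------

@dataclass
class LocalPrediction:
    """One test sample's outcome plus the audit trail of who trained its model."""

    test_id: str
    selected_low_ids: list[str]
    selected_hi_ids: list[str]
    predicted: str
    score: float  # Hi-high orientation
    clamped: bool

    def __post_init__(self) -> None:
        if self.predicted not in (GROUP_LOW, GROUP_HI):
            raise ValueError(f"predicted label {self.predicted!r} not in Low/Hi")
        if self.test_id in self.selected_low_ids or self.test_id in self.selected_hi_ids:
            raise ValueError(f"test sample {self.test_id!r} leaked into its own training set")

    def to_dict(self) -> dict:
        return {
            "test_id": self.test_id,
            "selected_low_ids": list(self.selected_low_ids),
            "selected_hi_ids": list(self.selected_hi_ids),
            "predicted": self.predicted,
            "score": self.score,
            "clamped": self.clamped,
        }


def _fit_on_subset(
    train: LabeledDataset,
    subset_ids: Iterable[str],
    x_test: np.ndarray,
    base,
) -> tuple[str, float]:
    # Build the design matrix in the dataset's storage order so the fit is
    # independent of the distance ranking (order-stable, and identical to a
    # plain full-data fit in the clamped limit).
    rows = sorted(train.matrix.row_index(s) for s in subset_ids)
    X = train.X[rows]
    y = train.labels[rows]
    base.fit(X, y)
    label = str(base.predict_label(x_test)[0])
    score = float(base.score_hi(x_test)[0])
    return label, score


def fit_predict_one(
    ds: LabeledDataset,
    test_id: str,
    sizes: GroupSizes,
    base,
    warn_on_clamp: bool = True,
) -> LocalPrediction:
    """Classify one sample of ``ds`` with a local-balanced model built from all
    the others (the test sample is excluded from training by construction)."""
    require_binary(ds)
    dv = distances_to_test(ds, test_id)
    labels = dict(zip(ds.sample_ids, ds.labels))
    from .selection import select_balanced_subset

    subset = select_balanced_subset(dv, labels, sizes, warn_on_clamp=warn_on_clamp)
    label, score = _fit_on_subset(ds, subset.ids, ds.X[ds.matrix.row_index(test_id)], base)
    return LocalPrediction(
        test_id, subset.low_ids, subset.hi_ids, label, score, subset.clamped
    )


def run_loo(
    ds: LabeledDataset,
    sizes: GroupSizes,
    base,
) -> list[LocalPrediction]:
    """Leave-one-out evaluation of the local-balanced model.

    Each sample is classified by a model trained on a balanced subset of the
    remaining samples; exactly one base-classifier fit per sample.  Results
    are ordered by the dataset's sample order and deterministic for a given
    configuration.
    """
    require_binary(ds)
    counts = ds.class_counts()
    if min(counts.values()) < 2:
        raise DataError("leave-one-out needs at least 2 samples per class")
    preds = []
    warned = False
    for sid in ds.sample_ids:
        try:
            p = fit_predict_one(ds, sid, sizes, base, warn_on_clamp=not warned)
        except Exception as exc:
            raise DataError(f"local model failed for test sample {sid!r}: {exc}") from exc
        warned = warned or p.clamped
        preds.append(p)
    return preds


def run_train_test(
    train: LabeledDataset,
    test: LabeledDataset,
    sizes: GroupSizes,
    base,
) -> list[LocalPrediction]:
    """Classify an external test set; every local model draws only from ``train``."""
    require_binary(train)
    if train.feature_ids != test.feature_ids:
        extra = set(train.feature_ids) ^ set(test.feature_ids)
        raise DataError(
            f"train/test feature mismatch ({len(extra)} differing): {sorted(extra)[:5]}..."
        )
    overlap = set(train.sample_ids) & set(test.sample_ids)
    if overlap:
        raise DataError(f"test ids overlap training set: {sorted(overlap)[:5]}...")
    preds = []
    warned = False
    for i, sid in enumerate(test.sample_ids):
        dv, subset = select_for_test_point(
            train, test.X[i], sid, sizes, warn_on_clamp=not warned
        )
        warned = warned or subset.clamped
        label, score = _fit_on_subset(train, subset.ids, test.X[i], base)
        preds.append(
            LocalPrediction(sid, subset.low_ids, subset.hi_ids, label, score, subset.clamped)
        )
    return preds


# ---------------------------------------------------------------------------
# base-classifier (global model) protocols, for like-for-like comparison
# ---------------------------------------------------------------------------

def run_base_loo(ds: LabeledDataset, base) -> list[LocalPrediction]:
    """Leave-one-out with the plain global base classifier (no subsetting)."""
    require_binary(ds)
    preds = []
    all_ids = list(ds.sample_ids)
    labels = dict(zip(ds.sample_ids, ds.labels))
    for sid in all_ids:
        train_ids = [s for s in all_ids if s != sid]
        label, score = _fit_on_subset(ds, train_ids, ds.X[ds.matrix.row_index(sid)], base)
        low = [s for s in train_ids if labels[s] == GROUP_LOW]
        hi = [s for s in train_ids if labels[s] == GROUP_HI]
        preds.append(LocalPrediction(sid, low, hi, label, score, True))
    return preds


def run_base_train_test(train: LabeledDataset, test: LabeledDataset, base) -> list[LocalPrediction]:
    """Train the global base classifier once on ``train``, classify all of ``test``."""
    require_binary(train)
    if train.feature_ids != test.feature_ids:
        raise DataError("train/test feature mismatch")
    overlap = set(train.sample_ids) & set(test.sample_ids)
    if overlap:
        raise DataError(f"test ids overlap training set: {sorted(overlap)[:5]}...")
    base.fit(train.X, train.labels)
    labels_pred = base.predict_label(test.X)
    scores = base.score_hi(test.X)
    labels = dict(zip(train.sample_ids, train.labels))
    low = [s for s in train.sample_ids if labels[s] == GROUP_LOW]
    hi = [s for s in train.sample_ids if labels[s] == GROUP_HI]
    return [
        LocalPrediction(sid, low, hi, str(l), float(s), True)
        for sid, l, s in zip(test.sample_ids, labels_pred, scores)
    ]


# ---------------------------------------------------------------------------
# group-size optimization
# ---------------------------------------------------------------------------

def default_size_grid(ds: LabeledDataset, max_size: int = 30) -> list[GroupSizes]:
    """Cross product n_low, n_hi in {2..min(max_size, class size - 1)} plus the
    clamped (full-class) pair."""
    counts = ds.class_counts()
    lo_max = min(max_size, counts[GROUP_LOW] - 1)
    hi_max = min(max_size, counts[GROUP_HI] - 1)
    grid = [
        GroupSizes(a, b)
        for a in range(2, lo_max + 1)
        for b in range(2, hi_max + 1)
    ]
    grid.append(GroupSizes(counts[GROUP_LOW], counts[GROUP_HI]))
    return grid


def optimize_group_sizes(
    ds: LabeledDataset,
    base,
    grid: Sequence[GroupSizes],
    positive: str = GROUP_LOW,
) -> tuple[GroupSizes, dict[GroupSizes, float]]:
    """Pick the group sizes maximizing leave-one-out AUC on ``ds``.

    Returns the winning pair and the full AUC-per-grid-point table for audit.
    Ties are broken toward smaller ``n_low``, then smaller ``n_hi``.  Grid
    points whose evaluation fails are skipped with a warning.
    """
    if not grid:
        raise DataError("empty group-size grid")
    truth = {s: l for s, l in zip(ds.sample_ids, ds.labels)}
    table: dict[GroupSizes, float] = {}
    for sizes in grid:
        try:
            preds = run_loo(ds, sizes, base)
        except DataError as exc:
            warnings.warn(f"skipping infeasible grid point {sizes}: {exc}", stacklevel=2)
            continue
        scores = np.array([p.score for p in preds])
        truths = [truth[p.test_id] for p in preds]
        oriented = scores if positive == GROUP_HI else -scores
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table[sizes] = _auc(oriented, truths, positive)
    if not table:
        raise DataError("every grid point was infeasible")
    best = max(table, key=lambda s: (table[s], -s.n_low, -s.n_hi))
    return best, table
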