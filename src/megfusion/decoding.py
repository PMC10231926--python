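"""Time-resolved multivariate decoding of sensor patterns.

Per time point, a linear max-margin classifier (linear SVM, cost C=1) is
trained under stratified fivefold cross-validation.  Class imbalance in
the training folds (recognition rates are ~50% but never exactly equal)
is handled with a resampling ensemble: up to ``max_resample_models``
classifiers are built, each trained on every minority-class sample plus
an equally sized random subsample of the majority class; the label
predicted by the (unweighted) majority of the models is the prediction
for a test sample.  Performance is the balanced accuracy — the mean of
per-class recalls — pooled over all cross-validation folds, in percent
(50 = chance for binary problems).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.svm import LinearSVC

from .conditions import CATEGORIES
from .synthgen import EpochedDataset

__all__ = [
    "DecodingConfig",
    "DecodingTimecourse",
    "balanced_accuracy",
    "decode_timecourse",
    "decode_category_pairwise",
]


@dataclass(frozen=True)
class DecodingConfig:
    svm_cost: float = 1.0
    n_folds: int = 5
    max_resample_models: int = 100
    time_step_ms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.max_resample_models < 1:
            raise ValueError("max_resample_models must be >= 1")


@dataclass
class DecodingTimecourse:
    time_ms: np.ndarray
    balanced_accuracy_percent: np.ndarray
    chance_percent: float = 50.0
    target: str = "outcome"
    subject: int | None = field(default=None)


def balanced_accuracy(true_labels, predicted_labels) -> float:
    """Mean of per-class recalls, in percent.

    Classes are those present in ``true_labels``; a class with no true
    instance is an error (its recall is undefined).
    """
    true = np.asarray(true_labels)
    pred = np.asarray(predicted_labels)
    if true.shape != pred.shape or true.ndim != 1:
        raise ValueError("label vectors must be 1-D and the same length")
    if true.size == 0:
        raise ValueError("empty label vectors")
    classes, counts = np.unique(true, return_counts=True)
    recalls = [
        np.mean(pred[true == cls] == cls) for cls, n in zip(classes, counts)
    ]
    return float(np.mean(recalls) * 100.0)


def _stratified_folds(
    strata: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Greedy per-stratum round-robin fold assignment after a seeded shuffle.

    Each fold receives approximately the same share of every stratum; the
    round-robin start offset rotates across strata so fold sizes stay
    balanced when stratum sizes are not multiples of n_folds.
    """
    assignment = np.empty(strata.size, dtype=int)
    offset = 0
    for stratum in np.unique(strata):
        idx = np.flatnonzero(strata == stratum)
        idx = rng.permutation(idx)
        assignment[idx] = (np.arange(idx.size) + offset) % n_folds
        offset = (offset + idx.size) % n_folds
    return assignment


def _capped_comb(n: int, k: int, cap: int) -> int:
    """min(C(n, k), cap) without forming the full binomial coefficient."""
    k = min(k, n - k)
    result = 1
    for i in range(k):
        result = result * (n - i) // (i + 1)
        if result >= cap:
            return cap
    return result


def _ensemble_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    cfg: DecodingConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Majority vote over subsampling-balanced linear SVMs.

    Vote ties (possible with an even model count) are broken by the class
    with the higher mean decision value across models.
    """
    classes, counts = np.unique(y_train, return_counts=True)
    if classes.size != 2:
        raise ValueError("ensemble decoding is binary")
    if counts[0] <= counts[1]:
        minority, majority = classes
    else:
        majority, minority = classes
    min_idx = np.flatnonzero(y_train == minority)
    maj_idx = np.flatnonzero(y_train == majority)
    n_min, n_maj = min_idx.size, maj_idx.size

    # number of distinct majority-class subsets, capped at the ensemble size;
    # when fewer distinct subsets exist they are drawn with replacement anyway
    n_models = _capped_comb(n_maj, n_min, cfg.max_resample_models)

    votes = np.zeros(X_test.shape[0], dtype=int)  # votes for classes[1]
    decision_sum = np.zeros(X_test.shape[0])
    for _ in range(n_models):
        sub = rng.choice(maj_idx, size=n_min, replace=False)
        train = np.concatenate([min_idx, sub])
        clf = LinearSVC(C=cfg.svm_cost, dual=True, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # liblinear convergence chatter
            clf.fit(X_train[train], y_train[train])
        dec = clf.decision_function(X_test)  # positive -> clf.classes_[1]
        pred_hi = dec > 0
        if not np.array_equal(clf.classes_, classes):
            pred_hi = ~pred_hi
            dec = -dec
        votes += pred_hi.astype(int)
        decision_sum += dec
    hi = votes * 2 > n_models
    tie = votes * 2 == n_models
    pred = np.where(hi, classes[1], classes[0])
    pred[tie] = np.where(decision_sum[tie] > 0, classes[1], classes[0])
    return pred


def _time_indices(time_ms: np.ndarray, sfreq_hz: float, step_ms: float) -> np.ndarray:
    dt = 1000.0 / sfreq_hz
    stride = max(1, int(round(step_ms / dt)))
    return np.arange(0, time_ms.size, stride)


def _binary_timecourse(
    data: np.ndarray,
    y: np.ndarray,
    strata: np.ndarray,
    t_idx: np.ndarray,
    cfg: DecodingConfig,
    rng: np.random.Generator,
    resample: bool = True,
) -> np.ndarray:
    """Pooled balanced accuracy per time point for one binary problem."""
    folds = _stratified_folds(strata, cfg.n_folds, rng)
    for k in range(cfg.n_folds):
        if np.unique(y[folds != k]).size < 2:
            raise ValueError(f"training fold {k} lacks a class")
    accs = np.empty(t_idx.size)
    for j, t in enumerate(t_idx):
        X = data[:, :, t]
        pred = np.empty_like(y)
        for k in range(cfg.n_folds):
            test = folds == k
            if resample:
                pred[test] = _ensemble_predict(
                    X[~test], y[~test], X[test], cfg, rng
                )
            else:
                clf = LinearSVC(C=cfg.svm_cost, dual=True, max_iter=5000)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(X[~test], y[~test])
                pred[test] = clf.predict(X[test])
        accs[j] = balanced_accuracy(y, pred)
    return accs


def decode_timecourse(
    dataset: EpochedDataset, target: str = "outcome", cfg: DecodingConfig | None = None
) -> DecodingTimecourse:
    """Time-resolved binary decoding of the recognition outcome."""
    if target != "outcome":
        raise ValueError("decode_timecourse decodes the recognition outcome; "
                         "use decode_category_pairwise for categories")
    cfg = cfg or DecodingConfig()
    y = (dataset.labels["outcome"] == "recognized").to_numpy().astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both recognition outcomes must be present")
    strata = dataset.condition_codes()
    t_idx = _time_indices(dataset.time_ms, dataset.sfreq_hz, cfg.time_step_ms)
    rng = np.random.default_rng(cfg.seed)
    accs = _binary_timecourse(dataset.data, y, strata, t_idx, cfg, rng)
    return DecodingTimecourse(
        time_ms=dataset.time_ms[t_idx],
        balanced_accuracy_percent=accs,
        target="outcome",
    )


def decode_category_pairwise(
    dataset: EpochedDataset,
    outcome_filter: str = "all",
    cfg: DecodingConfig | None = None,
    resample: bool = True,
) -> DecodingTimecourse:
    """Mean pairwise category decoding (6 category pairs) over time.

    ``outcome_filter`` restricts trials to recognized ("R"), unrecognized
    ("U"), or keeps all trials ("all").  ``resample=False`` reproduces the
    localizer-style analysis without the imbalance-resampling ensemble
    (appropriate when the design is already balanced).
    """
    cfg = cfg or DecodingConfig()
    keep = {
        "R": dataset.labels["outcome"] == "recognized",
        "U": dataset.labels["outcome"] == "unrecognized",
        "all": np.ones(dataset.n_trials, dtype=bool),
    }.get(outcome_filter)
    if keep is None:
        raise ValueError(f"unknown outcome_filter {outcome_filter!r}")
    keep = np.asarray(keep)
    data = dataset.data[keep]
    cats = dataset.labels["category"].to_numpy()[keep]
    strata = dataset.condition_codes()[keep]
    present = [c for c in CATEGORIES if (cats == c).any()]
    if len(present) < 2:
        raise ValueError(
            f"fewer than 2 categories present after filter {outcome_filter!r}"
        )
    t_idx = _time_indices(dataset.time_ms, dataset.sfreq_hz, cfg.time_step_ms)
    rng = np.random.default_rng(cfg.seed)
    pair_accs = []
    for a, b in combinations(present, 2):
        sel = (cats == a) | (cats == b)
        y = (cats[sel] == b).astype(int)
        pair_accs.append(
            _binary_timecourse(
                data[sel], y, strata[sel], t_idx, cfg, rng, resample=resample
            )
        )
    return DecodingTimecourse(
        time_ms=dataset.time_ms[t_idx],
        balanced_accuracy_percent=np.mean(pair_accs, axis=0),
        target=f"category[{outcome_filter}]",
    )
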