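"""Representational similarity analysis.

Builds 40 x 40 condition RDMs (dissimilarity = 1 - Pearson correlation
between condition-averaged activity patterns), the three hypothesis RDMs
(recognition, two-state, category), the within-outcome mean-dissimilarity
comparison, the category-model correlation timecourse, and MDS embedding
for visualization.  RDM diagonals are undefined and stored as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .conditions import (
    N_CONDITIONS,
    N_REAL_EXEMPLARS,
    category_labels_20,
    quadrant_slices,
)
from .stats import ClusterTestResult, cluster_sign_permutation_test
from .synthgen import EpochedDataset

__all__ = [
    "ModelRDM",
    "compute_rdm",
    "rdm_timecourse",
    "build_model_rdm",
    "mean_group_dissimilarity",
    "mean_group_dissimilarity_test",
    "category_model_correlation",
    "mds_embed",
]

MODEL_NAMES = ("recognition", "two_state", "category")


@dataclass(frozen=True)
class ModelRDM:
    """Binary-structured hypothesis RDM (low=0, high=1, NaN diagonal)."""

    name: str
    values: np.ndarray

    @property
    def size(self) -> int:
        return self.values.shape[0]


def compute_rdm(patterns: np.ndarray, condition_names=None) -> np.ndarray:
    """Correlation-distance RDM from a conditions x features array.

    entry(i, j) = 1 - Pearson r(pattern_i, pattern_j); diagonal NaN.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[0] < 2:
        raise ValueError("need a conditions x features array with >= 2 conditions")
    sd = patterns.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        name = condition_names[bad] if condition_names is not None else bad
        raise ValueError(f"zero-variance pattern for condition {name!r}")
    rdm = 1.0 - np.corrcoef(patterns)
    np.fill_diagonal(rdm, np.nan)
    return rdm


def rdm_timecourse(
    dataset: EpochedDataset, step_ms: float = 2.5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-timepoint 40 x 40 RDMs from condition-averaged sensor patterns.

    Returns (rdms, time_ms) where rdms has shape (n_times, 40, 40) and the
    time axis is subsampled to (approximately) ``step_ms`` increments.
    """
    codes = dataset.condition_codes()
    present = np.unique(codes)
    if present.size < N_CONDITIONS:
        missing = sorted(set(range(N_CONDITIONS)) - set(present))
        raise ValueError(f"missing conditions at positions {missing}")
    dt = 1000.0 / dataset.sfreq_hz
    stride = max(1, int(round(step_ms / dt)))
    t_idx = np.arange(0, dataset.time_ms.size, stride)

    # averaging operator: conditions x trials
    avg = np.zeros((N_CONDITIONS, dataset.n_trials))
    for cond in range(N_CONDITIONS):
        members = codes == cond
        avg[cond, members] = 1.0 / members.sum()

    rdms = np.empty((t_idx.size, N_CONDITIONS, N_CONDITIONS))
    for k, t in enumerate(t_idx):
        means = avg @ dataset.data[:, :, t]
        rdms[k] = compute_rdm(means)
    return rdms, dataset.time_ms[t_idx]


def build_model_rdm(name: str) -> ModelRDM:
    """One of the three hypothesis RDMs.

    recognition (40x40): recognized-recognized cells low, every cell
    involving an unrecognized condition high — recognized-trial patterns
    cluster while unrecognized patterns stay dispersed.
    two_state (40x40): within-outcome cells low, between-outcome cells
    high — patterns bifurcate into two outcome states.
    category (20x20): same-category cells low, different-category high.
    Levels are 0/1; only their ranks matter downstream.
    """
    if name == "recognition":
        values = np.ones((N_CONDITIONS, N_CONDITIONS))
        r_rows, r_cols = quadrant_slices("recognized")
        values[r_rows, r_cols] = 0.0
    elif name == "two_state":
        values = np.ones((N_CONDITIONS, N_CONDITIONS))
        for outcome in ("recognized", "unrecognized"):
            rows, cols = quadrant_slices(outcome)
            values[rows, cols] = 0.0
    elif name == "category":
        cats = category_labels_20()
        values = (cats[:, None] != cats[None, :]).astype(float)
    else:
        raise ValueError(f"unknown model RDM {name!r}; choose from {MODEL_NAMES}")
    np.fill_diagonal(values, np.nan)
    return ModelRDM(name=name, values=values)


def _quadrant_mean_offdiag(rdm: np.ndarray, outcome: str) -> float:
    rows, cols = quadrant_slices(outcome)
    quad = rdm[rows, cols]
    return float(np.nanmean(quad[~np.eye(quad.shape[0], dtype=bool)]))


def mean_group_dissimilarity(
    rdms: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean off-diagonal dissimilarity in the recognized (upper-left) and
    unrecognized (bottom-right) quadrants, per time point.

    ``rdms`` is (n_times, 40, 40); returns (mean_R, mean_U)."""
    rdms = np.asarray(rdms, dtype=float)
    mean_r = np.array([_quadrant_mean_offdiag(r, "recognized") for r in rdms])
    mean_u = np.array([_quadrant_mean_offdiag(r, "unrecognized") for r in rdms])
    return mean_r, mean_u


def mean_group_dissimilarity_test(
    subject_rdms: np.ndarray,
    time_ms: np.ndarray,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, ClusterTestResult]:
    """Test whether recognized-trial patterns cluster more than
    unrecognized ones (mean R-R dissimilarity < mean U-U dissimilarity).

    ``subject_rdms`` is (n_subjects, n_times, 40, 40).  Runs a one-sided
    cluster sign-permutation test on the per-subject difference
    (U - R) > 0.  Returns (mean_R, mean_U) as subjects x time arrays plus
    the cluster result.
    """
    subject_rdms = np.asarray(subject_rdms, dtype=float)
    if subject_rdms.ndim != 4 or subject_rdms.shape[0] < 2:
        raise ValueError("need >= 2 subjects of RDM timecourses")
    means = np.array([mean_group_dissimilarity(s) for s in subject_rdms])
    mean_r, mean_u = means[:, 0, :], means[:, 1, :]
    result = cluster_sign_permutation_test(
        mean_u - mean_r, chance=0.0, time_ms=time_ms, n_perm=n_perm, alpha=alpha, seed=seed
    )
    return mean_r, mean_u, result


def category_model_correlation(
    rdms: np.ndarray, outcome: str, model: ModelRDM | None = None
) -> np.ndarray:
    """Spearman rho between the within-outcome quadrant of each RDM and the
    category model, per time point (positive rho = category information).

    Constant quadrants yield NaN (undefined rho)."""
    if model is None:
        model = build_model_rdm("category")
    if model.size != N_REAL_EXEMPLARS:
        raise ValueError("category model must be 20 x 20")
    rdms = np.asarray(rdms, dtype=float)
    if rdms.ndim == 2:
        rdms = rdms[None]
    rows, cols = quadrant_slices(outcome)
    tril = np.tril_indices(N_REAL_EXEMPLARS, -1)
    model_vec = model.values[tril]
    rhos = np.empty(rdms.shape[0])
    for k, rdm in enumerate(rdms):
        vec = rdm[rows, cols][tril]
        if np.allclose(vec, vec[0]):
            rhos[k] = np.nan
            continue
        rhos[k] = sps.spearmanr(vec, model_vec).statistic
    return rhos


def mds_embed(rdm: np.ndarray, n_dims: int = 2, seed: int | None = 0) -> np.ndarray:
    """Metric, stress-minimizing MDS embedding of an RDM (for plots).

    Deterministic under a fixed seed.  Returns conditions x n_dims
    coordinates whose pairwise distances approximate the dissimilarities.
    """
    from sklearn.manifold import MDS

    rdm = np.asarray(rdm, dtype=float)
    n = rdm.shape[0]
    if n_dims >= n:
        raise ValueError(f"n_dims ({n_dims}) must be < n_conditions ({n})")
    d = rdm.copy()
    np.fill_diagonal(d, 0.0)
    mds = MDS(
        n_components=n_dims,
        dissimilarity="precomputed",
        metric=True,
        normalized_stress=False,
        n_init=4,
        random_state=seed,
    )
    return mds.fit_transform(d)


def mds_stress(rdm: np.ndarray, n_dims: int = 2, seed: int | None = 0) -> float:
    """Final stress of the metric MDS embedding (lower is better)."""
    from sklearn.manifold import MDS

    d = np.asarray(rdm, dtype=float).copy()
    np.fill_diagonal(d, 0.0)
    mds = MDS(
        n_components=n_dims,
        dissimilarity="precomputed",
        metric=True,
        normalized_stress=False,
        n_init=4,
        random_state=seed,
    )
    mds.fit(d)
    return float(mds.stress_)
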