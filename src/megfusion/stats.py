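"""Group-level nonparametric inference.

Implements the Wilcoxon signed-rank test (exact for small samples, normal
approximation with tie correction otherwise), the Mann-Whitney U test,
Bonferroni correction, and the two cluster-based permutation procedures
used throughout the pipeline:

* a sign-permutation test for subject-wise effect timecourses (e.g.
  decoding accuracy minus chance), with per-timepoint Wilcoxon tests as
  the cluster-defining statistic and a max-cluster-statistic null built
  by randomly flipping the sign of each subject's data;
* a condition-label permutation test for commonality timecourses, where
  the null is built by permuting the condition labels of the MEG RDMs
  (the same permutation at every time point within one draw).

Corrected p values use the add-one rule (1 + #{null >= obs}) / (1 + n_perm)
so they are never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "Cluster",
    "ClusterTestResult",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "bonferroni",
    "cluster_sign_permutation_test",
    "cluster_label_permutation_test",
]

EXACT_N_MAX = 12  # exact signed-rank null up to this sample size


@dataclass(frozen=True)
class Cluster:
    start_ms: float
    end_ms: float
    statistic: float
    corrected_p: float


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    mask: np.ndarray  # per-timepoint significance (cluster-corrected)
    time_ms: np.ndarray
    cluster_defining_alpha: float
    n_permutations: int
    seed: int | None
    null_max_stats: np.ndarray = field(repr=False, default=None)

    @property
    def any_significant(self) -> bool:
        return bool(self.mask.any())


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


def _signed_rank_parts(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop zero differences, return (ranks of |d|, signs)."""
    d = np.asarray(diffs, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite differences")
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all differences are zero; W undefined")
    ranks = sps.rankdata(np.abs(d))
    return ranks, np.sign(d)


def _exact_sf(ranks: np.ndarray, w: float) -> float:
    """P(W >= w) by exact enumeration of the 2^n sign assignments.

    Implemented as a convolution over per-observation Bernoulli rank
    contributions (equivalent to full enumeration, including under ties).
    Ranks are doubled so tied average ranks become integers.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(np.rint(2.0 * w))
    return float(pmf[w2:].sum())


def _normal_sf(ranks: np.ndarray, w: float) -> float:
    """P(W >= w) under the tie-corrected normal approximation.

    W = sum of ranks of positive differences is a sum of independent
    Bernoulli(1/2)-weighted ranks, hence mean sum(r)/2 and variance
    sum(r^2)/4 (which equals the classical tie-corrected variance).
    """
    mu = ranks.sum() / 2.0
    sigma = np.sqrt((ranks**2).sum() / 4.0)
    return float(sps.norm.sf((w - mu) / sigma))


def wilcoxon_signed_rank(
    values, mu: float = 0.0, alternative: str = "greater"
) -> tuple[float, float]:
    """Wilcoxon signed-rank test of ``values`` against location ``mu``.

    Returns (W, p) where W is the sum of the ranks of positive
    differences.  Zero differences are dropped (Wilcoxon's rule).  The
    null distribution is exact (full enumeration) for n <= 12 after zero
    removal, and a tie-corrected normal approximation otherwise.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    values = np.asarray(values, dtype=float)
    ranks, signs = _signed_rank_parts(values - mu)
    if ranks.size < 5:
        warnings.warn("fewer than 5 nonzero differences; test has little power")
    w = float(ranks[signs > 0].sum())
    sf = _exact_sf if ranks.size <= EXACT_N_MAX else _normal_sf
    total = float(ranks.sum())
    if alternative == "greater":
        p = sf(ranks, w)
    elif alternative == "less":
        # P(W <= w) = P(W' >= total - w) by symmetry of the flip W' = total - W
        p = sf(ranks, total - w)
    else:
        p = min(1.0, 2.0 * min(sf(ranks, w), sf(ranks, total - w)))
    return w, min(1.0, p)


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test (tie-corrected); thin wrapper around SciPy."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p values: min(1, p * m)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m ({m}) smaller than the number of tests ({p.size})")
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# Cluster sign-permutation test
# ---------------------------------------------------------------------------


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (start, stop) half-open index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


class _SignedRankEngine:
    """Vectorized per-timepoint Wilcoxon tests under sign permutation.

    |d| — and therefore the rank matrix, the tie correction, and any exact
    null distribution — are invariant under sign flips, so they are
    computed once; each permutation then reduces to array arithmetic.
    """

    def __init__(self, d: np.ndarray):
        n_sub, n_time = d.shape
        absd = np.abs(d)
        nonzero = absd > 0
        if not nonzero.any(axis=0).all():
            bad = int(np.flatnonzero(~nonzero.any(axis=0))[0])
            raise ValueError(f"all differences zero at time index {bad}")
        ranks = np.zeros_like(d)
        for t in range(n_time):
            nz = nonzero[:, t]
            ranks[nz, t] = sps.rankdata(absd[nz, t])
        self.ranks = ranks
        self.sign_d = np.sign(d)
        self.rank_total = ranks.sum(axis=0)
        self.normal_cols = nonzero.sum(axis=0) > EXACT_N_MAX
        self.mu = self.rank_total / 2.0
        self.sigma = np.sqrt((ranks**2).sum(axis=0) / 4.0)
        # exact survival tables, indexed by round(2 W)
        self.sf_tables: dict[int, np.ndarray] = {}
        for t in np.flatnonzero(~self.normal_cols):
            r2 = np.rint(2.0 * ranks[nonzero[:, t], t]).astype(int)
            total = int(r2.sum())
            pmf = np.zeros(total + 1)
            pmf[0] = 1.0
            for r in r2:
                shifted = np.zeros_like(pmf)
                shifted[r:] = pmf[: total + 1 - r]
                pmf = 0.5 * (pmf + shifted)
            self.sf_tables[t] = np.cumsum(pmf[::-1])[::-1]

    def w_and_p(self, signs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(W, one-sided 'greater' p), each n_perm x n_time, for sign
        matrices of shape n_perm x n_subjects (use +1s for the observed
        data)."""
        signs = np.atleast_2d(signs)
        # rank contribution of subject j is ranks * (1 + s_j * sign(d)) / 2
        w = 0.5 * (self.rank_total[None, :] + signs @ (self.ranks * self.sign_d))
        p = np.empty_like(w)
        nc = self.normal_cols
        p[:, nc] = sps.norm.sf((w[:, nc] - self.mu[nc]) / self.sigma[nc])
        for t, table in self.sf_tables.items():
            idx = np.rint(2.0 * w[:, t]).astype(int)
            p[:, t] = table[np.clip(idx, 0, table.size - 1)]
        return w, p


def _clusters_from_stats(
    stat: np.ndarray, suprathreshold: np.ndarray
) -> list[tuple[int, int, float]]:
    return [
        (a, b, float(stat[a:b].sum())) for a, b in _contiguous_runs(suprathreshold)
    ]


def cluster_sign_permutation_test(
    subject_effects: np.ndarray,
    chance: float = 0.0,
    time_ms: np.ndarray | None = None,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ClusterTestResult:
    """One-sided cluster-corrected test of subjects x time effects > chance.

    Per time point, a one-sided Wilcoxon signed-rank test against
    ``chance`` defines suprathreshold time points (p < ``alpha``); clusters
    are maximal contiguous runs scored by the sum of W statistics.  The
    null is built by flipping the sign of each subject's (effect - chance)
    timecourse with probability 1/2 and recording the maximum cluster
    statistic of each permutation.  A cluster is significant when its
    statistic exceeds the 95th percentile of that null (corrected p,
    add-one rule, <= alpha).
    """
    effects = np.asarray(subject_effects, dtype=float)
    if effects.ndim != 2:
        raise ValueError("subject_effects must be subjects x time")
    if effects.shape[0] < 5:
        raise ValueError(f"need >= 5 subjects, got {effects.shape[0]}")
    if not np.all(np.isfinite(effects)):
        raise ValueError("non-finite values in subject_effects")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p values will be coarse")
    n_sub, n_time = effects.shape
    if time_ms is None:
        time_ms = np.arange(n_time, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)

    d = effects - chance
    engine = _SignedRankEngine(d)
    w_obs, p_obs = (a[0] for a in engine.w_and_p(np.ones((1, n_sub))))
    observed = _clusters_from_stats(w_obs, p_obs < alpha)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    w_null, p_null = engine.w_and_p(signs)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        runs = _clusters_from_stats(w_null[i], p_null[i] < alpha)
        null_max[i] = max((s for _, _, s in runs), default=0.0)

    clusters = []
    mask = np.zeros(n_time, dtype=bool)
    for a, b, stat in observed:
        p_corr = (1.0 + np.sum(null_max >= stat)) / (1.0 + n_perm)
        clusters.append(Cluster(time_ms[a], time_ms[b - 1], stat, p_corr))
        if p_corr <= alpha:
            mask[a:b] = True
    return ClusterTestResult(
        clusters=clusters,
        mask=mask,
        time_ms=time_ms,
        cluster_defining_alpha=alpha,
        n_permutations=n_perm,
        seed=seed,
        null_max_stats=null_max,
    )


# ---------------------------------------------------------------------------
# Cluster label-permutation test (for commonality timecourses)
# ---------------------------------------------------------------------------


def cluster_label_permutation_test(
    meg_rdms: np.ndarray,
    fmri_rdm: np.ndarray,
    model_rdm: np.ndarray,
    time_ms: np.ndarray | None = None,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ClusterTestResult:
    """Cluster-corrected significance of a commonality timecourse.

    The observed statistic is the commonality coefficient C(t) between the
    MEG RDM at each time point, the (fixed) fMRI RDM, and the model RDM.
    Each permutation applies one random simultaneous row/column permutation
    of the MEG RDM condition labels — the same permutation at every time
    point, preserving the temporal structure of the null — and recomputes
    C(t).  The cluster-defining threshold at each time point is the 95th
    percentile of the permuted C values at that time point; clusters of
    suprathreshold observed C are scored by summed C against the
    max-cluster-statistic null.
    """
    from .fusion import _commonality_from_ranks, _prepare_rank_vectors

    meg_rdms = np.asarray(meg_rdms, dtype=float)
    if meg_rdms.ndim == 2:
        meg_rdms = meg_rdms[None]
    n_time, n_cond, _ = meg_rdms.shape
    if time_ms is None:
        time_ms = np.arange(n_time, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p values will be coarse")

    meg_ranks, f_ranks, m_ranks, pair_index = _prepare_rank_vectors(
        meg_rdms, fmri_rdm, model_rdm
    )
    c_obs = _commonality_from_ranks(meg_ranks, f_ranks, m_ranks)

    # a condition permutation induces a permutation of the pair entries;
    # ranks permute with the entries, so permuted rank vectors are just
    # reindexed columns of the precomputed rank matrix
    rng = np.random.default_rng(seed)
    n_pairs = meg_ranks.shape[1]
    c_null = np.empty((n_perm, n_time))
    for i in range(n_perm):
        perm = rng.permutation(n_cond)
        sigma = _pair_permutation(pair_index, perm, n_cond)
        c_null[i] = _commonality_from_ranks(meg_ranks[:, sigma], f_ranks, m_ranks)

    thresh = np.percentile(c_null, 100.0 * (1.0 - alpha), axis=0)
    observed = _clusters_from_stats(c_obs, c_obs > thresh)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        runs = _clusters_from_stats(c_null[i], c_null[i] > thresh)
        null_max[i] = max((s for _, _, s in runs), default=0.0)

    clusters = []
    mask = np.zeros(n_time, dtype=bool)
    for a, b, stat in observed:
        p_corr = (1.0 + np.sum(null_max >= stat)) / (1.0 + n_perm)
        clusters.append(Cluster(time_ms[a], time_ms[b - 1], stat, p_corr))
        if p_corr <= alpha:
            mask[a:b] = True
    return ClusterTestResult(
        clusters=clusters,
        mask=mask,
        time_ms=time_ms,
        cluster_defining_alpha=alpha,
        n_permutations=n_perm,
        seed=seed,
        null_max_stats=null_max,
    )


def _pair_permutation(
    pair_index: np.ndarray, perm: np.ndarray, n_cond: int
) -> np.ndarray:
    """Map a condition permutation to a permutation of lower-triangle pairs.

    ``pair_index`` is a (n_pairs, 2) array of (row, col) positions and
    ``perm[k]`` is the new label of condition k.  Entry p of the permuted
    vector is the original entry at conditions (perm[i], perm[j])."""
    lut = np.full((n_cond, n_cond), -1, dtype=int)
    for p, (i, j) in enumerate(pair_index):
        lut[i, j] = lut[j, i] = p
    i, j = perm[pair_index[:, 0]], perm[pair_index[:, 1]]
    return lut[i, j]
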