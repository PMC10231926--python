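"""Nonparametric inference: signed-rank/U tests and cluster permutation."""

from itertools import combinations, product

import numpy as np
import pytest
from scipy import stats as sps

from megfusion.stats import (
    bonferroni,
    cluster_label_permutation_test,
    cluster_sign_permutation_test,
    mann_whitney,
    wilcoxon_signed_rank,
)


def wilcoxon_enumeration_oracle(values, mu, alternative="greater"):
    """Exhaustive enumeration over all 2^n sign assignments."""
    d = np.asarray(values, float) - mu
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        np.asarray(signs) @ ranks
        for signs in product([0.0, 1.0], repeat=d.size)
    ]
    ws = np.asarray(ws)
    p_ge = np.mean(ws >= w_obs)
    p_le = np.mean(ws <= w_obs)
    if alternative == "greater":
        return w_obs, p_ge
    if alternative == "less":
        return w_obs, p_le
    return w_obs, min(1.0, 2 * min(p_ge, p_le))


def mannwhitney_enumeration_oracle(x, y, alternative="two-sided"):
    """Exhaustive enumeration over all group assignments of the pooled data."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n = x.size

    def u_stat(xs, ys):
        u = 0.0
        for xi in xs:
            for yi in ys:
                u += (xi > yi) + 0.5 * (xi == yi)
        return u

    u_obs = u_stat(x, y)
    idx = np.arange(pooled.size)
    us = []
    for keep in combinations(idx, n):
        keep = list(keep)
        rest = [i for i in idx if i not in keep]
        us.append(u_stat(pooled[keep], pooled[rest]))
    us = np.asarray(us)
    if alternative == "two-sided":
        mu = n * y.size / 2.0
        return u_obs, np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
    raise NotImplementedError


class TestWilcoxon:
    def test_all_positive_n10_single_extreme_ordering(self):
        w, p = wilcoxon_signed_rank(np.arange(1.0, 11.0), 0.0, "greater")
        assert w == 55.0
        assert p == pytest.approx(1.0 / 2**10)

    def test_symmetric_values_two_sided_near_one(self):
        vals = np.array([-4.0, -3.0, -2.0, -1.0, 1.0, 2.0, 3.0, 4.0])
        _, p = wilcoxon_signed_rank(vals, 0.0, "two-sided")
        assert p > 0.9

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
    def test_matches_exhaustive_enumeration_n6(self, seed, alternative):
        rng = np.random.default_rng(seed)
        vals = np.round(rng.normal(0.3, 1.0, 6), 2)
        vals = vals[vals != 0.0]
        if vals.size < 5:
            pytest.skip("degenerate draw")
        w, p = wilcoxon_signed_rank(vals, 0.0, alternative)
        w_ref, p_ref = wilcoxon_enumeration_oracle(vals, 0.0, alternative)
        assert w == w_ref
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0.5, 1.0, 11)
        _, p = wilcoxon_signed_rank(vals, 0.0, "greater")
        ref = sps.wilcoxon(vals, alternative="greater", method="exact").pvalue
        assert p == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_boundary(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0.4, 1.0, 30)
        _, p = wilcoxon_signed_rank(vals, 0.0, "greater")
        ref = sps.wilcoxon(vals, alternative="greater", method="approx",
                           correction=False).pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(np.full(8, 5.0), 5.0)


class TestMannWhitneyAndBonferroni:
    def test_identical_samples_two_sided_p_near_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        _, p = mann_whitney(x, x + 0.0)
        assert p > 0.85

    def test_matches_exhaustive_enumeration_n4(self):
        rng = np.random.default_rng(0)
        x = np.round(rng.normal(0, 1, 4), 2)
        y = np.round(rng.normal(1, 1, 4), 2)
        u, p = mann_whitney(x, y, "two-sided")
        u_ref, p_ref = mannwhitney_enumeration_oracle(x, y)
        assert u == u_ref
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney([], [1.0])

    def test_bonferroni_adjustment(self):
        np.testing.assert_allclose(bonferroni([0.01], m=5), [0.05])
        np.testing.assert_allclose(bonferroni([0.5, 0.9], m=4), [1.0, 1.0])
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], m=2)


class TestClusterSignPermutation:
    def test_sustained_effect_yields_one_covering_cluster(self):
        rng = np.random.default_rng(0)
        effects = 50.0 + rng.normal(0, 1.0, (12, 40))
        effects[:, 10:25] += 5.0  # strong sustained group effect
        res = cluster_sign_permutation_test(
            effects, chance=50.0, n_perm=800, seed=1
        )
        sig = [c for c in res.clusters if c.corrected_p <= 0.05]
        assert len(sig) == 1
        assert sig[0].start_ms <= 10 and sig[0].end_ms >= 24
        assert sig[0].corrected_p <= 2.0 / 800

    def test_isolated_subthreshold_blips_not_significant(self):
        rng = np.random.default_rng(2)
        effects = rng.normal(0, 1.0, (10, 60))
        effects[:, 30] += 0.4  # single-timepoint nudge
        res = cluster_sign_permutation_test(effects, 0.0, n_perm=400, seed=0)
        assert not res.any_significant

    def test_corrected_p_monotone_in_cluster_statistic(self):
        rng = np.random.default_rng(5)
        effects = rng.normal(0.0, 1.0, (14, 80))
        effects[:, 10:30] += 1.2
        effects[:, 50:55] += 0.9
        res = cluster_sign_permutation_test(effects, 0.0, n_perm=400, seed=0)
        if len(res.clusters) >= 2:
            stats_ = [c.statistic for c in res.clusters]
            ps = [c.corrected_p for c in res.clusters]
            order = np.argsort(stats_)
            assert np.all(np.diff(np.array(ps)[order]) <= 1e-12)

    def test_identical_seed_identical_result(self):
        rng = np.random.default_rng(1)
        effects = rng.normal(0.2, 1.0, (9, 30))
        a = cluster_sign_permutation_test(effects, 0.0, n_perm=300, seed=9)
        b = cluster_sign_permutation_test(effects, 0.0, n_perm=300, seed=9)
        np.testing.assert_array_equal(a.null_max_stats, b.null_max_stats)
        assert a.clusters == b.clusters

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            cluster_sign_permutation_test(np.zeros((4, 10)) + 1.0, 0.0)

    def test_nonfinite_input_rejected(self):
        effects = np.ones((6, 10))
        effects[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            cluster_sign_permutation_test(effects, 0.0)


class TestClusterLabelPermutation:
    def test_identical_seed_identical_permutation_stream(self, group_rdms):
        from megfusion import rsa

        rdms, times = group_rdms
        fmri = rdms[(times >= 500).argmax()]
        model = rsa.build_model_rdm("two_state").values
        a = cluster_label_permutation_test(rdms, fmri, model, times, n_perm=120, seed=4)
        b = cluster_label_permutation_test(rdms, fmri, model, times, n_perm=120, seed=4)
        assert a.clusters == b.clusters
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_planted_commonality_detected_in_window(self, group_rdms, small_config):
        from megfusion import rsa
        from megfusion.synthgen import generate_fmri_patterns

        rdms, times = group_rdms
        betas, _ = generate_fmri_patterns(small_config, mode="betas")
        fmri_rdm = rsa.compute_rdm(betas["V1"])
        model = rsa.build_model_rdm("two_state").values
        res = cluster_label_permutation_test(
            rdms, fmri_rdm, model, times, n_perm=300, seed=0
        )
        window = (times >= small_config.two_state_offset.start_ms) & (
            times <= small_config.two_state_offset.end_ms
        )
        coverage = res.mask[window].mean()
        assert coverage >= 0.8
        assert not res.mask[times < 0].any()

    def test_structureless_rdms_rarely_significant(self):
        rng = np.random.default_rng(0)
        from megfusion import rsa

        model = rsa.build_model_rdm("two_state").values
        hits = 0
        n_rep = 30
        for i in range(n_rep):
            def rnd():
                m = rng.random((40, 40))
                m = (m + m.T) / 2
                np.fill_diagonal(m, np.nan)
                return m
            meg = np.stack([rnd() for _ in range(12)])
            res = cluster_label_permutation_test(
                meg, rnd(), model, n_perm=150, seed=i
            )
            hits += res.any_significant
        assert hits <= 5  # ~binomial(30, 0.05) upper tail
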