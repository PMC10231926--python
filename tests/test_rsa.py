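"""RSA: correlation-distance RDMs, model RDMs, quadrant analyses, MDS."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import null_dataset
from megfusion import rsa
from megfusion.conditions import quadrant_slices
from megfusion.fusion import rdm_to_vector


def manual_pearson(x, y):
    """Direct evaluation of the Pearson formula (test oracle)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


def manual_spearman(x, y):
    """Rank correlation via explicit average ranks (test oracle)."""

    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        r = np.empty(v.size)
        i = 0
        sv = v[order]
        while i < v.size:
            j = i
            while j + 1 < v.size and sv[j + 1] == sv[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    return manual_pearson(ranks(x), ranks(y))


class TestComputeRdm:
    def test_identical_patterns_have_zero_dissimilarity(self):
        p = np.tile([1.0, 2.0, 5.0, 3.0], (3, 1))
        rdm = rsa.compute_rdm(p)
        off = rdm[~np.isnan(rdm)]
        assert np.allclose(off, 0.0)

    def test_anticorrelated_patterns_have_dissimilarity_two(self):
        p = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert rsa.compute_rdm(p)[0, 1] == pytest.approx(2.0)

    def test_matches_hand_evaluated_pearson_formula(self):
        x, y = [1.0, 2.0, 4.0], [2.0, 1.0, 3.0]
        rdm = rsa.compute_rdm(np.array([x, y]))
        assert rdm[0, 1] == pytest.approx(1.0 - manual_pearson(x, y), abs=1e-12)

    def test_zero_variance_condition_named_in_error(self):
        p = np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]])
        with pytest.raises(ValueError, match="cond_b"):
            rsa.compute_rdm(p, condition_names=["cond_a", "cond_b"])

    def test_invariant_to_offset_and_positive_rescale(self):
        rng = np.random.default_rng(0)
        p = rng.standard_normal((5, 20))
        base = rsa.compute_rdm(p)
        shifted = rsa.compute_rdm(3.7 * p + 11.0)
        np.testing.assert_allclose(base, shifted, atol=1e-12)


class TestRdmTimecourse:
    def test_grid_arithmetic_400hz(self):
        # 400 Hz over -500..2000 ms at 2.5 ms steps -> 1001 RDMs
        ds = null_dataset(reps=1, n_sensors=6, n_times=1001, sfreq_hz=400.0)
        rdms, times = rsa.rdm_timecourse(ds, step_ms=2.5)
        assert rdms.shape == (1001, 40, 40)
        assert times[0] == -500.0 and times[-1] == 2000.0

    def test_noise_only_entries_near_one(self):
        ds = null_dataset(reps=3, n_sensors=64, n_times=3, seed=4)
        rdms, _ = rsa.rdm_timecourse(ds, step_ms=1000.0)
        off = rdms[0][~np.isnan(rdms[0])]
        assert abs(off.mean() - 1.0) < 0.05

    def test_group_average_equals_average_of_subject_rdms(self, group_rdms):
        rdms, _ = group_rdms
        # symmetry and masked diagonal survive averaging
        assert np.allclose(rdms, np.swapaxes(rdms, 1, 2), equal_nan=True)
        assert np.isnan(rdms[:, np.arange(40), np.arange(40)]).all()

    def test_missing_condition_rejected(self):
        ds = null_dataset(reps=1, n_times=3)
        ds.labels.loc[0, "exemplar"] = 2  # exemplar 1 of face/recognized lost
        with pytest.raises(ValueError, match="missing conditions"):
            rsa.rdm_timecourse(ds, step_ms=1000.0)


class TestModelRdms:
    def test_recognition_model_structure(self):
        m = rsa.build_model_rdm("recognition").values
        rr, rc = quadrant_slices("recognized")
        ur, uc = quadrant_slices("unrecognized")
        off = ~np.eye(20, dtype=bool)
        assert np.all(m[rr, rc][off] == 0.0)
        assert np.all(m[ur, uc][off] == 1.0)
        assert np.all(m[0:20, 20:40] == 1.0)

    def test_two_state_model_structure(self):
        m = rsa.build_model_rdm("two_state").values
        off = ~np.eye(20, dtype=bool)
        for outcome in ("recognized", "unrecognized"):
            r, c = quadrant_slices(outcome)
            assert np.all(m[r, c][off] == 0.0)
        assert np.all(m[0:20, 20:40] == 1.0)

    def test_category_model_is_20x20_block_structure(self):
        m = rsa.build_model_rdm("category")
        assert m.values.shape == (20, 20)
        assert m.values[0, 1] == 0.0  # same category (face ex1 vs ex2)
        assert m.values[0, 5] == 1.0  # face vs animal

    def test_recognition_two_state_rank_correlation(self):
        # brute-force rank-correlation oracle; strictly between 0 and 1
        a = rdm_to_vector(rsa.build_model_rdm("recognition").values)
        b = rdm_to_vector(rsa.build_model_rdm("two_state").values)
        rho = manual_spearman(a, b)
        assert 0.0 < rho < 1.0
        assert sps.spearmanr(a, b).statistic == pytest.approx(rho, abs=1e-12)

    def test_model_levels_only_matter_by_rank(self):
        rng = np.random.default_rng(3)
        data = rng.random((40, 40))
        data = (data + data.T) / 2
        np.fill_diagonal(data, np.nan)
        m = rsa.build_model_rdm("recognition").values
        transformed = np.where(m == 1.0, 7.5, 0.2)  # any (low, high) pair
        np.fill_diagonal(transformed, np.nan)
        r1 = sps.spearmanr(rdm_to_vector(data), rdm_to_vector(m)).statistic
        r2 = sps.spearmanr(rdm_to_vector(data), rdm_to_vector(transformed)).statistic
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            rsa.build_model_rdm("three_state")


class TestQuadrantAnalyses:
    def test_quadrant_means_recover_block_values(self):
        rdm = np.full((40, 40), 0.8)
        rdm[:20, :20] = 0.2
        np.fill_diagonal(rdm, np.nan)
        mean_r, mean_u = rsa.mean_group_dissimilarity(rdm[None])
        assert mean_r[0] == pytest.approx(0.2)
        assert mean_u[0] == pytest.approx(0.8)

    def test_identical_quadrants_not_significant(self):
        rng = np.random.default_rng(0)
        # subjects x time x 40 x 40 symmetric noise, no R/U asymmetry
        subs = []
        for s in range(6):
            r = rng.random((8, 40, 40))
            r = (r + np.swapaxes(r, 1, 2)) / 2
            subs.append(r)
        subs = np.stack(subs)
        _, _, result = rsa.mean_group_dissimilarity_test(
            subs, np.arange(8.0), n_perm=200, seed=0
        )
        assert not result.any_significant

    def test_planted_shrinkage_yields_significant_cluster(self, group_rdms):
        rdms, times = group_rdms
        subs = rdms[None] + np.random.default_rng(1).normal(
            0, 0.005, (12,) + rdms.shape
        )
        _, _, result = rsa.mean_group_dissimilarity_test(
            subs, times, n_perm=300, seed=0
        )
        sig = times[result.mask]
        assert result.any_significant
        assert sig.min() >= 100.0 and sig.max() <= 1900.0

    def test_category_correlation_identity_and_null(self):
        model = rsa.build_model_rdm("category")
        rdm = np.ones((40, 40))
        rdm[:20, :20] = np.where(model.values == 1.0, 1.5, 0.5)
        np.fill_diagonal(rdm, np.nan)
        rho = rsa.category_model_correlation(rdm, "recognized")
        assert rho[0] == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        noise = rng.random((40, 40))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, np.nan)
        assert abs(rsa.category_model_correlation(noise, "recognized")[0]) < 0.2

    def test_planted_category_structure_only_in_recognized_quadrant(
        self, group_rdms
    ):
        rdms, times = group_rdms
        window = (times >= 400) & (times <= 1000)
        rho_r = rsa.category_model_correlation(rdms, "recognized")
        rho_u = rsa.category_model_correlation(rdms, "unrecognized")
        assert rho_r[window].mean() > 0.25
        assert abs(rho_u[window].mean()) < 0.1

    def test_constant_quadrant_reported_missing(self):
        rdm = np.ones((40, 40))
        np.fill_diagonal(rdm, np.nan)
        assert np.isnan(rsa.category_model_correlation(rdm, "recognized")[0])


class TestMds:
    def test_equidistant_conditions_embed_as_equilateral_triangle(self):
        rdm = np.full((3, 3), 1.0)
        np.fill_diagonal(rdm, np.nan)
        xy = rsa.mds_embed(rdm, n_dims=2, seed=0)
        d = [np.linalg.norm(xy[i] - xy[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
        assert np.allclose(d, d[0], rtol=1e-3)

    def test_zero_dissimilarity_pair_is_coincident(self):
        rdm = np.array(
            [[np.nan, 0.0, 1.0], [0.0, np.nan, 1.0], [1.0, 1.0, np.nan]]
        )
        xy = rsa.mds_embed(rdm, n_dims=2, seed=0)
        assert np.linalg.norm(xy[0] - xy[1]) < 1e-3

    def test_stress_non_increasing_with_more_dimensions(self):
        rng = np.random.default_rng(2)
        m = rng.random((8, 8))
        rdm = (m + m.T) / 2
        np.fill_diagonal(rdm, np.nan)
        s1 = rsa.mds_stress(rdm, n_dims=1, seed=0)
        s2 = rsa.mds_stress(rdm, n_dims=2, seed=0)
        assert s2 <= s1 + 1e-9

    def test_too_many_dimensions_rejected(self):
        rdm = np.full((3, 3), 1.0)
        with pytest.raises(ValueError, match="n_dims"):
            rsa.mds_embed(rdm, n_dims=3)
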