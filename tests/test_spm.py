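"""Statistic fields against classical per-node oracles, smoothness, clusters."""

import numpy as np
import pytest
from scipy import stats

from cyclespm.datatypes import CriticalThreshold, SmoothnessEstimate, StatField
from cyclespm.spm import (
    HotellingT2SPM,
    TwoSampleTSPM,
    bonferroni_alpha,
    cca_x2_field,
    cluster_inference,
    estimate_fwhm,
    hotelling_t2_field,
    regression_t_field,
    suprathreshold_segments,
    two_sample_t_field,
)
from cyclespm.synthetic import sample_smooth_fields


class TestTwoSampleTField:
    def test_identical_groups_give_zero_field(self):
        Y = np.arange(30.0).reshape(3, 10)
        field = two_sample_t_field(Y, Y.copy())
        # zero difference with zero pooled variance floor protection
        np.testing.assert_allclose(field.values, 0.0)

    def test_single_node_classical_value(self):
        A = np.array([[0.0], [1.0], [2.0]])
        B = np.array([[3.0], [4.0], [5.0]])
        field = two_sample_t_field(A, B)
        assert field.values[0] == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-3)
        assert field.values[0] == pytest.approx(-3.674, abs=1e-3)
        assert field.df == 4.0

    def test_every_node_matches_scipy(self, rng):
        A = rng.normal(size=(8, 21))
        B = rng.normal(size=(6, 21)) + 0.3
        field = two_sample_t_field(A, B)
        oracle = stats.ttest_ind(A, B, axis=0).statistic
        np.testing.assert_allclose(field.values, oracle, atol=1e-10)

    def test_zero_variance_nodes_are_floored_and_flagged(self):
        A = np.ones((4, 5))
        B = np.zeros((4, 5))
        field = two_sample_t_field(A, B)
        assert np.all(np.isfinite(field.values))
        assert field.extras["variance_floor_flag"] == list(range(5))


class TestHotellingT2Field:
    def test_p1_reduces_to_squared_t(self, rng):
        A = rng.normal(size=(7, 15))
        B = rng.normal(size=(9, 15))
        t2 = hotelling_t2_field(A[:, :, None], B[:, :, None]).values
        t = two_sample_t_field(A, B).values
        np.testing.assert_allclose(t2, t**2, atol=1e-10)

    def test_small_case_matches_direct_matrix_formula(self, rng):
        n1 = n2 = 5
        A = rng.normal(size=(n1, 4, 2))
        B = rng.normal(size=(n2, 4, 2))
        field = hotelling_t2_field(A, B)
        for q in range(4):
            d = A[:, q].mean(0) - B[:, q].mean(0)
            Ra = A[:, q] - A[:, q].mean(0)
            Rb = B[:, q] - B[:, q].mean(0)
            S = (Ra.T @ Ra + Rb.T @ Rb) / (n1 + n2 - 2)
            expected = (n1 * n2 / (n1 + n2)) * d @ np.linalg.solve(S, d)
            assert field.values[q] == pytest.approx(expected, abs=1e-10)

    def test_affine_invariance(self, rng):
        A = rng.normal(size=(6, 8, 3))
        B = rng.normal(size=(7, 8, 3)) + 0.5
        M = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        base = hotelling_t2_field(A, B).values
        mapped = hotelling_t2_field(A @ M.T, B @ M.T).values
        np.testing.assert_allclose(mapped, base, atol=1e-8)

    def test_df_and_sample_sizes_recorded(self, rng):
        field = hotelling_t2_field(rng.normal(size=(5, 4, 2)), rng.normal(size=(6, 4, 2)))
        assert field.df == (2, 9.0)
        assert field.sample_sizes == (5, 6)

    def test_insufficient_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            hotelling_t2_field(rng.normal(size=(2, 4, 3)), rng.normal(size=(2, 4, 3)))


class TestRegressionTField:
    def test_zero_slope_noise_free_gives_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        Y = np.ones((4, 6))
        field = regression_t_field(Y, x)
        np.testing.assert_allclose(field.values, 0.0)

    def test_perfect_fit_is_capped_and_flagged(self):
        x = np.array([1.0, 2.0, 3.0])
        Y = (2 * x)[:, None]
        field = regression_t_field(Y, x, stat_cap=1e6)
        assert field.values[0] == 1e6
        assert field.extras["cap_flag"] == [0]

    def test_every_node_matches_scipy_linregress(self, rng):
        x = rng.normal(size=12)
        Y = rng.normal(size=(12, 9)) + np.outer(x, rng.normal(size=9))
        field = regression_t_field(Y, x)
        for q in range(9):
            res = stats.linregress(x, Y[:, q])
            oracle = res.slope / res.stderr
            assert field.values[q] == pytest.approx(oracle, abs=1e-10)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regression_t_field(np.random.default_rng(0).normal(size=(5, 3)), np.ones(5))


class TestCcaX2Field:
    def test_p1_r_squared_is_pearson_squared(self, rng):
        x = rng.normal(size=20)
        Y = rng.normal(size=(20, 7))
        field = cca_x2_field(Y[:, :, None], x)
        for q in range(7):
            r = stats.pearsonr(x, Y[:, q]).statistic
            assert field.extras["r"][q] ** 2 == pytest.approx(r**2, abs=1e-10)

    def test_bartlett_transform_applied(self, rng):
        x = rng.normal(size=15)
        Y = rng.normal(size=(15, 4, 2))
        field = cca_x2_field(Y, x)
        n, p = 15, 2
        coef = n - 1 - (p + 2) / 2
        r2 = field.extras["r"] ** 2
        np.testing.assert_allclose(field.values, -coef * np.log(1 - r2), atol=1e-10)

    def test_multivariate_r_matches_multiple_correlation_oracle(self, rng):
        x = rng.normal(size=25)
        Y = rng.normal(size=(25, 3, 2)) + x[:, None, None] * 0.5
        field = cca_x2_field(Y, x)
        for q in range(3):
            # multiple correlation of x on the two components via OLS
            X = np.column_stack([np.ones(25), Y[:, q, 0], Y[:, q, 1]])
            beta, *_ = np.linalg.lstsq(X, x, rcond=None)
            resid = x - X @ beta
            r2 = 1 - resid.var() / x.var()
            assert field.extras["r"][q] ** 2 == pytest.approx(r2, abs=1e-10)

    def test_null_mean_near_chi2_mean(self):
        # X2 with p components is approximately chi-square with p df under
        # the null, so its node average should sit near p
        rng = np.random.default_rng(5)
        means = []
        for _ in range(200):
            x = rng.normal(size=40)
            Y = rng.normal(size=(40, 11, 2))
            means.append(cca_x2_field(Y, x).values.mean())
        assert np.mean(means) == pytest.approx(2.0, abs=0.15)

    def test_perfect_correlation_capped_and_flagged(self):
        x = np.linspace(0.0, 1.0, 10)
        Y = np.tile(x[:, None], (1, 3))[:, :, None]
        field = cca_x2_field(Y, x, stat_cap=500.0)
        assert np.all(field.values == 500.0)
        assert field.extras["cap_flag"] == [0, 1, 2]

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            cca_x2_field(rng.normal(size=(10, 4, 2)), np.full(10, 3.0))


class TestEstimateFwhm:
    def test_recovers_generator_smoothness(self):
        fields = sample_smooth_fields(500, 101, fwhm=20, sd=1.0, seed=99)
        est = estimate_fwhm(fields)
        assert 17.0 <= est.fwhm <= 23.0
        assert est.resels == pytest.approx(100.0 / est.fwhm)

    def test_white_noise_is_rougher_than_any_smoothed_field(self, rng):
        white = rng.normal(size=(200, 101))
        smoothed = sample_smooth_fields(200, 101, fwhm=5, sd=1.0, seed=1)
        assert estimate_fwhm(white).fwhm < estimate_fwhm(smoothed).fwhm

    def test_vanishing_gradient_gives_zero_resels(self):
        # almost-constant fields with a tiny common slope: near-zero roughness
        base = np.linspace(0, 1e-9, 101)
        fields = np.vstack([base + c for c in (1.0, 2.0, -1.0)])
        est = estimate_fwhm(fields - fields.mean(0))
        assert est.resels < 1e-3

    def test_all_zero_residuals_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            estimate_fwhm(np.zeros((5, 20)))


class TestClusterGeometry:
    def test_field_below_threshold_yields_no_clusters(self):
        field = StatField(np.full(101, 1.0), "t", 28.0)
        thr = CriticalThreshold(u=3.0, alpha=0.05, method="rft", two_tailed=True)
        smooth = SmoothnessEstimate(fwhm=10.0, resels=10.0)
        assert cluster_inference(field, thr, smooth) == []

    def test_plateau_cluster_endpoints_and_extent(self):
        z = np.zeros(101)
        z[10:31] = 5.0
        thr = CriticalThreshold(u=3.0, alpha=0.05, method="rft", two_tailed=False)
        smooth = SmoothnessEstimate(fwhm=10.0, resels=10.0)
        clusters = cluster_inference(StatField(z, "t", 28.0), thr, smooth)
        assert len(clusters) == 1
        c = clusters[0]
        # crossings interpolate between node 9 (z=0) and 10 (z=5) at u=3
        assert c.start_pct == pytest.approx(9.6)
        assert c.end_pct == pytest.approx(30.4)
        assert c.extent_pct == pytest.approx(20.8)
        assert 0 < c.p_value <= 1

    def test_negative_cluster_found_in_two_tailed_scan(self):
        z = np.zeros(101)
        z[50:60] = -5.0
        thr = CriticalThreshold(u=3.0, alpha=0.05, method="rft", two_tailed=True)
        smooth = SmoothnessEstimate(fwhm=10.0, resels=10.0)
        clusters = cluster_inference(StatField(z, "t", 28.0), thr, smooth)
        assert len(clusters) == 1
        assert clusters[0].sign == -1

    def test_segments_split_on_subthreshold_gaps(self):
        z = np.zeros(50)
        z[5:10] = 4.0
        z[20:30] = 4.0
        segs = suprathreshold_segments(z, 3.0)
        assert len(segs) == 2


class TestEstimators:
    def test_fitted_attributes_and_significance(self):
        rng = np.random.default_rng(2)
        A = sample_smooth_fields(12, 101, 15, 1.0, rng)
        B = sample_smooth_fields(12, 101, 15, 1.0, rng) + 2.0
        model = TwoSampleTSPM(alpha=0.05).fit(A, B)
        assert model.statistic_.shape == (101,)
        assert model.threshold_.u > 0
        assert model.significant_
        assert model.clusters_[0].sign == -1  # A sits below B

    def test_sklearn_param_interface(self):
        model = HotellingT2SPM(alpha=0.01)
        assert model.get_params()["alpha"] == 0.01
        model.set_params(alpha=0.2)
        assert model.alpha == 0.2

    def test_null_fit_is_rarely_significant(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(40):
            A = sample_smooth_fields(10, 101, 15, 1.0, rng)
            B = sample_smooth_fields(10, 101, 15, 1.0, rng)
            hits += TwoSampleTSPM().fit(A, B).significant_
        assert hits <= 6  # ~alpha of 40, generous bound

    def test_summary_is_json_serializable(self):
        import json

        rng = np.random.default_rng(4)
        A = sample_smooth_fields(6, 51, 10, 1.0, rng)
        B = sample_smooth_fields(6, 51, 10, 1.0, rng)
        model = TwoSampleTSPM().fit(A, B)
        json.dumps(model.summary())


@pytest.mark.parametrize("alpha,n,expected", [(0.05, 3, 0.05 / 3), (0.05, 1, 0.05), (0.05, 2, 0.025)])
def test_bonferroni_alpha(alpha, n, expected):
    assert bonferroni_alpha(alpha, n) == pytest.approx(expected)


def test_bonferroni_rejects_nonpositive_components():
    with pytest.raises(ValueError):
        bonferroni_alpha(0.05, 0)
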