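import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from passivecbt import outcomes as oc


class TestPercentImprovement:
    def test_half_improvement(self):
        assert oc.percent_improvement(30, 15) == pytest.approx(50.0)

    def test_no_change(self):
        assert oc.percent_improvement(30, 30) == 0.0

    def test_worsening_is_negative(self):
        assert oc.percent_improvement(20, 30) == pytest.approx(-50.0)

    def test_zero_baseline_raises(self):
        with pytest.raises(ValueError):
            oc.percent_improvement(0, 10)

    @given(
        baseline=st.integers(1, 48),
        delta=st.integers(-20, 20),
    )
    def test_matches_direct_formula(self, baseline, delta):
        post = baseline + delta
        got = oc.percent_improvement(baseline, post)
        assert got == pytest.approx(100.0 * (baseline - post) / baseline)
        # symmetric sign behavior around no-change
        assert (got > 0) == (post < baseline)


class TestNormalityScreen:
    def test_lognormal_sample_recommends_log(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(6.0, 1.0, 40)
        s = oc.normality_screen(x)
        assert s.recommend_log
        assert s.p_value < 0.05

    def test_normal_sample_passes(self):
        rng = np.random.default_rng(2)
        s = oc.normality_screen(rng.normal(50, 5, 40))
        assert not s.recommend_log
        assert s.p_value > 0.05

    def test_too_small_sample_raises(self):
        with pytest.raises(ValueError):
            oc.normality_screen([1.0, 2.0])

    def test_constant_sample_raises(self):
        with pytest.raises(ValueError):
            oc.normality_screen([3.0] * 10)


class TestCorrelate:
    def test_perfect_positive_linearity(self):
        x = np.arange(10.0)
        assert oc.correlate(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_perfect_negative_linearity(self):
        x = np.arange(10.0)
        assert oc.correlate(x, -x).r == pytest.approx(-1.0)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r = oc.correlate(x, y).r
        # covariance / sd product, computed independently
        expected = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_listwise_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, np.nan]
        res = oc.correlate(x, y)
        assert res.n == 3
        assert res.r == pytest.approx(1.0)

    @pytest.mark.parametrize("x,y", [([1, 2], [3, 4]), ([1, 1, 1], [1, 2, 3])])
    def test_degenerate_inputs_raise(self, x, y):
        with pytest.raises(ValueError):
            oc.correlate(x, y)

    @given(
        a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-100, 100),
    )
    def test_affine_invariance_and_symmetry(self, a, b):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r0 = oc.correlate(x, y).r
        assert oc.correlate(y, x).r == pytest.approx(r0, abs=1e-12)
        assert oc.correlate(a * x + b, y).r == pytest.approx(np.sign(a) * r0, abs=1e-9)


class TestRegression:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(5)
        x1, x2 = rng.normal(size=20), rng.normal(size=20)
        y = 1.0 + 2.0 * x1 - 3.0 * x2
        res = oc.regress_improvement(y, x1, x2)
        q = res.predictors["quantity"]
        f = res.predictors["log_frequency"]
        assert q.beta == pytest.approx(2.0, abs=1e-8)
        assert f.beta == pytest.approx(-3.0, abs=1e-8)
        # with zero residual the intervals collapse onto the estimates
        assert q.ci95_low == pytest.approx(q.beta, abs=1e-6)
        assert q.ci95_high == pytest.approx(q.beta, abs=1e-6)

    def test_orthogonal_predictors_match_bivariate_slopes(self):
        rng = np.random.default_rng(6)
        x1 = np.concatenate([np.ones(10), -np.ones(10)])
        x2 = np.tile([1.0, -1.0], 10)  # exactly orthogonal, both centered
        y = rng.normal(size=20)
        res = oc.regress_improvement(y, x1, x2)
        b1 = np.sum(x1 * (y - y.mean())) / np.sum(x1 **2)
        b2 = np.sum(x2 * (y - y.mean())) / np.sum(x2 **2)
        assert res.predictors["quantity"].beta == pytest.approx(b1, abs=1e-10)
        assert res.predictors["log_frequency"].beta == pytest.approx(b2, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        x1, x2 = rng.normal(size=30), rng.normal(size=30)
        y = 0.5 + 1.5 * x1 + 0.7 * x2 + rng.normal(size=30)
        res = oc.regress_improvement(y, x1, x2)
        X = np.column_stack([np.ones(30), x1, x2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.predictors["quantity"].beta == pytest.approx(beta[1], abs=1e-10)
        assert res.predictors["log_frequency"].beta == pytest.approx(beta[2], abs=1e-10)

    def test_collinear_predictors_raise(self):
        x1 = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear.*quantity.*log_frequency"):
            oc.regress_improvement(np.random.default_rng(0).normal(size=10), x1, 2 * x1)


class TestResampling:
    def _cohort(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        Y = rng.integers(5, 40, size=(n, 3)).astype(float)
        H = np.clip(40 + Y + rng.normal(0, 8, size=(n, 3)), 0, 100)
        return Y, H

    def test_degenerate_identical_timepoints(self):
        Y, H = self._cohort()
        Y = np.tile(Y[:, :1], 3)
        H = np.tile(H[:, :1], 3)
        res = oc.resample_single_timepoint(Y, H, n_iter=200, seed=1)
        full = oc.severity_home_correlation(Y, H)
        assert res.n_absent == 0
        assert np.allclose(res.r_values, full.r)
        assert res.median_r == pytest.approx(full.r)

    def test_seeded_single_iteration_matches_hand_trace(self):
        Y, H = self._cohort(seed=2)
        res = oc.resample_single_timepoint(Y, H, n_iter=1, seed=123)
        draws = np.random.default_rng(123).integers(0, 3, size=(1, Y.shape[0]))
        y = Y[np.arange(Y.shape[0]), draws[0]]
        h = H[np.arange(H.shape[0]), draws[0]]
        assert res.r_values[0] == pytest.approx(np.corrcoef(y, h)[0, 1], abs=1e-12)

    def test_bit_reproducible_given_seed(self):
        Y, H = self._cohort(seed=3)
        a = oc.resample_single_timepoint(Y, H, n_iter=500, seed=9)
        b = oc.resample_single_timepoint(Y, H, n_iter=500, seed=9)
        assert np.array_equal(a.r_values, b.r_values)

    def test_missing_pairs_dropped_per_iteration(self):
        Y, H = self._cohort(n=4, seed=4)
        H[0, :] = np.nan  # participant never usable
        res = oc.resample_single_timepoint(Y, H, n_iter=100, seed=5)
        assert np.isfinite(res.r_values).sum() + res.n_absent == 100

    def test_median_within_tolerance_of_pooled_r(self):
        Y, H = self._cohort(n=30, seed=6)
        res = oc.resample_single_timepoint(Y, H, n_iter=2000, seed=7)
        pooled = oc.severity_home_correlation(Y, H)
        assert abs(res.median_r - pooled.r) < 0.1


class TestMissingnessCheck:
    def test_unrelated_missingness_near_zero(self):
        rng = np.random.default_rng(8)
        frac = rng.uniform(0.3, 0.9, 40)
        ybocs = rng.integers(10, 40, 40)
        assert abs(oc.missingness_severity_check(frac, ybocs).r) < 0.4
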