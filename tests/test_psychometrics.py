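import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from optodetect.psychometrics import (
    C,
    crossval_predict,
    curve_points,
    curve_summary,
    fit_psychometric,
    positive_stimulus,
    psychometric,
    scaled_sigmoid,
    slope_at_midpoint,
)


class TestFunctionForm:
    def test_midpoint_is_half(self):
        assert psychometric(np.exp(0.7), 0.7, 1.3, 0.0, 0.0) == pytest.approx(0.5)

    def test_midpoint_with_rates(self):
        lam, gam = 0.1, 0.2
        assert psychometric(np.exp(0.7), 0.7, 1.3, lam, gam) == pytest.approx(
            gam + (1 - lam - gam) / 2
        )

    def test_width_definition(self):
        # x = e^(m + w/2) sits at the 95% point of S by construction of C
        m, w = 1.0, 0.8
        assert scaled_sigmoid(np.exp(m + w / 2), m, w) == pytest.approx(0.95, abs=1e-12)
        assert scaled_sigmoid(np.exp(m - w / 2), m, w) == pytest.approx(0.05, abs=1e-12)

    def test_limits(self):
        lam, gam = 0.07, 0.12
        assert psychometric(1e-12, 0.0, 1.0, lam, gam) == pytest.approx(gam, abs=1e-9)
        assert psychometric(1e12, 0.0, 1.0, lam, gam) == pytest.approx(1 - lam, abs=1e-9)

    def test_nonpositive_x_raises(self):
        with pytest.raises(ValueError):
            psychometric(0.0, 0.0, 1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            psychometric(-2.0, 0.0, 1.0, 0.0, 0.0)

    def test_bad_rates_raise(self):
        with pytest.raises(ValueError):
            psychometric(1.0, 0.0, 1.0, 0.6, 0.5)

    @given(
        m=st.floats(-2, 4),
        w=st.floats(0.1, 5),
        lam=st.floats(0, 0.3),
        gam=st.floats(0, 0.3),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, m, w, lam, gam):
        x = np.logspace(-3, 4, 200)
        y = psychometric(x, m, w, lam, gam)
        assert np.all(np.diff(y) >= 0)
        assert np.all(y >= gam - 1e-12) and np.all(y <= 1 - lam + 1e-12)


class TestCurvePoints:
    def test_x50_is_exp_m(self):
        x10, x50, x90 = curve_points((1.7, 0.9))
        assert x50 == pytest.approx(np.exp(1.7))

    def test_log_symmetry(self):
        x10, x50, x90 = curve_points((0.4, 2.1))
        assert x90 / x50 == pytest.approx(x50 / x10)

    def test_against_bisection_oracle(self):
        m, w = np.log(21.0), 1.35
        for p in (0.1, 0.5, 0.9):
            oracle = optimize.brentq(
                lambda x: scaled_sigmoid(x, m, w) - p, 1e-6, 1e6, xtol=1e-12
            )
            (got,) = curve_points((m, w), levels=[p])
            assert got == pytest.approx(oracle, rel=1e-8)

    def test_invalid_levels_raise(self):
        with pytest.raises(ValueError):
            curve_points((0.0, 1.0), levels=[0.0])
        with pytest.raises(ValueError):
            curve_points((0.0, 1.0), levels=[1.0])


class TestSlope:
    def _fit(self, m=0.0, w=None, lam=0.0, gam=0.0):
        from optodetect.psychometrics import PsychometricFit

        return PsychometricFit(m=m, w=w if w is not None else C, lam=lam, gamma=gam,
                               r2=1.0, log_likelihood=0.0)

    def test_unit_reduction(self):
        # lam = gam = 0, m = 0, w = C -> slope 1/sqrt(2*pi) at x = 1
        assert slope_at_midpoint(self._fit()) == pytest.approx(1 / np.sqrt(2 * np.pi))

    def test_matches_finite_difference(self):
        fit = self._fit(m=np.log(21.0), w=1.35, lam=0.05, gam=0.1)
        x50 = np.exp(fit.m)
        h = 1e-5 * x50
        fd = (
            psychometric(x50 + h, fit.m, fit.w, fit.lam, fit.gamma)
            - psychometric(x50 - h, fit.m, fit.w, fit.lam, fit.gamma)
        ) / (2 * h)
        assert slope_at_midpoint(fit) == pytest.approx(fd, rel=1e-6)

    def test_decreasing_in_width(self):
        slopes = [slope_at_midpoint(self._fit(m=1.0, w=w)) for w in (0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(slopes) < 0)

    def test_scaled_curve_variant(self):
        fit = self._fit(m=1.0, w=2.0, lam=0.1, gam=0.1)
        assert slope_at_midpoint(fit, of="psi") == pytest.approx(
            0.8 * slope_at_midpoint(fit, of="S")
        )


class TestFit:
    x = np.array([5.0, 10.0, 25.0, 50.0, 75.0, 100.0])

    def test_noiseless_identifiability(self):
        m, w, lam, gam = np.log(20.0), 1.2, 0.04, 0.08
        n = 1_000_000  # effectively continuous responses
        p = psychometric(self.x, m, w, lam, gam)
        fit = fit_psychometric(self.x, np.round(p * n), np.full(6, n), lam, gam, n_boot=0)
        assert fit.m == pytest.approx(m, abs=1e-3)
        assert fit.w == pytest.approx(w, abs=1e-2)
        assert fit.r2 == pytest.approx(1.0, abs=1e-5)

    def test_beats_dense_grid_oracle(self):
        rng = np.random.default_rng(5)
        p = psychometric(self.x, np.log(21.0), 1.35, 0.05, 0.1)
        k = rng.binomial(30, p)
        n = np.full(6, 30.0)
        fit = fit_psychometric(self.x, k, n, 0.05, 0.1, n_boot=0)

        def nll(m, w):
            pr = np.clip(psychometric(self.x, m, w, 0.05, 0.1), 1e-12, 1 - 1e-12)
            return -np.sum(k * np.log(pr) + (n - k) * np.log1p(-pr))

        grid = min(
            nll(m, w)
            for m in np.linspace(np.log(2), np.log(200), 60)
            for w in np.linspace(0.05, 8.0, 60)
        )
        assert -fit.log_likelihood <= grid + 1e-9

    def test_equal_weights_match_unweighted(self):
        rng = np.random.default_rng(2)
        k = rng.binomial(25, psychometric(self.x, 3.0, 1.0, 0.02, 0.1))
        n = np.full(6, 25)
        f1 = fit_psychometric(self.x, k, n, 0.02, 0.1, n_boot=0)
        f2 = fit_psychometric(self.x, k, n, 0.02, 0.1, weights=np.full(6, 1.0), n_boot=0)
        f3 = fit_psychometric(self.x, k, n, 0.02, 0.1, weights=np.full(6, 3.7), n_boot=0)
        assert f1.m == pytest.approx(f2.m) and f1.w == pytest.approx(f2.w)
        # constant rescaling: same optimum up to optimizer tolerance on a flat
        # likelihood surface — assert equivalence in likelihood and predictions
        assert f1.log_likelihood == pytest.approx(f3.log_likelihood, abs=1e-6)
        np.testing.assert_allclose(f1.predict(self.x), f3.predict(self.x), atol=1e-3)

    def test_bootstrap_cis_cover_truth(self):
        rng = np.random.default_rng(7)
        m, w = np.log(21.0), 1.35
        k = rng.binomial(200, psychometric(self.x, m, w, 0.05, 0.1))
        fit = fit_psychometric(self.x, k, np.full(6, 200), 0.05, 0.1, n_boot=100, seed=0)
        assert fit.ci_m is not None and fit.ci_m[0] <= fit.ci_m[1]
        assert fit.ci_m[0] - 0.3 <= m <= fit.ci_m[1] + 0.3  # loose: CI plausibility

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_psychometric([1.0, 1.0], [1, 1], [2, 2], 0.0, 0.0, n_boot=0)
        with pytest.raises(ValueError):
            fit_psychometric([-1.0, 2.0], [1, 1], [2, 2], 0.0, 0.0, n_boot=0)
        with pytest.raises(ValueError):
            fit_psychometric([1.0, 2.0], [3, 1], [2, 2], 0.0, 0.0, n_boot=0)

    def test_degenerate_data_flags_bound(self):
        # responses decreasing in x force w toward a bound -> flagged, not silent
        with pytest.warns(UserWarning):
            fit = fit_psychometric(
                [5.0, 50.0], [20, 1], [20, 20], 0.0, 0.05, n_boot=0
            )
        assert fit.at_bound


class TestCrossval:
    def _points(self, seed, signal=True, n_points=40):
        rng = np.random.default_rng(seed)
        x = rng.uniform(3, 100, n_points)
        p = psychometric(x, np.log(21.0), 1.35, 0.05, 0.1)
        n = np.full(n_points, 40)
        k = rng.binomial(40, p)
        if not signal:
            x = rng.uniform(3, 100, n_points)  # independent predictor
        return x, k, n

    def test_perfect_predictor(self):
        x, k, n = self._points(0)
        k = np.round(psychometric(x, np.log(21.0), 1.35, 0.05, 0.1) * 1e6)
        res = crossval_predict(x, k, np.full(len(x), 1e6), 0.05, 0.1, n_perm=50, seed=1)
        assert np.median(res.r2_test) > 0.99
        assert res.p_test == 0.0

    def test_null_predictor(self):
        x, k, n = self._points(3, signal=False)
        res = crossval_predict(x, k, n, 0.05, 0.1, n_perm=50, seed=1)
        assert np.median(res.r2_test) <= 0.0

    def test_requires_min_points(self):
        with pytest.raises(ValueError):
            crossval_predict([1, 2, 3, 4.0], [1] * 4, [2] * 4, 0.0, 0.0, n_perm=5)

    def test_positive_stimulus_floor(self):
        x = positive_stimulus([0.0, 0.02, 0.05])
        assert np.all(x > 0)
        assert x[1] == pytest.approx(0.02 + 1e-4)
        with pytest.raises(ValueError):
            positive_stimulus([-0.1])
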