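"""Fitting machinery: RMSE, likelihood, intervals, determinism, NA policy."""

import math

import numpy as np
import pytest

import acifit as af
from acifit.errors import AcifitError, DomainError
from acifit.inference import likelihood_ratio_interval
from acifit.synthetic import TOBACCO_SCHEDULE

from conftest import C3_BINDING_TRUTH, make_curve


class TestRmse:
    def test_identical_sequences(self):
        assert af.rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_simple_arithmetic(self):
        assert af.rmse([1, 2, 3], [1, 2, 4]) == pytest.approx(math.sqrt(1 / 3))

    def test_matches_two_pass_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(1, 50)
            a, b = rng.normal(size=n), rng.normal(size=n)
            acc = 0.0
            for x, y in zip(a, b):       # independent summation oracle
                acc += (x - y) ** 2
            assert af.rmse(a, b) == pytest.approx(math.sqrt(acc / n), rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(AcifitError):
            af.rmse([1.0], [1.0, 2.0])


class TestNegativeLogLikelihood:
    def test_zero_residuals(self):
        obs = np.ones(5)
        got = af.negative_log_likelihood(obs, obs, sigma=2.0)
        assert got == pytest.approx(5 * math.log(2.0 * math.sqrt(2 * math.pi)))

    def test_direct_formula(self, rng):
        obs, mod = rng.normal(size=8), rng.normal(size=8)
        ssr = float(np.sum((obs - mod) ** 2))
        for s in (0.5, 1.0, 5.0):
            expected = 8 * math.log(s * math.sqrt(2 * math.pi)) + ssr / (2 * s * s)
            assert af.negative_log_likelihood(obs, mod, s) == pytest.approx(expected)

    def test_sigma_must_be_positive(self):
        with pytest.raises(DomainError):
            af.negative_log_likelihood([1.0], [1.0], 0.0)

    def test_argmin_independent_of_sigma(self, c3_binding_curve, rng):
        """The NLL at different sigma values orders parameter vectors
        identically, so the best-fit parameters cannot depend on sigma."""
        from acifit.inference import MODELS, _make_nll
        adapter = MODELS["c3_aci"]
        arrays = adapter.prepare(c3_binding_curve)
        full0 = adapter.defaults(c3_binding_curve, None)
        idx = np.array([adapter.param_names.index(n)
                        for n in adapter.default_fit])
        nll1 = _make_nll(adapter, arrays, {}, full0, idx, sigma=1.0)
        nll5 = _make_nll(adapter, arrays, {}, full0, idx, sigma=5.0)
        bounds = np.array([adapter.default_bounds[n] for n in adapter.default_fit])
        draws = rng.uniform(bounds[:, 0], bounds[:, 1], size=(60, len(idx)))
        order1 = np.argsort(nll1.rows(draws), kind="stable")
        order5 = np.argsort(nll5.rows(draws), kind="stable")
        np.testing.assert_array_equal(order1, order5)


class TestLikelihoodRatioInterval:
    def gaussian_nll(self, x, se, best=50.0):
        return lambda v: 0.5 * ((np.asarray(v, float) - best) / se) ** 2

    def test_gaussian_matches_closed_form(self):
        se = 0.05
        ci = likelihood_ratio_interval(
            self.gaussian_nll(None, se), 50.0, 0.0, threshold=0.147,
            search_lower=0.0, search_upper=100.0)
        half = se * math.sqrt(-2.0 * math.log(0.147))
        assert ci.lower == pytest.approx(50.0 - half, rel=1e-6)
        assert ci.upper == pytest.approx(50.0 + half, rel=1e-6)
        assert ci.reliable

    def test_flat_step_likelihood_gives_na(self):
        def nll(v):
            v = np.asarray(v, float)
            return np.where(v < 10.0, ((v - 10.0) / 0.5) ** 2, 0.0)
        ci = likelihood_ratio_interval(nll, 12.0, 0.0, search_lower=-100.0,
                                       search_upper=1000.0)
        assert np.isinf(ci.upper)
        assert not ci.reliable
        assert math.isnan(ci.best)

    def test_threshold_one_collapses_to_best(self):
        ci = likelihood_ratio_interval(
            self.gaussian_nll(None, 1.0), 50.0, 0.0, threshold=1.0,
            search_lower=0.0, search_upper=100.0)
        assert ci.lower == pytest.approx(50.0, abs=1e-4)
        assert ci.upper == pytest.approx(50.0, abs=1e-4)

    def test_na_policy_switchable(self):
        def nll(v):
            return np.zeros(np.shape(np.asarray(v)))
        ci = likelihood_ratio_interval(nll, 1.0, 0.0, search_lower=-10.0,
                                       search_upper=10.0, na_policy=False)
        assert np.isinf(ci.upper) and np.isinf(ci.lower)
        assert ci.best == 1.0


class TestFitCurve:
    def test_noise_free_recovery(self, c3_binding_fit):
        for name, truth in C3_BINDING_TRUTH.items():
            assert f"{name}" in c3_binding_fit.intervals
            assert c3_binding_fit.params[name] == pytest.approx(truth, rel=5e-3)

    def test_interval_ordering_and_sigma(self, c3_binding_fit):
        fit = c3_binding_fit
        assert fit.sigma == max(fit.rmse, 1e-6)
        for ci in fit.intervals.values():
            if ci.reliable:
                assert ci.lower <= ci.best <= ci.upper

    def test_determinism_same_seed(self, c3_binding_curve):
        cfg = af.FitConfig(optimizer=af.OptimizerSettings(seed=9, maxiter=100))
        a = af.fit_curve(c3_binding_curve, "c3_aci", cfg)
        b = af.fit_curve(c3_binding_curve, "c3_aci", cfg)
        assert a.params == b.params
        assert a.intervals == b.intervals
        assert a.rmse == b.rmse

    def test_global_search_beats_random_vectors(self, c3_binding_curve,
                                                c3_binding_fit, rng):
        """Best SSR is no worse than 200 random in-bounds parameter draws."""
        from acifit.inference import MODELS, _make_nll
        adapter = MODELS["c3_aci"]
        arrays = adapter.prepare(c3_binding_curve)
        full0 = adapter.defaults(c3_binding_curve, None)
        names = adapter.default_fit
        idx = np.array([adapter.param_names.index(n) for n in names])
        nll = _make_nll(adapter, arrays, {}, full0, idx, sigma=1.0)
        bounds = np.array([adapter.default_bounds[n] for n in names])
        draws = rng.uniform(bounds[:, 0], bounds[:, 1], size=(200, len(names)))
        best = nll(np.array([c3_binding_fit.params[n] for n in names]))
        assert best <= np.min(nll.rows(draws)) + 1e-9

    def test_too_few_points_rejected(self):
        curve = make_curve("c3_aci", C3_BINDING_TRUTH, TOBACCO_SCHEDULE)
        curve.df = curve.df.iloc[:4]
        with pytest.raises(AcifitError):
            af.fit_curve(curve, "c3_aci")

    def test_aic_accounting(self, c3_binding_fit):
        fit = c3_binding_fit
        k = len(fit.fit_params) + 1
        assert fit.aic == pytest.approx(2 * k + 2 * fit.nll)

    def test_na_policy_marks_nonbinding_j(self):
        truth = dict(C3_BINDING_TRUTH, J=400.0)
        curve = make_curve("c3_aci", truth, TOBACCO_SCHEDULE, seed=3)
        fit = af.fit_curve(curve, "c3_aci")
        ci = fit.intervals["J"]
        assert np.isinf(ci.upper) and not ci.reliable and math.isnan(ci.best)
        assert math.isnan(fit.reported_params["J"])
        # other parameters still recovered
        for name in ("Vcmax", "Tp", "RL", "alpha_old"):
            assert fit.params[name] == pytest.approx(truth[name], rel=5e-3)

    def test_profiled_interval_wider_for_correlated_parameter(
            self, c3_binding_curve):
        """Tp and alpha_old trade off along the TPU branch; profiling the
        likelihood (re-optimizing the others) must widen Tp's interval
        relative to the one-at-a-time scan on a noisy curve."""
        curve = make_curve("c3_aci", C3_BINDING_TRUTH, TOBACCO_SCHEDULE,
                           noise_sd=0.5, seed=21)
        base = af.FitConfig(optimizer=af.OptimizerSettings(seed=2, maxiter=200))
        plain = af.fit_curve(curve, "c3_aci", base)
        prof_cfg = af.FitConfig(optimizer=af.OptimizerSettings(seed=2, maxiter=200),
                                profile=True)
        prof = af.fit_curve(curve, "c3_aci", prof_cfg)
        width = lambda ci: ci.upper - ci.lower
        assert width(prof.intervals["Tp"]) > 1.5 * width(plain.intervals["Tp"])
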