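"""C4 model: enzyme/light-limited quadratics, hyperbola, low-Ci subset."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

import acifit as af
from acifit.errors import DomainError
from acifit.gasex_io import ResponseCurveTable
from acifit.synthetic import MAIZE_SCHEDULE


def random_params(rng):
    return af.C4Params(
        Vcmax=rng.uniform(20, 120), Vpmax=rng.uniform(40, 250),
        Vpr=rng.uniform(40, 200), J=rng.uniform(50, 600),
        RL=rng.uniform(0.2, 4), fRLm=rng.uniform(0, 1),
        gbs=rng.uniform(0.001, 0.02), alpha_PSII=rng.uniform(0, 0.3),
    )


def enzyme_oracle(cm, p):
    """Brute-force root of the defining bundle-sheath balance."""
    vp = min(cm * p.Vpmax / (cm + p.Kp), p.Vpr)
    rm, ko, om = p.fRLm * p.RL, p.Ko * 1e3, p.Om * 1e3

    def f(a):
        cs = cm + (vp - a - rm) / p.gbs
        os = p.alpha_PSII * a / (0.047 * p.gbs) + om
        return a - ((cs - p.gamma_star * os) * p.Vcmax
                    / (cs + p.Kc * (1 + os / ko)) - p.RL)

    hi = min(p.Vcmax - p.RL, vp + p.gbs * cm - rm)
    return brentq(f, -60, hi + 1e-9, xtol=1e-12)


def light_oracle(cm, p):
    rm, om, x = p.fRLm * p.RL, p.Om * 1e3, p.x_etr
    vp = x * p.J / 2

    def f(a):
        cs = cm + (vp - a - rm) / p.gbs
        os = p.alpha_PSII * a / (0.047 * p.gbs) + om
        return a - ((cs - p.gamma_star * os) * (1 - x) * p.J
                    / (3 * cs + 7 * p.gamma_star * os) - p.RL)

    hi = min((1 - x) * p.J / 3 - p.RL, vp + p.gbs * cm - rm)
    return brentq(f, -60, hi + 1e-9, xtol=1e-12)


class TestPepCarboxylation:
    def test_michaelis_half_saturation(self):
        p = af.C4Params(Vpmax=120.0, Kp=80.0, Vpr=1e6)
        assert af.pep_carboxylation_rate(80.0, p) == pytest.approx(60.0)

    def test_regeneration_cap(self):
        p = af.C4Params(Vpmax=120.0, Kp=80.0, Vpr=80.0)
        assert af.pep_carboxylation_rate(40.0, p) == pytest.approx(40.0)
        assert af.pep_carboxylation_rate(1e6, p) == pytest.approx(80.0)
        assert af.pep_carboxylation_rate(40.0, p.with_(Vpr=0.0)) == 0.0


class TestEnzymeLimited:
    def test_roots_match_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            p = random_params(rng)
            cm = rng.uniform(5, 600)
            got = float(af.c4_enzyme_limited(cm, p))
            assert got == pytest.approx(enzyme_oracle(cm, p), rel=1e-9, abs=1e-9)

    def test_rubisco_saturated_limit(self):
        p = af.C4Params(Vpmax=5000.0, Vpr=5000.0)
        got = float(af.c4_enzyme_limited(5000.0, p))
        assert got == pytest.approx(p.Vcmax - p.RL, rel=1e-3)

    def test_supply_starved_ordering(self):
        p = af.C4Params(Vpmax=120.0, Vpr=0.0, gbs=0.003)
        got = float(af.c4_enzyme_limited(5.0, p))
        assert got < p.Vcmax - p.RL
        # bounded by the CO2 delivery rate gbs*Cm less mesophyll respiration
        assert got <= 0.003 * 5.0 - p.fRLm * p.RL + 1e-9


class TestLightLimited:
    def test_roots_match_brute_force_oracle(self):
        rng = np.random.default_rng(78)
        for _ in range(100):
            p = random_params(rng)
            cm = rng.uniform(5, 600)
            got = float(af.c4_light_limited(cm, p))
            assert got == pytest.approx(light_oracle(cm, p), rel=1e-9, abs=1e-9)

    def test_zero_j_gives_nonpositive_rate(self):
        p = af.C4Params(J=0.0)
        assert float(af.c4_light_limited(100.0, p)) <= 0.0

    def test_monotone_in_j_and_eventually_nonbinding(self):
        p = af.C4Params()
        cm = 150.0
        rates = [float(af.c4_light_limited(cm, p.with_(J=j)))
                 for j in np.linspace(0, 2000, 40)]
        assert np.all(np.diff(rates) >= -1e-9)
        res = af.c4_assimilation(np.linspace(20, 600, 30), p.with_(J=5000.0))
        np.testing.assert_array_equal(res.limiting, "enzyme")


class TestAssimilation:
    def test_min_contract_and_components(self):
        p = af.C4Params()
        res = af.c4_assimilation(np.linspace(10, 800, 40), p)
        assert np.all(res.An <= res.Ac + 1e-12)
        assert np.all(res.An <= res.Aj + 1e-12)
        # co-limitation: Ac below each component asymptote
        assert np.all(res.Ac <= res.Apc + 1e-9)
        assert np.all(res.Ac <= res.Apr + 1e-9)
        assert np.all(res.Ac <= res.Ar + 1e-9)

    def test_strict_colimitation_in_interior(self):
        p = af.C4Params()
        res = af.c4_assimilation(np.array([120.0]), p)
        comp = min(float(res.Apc[0]), float(res.Apr[0]), float(res.Ar[0]))
        assert float(res.Ac[0]) < comp

    def test_rubisco_vs_light_assumption_fits_similar_quality(self):
        """On a noisy curve whose plateau is set by PEP regeneration (so
        neither Rubisco nor light binds at high Ci), the two high-Ci
        assumptions fit with similar quality."""
        truth = dict(Vcmax=120.0, Vpmax=250.0, J=1000.0, RL=1.8)
        spec = af.SimSpec(model="c4_aci", true_params=truth,
                          schedule=MAIZE_SCHEDULE, noise_sd=0.5, seed=9,
                          tleaf=31.0)
        table, _ = af.generate_curve(spec, 0)
        curve = af.organize_response_curve_data(table, MAIZE_SCHEDULE)
        opt = af.OptimizerSettings(seed=0, maxiter=200)
        fit_r = af.fit_curve(curve, "c4_aci", af.FitConfig(optimizer=opt))
        fit_l = af.fit_curve(curve, "c4_aci", af.FitConfig(
            fit_params=["RL", "J", "Vpmax"], optimizer=opt,
            model_options={"assumption": "light"}))
        ratio = max(fit_r.rmse, fit_l.rmse) / min(fit_r.rmse, fit_l.rmse)
        assert ratio < 2.0

    def test_finite_gmc_closure(self):
        p = af.C4Params(gmc=1.0)
        res = af.c4_assimilation(np.array([200.0]), p)
        ref = af.c4_assimilation(np.array([200.0]), p.with_(gmc=np.inf))
        # drawdown An/gmc shifts Cm below Ci, lowering the rate slightly
        assert float(res.An[0]) < float(ref.An[0])


class TestHyperbola:
    def test_blackman_and_boundary_limits(self):
        h = af.HyperbolaParams(Vmax=60.0, initial_slope=0.6,
                               curvature=0.99999, RL=1.5)
        np.testing.assert_allclose(
            af.c4_hyperbola(np.array([50.0, 1e4]), h),
            [0.6 * 50 - 1.5, 60 - 1.5], rtol=1e-3)
        assert float(af.c4_hyperbola(0.0, h)) == pytest.approx(-1.5)
        assert h.Amax == pytest.approx(58.5)

    def test_rectangular_limit_handled(self):
        h = af.HyperbolaParams(Vmax=60.0, initial_slope=0.6, curvature=0.0, RL=1.0)
        got = float(af.c4_hyperbola(100.0, h))
        assert got == pytest.approx(0.6 * 100 * 60 / (0.6 * 100 + 60) - 1.0)

    @pytest.mark.parametrize("curvature", [0.2, 0.7, 1.0])
    def test_nondecreasing_and_concave(self, curvature):
        h = af.HyperbolaParams(Vmax=55.0, initial_slope=0.9,
                               curvature=curvature, RL=1.8)
        an = af.c4_hyperbola(np.linspace(0, 2000, 400), h)
        assert np.all(np.diff(an) >= -1e-10)
        assert np.all(np.diff(an, 2) <= 1e-8)


class TestLowCiSubset:
    def make_curve(self):
        # Ci near the set-points themselves (weak stomatal drawdown)
        ci = np.asarray(MAIZE_SCHEDULE.setpoints, float)
        df = pd.DataFrame({
            "co2_setpoint": MAIZE_SCHEDULE.setpoints, "Ci": ci,
            "An": np.linspace(0, 40, ci.size),
            "Qin": np.full(ci.size, 2000.0), "Tleaf": np.full(ci.size, 31.0),
        })
        return ResponseCurveTable("m", df, {})

    def test_maize_schedule_retains_two_lowest_points(self):
        out = af.low_ci_subset(self.make_curve(), threshold=60.0)
        np.testing.assert_allclose(out.column("co2_setpoint"), [30.0, 10.0])

    def test_degenerate_thresholds(self):
        curve = self.make_curve()
        with pytest.warns(UserWarning):
            empty = af.low_ci_subset(curve, threshold=0.0)
        assert len(empty) == 0 and empty.warnings
        assert len(af.low_ci_subset(curve, threshold=np.inf)) == len(curve)
        with pytest.raises(DomainError):
            af.low_ci_subset(empty, threshold=10.0)

    def test_low_ci_fit_identifies_vpmax(self, c4_curve):
        """Fitting only Ci <= 60 of a noise-free mechanistic curve recovers
        Vpmax within 1%."""
        sub = af.low_ci_subset(c4_curve, threshold=60.0)
        cfg = af.FitConfig(fit_params=["Vpmax"],
                           fixed={"RL": 1.8, "Vcmax": 65.0},
                           optimizer=af.OptimizerSettings(seed=0, maxiter=150))
        fit = af.fit_curve(sub, "c4_aci", cfg)
        assert fit.params["Vpmax"] == pytest.approx(140.0, rel=1e-2)
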