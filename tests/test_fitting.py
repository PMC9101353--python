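"""Estimation chain: slopes, relaxation times, recruitment, local ODE fit."""

import numpy as np
import pytest

from sfmech.exceptions import (
    IdentifiabilityWarning,
    ModelValidityError,
    NumericalError,
)
from sfmech.fitting import (
    derived_mechanics,
    fit_exponential_relax,
    fit_linear_strain_response,
    fit_local_ode,
    fit_recruitment,
)
from sfmech.localode import LocalOdeParams, simulate_local_chi
from sfmech.model import intensity_model
from sfmech.synthetic import generate_local_traces


class TestLinearStrainResponse:
    def test_exact_line_recovered(self):
        eps = np.array([-0.4, -0.2, 0.1, 0.3])
        y = 189.5 * eps + 66.2
        fit = fit_linear_strain_response(eps, y)
        assert fit["slope"] == pytest.approx(189.5, rel=1e-12)
        assert fit["intercept"] == pytest.approx(66.2, rel=1e-12)

    def test_weighted_fit_uses_errors(self):
        eps = np.array([0.1, 0.2, 0.3, 0.4])
        y = 189.5 * eps + np.array([0.0, 0.0, 0.0, 50.0])
        # heavily down-weight the corrupted point
        fit = fit_linear_strain_response(eps, y, errors=[1, 1, 1, 1000])
        assert fit["slope"] == pytest.approx(189.5, rel=1e-3)

    def test_two_points_exact_with_undefined_sd(self):
        fit = fit_linear_strain_response([0.1, 0.3], [85.0, 123.0])
        assert fit["slope"] == pytest.approx(190.0)
        assert np.isnan(fit.sd["slope"])
        assert fit.diagnostics["exact_interpolation"]

    def test_singular_design_rejected(self):
        with pytest.raises(NumericalError):
            fit_linear_strain_response([0.2, 0.2], [1.0, 2.0])


class TestExponentialRelax:
    def test_exact_saturation_curve(self):
        t = np.arange(0, 900, 2.0)
        y = 1.0 - np.exp(-t / 427.0)
        fit = fit_exponential_relax(t, y)
        assert fit["timescale"] == pytest.approx(427.0, rel=1e-6)
        assert fit["plateau"] == pytest.approx(1.0, rel=1e-6)

    def test_noisy_radius_relaxation(self, rng):
        t = np.arange(0, 900, 2.0)
        y = 65.6 + 38.0 * np.exp(-t / 327.3) + rng.normal(0, 1.5, len(t))
        fit = fit_exponential_relax(t, y)
        assert fit["timescale"] == pytest.approx(327.3, rel=0.10)

    def test_overshoot_slow_scale(self, rng):
        t = np.arange(0, 900, 2.0)
        y = 0.2 * (np.exp(-t / 178.5) - np.exp(-t / 40.0))
        y = y + rng.normal(0, 0.003, len(t))
        fit = fit_exponential_relax(t, y, kind="overshoot")
        assert fit["timescale"] == pytest.approx(178.5, rel=0.10)
        assert fit["timescale_fast"] < fit["timescale"]


class TestRecruitment:
    def test_exact_model_data(self):
        eps = np.array([0.1, 0.2, 0.3, 0.4])
        fit = fit_recruitment(eps, 0.64 * eps, 0.64 / 427.0 * eps)
        assert fit["alpha"] == pytest.approx(0.64, rel=1e-12)
        assert fit["t_star"] == pytest.approx(427.0, rel=1e-12)

    def test_printed_rate_gives_printed_timescale(self):
        eps = np.array([0.1, 0.2, 0.3])
        fit = fit_recruitment(eps, 0.64 * eps, 1.5e-3 * eps)
        assert fit["t_star"] == pytest.approx(426.7, abs=0.1)
        assert round(fit["t_star"]) == 427

    def test_noisy_cohort_within_reported_spread(self, rng):
        eps_levels = [0.1, 0.2, 0.3, 0.4]
        t = np.arange(0, 900, 2.0)
        plateaus, slopes = [], []
        for e in eps_levels:
            per_p, per_s = [], []
            for _ in range(10):
                y = intensity_model(e, t, 0.64, 427.0)
                y = (1 + y) * (1 + 0.05 * rng.standard_normal(len(t))) - 1
                fit = fit_exponential_relax(t, y)
                per_p.append(fit["plateau"])
                per_s.append(-fit["amplitude"] / fit["timescale"])
            plateaus.append(np.mean(per_p))
            slopes.append(np.mean(per_s))
        fit = fit_recruitment(eps_levels, plateaus, slopes)
        assert fit["alpha"] == pytest.approx(0.64, abs=0.15)

    def test_negative_rate_rejected(self):
        with pytest.raises(NumericalError):
            fit_recruitment([0.1, 0.2, 0.3], [0.06, 0.13, 0.19],
                            [-1e-4, -2e-4, -3e-4])


class TestDerivedMechanics:
    def test_printed_chain(self, geometry):
        fit = derived_mechanics(189.5, 104.9, 11.3, 0.6, geometry.L0, geometry.R0)
        assert fit["sigma_pN_per_um"] == pytest.approx(35.7, abs=0.1)
        assert fit["lambda0"] == pytest.approx(2.3, abs=0.05)
        assert fit["K0"] == pytest.approx(0.19, abs=0.005)
        assert fit["k"] == pytest.approx(0.23, abs=0.005)
        assert fit["K0_over_k"] == pytest.approx(0.8, abs=0.01)
        assert fit["lf"] == pytest.approx(189.5, rel=1e-12)

    def test_symmetric_springs(self, geometry):
        fit = derived_mechanics(189.5, 189.5 / 2, 11.3, 0.6,
                                geometry.L0, geometry.R0)
        assert fit["k"] == pytest.approx(fit["K0"], rel=1e-12)

    def test_scale_consistency(self, geometry):
        a = derived_mechanics(189.5, 104.9, 11.3, 0.6, geometry.L0, geometry.R0)
        b = derived_mechanics(189.5, 104.9, 22.6, 0.3, geometry.L0, geometry.R0)
        for key in a.estimates:
            assert a[key] == pytest.approx(b[key], rel=1e-12)

    def test_inverted_slopes_rejected(self, geometry):
        with pytest.raises(ModelValidityError):
            derived_mechanics(104.9, 189.5, 11.3, 0.6, geometry.L0, geometry.R0)


class TestLocalOdeFit:
    def test_noiseless_self_consistency(self):
        # strongly nonlinear regime: all four groups are identified
        truth = LocalOdeParams(nu=1 / 320, tau=240.0, f=3.0, Gamma=0.8)
        t = np.arange(0, 902, 2.0)
        clean = simulate_local_chi(truth, t_grid=t, form="first").xi
        fit = fit_local_ode(clean, t=t, init=truth)
        for name, true_val in [("nu", truth.nu), ("tau", truth.tau),
                               ("f", truth.f), ("Gamma", truth.Gamma)]:
            assert fit[name] == pytest.approx(true_val, rel=0.02), name

    def test_weak_nonlinearity_anchors_f(self, params):
        # the ridge regime: f is constrained to the static-analysis anchor
        sigma0 = 0.035
        truth = LocalOdeParams(nu=1 / 320, tau=240.0, Gamma=0.8,
                               f=0.19 * 0.2 / (2 * sigma0))
        t = np.arange(0, 902, 2.0)
        traces, _ = generate_local_traces(truth, 3, t, cv=0.05, seed=11)
        init = LocalOdeParams.from_global(params, eps_l=0.2)
        with pytest.warns(IdentifiabilityWarning):
            fit = fit_local_ode(traces[0], t=t, init=init, K0=0.19,
                                eps_l=0.2, R0=65.6)
        assert fit.diagnostics["f_constrained"]
        assert fit["sigma0"] * 1e3 == pytest.approx(35.0, abs=15.0)
        # the passive time scale stays data-driven
        assert 100 < 1 / fit["nu"] < 1000

    def test_flat_trace_degenerate(self):
        t = np.arange(0, 200, 2.0)
        with pytest.warns(IdentifiabilityWarning):
            fit = fit_local_ode(np.zeros(len(t)), t=t)
        assert fit["f"] == 0.0
        assert "nu" in fit.diagnostics["unidentifiable"]

    def test_residual_norm_matches_recomputation(self):
        truth = LocalOdeParams(nu=1 / 320, tau=240.0, f=3.0, Gamma=0.8)
        t = np.arange(0, 602, 2.0)
        clean = simulate_local_chi(truth, t_grid=t, form="first").xi
        fit = fit_local_ode(clean, t=t, init=truth)
        from sfmech.fitting import _simulate_xi

        theta = (fit["nu"], fit["tau"], fit["f"], fit["Gamma"])
        xi = _simulate_xi(theta, t, fit.diagnostics["xi0"],
                          fit.diagnostics["xidot0"])
        assert fit.residual_norm == pytest.approx(
            float(np.sum((xi - clean) ** 2)), rel=1e-6, abs=1e-12)
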