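"""Unit tests for the three-element bundle model's closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfmech.exceptions import (
    DomainWarning,
    InvalidParameterError,
    ModelValidityError,
)
from sfmech.model import (
    GlobalMechParams,
    StretchProtocol,
    density_variation,
    elastic_constant_t,
    elastic_reference,
    intensity_model,
    motor_force,
    radius_long_time,
    radius_short_time,
    solve_rate_implicit,
)


class TestMotorForce:
    @pytest.mark.parametrize(
        "rate, lambda0, V, expected",
        [
            (0.0, 2.3, 0.1, 2.3),                      # stall force at zero rate
            (0.1, 1.0, 0.1, np.exp(-1.0)),             # one velocity scale
            (0.05, 2.3, 0.1, 2.3 * np.exp(-0.25)),     # hand-evaluated Gaussian
        ],
    )
    def test_values(self, rate, lambda0, V, expected):
        assert motor_force(rate, lambda0, V) == pytest.approx(expected, rel=1e-12)

    @given(rate=st.floats(-5, 5), V=st.floats(0.01, 2), lam=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_even_and_bounded(self, rate, V, lam):
        f = motor_force(rate, lam, V)
        assert f == pytest.approx(motor_force(-rate, lam, V), rel=1e-12)
        assert 0.0 <= f <= lam
        if (rate / V) ** 2 < 700:  # above this the Gaussian underflows
            assert f > 0.0

    def test_invalid_velocity_scale(self):
        with pytest.raises(InvalidParameterError):
            motor_force(0.1, 2.3, -1.0)


class TestRateSolve:
    def test_zero_rate_when_elastic_terms_balance(self, params):
        # K*(dl - d2) == k*d2 makes the RHS equal lambda0 and g(0) = lambda0
        d2 = 1.0
        dl = d2 + params.k * d2 / params.K0
        rate = solve_rate_implicit(d2, dl, params, params.K0)
        assert rate == pytest.approx(0.0, abs=1e-12)

    def test_against_grid_scan_oracle(self, params, rng):
        # independent root finder: dense scan of g(x) and linear refinement
        gamma, lam, V = params.gamma, params.lambda0, params.V
        for _ in range(100):
            d2 = rng.uniform(-2, 2)
            dl = rng.uniform(-5, 5)
            K = rng.uniform(0.05, 0.5)
            rhs = K * (dl - d2) + lam - params.k * d2

            xs = np.linspace(-1.0, 1.0, 2_000_001)
            g = gamma * xs + lam * np.exp(-(xs**2) / V**2) - rhs
            idx = np.flatnonzero(np.diff(np.sign(g)))
            if len(idx) != 1:
                continue
            i = idx[0]
            # linear interpolation inside the bracketing 1e-6 cell
            x_oracle = xs[i] - g[i] * (xs[i + 1] - xs[i]) / (g[i + 1] - g[i])

            rate = solve_rate_implicit(d2, dl, params, K)
            assert rate == pytest.approx(x_oracle, abs=1e-8)

    def test_high_dissipation_linearization(self, params):
        # gamma -> inf: the Gaussian stays ~lambda0 and rate -> F_net / gamma
        import dataclasses

        p = dataclasses.replace(params, gamma=1e6)
        F = 1.0
        d2, dl, K = 0.0, F / params.K0, params.K0
        rate = solve_rate_implicit(d2, dl, p, K)
        assert rate == pytest.approx(F / p.gamma, rel=0.01)

    def test_specified_load_case(self, params):
        # gamma=100, lambda0=2.3, V=0.1, net elastic load 1 nN:
        # root of 100x + 2.3 exp(-100 x^2) = 3.3 via the same grid oracle
        import dataclasses

        p = dataclasses.replace(params, gamma=100.0, lambda0=2.3, V=0.1)
        d2, K = 0.0, 1.0
        dl = 1.0  # K*(dl-d2) = 1 nN
        xs = np.linspace(-1, 1, 2_000_001)
        g = 100 * xs + 2.3 * np.exp(-100 * xs**2) - 3.3
        i = np.flatnonzero(np.diff(np.sign(g)))[0]
        x_oracle = xs[i] - g[i] * (xs[i + 1] - xs[i]) / (g[i + 1] - g[i])
        assert solve_rate_implicit(d2, dl, p, K) == pytest.approx(x_oracle, abs=1e-8)


class TestElasticity:
    def test_compression_leaves_main_spring(self, params):
        assert elastic_constant_t(-0.2, 500.0, params) == params.K0

    def test_steady_state_reduction(self, params):
        # 19% softening at eps = 0.3 with alpha = 0.64
        K_inf = elastic_constant_t(0.3, np.inf, params)
        assert K_inf / params.K0 == pytest.approx(1 - 0.64 * 0.3, rel=1e-12)

    def test_at_one_recruitment_time(self, params):
        K = elastic_constant_t(0.3, params.t_star, params)
        expected = params.K0 * (1 - 0.192 * (1 - np.exp(-1)))
        assert K == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_spring_rejected(self, params):
        import dataclasses

        p = dataclasses.replace(params, alpha=4.0)
        with pytest.raises(ModelValidityError):
            elastic_constant_t(0.3, 100.0, p)


class TestRadiusLimits:
    def test_short_time_line(self, params):
        # slope K0*L0/sigma = E*A/sigma = 189.5 um by construction
        assert radius_short_time(0.0, params, 36.47, 66.2) == 66.2
        assert radius_short_time(0.2, params, 36.47, 66.2) == pytest.approx(104.1, abs=0.05)
        r0p = 80.0
        assert radius_short_time(-0.1, params, 36.47, r0p) == pytest.approx(
            r0p - 18.95, abs=0.005)

    def test_long_time_compression_returns_to_rest(self, params):
        for eps in (-0.05, -0.2, -0.4):
            assert radius_long_time(eps, params, 36.47, 65.6) == 65.6

    def test_long_time_alpha_zero_is_linear_viscoelastic(self, params):
        import dataclasses

        p = dataclasses.replace(params, alpha=0.0)
        series_slope = p.k * p.K0 / (p.k + p.K0) * 36.47 / p.sigma
        for eps in (0.1, 0.25, 0.4):
            assert radius_long_time(eps, p, 36.47, 65.6) == pytest.approx(
                65.6 + series_slope * eps, rel=1e-12)

    def test_long_time_quadratic_softening(self, params):
        # hand evaluation: DR = 104.9 * (1 - 0.64 * k/(k+K0) * 0.3) * 0.3
        frac = params.k / (params.k + params.K0)
        basis = params.k * params.K0 / (params.k + params.K0) * 36.47 / params.sigma
        expected = basis * (1 - 0.64 * frac * 0.3) * 0.3
        got = radius_long_time(0.3, params, 36.47, 65.6) - 65.6
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(28.2, abs=0.15)


class TestIntensityAndDensity:
    def test_recruitment_curve(self):
        assert intensity_model(0.25, 0.0, 0.64, 427.0) == 0.0
        assert intensity_model(0.25, 1e9, 0.64, 427.0) == pytest.approx(0.16, rel=1e-9)
        # initial slope alpha*eps/t*
        t = np.array([0.0, 1e-3])
        y = intensity_model(0.2, t, 0.64, 427.0)
        assert (y[1] - y[0]) / 1e-3 == pytest.approx(0.64 * 0.2 / 427.0, rel=1e-3)

    def test_compression_branch_is_flagged_zero(self):
        with pytest.warns(DomainWarning):
            assert intensity_model(-0.2, 100.0, 0.64, 427.0) == 0.0

    @pytest.mark.parametrize(
        "I_ratio, eps_len, expected",
        [
            (1.0, 0.0, 0.0),
            (1.0, -0.2, 0.25),                # compressed at constant content
            (1.192, 0.3, 1.192 / 1.3 - 1.0),  # recruitment under extension
        ],
    )
    def test_density_variation(self, I_ratio, eps_len, expected):
        assert density_variation(I_ratio, eps_len) == pytest.approx(expected, rel=1e-12)

    def test_elastic_reference_line(self):
        assert elastic_reference(0.3) == -0.3

    def test_density_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            density_variation(0.0, 0.1)
        with pytest.raises(InvalidParameterError):
            density_variation(1.0, -1.0)


class TestTypes:
    def test_params_validation(self):
        with pytest.raises(InvalidParameterError):
            GlobalMechParams(K0=-1, k=0.2, gamma=100, lambda0=2.3, V=0.1,
                             sigma=0.035, E=11.3, A=0.6, alpha=0.64, t_star=427)

    def test_from_modulus_consistency(self):
        p = GlobalMechParams.from_modulus(
            11.3, 0.6, 36.47, k=0.23, gamma=100, lambda0=2.3, V=0.1,
            sigma=0.035, alpha=0.64, t_star=427)
        assert p.K0 == pytest.approx(11.3 * 0.6 / 36.47, rel=1e-12)

    def test_compression_protocol_requires_prestretch(self):
        with pytest.raises(InvalidParameterError):
            StretchProtocol(epsilon=-0.2, direction="compression")

    def test_large_strain_warns(self):
        from sfmech.exceptions import StrainRangeWarning

        with pytest.warns(StrainRangeWarning):
            StretchProtocol(epsilon=0.55)
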