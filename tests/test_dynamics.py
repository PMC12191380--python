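"""Deterministic skeleton: Hill kinetics, drift, Jacobian, fixed points."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import root

from grnmemory import (
    ConstitutiveGeneParams,
    FeedbackLoopParams,
    PromoterBindingParams,
    StatePoint,
    constitutive_steady_state,
    drift,
    find_fixed_points,
    hill_activation,
    hill_derivative,
    jacobian,
    qss_bound_fraction,
)
from grnmemory.errors import InvalidParameterError


class TestHillActivation:
    @pytest.mark.parametrize("K,n", [(1.0, 1.0), (5.0, 2.0), (30.0, 4.0)])
    def test_half_maximal_at_threshold(self, K, n):
        assert hill_activation(K, K, n) == pytest.approx(0.5)

    @pytest.mark.parametrize("K,n", [(1.0, 1.0), (7.0, 3.0)])
    def test_zero_input_silent(self, K, n):
        assert hill_activation(0.0, K, n) == 0.0

    def test_direct_evaluation(self):
        # v = 3K with n = 1: 3 / (1 + 3)
        assert hill_activation(3.0, 1.0, 1.0) == pytest.approx(0.75)

    def test_huge_input_saturates_without_overflow(self):
        assert hill_activation(1e300, 5.0, 4.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("K,n", [(0.0, 1.0), (-1.0, 1.0), (5.0, 0.5)])
    def test_invalid_parameters_rejected(self, K, n):
        with pytest.raises(InvalidParameterError):
            hill_activation(1.0, K, n)

    @settings(derandomize=True, max_examples=200)
    @given(
        v1=st.floats(0.0, 1e6),
        dv=st.floats(0.0, 1e6),
        K=st.floats(0.01, 1e4),
        dK=st.floats(0.0, 1e4),
        n=st.floats(1.0, 6.0),
    )
    def test_monotone_and_bounded(self, v1, dv, K, dK, n):
        lo, hi = hill_activation(v1, K, n), hill_activation(v1 + dv, K, n)
        # mathematically < 1, but deep saturation rounds to 1.0 in floats
        assert 0.0 <= lo <= hi <= 1.0
        # nonincreasing in K at fixed positive v
        if v1 > 0:
            assert hill_activation(v1, K + dK, n) <= hill_activation(v1, K, n) + 1e-15


class TestBuildingBlocks:
    @pytest.mark.parametrize("k,mu,expected", [(5.0, 0.5, 10.0), (0.5, 0.5, 1.0), (7.0, 2.0, 3.5)])
    def test_constitutive_steady_state(self, k, mu, expected):
        assert constitutive_steady_state(ConstitutiveGeneParams(k_x=k, mu_x=mu)) == pytest.approx(expected)

    def test_qss_bound_fraction_half_maximal_at_K(self):
        p = PromoterBindingParams(k_on=2.0, k_off=1.0, D_total=1.0)
        assert p.K == pytest.approx(0.5)
        assert qss_bound_fraction(p.K, p) == pytest.approx(0.5)
        assert qss_bound_fraction(0.0, p) == 0.0
        assert qss_bound_fraction(1.5, p) == pytest.approx(0.75)

    def test_qss_equals_hill_with_unit_cooperativity(self):
        p = PromoterBindingParams(k_on=0.4, k_off=2.0, D_total=3.0)
        for x in [0.0, 1.0, 5.0, 42.0]:
            assert qss_bound_fraction(x, p) == pytest.approx(hill_activation(x, p.K, 1.0))


class TestDrift:
    def test_origin_is_always_quiescent(self, basal_params, bistable_params):
        for p in (basal_params, bistable_params):
            assert drift(StatePoint(0.0, 0.0), p) == pytest.approx([0.0, 0.0])

    def test_vanishes_at_symmetric_fixed_point(self, basal_params):
        assert drift(StatePoint(5.0, 5.0), basal_params) == pytest.approx([0.0, 0.0])

    def test_direct_evaluation(self):
        p = FeedbackLoopParams(k_xy=4.0, k_yx=1.0, K_xy=10.0, K_yx=1.0, n=1.0, mu_x=1.0, mu_y=1.0)
        # x-component at (0, 10): 4 * 0.5 - 1 * 0 = 2
        assert drift(StatePoint(0.0, 10.0), p)[0] == pytest.approx(2.0)


class TestJacobian:
    def test_symmetric_fixed_point_value(self, basal_params):
        J = jacobian(StatePoint(5.0, 5.0), basal_params)
        assert J == pytest.approx(np.array([[-0.5, 0.25], [0.25, -0.5]]))

    def test_saturated_activation_has_zero_gain(self, basal_params):
        J = jacobian(StatePoint(5.0, 1e12), basal_params)
        assert J[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_diagonal_is_always_degradation(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = FeedbackLoopParams(
                k_xy=rng.uniform(1, 20), k_yx=rng.uniform(1, 20),
                K_xy=rng.uniform(1, 20), K_yx=rng.uniform(1, 20),
                n=rng.integers(1, 4), mu_x=rng.uniform(0.2, 2), mu_y=rng.uniform(0.2, 2),
            )
            J = jacobian(StatePoint(rng.uniform(0, 30), rng.uniform(0, 30)), p)
            assert J[0, 0] == -p.mu_x and J[1, 1] == -p.mu_y

    def test_matches_finite_differences(self):
        """Analytic Jacobian vs central differences on 100 random states/params."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = FeedbackLoopParams(
                k_xy=rng.uniform(1, 30), k_yx=rng.uniform(1, 30),
                K_xy=rng.uniform(1, 30), K_yx=rng.uniform(1, 30),
                n=float(rng.integers(1, 5)), mu_x=rng.uniform(0.2, 2), mu_y=rng.uniform(0.2, 2),
            )
            s = StatePoint(rng.uniform(0.5, 50), rng.uniform(0.5, 50))
            J = jacobian(s, p)
            h = 1e-6
            fd = np.empty((2, 2))
            for j in range(2):
                dp = [0.0, 0.0]
                dp[j] = h * max(1.0, abs(s[j]))
                up = drift(StatePoint(s.x + dp[0], s.y + dp[1]), p)
                dn = drift(StatePoint(s.x - dp[0], s.y - dp[1]), p)
                fd[:, j] = (up - dn) / (2 * dp[j])
            assert np.allclose(J, fd, rtol=1e-6, atol=1e-8 * np.abs(J).max())


def _oracle_fixed_points(p: FeedbackLoopParams, n_grid: int = 25) -> list[tuple[float, float]]:
    """Independent fixed-point oracle: damped-Newton multistart over a 2-D
    grid of initial guesses, deduplicated."""
    bx, by = p.k_xy / p.mu_x, p.k_yx / p.mu_y

    def _hill(v, K, n):
        v = max(v, 0.0)  # clamp so Newton steps may overshoot below zero
        return v**n / (K**n + v**n)

    def _field(v):
        x, y = v
        return [
            p.k_xy * _hill(y, p.K_xy, p.n) - p.mu_x * x,
            p.k_yx * _hill(x, p.K_yx, p.n) - p.mu_y * y,
        ]

    found: list[tuple[float, float]] = []
    for x0 in np.linspace(0, bx, n_grid):
        for y0 in np.linspace(0, by, n_grid):
            sol = root(_field, [x0, y0], tol=1e-12)
            if not sol.success:
                continue
            x, y = sol.x
            if x < -1e-9 or y < -1e-9 or x > bx * 1.001 or y > by * 1.001:
                continue
            x, y = max(x, 0.0), max(y, 0.0)
            if np.max(np.abs(drift(StatePoint(x, y), p))) > 1e-9:
                continue
            if all(abs(x - a) > 1e-5 * max(bx, 1) or abs(y - b) > 1e-5 * max(by, 1)
                   for a, b in found):
                found.append((x, y))
    return sorted(found)


def _param_battery() -> list[FeedbackLoopParams]:
    rng = np.random.default_rng(2024)
    battery = [
        FeedbackLoopParams.symmetric(k=5.0, K=5.0, mu=0.5, n=1.0),
        FeedbackLoopParams.symmetric(k=20.0, K=8.0, mu=1.0, n=2.0),
        FeedbackLoopParams.symmetric(k=4.0, K=10.0, mu=1.0, n=2.0),  # monostable at the origin
    ]
    while len(battery) < 20:
        battery.append(FeedbackLoopParams(
            k_xy=rng.uniform(2, 30), k_yx=rng.uniform(2, 30),
            K_xy=rng.uniform(1, 25), K_yx=rng.uniform(1, 25),
            n=float(rng.integers(1, 4)), mu_x=rng.uniform(0.3, 2), mu_y=rng.uniform(0.3, 2),
        ))
    return battery


class TestFindFixedPoints:
    def test_basal_loop_has_saddle_origin_and_stable_active_state(self, basal_params):
        fps = find_fixed_points(basal_params)
        assert len(fps) == 2
        origin, on = fps
        assert origin.state == StatePoint(0.0, 0.0)
        assert not origin.is_stable
        assert sorted(origin.eigenvalues.real) == pytest.approx([-1.5, 0.5])
        assert on.state.x == pytest.approx(5.0, abs=1e-6)
        assert on.state.y == pytest.approx(5.0, abs=1e-6)
        assert on.is_stable
        assert sorted(on.eigenvalues.real) == pytest.approx([-0.75, -0.25])

    def test_cooperative_loop_is_bistable_with_interior_saddle(self, bistable_params):
        fps = find_fixed_points(bistable_params)
        assert [fp.stability for fp in fps] == ["stable", "saddle", "stable"]
        assert [fp.state.x for fp in fps] == pytest.approx([0.0, 4.0, 16.0], abs=1e-6)

    def test_drift_residual_bound_holds_everywhere(self):
        for p in _param_battery():
            for fp in find_fixed_points(p):
                assert np.max(np.abs(drift(fp.state, p))) <= 1e-8

    def test_symmetric_params_give_diagonal_fixed_points(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = FeedbackLoopParams.symmetric(
                k=rng.uniform(2, 30), K=rng.uniform(1, 25),
                mu=rng.uniform(0.3, 2), n=float(rng.integers(1, 4)),
            )
            for fp in find_fixed_points(p):
                assert fp.state.x == pytest.approx(fp.state.y, abs=1e-6)

    @pytest.mark.parametrize("p", _param_battery())
    def test_agrees_with_multistart_root_oracle(self, p):
        """Same count and locations (within 1e-4) as an independent
        damped-Newton multistart solve of the 2-D drift field."""
        ours = [(fp.state.x, fp.state.y) for fp in find_fixed_points(p)]
        oracle = _oracle_fixed_points(p)
        assert len(ours) == len(oracle)
        for (x1, y1), (x2, y2) in zip(sorted(ours), oracle):
            assert x1 == pytest.approx(x2, abs=1e-4)
            assert y1 == pytest.approx(y2, abs=1e-4)

    def test_autoregulatory_constructor_restricts_to_diagonal(self):
        p = FeedbackLoopParams.autoregulatory(k=20.0, K=8.0, mu=1.0, n=2.0)
        xs = sorted(fp.state.x for fp in find_fixed_points(p))
        # dx/dt = k H(x; K, n) - mu x has the same roots along x = y
        assert xs == pytest.approx([0.0, 4.0, 16.0], abs=1e-6)
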