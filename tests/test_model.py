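"""Kinetic model: parameterization, exact solution and numerical oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mibikinetics import (
    CompartmentState,
    KineticParameters,
    RegimeViolationError,
    decay_constant,
    rhs,
    simulate_closed_form,
    simulate_numeric,
    total_amount,
)

from conftest import random_params

rates = st.floats(0.0, 2.0, allow_nan=False)


@pytest.mark.parametrize(
    ("half_life", "expected"),
    [(6.0, math.log(2) / 6), (1.0, math.log(2)), (math.log(2), 1.0)],
)
def test_decay_constant_closed_form(half_life, expected):
    assert decay_constant(half_life) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("bad", [0.0, -1.0])
def test_decay_constant_rejects_nonpositive_half_life(bad):
    with pytest.raises(ValueError):
        decay_constant(bad)


def test_parameters_reject_negative_rates_and_nonpositive_dose():
    with pytest.raises(ValueError):
        KineticParameters(beta_zx=-0.1)
    with pytest.raises(ValueError):
        KineticParameters(n0=0.0)


def test_regime_check_flags_leaky_tumor_and_strong_normal_uptake():
    KineticParameters(beta_zx=0.5, beta_zy=0.25, beta_xz=0.1, beta_yz=0.5).validate_regime()
    # fully retentive limit is accepted
    KineticParameters(beta_zx=1.0, beta_zy=0.5).validate_regime()
    with pytest.raises(RegimeViolationError):
        KineticParameters(beta_zx=0.5, beta_zy=0.25, beta_xz=0.5, beta_yz=0.1).validate_regime()
    with pytest.raises(RegimeViolationError):
        KineticParameters(beta_zx=0.25, beta_zy=0.5, beta_xz=0.1, beta_yz=0.5).validate_regime()


class TestRhs:
    def test_decay_only_bolus(self):
        params = KineticParameters(lambda_decay=0.2)
        state = CompartmentState(x=0.0, y=0.0, z=1.0)
        assert rhs(state, params) == pytest.approx((0.0, 0.0, -0.2))

    def test_all_rates_zero_is_stationary(self):
        derivs = rhs(CompartmentState(0.3, 0.2, 0.5), KineticParameters())
        assert derivs == (0.0, 0.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        lam=rates, elim=rates, bzx=rates, bzy=rates, bxz=rates, byz=rates,
        x=st.floats(0, 5), y=st.floats(0, 5), z=st.floats(0, 5),
    )
    def test_derivative_sum_identity(self, lam, elim, bzx, bzy, bxz, byz, x, y, z):
        """d(x+y+z)/dt = -lambda*(x+y+z) - E*z for any state."""
        params = KineticParameters(
            lambda_decay=lam, elim=elim, beta_zx=bzx, beta_zy=bzy, beta_xz=bxz, beta_yz=byz
        )
        derivs = rhs(CompartmentState(x, y, z), params)
        assert sum(derivs) == pytest.approx(-lam * (x + y + z) - elim * z, abs=1e-9)


class TestClosedForm:
    def test_pure_decay_halves_in_one_half_life(self):
        params = KineticParameters(lambda_decay=decay_constant(6.0))
        traj = simulate_closed_form(params, np.array([0.0, 6.0]))
        assert traj.x[1] == 0.0 and traj.y[1] == 0.0
        assert traj.z[1] == pytest.approx(0.5, rel=1e-12)

    def test_branching_ratio_long_time_limit(self):
        # no decay/elimination/return flux: dose splits as beta_zx : beta_zy
        params = KineticParameters(beta_zx=1.0, beta_zy=0.5)
        traj = simulate_closed_form(params, np.array([0.0, 200.0]))
        assert traj.x[-1] == pytest.approx(2 / 3, abs=1e-9)
        assert traj.y[-1] == pytest.approx(1 / 3, abs=1e-9)
        assert traj.z[-1] == pytest.approx(0.0, abs=1e-9)

    def test_matches_numeric_oracle_on_washout_scenario(self, fig6a_params):
        times = np.array([0.5, 1.0, 2.0, 4.0])
        cf = simulate_closed_form(fig6a_params, times)
        num = simulate_numeric(fig6a_params, times, step=1e-3)
        for a, b in ((cf.x, num.x), (cf.y, num.y), (cf.z, num.z)):
            assert np.max(np.abs(a - b)) <= 1e-6 * max(np.max(np.abs(a)), 1e-12)

    def test_rejects_unordered_or_duplicate_grid(self, fig6a_params):
        with pytest.raises(ValueError):
            simulate_closed_form(fig6a_params, np.array([0.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            simulate_closed_form(fig6a_params, np.array([0.0, 2.0, 1.0]))

    def test_repeated_eigenvalue_fallback(self):
        # all compartments decoupled with identical eigenvalues -lambda
        params = KineticParameters(lambda_decay=0.3)
        traj = simulate_closed_form(params, np.linspace(0, 10, 11))
        assert np.allclose(traj.z, np.exp(-0.3 * traj.times), rtol=1e-12)


class TestNumericIntegrator:
    def test_pure_decay_high_accuracy(self):
        params = KineticParameters(lambda_decay=decay_constant(6.0))
        traj = simulate_numeric(params, np.array([6.0]), step=1e-3)
        assert traj.z[0] == pytest.approx(0.5, abs=1e-8)

    def test_zero_rates_constant_trajectory(self):
        traj = simulate_numeric(KineticParameters(n0=2.0), np.linspace(0.5, 5, 10), step=0.01)
        assert np.all(traj.x == 0) and np.all(traj.y == 0)
        assert np.allclose(traj.z, 2.0)

    def test_rejects_nonpositive_or_oversized_step(self, fig6a_params):
        with pytest.raises(ValueError):
            simulate_numeric(fig6a_params, np.array([1.0]), step=0.0)
        with pytest.raises(ValueError):
            simulate_numeric(fig6a_params, np.array([0.1, 0.2]), step=0.5)

    def test_oracle_equivalence_random_sweep(self):
        """Closed form and RK4 agree to 1e-6 relative over random draws."""
        rng = np.random.default_rng(1234)
        times = np.linspace(0.25, 8.0, 8)
        for _ in range(25):
            params = random_params(rng)
            cf = simulate_closed_form(params, times)
            num = simulate_numeric(params, times, step=5e-3)
            scale = max(cf.x.max(), cf.y.max(), cf.z.max())
            diff = max(
                np.max(np.abs(cf.x - num.x)),
                np.max(np.abs(cf.y - num.y)),
                np.max(np.abs(cf.z - num.z)),
            )
            assert diff <= 1e-6 * scale


class TestTotalAmount:
    def test_conserved_without_decay_or_elimination(self):
        params = KineticParameters(beta_zx=1.0, beta_zy=0.5, beta_xz=0.2, beta_yz=0.6)
        traj = simulate_closed_form(params, np.linspace(0, 24, 97))
        assert np.max(np.abs(total_amount(traj) - 1.0)) <= 1e-9

    def test_follows_decay_envelope_without_elimination(self):
        lam = decay_constant(6.0)
        params = KineticParameters(
            lambda_decay=lam, beta_zx=0.7, beta_zy=0.35, beta_xz=0.1, beta_yz=0.5
        )
        traj = simulate_closed_form(params, np.linspace(0, 24, 97))
        envelope = np.exp(-lam * traj.times)
        assert np.max(np.abs(total_amount(traj) - envelope)) <= 1e-9

    def test_elimination_pulls_total_below_decay_envelope(self, fig6a_params):
        traj = simulate_closed_form(fig6a_params, np.linspace(0, 12, 49))
        envelope = np.exp(-fig6a_params.lambda_decay * traj.times)
        total = total_amount(traj)
        assert np.all(np.diff(total) < 0)
        assert np.all(total[1:] < envelope[1:])


class TestTrajectoryProperties:
    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(lam=rates, elim=rates, bzx=rates, bzy=rates, bxz=rates, byz=rates)
    def test_nonnegative_series(self, lam, elim, bzx, bzy, bxz, byz):
        params = KineticParameters(
            lambda_decay=lam, elim=elim, beta_zx=bzx, beta_zy=bzy, beta_xz=bxz, beta_yz=byz
        )
        traj = simulate_closed_form(params, np.linspace(0, 24, 25))
        assert traj.x.min() >= 0 and traj.y.min() >= 0 and traj.z.min() >= 0

    def test_linear_in_dose(self, fig6a_params, fine_grid):
        base = simulate_closed_form(fig6a_params, fine_grid)
        scaled = simulate_closed_form(fig6a_params.with_updates(n0=3.5), fine_grid)
        assert np.array_equal(scaled.x, 3.5 * base.x)
        assert np.array_equal(scaled.y, 3.5 * base.y)
        assert np.array_equal(scaled.z, 3.5 * base.z)

    def test_blood_monotone_without_return_flux(self):
        params = KineticParameters(lambda_decay=0.1, elim=0.2, beta_zx=0.8, beta_zy=0.4)
        traj = simulate_closed_form(params, np.linspace(0, 12, 121))
        assert np.all(np.diff(traj.z) <= 0)
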