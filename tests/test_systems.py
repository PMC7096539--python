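"""Right-hand sides, Jacobians and observables of the model systems."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epileptor import FrozenInputs, ParameterSet, SystemId, jacobian, observable, rhs
from epileptor.integrate import integrate_deterministic
from epileptor.systems import DIMS, f1, f2


P = ParameterSet()


class TestRhs:
    def test_sub2_hand_evaluated(self):
        # f2(-0.25) = 0, so at (x2, y2) = (-0.25, 0) with zero drive the
        # derivative is (x2 - x2^3, 0) = (-0.234375, 0)
        d = rhs(SystemId.SUB2, [-0.25, 0.0], P, FrozenInputs(external_input=0.0))
        np.testing.assert_allclose(d, [-0.234375, 0.0], atol=1e-15)

    @pytest.mark.parametrize("system,dim", [(s, d) for s, d in DIMS.items()])
    def test_dimension_checked(self, system, dim):
        frozen = FrozenInputs(z_frozen=3.0)
        with pytest.raises(ValueError):
            rhs(system, np.zeros(dim + 1), P, frozen)

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError):
            rhs(SystemId.SUB2, [np.nan, 0.0], P)

    def test_full_equilibrium_residual(self):
        from epileptor import find_equilibria

        p = P.with_(m=0.5, x0=-1.6)
        eq = find_equilibria(SystemId.FULL, p)[0]
        x1, y1, z, x2, y2 = eq.state
        # complete the state with the stationary filter value; under the
        # printed-Jacobian convention only the first five components vanish
        # up to the (omitted) 0.002*g feed into the x2 equation
        g = x1 / p.gamma_filter
        d = rhs(SystemId.FULL, [x1, y1, z, x2, y2, g], p)
        assert np.max(np.abs(d[[0, 1, 2, 4, 5]])) < 1e-8
        assert abs(d[3] - 0.002 * g) < 1e-8

    @pytest.mark.parametrize("eps", [1e-4, 1e-6, 1e-8])
    def test_piecewise_seams_continuous(self, eps):
        # f1 vanishes at x1 = 0 from both sides, f2 at x2 = -0.25, and the
        # two z laws agree at z = 0
        for z in (0.0, 2.0, 3.5):
            lo = rhs(SystemId.SUB1, [-eps, 1.0], P, FrozenInputs(z_frozen=z))
            hi = rhs(SystemId.SUB1, [+eps, 1.0], P, FrozenInputs(z_frozen=z))
            assert np.max(np.abs(lo - hi)) < 50 * eps
        lo = rhs(SystemId.SUB2, [-0.25 - eps, 0.3], P)
        hi = rhs(SystemId.SUB2, [-0.25 + eps, 0.3], P)
        assert np.max(np.abs(lo - hi)) < 50 * eps
        lo = rhs(SystemId.FASTSLOW, [0.5, -1.0, -eps], P)
        hi = rhs(SystemId.FASTSLOW, [0.5, -1.0, +eps], P)
        assert np.max(np.abs(lo - hi)) < 50 * eps

    @given(x1=st.floats(-3, 3), x2=st.floats(-2, 2), z=st.floats(-2, 6))
    @settings(max_examples=50, deadline=None)
    def test_f1_f2_branch_agreement_at_seams(self, x1, x2, z):
        # the seam values themselves belong to both branch formulas
        assert f1(0.0, x2, z, P, True) == 0.0
        assert abs(P.a * 0.0 - f2(-0.25, P)) < 1e-15
        # f2 is continuous and piecewise linear/flat
        assert f2(x2, P) >= 0.0 or x2 < -0.25


def _fd_jacobian(fun, x, h=1e-6):
    n = len(x)
    J = np.zeros((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h * max(1.0, abs(x[j]))
        J[:, j] = (fun(x + e) - fun(x - e)) / (2 * e[j])
    return J


class TestJacobian:
    @pytest.mark.parametrize("system", [SystemId.SUB1, SystemId.SUB2,
                                        SystemId.FASTSLOW, SystemId.FULL])
    def test_matches_finite_differences_off_seam(self, system):
        rng = np.random.default_rng(7)
        frozen = FrozenInputs(z_frozen=3.0)
        for _ in range(100):
            if system is SystemId.SUB2:
                x = rng.uniform([-2, -2], [2, 2])
                if abs(x[0] + 0.25) < 1e-3:
                    continue
                fun = lambda v: rhs(system, v, P)
                J = jacobian(system, x, P)
            elif system is SystemId.SUB1:
                x = rng.uniform([-2, -6], [2, 2])
                if abs(x[0]) < 1e-3:
                    continue
                fun = lambda v: rhs(system, v, P, frozen)
                J = jacobian(system, x, P, frozen)
            elif system is SystemId.FASTSLOW:
                x = rng.uniform([-2, -6, -1.5], [2, 2, 5])
                if abs(x[0]) < 1e-3 or abs(x[2]) < 1e-3:
                    continue
                fun = lambda v: rhs(system, v, P)
                J = jacobian(system, x, P)
            else:
                x = rng.uniform([-2, -6, -1.5, -1.5, -1], [2, 2, 5, 1.5, 2])
                if min(abs(x[0]), abs(x[2]), abs(x[3] + 0.25)) < 1e-3:
                    continue
                # g enters no printed Jacobian entry; differentiate the
                # first five components at fixed g = 0
                fun = lambda v: rhs(
                    SystemId.FULL, np.append(v, 0.0), P
                )[:5]
                J = jacobian(system, x, P)
            Jfd = _fd_jacobian(fun, x)
            denom = np.maximum(1.0, np.abs(J))
            assert np.max(np.abs(J - Jfd) / denom) < 1e-6

    def test_sub2_trace_at_origin(self):
        J = jacobian(SystemId.SUB2, [0.0, 0.0], P)
        assert np.trace(J) == pytest.approx(1.0 - 0.0 - 1.0 / P.tau2)
        assert np.trace(J) == pytest.approx(0.9)

    def test_full_z_row_for_nonnegative_z(self):
        J = jacobian(SystemId.FULL, [0.5, -1.0, 3.0, -0.3, 0.0, 0.0], P)
        np.testing.assert_allclose(
            J[2], [P.r * P.s, 0.0, -P.r, 0.0, 0.0], rtol=0, atol=0
        )

    def test_full_z_row_for_negative_z(self):
        z = -0.5
        J = jacobian(SystemId.FULL, [0.5, -1.0, z, -0.3, 0.0, 0.0], P)
        assert J[2, 2] == pytest.approx(P.r * (-1.0 - 0.7 * z ** 6))


class TestObservable:
    def test_psi_cancellation(self):
        traj = integrate_deterministic(
            SystemId.FULL, [1.0, 0.0, 3.0, 1.0, 0.0, 0.0], 0.01, P
        )
        assert observable(traj, "psi")[0] == pytest.approx(0.0)

    def test_psi1_is_x1(self):
        traj = integrate_deterministic(
            SystemId.FULL, [0.0, -5.0, 3.0, 0.0, 0.0, 0.01], 50.0, P
        )
        np.testing.assert_array_equal(
            observable(traj, "psi1"), traj.component("x1")
        )

    def test_unknown_observable(self):
        traj = integrate_deterministic(
            SystemId.FULL, [0.0, -5.0, 3.0, 0.0, 0.0, 0.01], 1.0, P
        )
        with pytest.raises(ValueError):
            observable(traj, "nope")
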