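"""Equilibrium solving, closed forms, stability tables."""

import math

import numpy as np
import pytest

from epileptor import (
    FrozenInputs,
    ParameterSet,
    StabilityClass,
    SystemId,
    classify_stability,
    find_equilibria,
    hopf_m_at_z,
    stability_table_check,
    sub1_closed_form_points,
    sub1_equilibria_analytic,
    sub2_equilibria_analytic,
    sub2_snic_point,
)
from epileptor.equilibria import full_frozen_equilibria

P = ParameterSet()


class TestClassify:
    @pytest.mark.parametrize(
        "eigs,expected",
        [
            ([-1, -2], StabilityClass.STABLE_NODE),
            ([0.5 + 2j, 0.5 - 2j], StabilityClass.UNSTABLE_FOCUS),
            ([-0.1, 0.3], StabilityClass.SADDLE),
            ([-1 + 1j, -1 - 1j], StabilityClass.STABLE_FOCUS),
            ([1.0, 2.0], StabilityClass.UNSTABLE_NODE),
            # mixed sign with only a complex unstable pair spirals out
            ([0.3 + 1j, 0.3 - 1j, -2.0], StabilityClass.UNSTABLE_FOCUS),
            # a real unstable direction makes a saddle even with complex
            # unstable pairs present
            ([0.3 + 1j, 0.3 - 1j, 0.2, -2.0], StabilityClass.SADDLE),
        ],
    )
    def test_taxonomy(self, eigs, expected):
        assert classify_stability(eigs) is expected

    def test_marginal_flagged(self):
        assert classify_stability([1e-12, -1.0]) is StabilityClass.MARGINAL

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_stability([])


class TestSub1:
    def test_three_equilibria_at_z31(self):
        eqs = sub1_equilibria_analytic(3.1, P)
        classes = sorted(e.stability.value for e in eqs)
        assert classes == ["saddle", "stable focus", "stable node"]
        assert all(e.residual < 1e-10 for e in eqs)

    def test_agrees_with_generic_solver(self):
        a = sub1_equilibria_analytic(3.1, P)
        b = find_equilibria(SystemId.SUB1, P, FrozenInputs(z_frozen=3.1))
        assert len(a) == len(b)
        for ea, eb in zip(a, b):
            np.testing.assert_allclose(ea.state, eb.state, atol=1e-10)

    def test_quadratic_branch_discriminant_at_z31(self):
        # R = 0.6 (z-4)^2 = 0.486; delta+ = R^2 + 20 (1 - z + Iext1); the
        # (R + sqrt(delta))/(2d) root is the only nonnegative one there
        z = 3.1
        R = 0.6 * (z - 4.0) ** 2
        assert R == pytest.approx(0.486)
        delta = R * R + 20.0 * (1.0 - z + P.Iext1)
        assert delta > 0
        roots = [(R - math.sqrt(delta)) / 10.0, (R + math.sqrt(delta)) / 10.0]
        valid = [r for r in roots if r >= 0]
        eq_x1 = [e.state[0] for e in sub1_equilibria_analytic(z, P) if e.state[0] >= 0]
        np.testing.assert_allclose(sorted(valid), sorted(eq_x1), atol=1e-12)

    def test_existence_window_of_upper_branch(self):
        # for m <= 0 an x1 >= 0 equilibrium exists iff z <= Iext1 + 1 or
        # z >= max(X) + 4
        cf = sub1_closed_form_points(P)
        for z in [0.0, 2.0, 4.0, 4.09]:
            assert any(e.state[0] >= 0 for e in sub1_equilibria_analytic(z, P))
        for z in [4.2, 5.0, 7.0]:
            assert not any(
                e.state[0] >= 0 for e in sub1_equilibria_analytic(z, P)
            )
        assert any(
            e.state[0] >= 0
            for e in sub1_equilibria_analytic(cf.z_SN_outer + 0.1, P)
        )

    def test_cubic_fold_location(self):
        cf = sub1_closed_form_points(P)
        assert cf.x1_fold == pytest.approx(2 * (P.b - P.d) / (3 * P.a))
        assert cf.x1_fold == pytest.approx(-4.0 / 3.0)


class TestClosedForms:
    def test_lower_fold_value(self):
        cf = sub1_closed_form_points(P)
        assert cf.z_SN1 == pytest.approx(P.Iext1 - 5.0 / 27.0, abs=1e-12)
        assert cf.z_SN1 == pytest.approx(2.9148, abs=1e-4)

    def test_upper_fold_for_nonpositive_m(self):
        cf = sub1_closed_form_points(P)
        assert cf.z_SN2 == pytest.approx(4.1)

    def test_upper_fold_for_positive_m_from_quartic(self):
        cf = sub1_closed_form_points(P.with_(m=0.5))
        # the fold is where the quadratic-branch discriminant vanishes
        R = 0.5 + 0.6 * (cf.z_SN2 - 4.0) ** 2
        delta = R * R + 20.0 * (1.0 - cf.z_SN2 + P.Iext1)
        assert abs(delta) < 1e-6

    def test_hopf_location_and_numeric_crossing(self):
        cf = sub1_closed_form_points(P)
        assert cf.z_H == pytest.approx(4.0 - math.sqrt(5.0 / 3.0))
        # confirm the focus flips stability across z_H
        def focus_re(z):
            eqs = [e for e in sub1_equilibria_analytic(z, P) if e.state[0] >= 0]
            eq = max(eqs, key=lambda e: e.state[0])
            return max(ev.real for ev in eq.eigenvalues)

        assert focus_re(cf.z_H - 1e-3) > 0 > focus_re(cf.z_H + 1e-3)

    def test_no_hopf_beyond_unit_m(self):
        assert sub1_closed_form_points(P.with_(m=2.0)).z_H is None

    def test_quartic_coefficients(self):
        cf = sub1_closed_form_points(P.with_(m=0.7))
        assert cf.p == pytest.approx(10 * 0.7 / 3)
        assert cf.q == pytest.approx(-500.0 / 9.0)
        assert cf.w == pytest.approx((25.0 / 9.0) * (0.7 ** 2 + 20 * (P.Iext1 - 3)))


class TestHopfThreshold:
    @pytest.mark.parametrize(
        "z,expected", [(3.1, 0.514), (0.0, -8.6), (4.0, 1.0)]
    )
    def test_trace_zero_solution(self, z, expected):
        assert hopf_m_at_z(z, P) == pytest.approx(expected)

    @pytest.mark.parametrize("z", [3.1, 0.0])
    def test_confirmed_by_eigenvalue_sweep(self, z):
        m_h = hopf_m_at_z(z, P)

        def focus_re(m):
            eqs = [
                e
                for e in sub1_equilibria_analytic(z, P.with_(m=m))
                if e.state[0] >= 0
            ]
            eq = max(eqs, key=lambda e: e.state[0])
            return max(ev.real for ev in eq.eigenvalues)

        assert focus_re(m_h - 1e-3) < 0 < focus_re(m_h + 1e-3)


class TestSub2:
    def test_snic_drive_closed_form(self):
        val = sub2_snic_point(P)
        assert val == pytest.approx(2.0 / (3.0 * math.sqrt(3.0)))
        assert round(val, 3) == 0.385

    def test_root_count_flips_across_snic(self):
        star = sub2_snic_point(P)
        lo = sub2_equilibria_analytic(P, external_input=star - 1e-3)
        hi = sub2_equilibria_analytic(P, external_input=star + 1e-3)
        assert len(lo) == 3
        assert len(hi) == 1

    def test_det_root_on_lower_branch(self):
        x2 = -1.0 / math.sqrt(3.0)
        assert x2 < -0.25
        # Det(J2) = G2 - (1 - 3 x2^2)/tau2 with G2 = 0 on this branch
        assert -(1.0 - 3.0 * x2 ** 2) / P.tau2 == pytest.approx(0.0, abs=1e-15)

    def test_phase_plane_cases(self):
        # zero drive: single stable node; unit drive: single unstable focus
        lo = sub2_equilibria_analytic(P, external_input=0.0)
        assert [e.stability for e in lo] == [StabilityClass.STABLE_NODE]
        hi = sub2_equilibria_analytic(P, external_input=1.0)
        assert [e.stability for e in hi] == [StabilityClass.UNSTABLE_FOCUS]
        mid = sub2_equilibria_analytic(P, external_input=0.38)
        assert sorted(e.stability.value for e in mid) == [
            "saddle", "stable node", "unstable focus",
        ]


class TestFullModel:
    @pytest.mark.parametrize(
        "m,x0,n,classes",
        [
            (0.0, -1.6, 1, ["saddle"]),
            (0.5, -1.6, 1, ["saddle"]),
            (0.0, -0.9, 3, ["saddle", "stable focus", "unstable focus"]),
            (0.5, -0.9, 3, ["saddle", "unstable focus", "unstable focus"]),
        ],
    )
    def test_counts_and_classes(self, m, x0, n, classes):
        eqs = find_equilibria(SystemId.FULL, P.with_(m=m, x0=x0))
        assert len(eqs) == n
        assert sorted(e.stability.value for e in eqs) == sorted(classes)
        assert all(e.residual < 1e-10 for e in eqs)

    def test_stable_node_under_stationary_filter_convention(self):
        # with the filter variable at its stationary value the normal
        # state's equilibrium is a genuine stable node of the 6-state flow
        p = P.with_(m=0.0, x0=-2.5, g_convention="stationary")
        eqs = find_equilibria(SystemId.FULL, p)
        assert [e.stability for e in eqs] == [StabilityClass.STABLE_NODE]

    def test_classification_consistent_with_eigen_recomputation(self):
        from epileptor import jacobian

        for m, x0 in [(0.0, -0.9), (0.5, -1.6)]:
            for eq in find_equilibria(SystemId.FULL, P.with_(m=m, x0=x0)):
                eig = np.linalg.eigvals(
                    jacobian(SystemId.FULL, eq.state, P.with_(m=m, x0=x0))
                )
                assert classify_stability(eig) is eq.stability

    def test_counts_piecewise_constant_in_x0(self):
        # equilibrium count only changes at fold crossings; within the
        # single-saddle regime it stays 1
        for x0 in [-1.8, -1.7, -1.6, -1.5]:
            assert len(find_equilibria(SystemId.FULL, P.with_(x0=x0))) == 1

    def test_frozen_z_solves_four_dimensional_system(self):
        eqs = full_frozen_equilibria(3.4, P.with_(m=0.5))
        assert len(eqs) >= 3
        for e in eqs:
            assert e.frozen_z == 3.4
            assert e.eigenvalues.shape == (4,)
            assert e.residual < 1e-9


class TestStabilityTables:
    @pytest.mark.parametrize(
        "table,p",
        [
            ("T2", P),
            ("T3", P.with_(m=0.5)),
            ("T4", P.with_(m=2.0)),
            ("T5", P),
            ("T6", P),
        ],
    )
    def test_sign_patterns(self, table, p):
        report = stability_table_check(table, p)
        assert report["ok"], report

    def test_regime_guards(self):
        with pytest.raises(ValueError):
            stability_table_check("T2", P.with_(m=0.5))
        with pytest.raises(ValueError):
            stability_table_check("T9", P)
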