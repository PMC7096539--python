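"""Bifurcation diagrams, cycle envelopes, and onset/offset classes."""

import numpy as np
import pytest

from epileptor import ParameterSet, StabilityClass, SystemId
from epileptor.continuation import (
    cycle_envelope,
    detect_bifurcations,
    sweep_branches,
)
from epileptor.equilibria import sub1_closed_form_points

P = ParameterSet()


@pytest.fixture(scope="module")
def sub1_diag_m0():
    diag = sweep_branches(SystemId.SUB1, (-2.0, 6.0), 401, P)
    detect_bifurcations(diag)
    return diag


class TestSweep:
    def test_minimum_grid_enforced(self):
        with pytest.raises(ValueError):
            sweep_branches(SystemId.SUB1, (0, 1), 2, P)

    def test_sub1_upper_branch_split_by_hopf(self, sub1_diag_m0):
        # the upper branch splits into stable-focus and unstable-focus
        # sub-branches at the Hopf point
        kinds = {b.stability for b in sub1_diag_m0.branches if len(b) > 3}
        assert StabilityClass.STABLE_FOCUS in kinds
        assert StabilityClass.UNSTABLE_FOCUS in kinds
        assert StabilityClass.SADDLE in kinds
        assert StabilityClass.STABLE_NODE in kinds

    def test_branch_points_partition_grid_equilibria(self, sub1_diag_m0):
        # every grid equilibrium belongs to exactly one branch
        from epileptor.continuation import frozen_equilibria

        n_pts = sum(len(b) for b in sub1_diag_m0.branches)
        n_eqs = sum(
            len(frozen_equilibria(SystemId.SUB1, z, P))
            for z in sub1_diag_m0.z_grid
        )
        assert n_pts == n_eqs

    def test_full_m05_branch_classes(self):
        # Z-lower stable nodes, Z-middle saddles, Z-upper unstable foci
        diag = sweep_branches(SystemId.FULL, (2.95, 3.6), 41, P.with_(m=0.5))
        lower = [b for b in diag.branches if b.x1.mean() < -1.5 and len(b) > 5]
        middle = [
            b for b in diag.branches if -1.2 < b.x1.mean() < -0.3 and len(b) > 5
        ]
        upper = [b for b in diag.branches if 0.2 < b.x1.mean() < 0.8 and len(b) > 5]
        assert {b.stability for b in lower} == {StabilityClass.STABLE_NODE}
        assert {b.stability for b in middle} == {StabilityClass.SADDLE}
        assert StabilityClass.UNSTABLE_FOCUS in {b.stability for b in upper}

    def test_full_m_minus8_upper_branch_stable_nodes(self):
        # in the depolarization-block regime the upper branch consists of
        # stable nodes (the imaginary parts have vanished)
        diag = sweep_branches(
            SystemId.FULL, (3.0, 4.0), 41, P.with_(m=-8.0, Iext2=0.0)
        )
        upper = [b for b in diag.branches if b.x1.mean() > 0 and len(b) > 5]
        assert upper
        assert {b.stability for b in upper} == {StabilityClass.STABLE_NODE}

    def test_csv_export(self, sub1_diag_m0, tmp_path):
        path = tmp_path / "diag.csv"
        sub1_diag_m0.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "branch,z,x1,stability"


class TestDetect:
    def test_sub1_folds_match_closed_forms(self, sub1_diag_m0):
        cf = sub1_closed_form_points(P)
        sn = sorted(q.z for q in sub1_diag_m0.points if q.kind == "SN")
        step = sub1_diag_m0.z_grid[1] - sub1_diag_m0.z_grid[0]
        assert any(abs(z - cf.z_SN1) < step for z in sn)
        assert any(abs(z - cf.z_SN2) < step for z in sn)

    def test_sub1_hopf_matches_closed_form(self, sub1_diag_m0):
        cf = sub1_closed_form_points(P)
        hopf = [q.z for q in sub1_diag_m0.points if q.kind == "HOPF"]
        step = sub1_diag_m0.z_grid[1] - sub1_diag_m0.z_grid[0]
        assert len(hopf) >= 1
        assert min(abs(z - cf.z_H) for z in hopf) < step

    def test_all_stable_branch_has_no_points(self):
        # a window of the lower branch only: single stable branch, nothing
        # to detect
        diag = sweep_branches(SystemId.SUB1, (4.3, 5.5), 21, P)
        stable_only = [b for b in diag.branches if b.stability.is_stable]
        pts = [
            q
            for q in detect_bifurcations(diag)
            if 4.3 < q.z < 5.5 and q.kind == "HOPF"
        ]
        assert stable_only
        assert pts == []


class TestEnvelope:
    def test_hopf_termination_matches_closed_form(self):
        cf = sub1_closed_form_points(P)
        env = cycle_envelope(SystemId.SUB1, np.linspace(2.0, 3.0, 60), P)
        assert env.term_high == "HOPF"
        assert abs(env.z_term_high - cf.z_H) < 0.02
        # amplitude shrinks toward the Hopf end
        idx = np.flatnonzero(env.has_cycle)
        amp = env.max_x1[idx] - env.min_x1[idx]
        assert amp[-1] < 0.2
        assert amp[0] > amp[-1]

    def test_homoclinic_termination_keeps_amplitude(self):
        env = cycle_envelope(
            SystemId.SUB1, np.linspace(2.5, 3.2, 60), P.with_(m=2.0)
        )
        assert env.term_high == "HOMOCLINIC"
        idx = np.flatnonzero(env.has_cycle)
        amp = env.max_x1[idx] - env.min_x1[idx]
        assert amp[-1] > 0.5

    def test_envelope_bounds_long_simulation(self):
        # inside the stable-cycle range a long direct run stays within the
        # envelope's max/min band (2% tolerance)
        from epileptor import FrozenInputs, drop_transient, integrate_deterministic

        z = 2.0
        env = cycle_envelope(SystemId.SUB1, np.array([z - 0.01, z, z + 0.01]), P)
        traj = integrate_deterministic(
            SystemId.SUB1, [0.6, -1.0], 600.0, P, frozen=FrozenInputs(z_frozen=z)
        )
        x1 = drop_transient(traj, 300.0).component("x1")
        width = env.max_x1[1] - env.min_x1[1]
        assert x1.max() <= env.max_x1[1] + 0.02 * width
        assert x1.min() >= env.min_x1[1] - 0.02 * width


class TestOnsetOffset:
    def test_burster_class_table(self, sle_table):
        from conftest import SLE_CONFIGS

        for key, expected in SLE_CONFIGS.items():
            assert sle_table[key].label == expected, key
        # the depolarization-block switch is the m = -8 fold/fold case
        assert sle_table[(-8.0, 0.0)].ictal_state == "db"
        assert sle_table[(-1.0, 0.0)].ictal_state == "nonoscillatory"

    def test_bistability_interval_starts_at_lower_fold(self, sle_table):
        cf = sub1_closed_form_points(P)
        for res in sle_table.values():
            assert res.has_sle
            assert res.bistability[0] == pytest.approx(cf.z_SN1, abs=1e-6)
            assert res.bistability[1] > res.bistability[0]

    def test_no_sle_when_stable_equilibrium_exists(self):
        from epileptor import classify_sle

        res = classify_sle(P.with_(m=0.0, x0=-2.5))
        assert not res.has_sle
        assert res.label is None
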