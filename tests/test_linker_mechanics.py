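"""Base-pair step algebra, elastic energy and the linker boundary solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromofiber.linker_mechanics import (
    REST_RISE,
    REST_TWIST,
    BpStep,
    LinkerSolver,
    StiffnessModel,
    elastic_energy,
    extract_steps,
    optimize_linker,
    reconstruct_frames,
)
from chromofiber.linker_mechanics import _rot, step_transform


def random_steps(rng, n, twist_sd=8.0, bend_sd=6.0, disp_sd=0.5):
    return np.column_stack(
        [
            rng.normal(REST_TWIST, twist_sd, n),
            rng.normal(0, bend_sd, n),
            rng.normal(0, bend_sd, n),
            rng.normal(0, disp_sd, n),
            rng.normal(0, disp_sd, n),
            rng.normal(REST_RISE, 0.3, n),
        ]
    )


class TestStepFrameConversion:
    def test_rest_chain_is_straight_helix(self, rest_steps):
        R, o = reconstruct_frames(np.eye(3), np.zeros(3), rest_steps(10))
        # 10 rest steps: end displaced exactly 10 x 3.35 A along start Z
        np.testing.assert_allclose(o[-1], [0.0, 0.0, 33.5], atol=1e-12)
        # net rotation about Z is 345 degrees
        ang = np.degrees(np.arctan2(R[-1][1, 0], R[-1][0, 0]))
        assert ang == pytest.approx(-15.0, abs=1e-9)

    def test_single_roll_round_trip(self):
        s = np.array([[REST_TWIST, 90.0, 0.0, 0.0, 0.0, REST_RISE]])
        R, o = reconstruct_frames(np.eye(3), np.zeros(3), s)
        back = extract_steps(R, o)
        np.testing.assert_allclose(back, s, atol=1e-9)

    def test_pure_z_rotation_plus_rise_is_rest_step(self):
        R2 = _rot(np.array([0.0, 0.0, 1.0]), np.deg2rad(REST_TWIST))
        frames_R = np.stack([np.eye(3), R2])
        frames_o = np.stack([np.zeros(3), np.array([0.0, 0.0, REST_RISE])])
        step = extract_steps(frames_R, frames_o)[0]
        np.testing.assert_allclose(
            step, [REST_TWIST, 0, 0, 0, 0, REST_RISE], atol=1e-9
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_round_trip_random_chains(self, seed):
        rng = np.random.default_rng(seed)
        steps = random_steps(rng, 20)
        R, o = reconstruct_frames(np.eye(3), np.zeros(3), steps)
        np.testing.assert_allclose(extract_steps(R, o), steps, atol=1e-8)

    def test_extract_rejects_coincident_origins(self):
        R = np.stack([np.eye(3), np.eye(3)])
        o = np.zeros((2, 3))
        with pytest.raises(ValueError, match="degenerate"):
            extract_steps(R, o)

    def test_core_twist_near_rest(self, core):
        tw = core.twist_profile()
        assert tw.mean() == pytest.approx(REST_TWIST, abs=1e-6)
        assert tw.std() < 0.1


class TestElasticEnergy:
    def test_rest_state_costs_nothing(self, rest_steps):
        assert elastic_energy(rest_steps(12)) == 0.0

    def test_quadratic_in_twist_deviation(self):
        f = StiffnessModel()
        f_tw = f.matrix[0, 0]
        for delta in (2.0, 4.0):
            s = np.array([[REST_TWIST + delta, 0, 0, 0, 0, REST_RISE]])
            assert elastic_energy(s, f) == pytest.approx(0.5 * f_tw * delta**2)

    def test_twist_roll_cross_term(self):
        f = StiffnessModel()
        s_tw = np.array([[REST_TWIST + 5, 0, 0, 0, 0, REST_RISE]])
        s_ro = np.array([[REST_TWIST, 5, 0, 0, 0, REST_RISE]])
        s_both = np.array([[REST_TWIST + 5, 5, 0, 0, 0, REST_RISE]])
        cross = elastic_energy(s_both, f) - elastic_energy(s_tw, f) - elastic_energy(s_ro, f)
        # the interaction equals exactly the off-diagonal contribution
        assert cross == pytest.approx(f.matrix[0, 1] * 25.0)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(4)
        steps = random_steps(rng, 15)
        R0 = _rot(np.array([0.3, 0.9, 0.1]) / np.linalg.norm([0.3, 0.9, 0.1]), 1.1)
        R, o = reconstruct_frames(R0, np.array([5.0, -2.0, 7.0]), steps)
        np.testing.assert_allclose(
            elastic_energy(extract_steps(R, o)), elastic_energy(steps), rtol=1e-9
        )

    def test_rejects_indefinite_stiffness(self):
        bad = np.eye(6)
        bad[0, 0] = -1.0
        with pytest.raises(ValueError, match="positive definite"):
            StiffnessModel(bad)


class TestLinkerOptimization:
    def test_rest_boundary_recovers_rest_chain(self, rest_steps):
        L = 20
        R, o = reconstruct_frames(np.eye(3), np.zeros(3), rest_steps(L + 1))
        sols = optimize_linker(np.eye(3), np.zeros(3), R[-1], o[-1], L)
        assert sols[0].elastic_energy == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(sols[0].steps, rest_steps(L + 1), atol=1e-6)

    def test_pure_twist_branch_matches_uniform_closed_form(self, rest_steps):
        # a boundary rotated by +360 about the helix axis is identical, so
        # the +-1-turn topoisomers must appear with the uniform-twist energy
        L = 20
        f = StiffnessModel()
        R, o = reconstruct_frames(np.eye(3), np.zeros(3), rest_steps(L + 1))
        sols = optimize_linker(np.eye(3), np.zeros(3), R[-1], o[-1], L)
        by_off = {c.twist_offset: c for c in sols}
        e_uniform = 0.5 * f.matrix[0, 0] * (360.0 / (L + 1)) ** 2 * (L + 1)
        for off in (360.0, -360.0):
            assert by_off[off].elastic_energy == pytest.approx(e_uniform, rel=0.01)
            # uniform distribution across steps
            tw = by_off[off].steps[:, 0]
            assert tw.std() < 0.2

    def test_topoisomers_stay_distinct(self, core):
        # fiber-like boundary: solutions one turn apart must coexist with
        # different energies, not collapse onto one basin
        from chromofiber.nucleosome_geometry import FiberParams, compose_frames, place_nucleosomes

        params = FiberParams(r=53.0, h=29.0, phi=172.0, rho=-15.0, L=20, N=2)
        frames = place_nucleosomes(params)
        exit_R, exit_o = compose_frames(frames[0], core.exit_R, core.exit_o)
        entry_R, entry_o = compose_frames(frames[1], core.entry_R, core.entry_o)
        sols = [c for c in optimize_linker(exit_R, exit_o, entry_R, entry_o, 20) if c.converged]
        offsets = {c.twist_offset for c in sols}
        assert {0.0, 360.0}.issubset(offsets) or {0.0, -360.0}.issubset(offsets)
        energies = sorted(c.elastic_energy for c in sols)
        assert energies[1] - energies[0] > 1.0

    def test_planar_bend_near_elastic_rod_energy(self, rest_steps):
        # uniform 60-degree bend about a fixed axis phased into roll/tilt:
        # the optimizer must do at least as well as the constructed chain
        L = 20
        beta = np.deg2rad(60.0 / (L + 1))
        axis = np.array([0.0, 1.0, 0.0])
        rr, dd = step_transform(np.array([REST_TWIST, 0, 0, 0, 0, REST_RISE]))
        R_list, o_list = [np.eye(3)], [np.zeros(3)]
        for _ in range(L + 1):
            o_list.append(o_list[-1] + R_list[-1] @ dd)
            R_list.append(_rot(axis, beta) @ R_list[-1] @ rr)
        R, o = np.array(R_list), np.array(o_list)
        e_constructed = elastic_energy(extract_steps(R, o))
        sols = optimize_linker(np.eye(3), np.zeros(3), R[-1], o[-1], L)
        assert sols[0].converged
        assert sols[0].elastic_energy <= e_constructed * 1.001
        assert sols[0].elastic_energy > 0.25 * e_constructed

    def test_boundary_constraint_satisfied_tightly(self, rest_steps):
        L = 15
        rng = np.random.default_rng(7)
        steps = random_steps(rng, L + 1, twist_sd=4, bend_sd=3, disp_sd=0.2)
        R, o = reconstruct_frames(np.eye(3), np.zeros(3), steps)
        sols = optimize_linker(np.eye(3), np.zeros(3), R[-1], o[-1], L)
        best = sols[0]
        R2, o2 = reconstruct_frames(np.eye(3), np.zeros(3), best.steps)
        assert np.linalg.norm(o2[-1] - o[-1]) < 1e-3
        assert np.abs(R2[-1] - R[-1]).max() < 1e-3

    def test_unreachable_boundary_raises(self):
        solver = LinkerSolver(10)
        with pytest.raises(ValueError, match="reach"):
            solver.solve(np.eye(3), np.array([500.0, 0.0, 0.0]))

    def test_coincident_boundary_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            optimize_linker(np.eye(3), np.zeros(3), np.eye(3), np.zeros(3), 10)


def test_bpstep_dataclass_round_trip():
    s = BpStep(twist=36.0, roll=2.0, rise=3.3)
    arr = s.as_array()
    assert arr[0] == 36.0 and arr[5] == 3.3
    assert BpStep.rest().twist == REST_TWIST
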