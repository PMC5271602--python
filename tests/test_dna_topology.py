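"""Writhe, twist and linking-number machinery."""

import numpy as np
import pytest

from chromofiber.dna_topology import (
    FiberPath,
    close_ends,
    dlk_vs_N,
    linking_number,
    twist_change,
    writhe,
    writhe_brute_force,
)
from chromofiber.linker_mechanics import optimize_linker, reconstruct_frames
from chromofiber.nucleosome_geometry import FiberParams, compose_frames, place_nucleosomes


def subdivide(v, max_len):
    out = []
    n = v.shape[0]
    for i in range(n):
        a, b = v[i], v[(i + 1) % n]
        k = max(1, int(np.ceil(np.linalg.norm(b - a) / max_len)))
        for j in range(k):
            out.append(a + (b - a) * j / k)
    return np.array(out)


def closed_helix(n_turns=5, radius=50.0, pitch=40.0, n=200):
    t = np.linspace(0, 2 * np.pi * n_turns, n, endpoint=False)
    return np.column_stack(
        [radius * np.cos(t), radius * np.sin(t), pitch * t / (2 * np.pi)]
    )


@pytest.fixture(scope="module")
def small_fiber(core):
    params = FiberParams(r=53.0, h=29.0, phi=172.0, rho=-15.0, L=20, N=6)
    frames = place_nucleosomes(params)
    exit_R, exit_o = compose_frames(frames[0], core.exit_R, core.exit_o)
    entry_R, entry_o = compose_frames(frames[1], core.entry_R, core.entry_o)
    linker = optimize_linker(exit_R, exit_o, entry_R, entry_o, params.L)[0]
    return FiberPath(params, core, linker, frames)


class TestWrithe:
    def test_planar_polygon_is_writhe_free(self):
        th = np.linspace(0, 2 * np.pi, 17)[:-1]
        poly = np.column_stack([50 * np.cos(th), 50 * np.sin(th), np.zeros(16)])
        assert abs(writhe(poly)) < 1e-9
        # a non-convex but simple (star-shaped) planar polygon
        rng = np.random.default_rng(0)
        radii = rng.uniform(20, 60, 16)
        star = np.column_stack(
            [radii * np.cos(th), radii * np.sin(th), np.zeros(16)]
        )
        assert abs(writhe(star)) < 1e-9

    def test_mirror_flips_sign(self):
        curve = close_ends(closed_helix())
        mirrored = curve.vertices.copy()
        mirrored[:, 2] *= -1
        assert writhe(mirrored) == pytest.approx(-writhe(curve), abs=1e-9)

    def test_matches_gauss_integral_on_closed_helix(self):
        curve = close_ends(closed_helix())
        wq = writhe(curve)
        wb = writhe_brute_force(subdivide(curve.vertices, 5.0))
        assert wq == pytest.approx(wb, abs=1e-3)
        # the right-handed helix has positive writhe near n(1 - sin(pitch angle))
        alpha = np.arctan2(40.0, 2 * np.pi * 50.0)
        assert wq == pytest.approx(5 * (1 - np.sin(alpha)), abs=0.05)

    def test_invariant_under_vertex_refinement(self):
        curve = close_ends(closed_helix())
        w0 = writhe(curve)
        assert writhe(subdivide(curve.vertices, 10.0)) == pytest.approx(w0, abs=1e-9)


class TestClosure:
    def test_adds_exactly_four_coplanar_points(self):
        helix = closed_helix(n_turns=3, n=120)
        curve = close_ends(helix)
        assert curve.n_vertices == 124
        added = curve.vertices[list(curve.closure_indices)]
        # coplanar with the fiber axis: all four have zero y in the plane
        # spanned by z and the entry-point direction
        entry = helix[0] - np.array([0, 0, helix[0] @ [0, 0, 1]])
        u = entry / np.linalg.norm(entry)
        normal = np.cross([0, 0, 1.0], u)
        assert np.abs(added @ normal).max() < 1e-6

    def test_offsets_match_convention(self):
        helix = closed_helix(n_turns=3, n=120)
        curve = close_ends(helix)
        p_top, q_top, q_bot, p_bot = curve.vertices[list(curve.closure_indices)]
        zmax, zmin = helix[:, 2].max(), helix[:, 2].min()
        assert p_top[2] == pytest.approx(zmax + 350.0)
        assert p_bot[2] == pytest.approx(zmin - 350.0)
        assert np.linalg.norm(q_top - p_top) == pytest.approx(500.0)

    def test_closure_through_envelope_rejected(self):
        helix = closed_helix(n_turns=3, n=120)
        env = [(np.array([0.0, 0.0, helix[:, 2].max() + 100.0]), 60.0)]
        with pytest.raises(ValueError, match="closure"):
            close_ends(helix, envelopes=env)


class TestTwist:
    def test_rest_chain_no_twist_change(self, rest_steps):
        R, o = reconstruct_frames(np.eye(3), np.zeros(3), rest_steps(30))
        assert twist_change(R, o) == pytest.approx(0.0, abs=1e-12)

    def test_ten_extra_degrees_per_step(self):
        steps = np.tile([44.5, 0, 0, 0, 0, 3.35], (36, 1))
        R, o = reconstruct_frames(np.eye(3), np.zeros(3), steps)
        assert twist_change(R, o) == pytest.approx(1.0, abs=1e-9)

    def test_core_contributes_no_twist_change(self, core):
        assert twist_change(core.bp_R, core.bp_o) == pytest.approx(0.0, abs=1e-6)


class TestLinkingNumber:
    def test_straight_relaxed_dna_closes_to_zero(self, rest_steps):
        R, o = reconstruct_frames(np.eye(3), np.zeros(3), rest_steps(100))
        curve = close_ends(o, axis_point=np.zeros(3), axis_dir=np.array([0, 0, 1.0]))
        dlk = writhe(curve) + twist_change(R, o)
        assert dlk == pytest.approx(0.0, abs=1e-3)

    def test_block_decomposition_equals_direct_sum(self, small_fiber):
        res = linking_number(small_fiber, 6)
        R_all, o_all = small_fiber.bp_frames(6)
        wr_direct = writhe(close_ends(o_all))
        tw_direct = twist_change(R_all, o_all)
        assert res.wr == pytest.approx(wr_direct, abs=1e-6)
        assert res.delta_tw == pytest.approx(tw_direct, abs=1e-6)
        # the identity dLk = Wr + dTw holds exactly by construction
        assert res.delta_lk == res.wr + res.delta_tw

    def test_insensitive_to_closure_offsets(self, small_fiber):
        res = linking_number(small_fiber, 6)
        R_all, o_all = small_fiber.bp_frames(6)
        far = close_ends(o_all, axial_offset=700.0, lateral_offset=1000.0)
        dlk_far = writhe(far) + twist_change(R_all, o_all)
        assert abs(dlk_far - res.delta_lk) < 0.01

    def test_mirror_fiber_flips_writhe(self, small_fiber):
        R_all, o_all = small_fiber.bp_frames(6)
        mirrored = o_all.copy()
        mirrored[:, 2] *= -1
        w = writhe(close_ends(o_all))
        wm = writhe(close_ends(mirrored))
        assert wm == pytest.approx(-w, rel=1e-9)

    def test_dlk_vs_N_converges_monotonically_toward_limit(self, small_fiber):
        res = dlk_vs_N(small_fiber, [5, 10, 20, 40, 100])
        per = [r.delta_lk_per_nucleosome for r in res]
        # deviation from the N=100 value shrinks with N
        dev = [abs(p - per[-1]) for p in per[:-1]]
        assert all(dev[i + 1] <= dev[i] + 1e-6 for i in range(len(dev) - 1))
        assert dev[0] < 0.2

    def test_requires_at_least_two_nucleosomes(self, small_fiber):
        with pytest.raises(ValueError):
            dlk_vs_N(small_fiber, [1])
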