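"""Ideal core geometry, fiber placement and PDB input."""

import numpy as np
import pytest

from chromofiber.linker_mechanics import extract_steps
from chromofiber.nucleosome_geometry import (
    CORE_BP,
    FiberParams,
    Frame,
    load_core_from_pdb,
    make_ideal_core,
    place_nucleosomes,
)


class TestIdealCore:
    def test_frame_count_and_contour_length(self, core):
        assert core.n_bp == CORE_BP
        seg = np.linalg.norm(np.diff(core.bp_o, axis=0), axis=1)
        # closed form: n_turns * sqrt((2 pi R)^2 + P^2)
        expected = 1.67 * np.hypot(2 * np.pi * 41.9, 25.9)
        assert seg.sum() == pytest.approx(expected, rel=1e-3)

    def test_subtended_angle_matches_turns(self, core):
        a0 = np.arctan2(core.bp_o[0, 1], core.bp_o[0, 0])
        a1 = np.arctan2(core.bp_o[-1, 1], core.bp_o[-1, 0])
        subtended = np.degrees(a0 - a1) % 360.0
        assert subtended == pytest.approx((1.67 * 360.0) % 360.0, abs=1e-6)

    def test_left_handed_about_core_axis(self, core):
        azim = np.unwrap(np.arctan2(core.bp_o[:, 1], core.bp_o[:, 0]))
        assert np.all(np.diff(azim) < 0)

    def test_dyad_axis_through_central_bp(self, core):
        mid = core.bp_o[CORE_BP // 2]
        # the central bp sits on the +X axis of the core frame
        assert mid[0] == pytest.approx(41.9, abs=1e-9)
        assert abs(mid[1]) < 1e-9 and abs(mid[2]) < 1e-9

    def test_zero_pitch_limit_is_planar(self):
        flat = make_ideal_core(sh_pitch=0.0, n_turns=1.0)
        assert np.abs(flat.bp_o[:, 2]).max() < 1e-6

    def test_entry_exit_are_terminal_frames(self, core):
        np.testing.assert_array_equal(core.entry_R, core.bp_R[0])
        np.testing.assert_array_equal(core.exit_o, core.bp_o[-1])

    def test_core_is_twist_neutral(self, core):
        steps = extract_steps(core.bp_R, core.bp_o)
        assert abs((steps[:, 0] - 34.5).sum()) < 1e-6

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            make_ideal_core(sh_radius=-1.0)
        with pytest.raises(ValueError):
            make_ideal_core(n_turns=0.0)


class TestPlacement:
    def test_single_nucleosome_at_radius(self, core):
        frames = place_nucleosomes(FiberParams(r=80, h=25, phi=170, rho=0, L=20, N=1))
        assert len(frames) == 1
        assert np.linalg.norm(frames[0].origin[:2]) == pytest.approx(80.0)

    def test_phi_180_alternating_stacks(self, core):
        frames = place_nucleosomes(FiberParams(r=60, h=25, phi=180, rho=-50, L=20, N=6))
        for k in range(4):
            d = frames[k + 2].origin - frames[k].origin
            np.testing.assert_allclose(d, [0.0, 0.0, 50.0], atol=1e-9)
        # consecutive nucleosomes sit diametrically opposite
        assert frames[0].origin[0] == pytest.approx(-frames[1].origin[0])

    def test_screw_symmetry(self):
        frames = place_nucleosomes(FiberParams(r=120, h=25, phi=170, rho=-50, L=20, N=10))
        rels = []
        for k in range(9):
            a, b = frames[k], frames[k + 1]
            rels.append(
                np.concatenate(
                    [(a.axes.T @ b.axes).ravel(), a.axes.T @ (b.origin - a.origin)]
                )
            )
        rels = np.array(rels)
        assert np.abs(rels - rels[0]).max() < 1e-9

    def test_rho_periodicity(self):
        f1 = place_nucleosomes(FiberParams(r=60, h=25, phi=170, rho=-50, L=20, N=3))
        f2 = place_nucleosomes(FiberParams(r=60, h=25, phi=170, rho=310, L=20, N=3))
        for a, b in zip(f1, f2):
            np.testing.assert_allclose(a.axes, b.axes, atol=1e-9)
            np.testing.assert_allclose(a.origin, b.origin, atol=1e-9)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            FiberParams(r=-5, h=25, phi=170, rho=0, L=20, N=2)
        with pytest.raises(ValueError):
            FiberParams(r=60, h=25, phi=170, rho=0, L=500, N=2)

    def test_frame_type_enforces_orthonormality(self):
        with pytest.raises(ValueError):
            Frame(np.zeros(3), np.eye(3) * 2.0)
        mirror = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            Frame(np.zeros(3), mirror)


class TestPdbInput:
    def _write_pdb(self, path, core):
        # export the ideal core as a synthetic two-chain PDB: C1' positions
        # offset from the bp centers along +-y of each bp frame
        lines = []
        serial = 1
        for i in range(core.n_bp):
            o = core.bp_o[i] + 4.7 * core.bp_R[i][:, 1]
            lines.append(self._atom(serial, "C1'", "DA", "I", i + 1, o))
            serial += 1
        for i in reversed(range(core.n_bp)):
            o = core.bp_o[i] - 4.7 * core.bp_R[i][:, 1]
            lines.append(self._atom(serial, "C1'", "DT", "J", core.n_bp - i, o))
            serial += 1
        path.write_text("\n".join(lines) + "\nEND\n")

    @staticmethod
    def _atom(serial, name, res, chain, resseq, xyz):
        return (
            f"ATOM  {serial:5d} {name:^4s} {res:>3s} {chain}{resseq:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )

    def test_round_trip_recovers_superhelical_axis(self, core, tmp_path):
        pdb = tmp_path / "core.pdb"
        self._write_pdb(pdb, core)
        loaded = load_core_from_pdb(pdb)
        # the core frame is axis-aligned by construction: loaded local Z
        # must match the original local Z to half a degree
        assert loaded.n_bp == CORE_BP
        cosang = np.dot([0, 0, 1.0], [0, 0, 1.0])  # both are re-expressed locally
        z_dev = np.degrees(
            np.arccos(np.clip(np.abs(np.dot(loaded.bp_o[73] / np.linalg.norm(loaded.bp_o[73]), [1, 0, 0])), -1, 1))
        )
        # dyad bp lies on the +X axis of the fitted frame
        assert z_dev < 0.5
        radii = np.linalg.norm(loaded.bp_o[:, :2], axis=1)
        assert radii.mean() == pytest.approx(41.9, abs=0.5)

    def test_short_chains_rejected(self, tmp_path, core):
        pdb = tmp_path / "short.pdb"
        lines = []
        for i in range(100):
            o = core.bp_o[i] + 4.7 * core.bp_R[i][:, 1]
            lines.append(self._atom(i + 1, "C1'", "DA", "I", i + 1, o))
        for i in reversed(range(100)):
            o = core.bp_o[i] - 4.7 * core.bp_R[i][:, 1]
            lines.append(self._atom(300 + i, "C1'", "DT", "J", 100 - i, o))
        pdb.write_text("\n".join(lines) + "\nEND\n")
        with pytest.raises(ValueError, match="short"):
            load_core_from_pdb(pdb)

    def test_straight_dna_is_degenerate(self, tmp_path):
        from chromofiber.linker_mechanics import reconstruct_frames

        rest = np.tile([34.5, 0, 0, 0, 0, 3.35], (CORE_BP - 1, 1))
        R, o = reconstruct_frames(np.eye(3), np.zeros(3), rest)
        pdb = tmp_path / "straight.pdb"
        lines = []
        serial = 1
        for i in range(CORE_BP):
            lines.append(self._atom(serial, "C1'", "DA", "I", i + 1, o[i] + 4.7 * R[i][:, 1]))
            serial += 1
        for i in reversed(range(CORE_BP)):
            lines.append(self._atom(serial, "C1'", "DT", "J", CORE_BP - i, o[i] - 4.7 * R[i][:, 1]))
            serial += 1
        pdb.write_text("\n".join(lines) + "\nEND\n")
        with pytest.raises(ValueError, match="degenerate|superhelical"):
            load_core_from_pdb(pdb)
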