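"""Dyad-map synthesis, occupancy profiles, peak calling, NRL estimation."""

import numpy as np
import pandas as pd
import pytest

from chromofiber.nrl_pipeline import (
    DOWN_PRESET,
    UP_PRESET,
    DyadMap,
    GeneSet,
    call_peaks,
    estimate_nrl,
    occupancy_profile,
    select_gene_groups,
    synthesize_dyad_map,
    synthesize_gene_set,
)


class TestGeneGroups:
    def test_quartile_sizes_match(self):
        gs = synthesize_gene_set(3440, seed=3)
        up, down = select_gene_groups(gs)
        assert len(up) == len(down) == 860
        assert not set(up) & set(down)

    def test_rate_ranges_disjoint(self):
        gs = synthesize_gene_set(2000, seed=5)
        up, down = select_gene_groups(gs)
        rates = gs.table.set_index("gene")["rate"]
        assert rates[up].min() > rates[down].max()

    def test_uniform_rates_tie_break_deterministic(self):
        tbl = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(16)], "rate": 1.0, "length": 2000}
        )
        up1, down1 = select_gene_groups(GeneSet(tbl))
        up2, down2 = select_gene_groups(GeneSet(tbl.sample(frac=1, random_state=0)))
        assert up1 == up2 and down1 == down2

    def test_too_few_genes_rejected(self):
        tbl = pd.DataFrame({"gene": ["a", "b"], "rate": [1, 2], "length": [2000, 2000]})
        with pytest.raises(ValueError, match="at least 8"):
            select_gene_groups(GeneSet(tbl))


class TestOccupancyProfile:
    def test_single_dyad_unsmoothed(self):
        dm = DyadMap(pd.DataFrame({"gene": ["g"], "pos": [100], "fragment_length": [150]}))
        pos, prof = occupancy_profile(dm, smooth=0)
        assert prof[pos == 100] == pytest.approx(1.0)
        assert prof.sum() == pytest.approx(1.0)

    def test_box_smoothing_of_delta(self):
        dm = DyadMap(pd.DataFrame({"gene": ["g"], "pos": [100], "fragment_length": [150]}))
        pos, prof = occupancy_profile(dm)
        plateau = prof[(pos >= 75) & (pos <= 125)]
        np.testing.assert_allclose(plateau, 1.0 / 51, atol=1e-12)

    def test_normalization_by_group_size(self):
        dm = synthesize_dyad_map(n_genes=100, seed=0)
        pos, prof = occupancy_profile(dm, smooth=0, frag_filter=None)
        in_window = dm.records["pos"].between(-200, 1000).sum()
        assert prof.sum() == pytest.approx(in_window / 100)

    def test_smoothing_conserves_mass_away_from_edges(self):
        dm = synthesize_dyad_map(n_genes=50, seed=1)
        pos, raw = occupancy_profile(dm, smooth=0)
        _, smooth = occupancy_profile(dm)
        sel = (pos > -150) & (pos < 950)
        assert smooth[sel].sum() == pytest.approx(raw[sel].sum(), rel=0.02)

    def test_fragment_filter_applies(self):
        df = pd.DataFrame(
            {"gene": ["g", "g"], "pos": [100, 200], "fragment_length": [150, 200]}
        )
        pos, prof = occupancy_profile(DyadMap(df), smooth=0)
        assert prof[pos == 100] == 1.0
        assert prof[pos == 200] == 0.0

    def test_empty_group_rejected(self):
        dm = synthesize_dyad_map(n_genes=5, seed=0)
        with pytest.raises(ValueError, match="empty"):
            occupancy_profile(dm, group=[])


class TestPeaksAndNrl:
    def test_cosine_peaks_at_period_multiples(self):
        pos = np.arange(-200, 1001)
        prof = 1.0 + np.cos(2 * np.pi * pos / 165.0)
        peaks = call_peaks(pos, prof)
        expected = [0, 165, 330, 495, 660, 825, 990]
        kept = [p for p in expected if -160 <= p <= 960]
        assert len(peaks) == len(kept)
        assert np.abs(peaks - np.array(kept)).max() <= 1

    def test_merged_peaks_report_once(self):
        # two maxima 30 bp apart fall inside one +-40 bp window and are
        # reported as a single peak; a distant third peak stays separate
        pos = np.arange(0, 600)
        prof = (
            np.exp(-0.5 * ((pos - 180) / 12.0) ** 2)
            + 0.95 * np.exp(-0.5 * ((pos - 210) / 12.0) ** 2)
            + np.exp(-0.5 * ((pos - 450) / 12.0) ** 2)
        )
        peaks = call_peaks(pos, prof)
        assert len(peaks) == 2
        assert abs(peaks[1] - 450) <= 1

    def test_generator_ground_truth_peak_count(self):
        dm = synthesize_dyad_map(n_genes=860, nrl=167, n_nucleosomes=5, seed=4)
        pos, prof = occupancy_profile(dm)
        peaks = call_peaks(pos, prof)
        assert len(peaks) == 5

    def test_exact_arithmetic(self):
        est = estimate_nrl([100, 265, 430, 595])
        assert est.nrl_mean == pytest.approx(165.0)
        assert est.nrl_sd == pytest.approx(0.0)

    def test_hand_computed_spacings(self):
        est = estimate_nrl([100, 261, 428, 590])
        assert est.nrl_mean == pytest.approx(163.333, abs=1e-3)
        assert est.nrl_sd == pytest.approx(np.std([161, 167, 162], ddof=1))

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError, match="3 peaks"):
            estimate_nrl([100, 265])


class TestGenerator:
    def test_zero_phase_noise_gives_exact_ladder_positions(self):
        # without phase noise every dyad sits exactly on the common ladder
        # (Poisson read thinning may drop rungs, never displace them)
        dm = synthesize_dyad_map(n_genes=5, phase_sd=0.0, seed=6)
        ladder = {60 + k * 165 for k in range(7)}
        assert set(dm.records["pos"]) <= ladder

    def test_nrl_difference_moves_distal_peaks(self):
        a = synthesize_dyad_map(n_genes=3, nrl=167, phase_sd=0.0, seed=7)
        b = synthesize_dyad_map(n_genes=3, nrl=161, phase_sd=0.0, seed=7)
        pa = sorted(set(a.records["pos"]))
        pb = sorted(set(b.records["pos"]))
        for k, (x, y) in enumerate(zip(pa, pb)):
            assert x - y == 6 * k

    def test_determinism(self):
        a = synthesize_dyad_map(n_genes=20, seed=9)
        b = synthesize_dyad_map(n_genes=20, seed=9)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_distal_peaks_broaden(self):
        dm = synthesize_dyad_map(n_genes=860, nrl=165, seed=10)
        rec = dm.records
        sd_first = rec[rec["pos"].between(20, 110)]["pos"].std()
        sd_fifth = rec[rec["pos"].between(20 + 4 * 165, 110 + 4 * 165)]["pos"].std()
        assert sd_fifth > sd_first

    def test_bed_round_trip(self, tmp_path):
        dm = synthesize_dyad_map(n_genes=10, seed=11)
        path = tmp_path / "dyads.bed"
        dm.to_bed(path)
        back = DyadMap.from_bed(path)
        pd.testing.assert_frame_equal(
            back.records.reset_index(drop=True),
            dm.records.reset_index(drop=True),
            check_dtype=False,
        )


class TestParameterRecovery:
    @pytest.mark.parametrize("nrl", [157, 161, 167, 172])
    def test_recovery_within_1p5_bp(self, nrl):
        errs = []
        for seed in range(3):
            dm = synthesize_dyad_map(n_genes=860, nrl=nrl, seed=seed)
            pos, prof = occupancy_profile(dm)
            est = estimate_nrl(call_peaks(pos, prof))
            errs.append(abs(est.nrl_mean - nrl))
        assert max(errs) <= 1.5

    def test_down_maps_have_higher_peaks(self):
        up = synthesize_dyad_map(n_genes=860, seed=12, **UP_PRESET)
        down = synthesize_dyad_map(n_genes=860, seed=12, **DOWN_PRESET)
        _, p_up = occupancy_profile(up)
        _, p_down = occupancy_profile(down)
        assert p_down.max() > p_up.max()
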