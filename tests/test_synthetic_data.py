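"""Generator contracts: determinism, conservation, calibration, round trips."""

import numpy as np
import pandas as pd
import pytest

from asbscan import io as aio
from asbscan.ld_annotator import compute_r2
from asbscan.region_filters import pad_and_merge
from asbscan.synthetic_data import (
    GALNT2_GWAS_ENTRIES,
    SimulationConfig,
    generate_exclusion_tracks,
    generate_gwas_catalog,
    generate_haplotype_panel,
    generate_reference,
    plant_het_snps,
    simulate_reads,
)


class TestGenerateReference:
    def test_length_and_alphabet(self):
        seq = generate_reference(10, seed=1)
        assert len(seq) == 10 and set(seq) <= set("ACGT")

    def test_single_base(self):
        assert generate_reference(1, seed=7) in "ACGT"

    def test_deterministic(self):
        assert generate_reference(500, seed=3) == generate_reference(500, seed=3)
        assert generate_reference(500, seed=3) != generate_reference(500, seed=4)

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            generate_reference(0, seed=1)


class TestPlantHetSnps:
    def test_empty(self):
        assert plant_het_snps("ACGT" * 25, 0, seed=1) == []

    def test_ref_alleles_match_reference(self):
        ref = generate_reference(5000, seed=2)
        snps = plant_het_snps(ref, 5, seed=3)
        assert len(snps) == 5
        for s in snps:
            assert ref[s.position - 1] == s.ref_allele
            assert s.alt_allele != s.ref_allele

    def test_positions_increasing_spaced_no_collisions(self):
        ref = generate_reference(200_000, seed=5)
        positions = [s.position for s in plant_het_snps(ref, 1000, seed=6, read_length=36)]
        assert len(set(positions)) == 1000
        diffs = np.diff(positions)
        assert (diffs > 0).all() and (diffs >= 36).all()

    def test_margin_from_contig_ends(self):
        ref = generate_reference(1000, seed=8)
        for s in plant_het_snps(ref, 5, seed=8, read_length=50):
            assert 50 <= s.position - 1 <= len(ref) - 50

    def test_too_many_rejected(self):
        with pytest.raises(ValueError):
            plant_het_snps("A" * 200, 100, seed=1, read_length=36)


class TestSimulateReads:
    def test_mean_depth_zero_is_empty(self):
        ref = generate_reference(1000, seed=1)
        snps = plant_het_snps(ref, 3, seed=1)
        cfg = SimulationConfig(1000, 3, mean_depth=0, seed=1)
        reads, truth = simulate_reads(cfg, ref, snps)
        assert reads == []
        assert (truth.sites[["true_g1", "true_g2"]].to_numpy() == 0).all()

    def test_unknown_imbalance_id_rejected(self):
        ref = generate_reference(1000, seed=1)
        snps = plant_het_snps(ref, 3, seed=1)
        cfg = SimulationConfig(1000, 3, imbalance_map={"nope": 0.7}, seed=1)
        with pytest.raises(KeyError):
            simulate_reads(cfg, ref, snps)

    def test_degenerate_imbalance_rejected(self):
        # imbalance must be strictly inside (0, 1)
        cfg = SimulationConfig(1000, 1, imbalance_map={"snp00000": 1.0}, seed=1)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_conservation_truth_counts_sum_to_reads(self, small_dataset):
        truth, reads = small_dataset["truth"], small_dataset["reads"]
        per_site = pd.Series([r.origin_snp for r in reads]).value_counts()
        for row in truth.sites.itertuples():
            assert row.true_g1 + row.true_g2 == per_site.get(row.snp_id, 0)

    def test_balanced_site_ratio_within_3_se(self):
        # law-of-large-numbers calibration at depth 10 000, error-free
        ref = generate_reference(2000, seed=21)
        snps = plant_het_snps(ref, 1, seed=21)
        cfg = SimulationConfig(2000, 1, mean_depth=10_000, error_rate=0.0, seed=21)
        _, truth = simulate_reads(cfg, ref, snps)
        row = truth.sites.iloc[0]
        n = row.true_g1 + row.true_g2
        se = np.sqrt(0.25 / n)
        assert abs(row.true_g1 / n - 0.5) <= 3 * se

    def test_byte_identical_outputs_for_same_seed(self):
        ref = generate_reference(5000, seed=4)
        snps = plant_het_snps(ref, 10, seed=4)
        cfg = SimulationConfig(5000, 10, error_rate=0.01, seed=4)
        reads_a, truth_a = simulate_reads(cfg, ref, snps)
        reads_b, truth_b = simulate_reads(cfg, ref, snps)
        assert [(r.name, r.seq, r.start, r.reverse) for r in reads_a] == [
            (r.name, r.seq, r.start, r.reverse) for r in reads_b
        ]
        pd.testing.assert_frame_equal(truth_a.sites, truth_b.sites)


class TestExclusionTracks:
    def _snps(self, n=100):
        ref = generate_reference(200_000, seed=31)
        return plant_het_snps(ref, n, seed=31), 200_000

    def test_fraction_zero_all_empty(self):
        snps, L = self._snps()
        tracks = generate_exclusion_tracks(snps, 0.0, seed=1, contig_length=L)
        assert all(not t.intervals for t in tracks.values())

    def test_fraction_one_masks_every_snp(self):
        snps, L = self._snps()
        from asbscan.synthetic_data import TruthTable

        truth = TruthTable(sites=pd.DataFrame({"snp_id": [s.snp_id for s in snps]}))
        generate_exclusion_tracks(snps, 1.0, seed=1, contig_length=L, truth=truth)
        assert truth.sites["masked"].all()

    def test_truth_flags_match_brute_force(self):
        snps, L = self._snps()
        from asbscan.synthetic_data import TruthTable

        truth = TruthTable(sites=pd.DataFrame({"snp_id": [s.snp_id for s in snps]}))
        tracks = generate_exclusion_tracks(
            snps, 0.3, seed=2, contig_length=L, truth=truth
        )
        for label, track in tracks.items():
            merged = pad_and_merge(track)
            expected = [
                any(iv.start <= s.pos0 < iv.end and iv.contig == s.contig for iv in merged)
                for s in snps
            ]
            assert truth.sites[f"in_{label}"].tolist() == expected

    def test_bad_fraction_rejected(self):
        snps, L = self._snps(10)
        with pytest.raises(ValueError):
            generate_exclusion_tracks(snps, 1.5, seed=1, contig_length=L)


class TestHaplotypePanel:
    def test_target_one_is_exact_copy(self):
        panel, realized = generate_haplotype_panel("idx", [("p1", 1.0)], 100, seed=1)
        assert (panel["p1"] == panel["idx"]).all()
        assert realized.realized_r2.iloc[0] == 1.0

    def test_target_zero_near_independent(self):
        _, realized = generate_haplotype_panel("idx", [("p1", 0.0)], 10_000, seed=2)
        assert realized.realized_r2.iloc[0] < 0.01

    def test_target_09_calibrated(self):
        _, realized = generate_haplotype_panel("idx", [("p1", 0.9)], 10_000, seed=3)
        assert abs(realized.realized_r2.iloc[0] - 0.9) <= 0.05

    def test_realized_matches_ld_module_exactly(self):
        panel, realized = generate_haplotype_panel(
            "idx", [("a", 0.5), ("b", 0.8)], 500, seed=4
        )
        for row in realized.itertuples():
            r2 = compute_r2(panel["idx"].to_numpy(), panel[row.partner_id].to_numpy())
            assert abs(r2 - row.realized_r2) < 1e-12

    @pytest.mark.parametrize("n", [10, 21])
    def test_odd_or_tiny_panel_rejected(self, n):
        with pytest.raises(ValueError):
            generate_haplotype_panel("idx", [("p1", 0.5)], n, seed=1)


class TestGwasCatalog:
    def test_empty(self):
        assert len(generate_gwas_catalog([])) == 0

    def test_galnt2_locus_entries(self):
        cat = generate_gwas_catalog(GALNT2_GWAS_ENTRIES)
        assert len(cat) == 4
        assert set(cat.snp_id) == {"rs2144300", "rs4846914", "rs10489615", "rs10127775"}
        assert set(cat.trait) == {"HDL-C, TG", "HDL-C", "Metabolite levels"}

    def test_duplicate_rejected(self):
        with pytest.raises(ValueError):
            generate_gwas_catalog([("rs1", "t", 5), ("rs1", "t", 9)])

    def test_round_trip(self, tmp_path):
        cat = generate_gwas_catalog(GALNT2_GWAS_ENTRIES)
        path = tmp_path / "cat.tsv"
        cat.to_csv(path, sep="\t", index=False)
        back = aio.read_gwas_catalog(path)
        assert [(g.gwas_snp_id, g.trait, g.position) for g in back] == [
            (s, t, p) for s, t, p in GALNT2_GWAS_ENTRIES
        ]
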