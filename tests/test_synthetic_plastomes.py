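"""Simulator: construction invariants, planting operations, determinism."""

import numpy as np
import pytest

from plastdiff.plastome_io import Feature, revcomp
from plastdiff.synthetic_plastomes import (
    SimConfig,
    SimulationError,
    TruthManifest,
    apply_manifest,
    fourfold_third_positions,
    plant_repeat_indel,
    plant_synonymous_snp,
    simulate_pair,
    small_config,
)

from conftest import random_dna


class TestConfig:
    def test_region_fractions_must_sum_to_one(self):
        with pytest.raises(SimulationError, match="fractions"):
            SimConfig(seed=0, lsc_frac=0.6, ssc_frac=0.2, ir_frac=0.2)

    def test_negative_counts_rejected(self):
        with pytest.raises(SimulationError):
            small_config(n_snp=-1)

    def test_slippage_within_indel_budget(self):
        with pytest.raises(SimulationError, match="budget"):
            small_config(n_indel=2, n_ssr_polymorphic=8, n_ssr_seeded=20,
                         n_ssr_polymorphic_ir_pairs=0, n_ssr_ir_pairs=0)


class TestSimulatePair:
    def test_no_mutations_means_identical_genomes(self):
        cfg = small_config(seed=5, n_snp=0, n_indel=0,
                           n_ssr_polymorphic=0, n_ssr_polymorphic_ir_pairs=0)
        genome_a, genome_b, manifest = simulate_pair(cfg)
        assert genome_a.seq == genome_b.seq
        assert manifest.events == []

    def test_identical_seed_bit_identical(self):
        a1, b1, m1 = simulate_pair(small_config(seed=7))
        a2, b2, m2 = simulate_pair(small_config(seed=7))
        assert a1.seq == a2.seq and b1.seq == b2.seq
        assert m1.event_keys() == m2.event_keys()

    def test_different_seed_differs(self):
        _, b1, _ = simulate_pair(small_config(seed=7))
        _, b2, _ = simulate_pair(small_config(seed=8))
        assert b1.seq != b2.seq

    def test_planted_counts_match_config(self, sim_small):
        cfg, _, _, manifest = sim_small
        assert manifest.n_snp == cfg.n_snp
        assert manifest.n_indel == cfg.n_indel
        assert manifest.n_polymorphic_ssr == cfg.n_ssr_polymorphic

    def test_ir_identity_holds_in_both_genomes(self, sim_small):
        _, genome_a, genome_b, _ = sim_small
        for g in (genome_a, genome_b):
            ira = g.fetch(*g.regions["IRa"])
            irb = g.fetch(*g.regions["IRb"])
            assert revcomp(irb) == ira

    def test_manifest_roundtrip_reproduces_genome_a(self, sim_small):
        _, genome_a, genome_b, manifest = sim_small
        assert apply_manifest(genome_b, manifest) == genome_a.seq

    def test_manifest_positions_valid_and_spaced(self, sim_small):
        cfg, _, genome_b, manifest = sim_small
        ivs = sorted((e.pos, e.pos + max(1, len(e.ref))) for e in manifest.events)
        assert ivs[0][0] >= 0 and ivs[-1][1] <= genome_b.length_bp
        for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
            assert s1 - e0 >= cfg.min_event_spacing

    def test_snp_alleles_match_reference(self, sim_small):
        _, _, genome_b, manifest = sim_small
        for ev in manifest.events:
            if ev.kind == "SNP":
                assert genome_b.seq[ev.pos] == ev.ref
                assert ev.alt != ev.ref
            elif ev.kind == "deletion":
                assert genome_b.seq[ev.pos : ev.pos + len(ev.ref)] == ev.ref

    def test_manifest_json_roundtrip(self, sim_small, tmp_path):
        _, _, _, manifest = sim_small
        manifest.to_json(tmp_path / "m.json")
        back = TruthManifest.from_json(tmp_path / "m.json")
        assert back.event_keys() == manifest.event_keys()
        assert len(back.ssrs) == len(manifest.ssrs)

    def test_output_files_readable_by_io_layer(self, tmp_path):
        from plastdiff.plastome_io import read_plastome

        cfg = small_config(seed=21)
        genome_a, genome_b, _ = simulate_pair(cfg, outdir=tmp_path)
        back = read_plastome(tmp_path / "genomeB.fasta", tmp_path / "genomeB.features.tsv")
        assert back.seq == genome_b.seq
        back_a = read_plastome(tmp_path / "genomeA.fasta", tmp_path / "genomeA.features.tsv")
        assert back_a.seq == genome_a.seq

    def test_study_scale_defaults(self):
        cfg = SimConfig(seed=0)
        assert cfg.genome_len == 160_000
        assert (cfg.n_snp, cfg.n_indel) == (75, 80)
        assert cfg.ts_fraction == 0.85
        assert cfg.coding_snp_mode == "synonymous_only"

    def test_infeasible_spacing_raises_helpful_error(self):
        with pytest.raises(SimulationError, match="place|spacing"):
            simulate_pair(small_config(seed=1, n_snp=400, n_indel=300))


class TestPlantingOps:
    def test_repeat_expansion_detected_by_association_test(self, rng):
        from plastdiff.mutation_scan import MutationEvent, repeat_association
        from conftest import make_plastome

        seq = random_dna(rng, 600)
        new, record = plant_repeat_indel(seq, 56, 300, kind="insertion")
        assert len(new) == len(seq) + 56
        ev = MutationEvent("insertion", "x", "intergenic_spacer", "LSC",
                           record.pos + 1, "", record.alt, 56)
        ok, _ = repeat_association(ev, make_plastome(seq))
        assert ok and record.repeat_associated

    def test_contraction_requires_tandem(self, rng):
        seq = random_dna(rng, 300)
        with pytest.raises(SimulationError, match="tandem"):
            plant_repeat_indel(seq, 20, 100, kind="deletion")
        tandem = seq[:100] + seq[100:120] + seq[100:120] + seq[140:]
        new, record = plant_repeat_indel(tandem, 20, 100, kind="deletion")
        assert len(new) == len(tandem) - 20
        assert record.kind == "deletion"

    def test_size_bounds_enforced(self, rng):
        with pytest.raises(SimulationError, match="size"):
            plant_repeat_indel(random_dna(rng, 200), 10, 100)

    def test_synonymous_snp_is_synonymous(self, rng):
        from plastdiff.coding_effects import classify_effect

        coding = "ATG" + "GCT" * 30 + "TAA"  # Ala codons: four-fold third sites
        cds = Feature("g", "CDS", "+", [(0, len(coding))])
        for _ in range(10):
            new, record = plant_synonymous_snp(coding, cds, rng)
            codon_start = (record.pos // 3) * 3
            effect, _ = classify_effect(
                coding[codon_start : codon_start + 3], new[codon_start : codon_start + 3]
            )
            assert effect == "synonymous"
            assert record.effect == "synonymous"

    def test_cds_without_fourfold_site_rejected(self, rng):
        cds = Feature("g", "CDS", "+", [(0, 6)])
        with pytest.raises(SimulationError, match="four-fold"):
            plant_synonymous_snp("ATGTAA", cds, rng)

    def test_fourfold_positions_minus_strand(self):
        coding = "ATGGCTTAA"  # GCT third position is four-fold
        genomic = revcomp(coding)
        cds = Feature("g", "CDS", "-", [(0, 9)])
        sites = fourfold_third_positions(genomic, cds)
        # coding offset 5 maps to genomic offset 9-1-5 = 3
        assert sites == [3]


class TestManifestAnnotations:
    def test_region_labels_match_reference_partition(self, sim_small):
        _, _, genome_b, manifest = sim_small
        for ev in manifest.events:
            assert ev.region_label == genome_b.region_of(ev.pos)

    def test_large_indels_marked_repeat_associated(self, sim_full):
        cfg, _, _, manifest = sim_full
        large = [e for e in manifest.events
                 if e.kind != "SNP" and max(len(e.ref), len(e.alt)) > 10]
        assert len(large) == cfg.n_large
        assert all(e.repeat_associated for e in large)

    def test_coding_snps_marked_synonymous(self, sim_small):
        _, _, _, manifest = sim_small
        coding = [e for e in manifest.events if e.effect != "NA"]
        assert coding
        assert all(e.effect == "synonymous" for e in coding)
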