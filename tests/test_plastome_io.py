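"""Genome model, annotation I/O, region detection and summaries."""

import pytest

from plastdiff.plastome_io import (
    Feature,
    Plastome,
    PlastomeError,
    compare_summaries,
    detect_inverted_repeats,
    read_plastome,
    revcomp,
    summarize,
    write_plastome,
)

from conftest import make_plastome, random_dna


class TestPlastomeModel:
    def test_region_tiling_enforced(self):
        with pytest.raises(PlastomeError, match="tile"):
            Plastome("x", "ACGT" * 100, {
                "LSC": (0, 100), "IRb": (120, 200), "SSC": (200, 300), "IRa": (300, 400),
            })

    def test_feature_out_of_bounds_names_feature(self):
        with pytest.raises(PlastomeError, match="rps16"):
            make_plastome("ACGT" * 25, [Feature("rps16", "gene", "+", [(90, 120)])])

    def test_invalid_bases_rejected(self):
        with pytest.raises(PlastomeError, match="invalid"):
            make_plastome("ACGTX" * 20)

    def test_ir_mismatch_count(self, rng):
        seq = random_dna(rng, 400)
        regions = {"LSC": (0, 150), "IRb": (150, 200), "SSC": (200, 350), "IRa": (350, 400)}
        seq = seq[:350] + revcomp(seq[150:200])  # make IRa the exact mirror of IRb
        p = Plastome("x", seq, regions)
        assert p.ir_mismatches == 0
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[360]]
        p2 = Plastome("x", seq[:360] + flip + seq[361:], regions)
        assert p2.ir_mismatches == 1

    def test_circular_fetch_wraps(self):
        p = make_plastome("ACGTACGTAA")
        assert p.fetch(8, 12) == "AAAC"


class TestRegionDetection:
    def test_auto_detects_planted_irs(self, rng):
        # standard layout LSC[0,200) IRb[200,250) SSC[250,350) IRa[350,400)
        seq = random_dna(rng, 400)
        irb = seq[200:250]
        seq = seq[:350] + revcomp(irb) + seq[400:]
        if seq[250] == revcomp(seq[349]):  # keep the planted repeat maximal
            seq = seq[:250] + ("A" if seq[250] != "A" else "C") + seq[251:]
        regions = detect_inverted_repeats(seq, min_len=40)
        assert regions["IRb"] == (200, 250)
        assert regions["IRa"] == (350, 400)
        assert regions["LSC"] == (0, 200)
        assert regions["SSC"] == (250, 350)

    def test_no_ir_found_rejected(self, rng):
        with pytest.raises(PlastomeError, match="no inverted repeat"):
            detect_inverted_repeats(random_dna(rng, 500), min_len=100)

    def test_auto_matches_simulator_truth(self, sim_small):
        _, _, genome_b, _ = sim_small
        det = detect_inverted_repeats(genome_b.seq, min_len=1500)
        assert det == genome_b.regions


class TestReadWrite:
    def test_round_trip_bit_exact(self, sim_small, tmp_path):
        _, _, genome_b, _ = sim_small
        write_plastome(genome_b, tmp_path / "g.fa", tmp_path / "g.tsv")
        back = read_plastome(tmp_path / "g.fa", tmp_path / "g.tsv")
        assert back.seq == genome_b.seq
        assert back.regions == genome_b.regions
        assert [(f.name, f.ftype, f.strand, f.exons) for f in back.features] == [
            (f.name, f.ftype, f.strand, f.exons) for f in genome_b.features
        ]

    def test_multi_record_fasta_rejected(self, tmp_path):
        (tmp_path / "two.fa").write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(PlastomeError, match="exactly one"):
            read_plastome(tmp_path / "two.fa")

    def test_annotation_out_of_bounds_names_feature(self, sim_small, tmp_path):
        _, _, genome_b, _ = sim_small
        write_plastome(genome_b, tmp_path / "g.fa", tmp_path / "g.tsv")
        tsv = (tmp_path / "g.tsv").read_text().rstrip("\n")
        tsv += f"\nbadgene\tgene\t+\t{genome_b.length_bp - 5}\t{genome_b.length_bp + 40}\t\n"
        (tmp_path / "g.tsv").write_text(tsv + "\n")
        with pytest.raises(PlastomeError, match="badgene"):
            read_plastome(tmp_path / "g.fa", tmp_path / "g.tsv")

    def test_genbank_annotation_dialect(self, tmp_path):
        gbk = """LOCUS       toy                       60 bp    DNA     circular PLN 01-JAN-2020
DEFINITION  toy record.
FEATURES             Location/Qualifiers
     gene            4..15
                     /gene="psbA"
     CDS             join(4..9,13..15)
                     /gene="psbA"
ORIGIN
        1 atgaaatggc ctaaacgtac gtacgtacgt acgtacgtac gtacgtaagc atgcatgcat
//
"""
        (tmp_path / "toy.gbk").write_text(gbk)
        (tmp_path / "toy.fa").write_text(">toy\n" + "ATGAAATGGCCTAAACGTACGTACGTACGTACGTACGTACGTACGTAAGCATGCATGCAT\n")
        p = read_plastome(
            tmp_path / "toy.fa", tmp_path / "toy.gbk",
            region_spec={"LSC": (0, 60), "IRb": (60, 60), "SSC": (60, 60), "IRa": (60, 60)},
        )
        cds = [f for f in p.features if f.ftype == "CDS"][0]
        assert cds.name == "psbA"
        assert cds.exons == [(3, 9), (12, 15)]
        assert cds.has_introns


class TestSummaries:
    def test_gc_and_coding_percent(self):
        p = make_plastome(
            "ACGT" * 25,
            [Feature("g1", "CDS", "+", [(0, 30)]), Feature("g1", "gene", "+", [(0, 30)])],
        )
        s = summarize(p)
        assert s.gc_percent == 50.00
        assert s.coding_percent == 30.00

    def test_duplicate_gene_names_collapse_in_unique_count(self, rng):
        feats = [
            Feature("dup", "gene", "+", [(10, 40)]),
            Feature("dup", "gene", "-", [(60, 90)]),
            Feature("solo", "gene", "+", [(110, 140)]),
        ]
        p = make_plastome(random_dna(rng, 200), feats)
        s = summarize(p)
        assert s.n_genes == 3
        assert s.n_genes_unique == 2

    def test_n_bases_counted_in_length_only(self):
        p = make_plastome("GGCCNNNN" + "AT" * 6)
        s = summarize(p)
        assert s.gc_percent == round(4 / 20 * 100, 2)

    def test_rotation_invariance_of_percentages(self, rng):
        seq = random_dna(rng, 300)
        feats = [Feature("g", "CDS", "+", [(50, 110)])]
        s1 = summarize(make_plastome(seq, feats))
        k = 37  # rotate genome and feature identically
        seq2 = seq[k:] + seq[:k]
        feats2 = [Feature("g", "CDS", "+", [(50 - k, 110 - k)])]
        s2 = summarize(make_plastome(seq2, feats2))
        assert s1.gc_percent == s2.gc_percent
        assert s1.coding_percent == s2.coding_percent

    def test_compare_summaries_deltas_brute_force(self, sim_small):
        _, genome_a, genome_b, _ = sim_small
        sa, sb = summarize(genome_a), summarize(genome_b)
        table = compare_summaries(sa, sb)
        assert (table.loc[table["item"] == "Genome size (bp)", "delta"].iloc[0]
                == genome_a.length_bp - genome_b.length_bp)
        for _, row in table.iterrows():
            assert row["delta"] == pytest.approx(row[sa.genome_id] - row[sb.genome_id])

    def test_identical_genomes_zero_deltas(self, sim_small):
        _, _, genome_b, _ = sim_small
        s = summarize(genome_b)
        table = compare_summaries(s, s)
        assert (table["delta"] == 0).all()
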