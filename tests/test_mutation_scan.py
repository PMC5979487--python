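"""Event calling, ts/tv classification, repeat association, tabulation."""

import itertools

import pytest

from plastdiff.aligner import PairwiseAlignment, global_align, left_normalize_indels
from plastdiff.locus_catalog import LocusPair
from plastdiff.mutation_scan import (
    EventError,
    MutationEvent,
    call_events,
    classify_ts_tv,
    events_table,
    is_tandem_array,
    large_indel_table,
    repeat_association,
    tabulate_events,
    write_vcf,
)

from conftest import make_plastome, random_dna

PUR = {"A", "G"}


def pair_for(seq_a, seq_b, name="locus", category="gene", region="LSC", offset=0):
    return LocusPair(name, category, region, seq_a, seq_b,
                     (offset, offset + len(seq_a)), (offset, offset + len(seq_b)))


def events_for(seq_a, seq_b, **kw):
    aln = left_normalize_indels(global_align(seq_a, seq_b))
    return call_events(aln, pair_for(seq_a, seq_b, **kw))


class TestCallEvents:
    def test_identical_sequences_no_events(self):
        assert events_for("ACGTACGTAC", "ACGTACGTAC") == []

    def test_single_snp(self):
        evs = events_for("ACGAT", "ACGTT")
        assert len(evs) == 1
        ev = evs[0]
        assert (ev.kind, ev.pos_ref, ev.ref_allele, ev.alt_allele) == ("SNP", 4, "T", "A")
        assert ev.ts_tv == "transversion"

    def test_insertion_event_single_run(self):
        aln = PairwiseAlignment("ACTTGT", "AC--GT", 0.0)
        evs = call_events(aln, pair_for("ACTTGT", "ACGT"))
        assert len(evs) == 1
        ev = evs[0]
        assert (ev.kind, ev.size_bp, ev.alt_allele, ev.pos_ref) == ("insertion", 2, "TT", 3)

    def test_deletion_event_single_run(self):
        aln = PairwiseAlignment("AC--GT", "ACTTGT", 0.0)
        evs = call_events(aln, pair_for("ACGT", "ACTTGT"))
        assert len(evs) == 1
        ev = evs[0]
        assert (ev.kind, ev.size_bp, ev.ref_allele, ev.pos_ref) == ("deletion", 2, "TT", 3)

    def test_long_gap_is_one_event(self, rng):
        b = random_dna(rng, 200)
        a = b[:80] + b[124:]  # remove 44 bp
        evs = events_for(a, b)
        assert len(evs) == 1
        assert evs[0].kind == "deletion"
        assert evs[0].size_bp == 44

    def test_unnormalized_alignment_rejected(self):
        aln = PairwiseAlignment("AAA-A", "AAAAA", 0.0)  # shiftable gap
        with pytest.raises(EventError, match="normalized"):
            call_events(aln, pair_for("AAAA", "AAAAA"))

    def test_n_columns_excluded_from_snp_calling(self):
        aln = PairwiseAlignment("ANGT", "ACGT", 0.0)
        assert call_events(aln, pair_for("ANGT", "ACGT")) == []

    def test_reference_offset_applied(self):
        evs = events_for("ACGAT", "ACGTT", offset=1000)
        assert evs[0].pos_ref == 1004

    def test_recovery_matches_manifest_exactly(self, sim_small, sim_small_report):
        """On simulated data the called event set equals the planted truth."""
        _, _, _, manifest = sim_small
        called = {e.key() for e in sim_small_report.events}
        assert called == manifest.event_keys()


class TestTsTv:
    def test_exhaustive_twelve_pairs_match_definition(self):
        """Enumerated oracle: transition iff both alleles share a purine or
        pyrimidine class."""
        for ref, alt in itertools.permutations("ACGT", 2):
            expected = (
                "transition"
                if ({ref, alt} <= PUR or {ref, alt} <= {"C", "T"})
                else "transversion"
            )
            assert classify_ts_tv(ref, alt) == expected

    @pytest.mark.parametrize("bad", [("A", "A"), ("N", "A"), ("A", "N")])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(EventError):
            classify_ts_tv(*bad)


class TestRepeatAssociation:
    def make_event(self, kind, pos1, allele):
        ref = allele if kind == "deletion" else ""
        alt = allele if kind == "insertion" else ""
        return MutationEvent(kind, "x", "intergenic_spacer", "LSC",
                             pos1, ref, alt, len(allele))

    def test_internal_tandem_always_true(self, rng):
        genome = make_plastome(random_dna(rng, 500))
        ev = self.make_event("insertion", 250, "AT" * 8)
        ok, evidence = repeat_association(ev, genome)
        assert ok and evidence["rule"] == "internal_tandem"

    def test_flank_duplication_detected(self, rng):
        seq = random_dna(rng, 600)
        block = seq[300:356]  # the insertion duplicates its 56-bp left flank
        genome = make_plastome(seq)
        ev = self.make_event("insertion", 357, block)
        ok, evidence = repeat_association(ev, genome)
        assert ok and evidence["rule"] == "flank_match"

    def test_deleted_tandem_unit_detected(self, rng):
        seq = random_dna(rng, 600)
        seq = seq[:300] + seq[300:340] + seq[300:340] + seq[380:]
        genome = make_plastome(seq)
        ev = self.make_event("deletion", 341, seq[340:380])
        ok, _ = repeat_association(ev, genome)
        assert ok

    def test_random_insertions_rarely_associate(self, rng):
        """A random 20-mer with no planted copy almost never matches."""
        false_positives = 0
        n = 1000
        for _ in range(n):
            genome = make_plastome(random_dna(rng, 400))
            allele = random_dna(rng, 20)
            if is_tandem_array(allele):
                continue
            ok, _ = repeat_association(self.make_event("insertion", 200, allele), genome)
            false_positives += int(ok)
        assert false_positives / n < 0.05

    def test_small_indel_rejected(self, rng):
        genome = make_plastome(random_dna(rng, 100))
        with pytest.raises(EventError, match="larger than 10"):
            repeat_association(self.make_event("insertion", 50, "ACGTACGT"), genome)

    def test_snp_rejected(self, rng):
        genome = make_plastome(random_dna(rng, 100))
        ev = MutationEvent("SNP", "x", "gene", "LSC", 10, "A", "G", 1, "transition")
        with pytest.raises(EventError, match="indel"):
            repeat_association(ev, genome)


class TestTabulation:
    def test_empty_event_list_all_zero(self):
        region, category = tabulate_events([])
        assert (region[["SNP", "indel"]].to_numpy() == 0).all()
        assert (category[["SNP", "indel"]].to_numpy() == 0).all()

    def test_planted_counts_land_in_cells(self):
        evs = [
            MutationEvent("SNP", "g", "gene", "LSC", i * 30, "A", "G", 1, "transition")
            for i in range(10)
        ] + [
            MutationEvent("deletion", "s", "intergenic_spacer", "SSC", 1000 + i * 40, "ACG", "", 3)
            for i in range(5)
        ]
        region, category = tabulate_events(evs)
        assert region.loc["LSC", "SNP"] == 10
        assert region.loc["SSC", "indel"] == 5
        assert category.loc["gene", "SNP"] == 10
        assert category.loc["intergenic_spacer", "deletion"] == 5

    def test_marginals_equal_brute_force_recount(self, sim_small_report):
        events = sim_small_report.events
        region, category = tabulate_events(events)
        assert region["total"].sum() == len(events)
        assert category["total"].sum() == len(events)
        for label in ("LSC", "SSC", "IR"):
            assert region.loc[label, "SNP"] == sum(
                1 for e in events if e.kind == "SNP" and e.region_label == label
            )

    def test_large_indel_table_threshold(self, sim_small_report):
        table = large_indel_table(sim_small_report.events)
        assert (table["size_bp"] >= 11).all()
        assert table["start_position"].is_monotonic_increasing


class TestExports:
    def test_events_table_sorted_and_complete(self, sim_small_report):
        df = events_table(sim_small_report.events)
        assert len(df) == len(sim_small_report.events)
        assert df["pos_ref"].is_monotonic_increasing

    def test_vcf_round_trips_alleles(self, sim_small, sim_small_report, tmp_path):
        _, _, genome_b, _ = sim_small
        path = tmp_path / "events.vcf"
        write_vcf(sim_small_report.events, genome_b, path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == len(sim_small_report.events)
        for line in lines:
            chrom, pos, _, ref, alt = line.split("\t")[:5]
            assert chrom == genome_b.id
            # REF allele must match the reference sequence at POS
            p = int(pos) - 1
            assert genome_b.seq[p : p + len(ref)] == ref
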