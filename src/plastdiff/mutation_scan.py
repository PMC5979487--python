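"""Discrete mutational events from locus alignments.

Each mismatching non-N column is one SNP; each maximal gap run in either row
is one indel event regardless of length (a 44-bp gap counts as a single
event).  Coordinates are reported on the reference genome (by convention the
previously published genome, genome "B"), 1-based.  Large indels (> 10 bp)
can be tested for association with flanking or internal DNA repeats, the
signature of repeat expansion/contraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .aligner import PairwiseAlignment, is_left_normalized
from .locus_catalog import LocusPair
from .plastome_io import Plastome, revcomp

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

REGION_ORDER = ("LSC", "SSC", "IR")
CATEGORY_ORDER = ("gene", "intergenic_spacer", "intron")
KIND_ORDER = ("SNP", "insertion", "deletion")


class EventError(ValueError):
    pass


@dataclass
class MutationEvent:
    """One SNP or one indel event between the two genomes.

    ``pos_ref`` is 1-based on the reference genome: for SNPs and deletions
    the first affected reference base, for insertions the reference base
    before which the insertion occurs.  Indel alleles are the inserted or
    deleted run itself (no gap characters, no anchor base).
    """

    kind: str  # SNP | insertion | deletion
    locus_name: str
    category: str
    region_label: str
    pos_ref: int
    ref_allele: str
    alt_allele: str
    size_bp: int
    ts_tv: str = "NA"  # transition | transversion | NA
    repeat_associated: object = None  # True | False | None (= not assessed)

    def key(self) -> tuple:
        """Identity of the event for set comparison against a truth manifest."""
        return (self.kind, self.pos_ref, self.ref_allele, self.alt_allele)


def classify_ts_tv(ref: str, alt: str) -> str:
    """Transition (purine<->purine / pyrimidine<->pyrimidine) or transversion."""
    if ref not in "ACGT" or alt not in "ACGT":
        raise EventError(f"cannot classify substitution with non-ACGT allele: {ref}>{alt}")
    if ref == alt:
        raise EventError("ref and alt alleles are identical")
    both = {ref, alt}
    if both <= PURINES or both <= PYRIMIDINES:
        return "transition"
    return "transversion"


def call_events(
    aln: PairwiseAlignment,
    locus: LocusPair,
    ref_offset: int | None = None,
) -> list[MutationEvent]:
    """Convert a left-normalized locus alignment into mutation events.

    ``aln.aligned_a`` holds the query genome's copy, ``aln.aligned_b`` the
    reference copy; ``ref_offset`` is the 0-based start of the locus in the
    reference genome (defaults to the pair's own reference interval).
    Columns containing N are excluded from SNP calling.
    """
    if not is_left_normalized(aln):
        raise EventError("alignment must be left-normalized before event calling")
    if ref_offset is None:
        ref_offset = locus.interval_b[0]

    events: list[MutationEvent] = []
    a, b = aln.aligned_a, aln.aligned_b
    ncols = len(a)
    ref_pos = ref_offset  # 0-based position of the next reference base
    i = 0
    while i < ncols:
        ca, cb = a[i], b[i]
        if ca != "-" and cb != "-":
            if ca != cb and ca != "N" and cb != "N":
                events.append(
                    MutationEvent(
                        kind="SNP",
                        locus_name=locus.name,
                        category=locus.category,
                        region_label=locus.region_label,
                        pos_ref=ref_pos + 1,
                        ref_allele=cb,
                        alt_allele=ca,
                        size_bp=1,
                        ts_tv=classify_ts_tv(cb, ca),
                    )
                )
            ref_pos += 1
            i += 1
        elif ca == "-":
            # reference bases absent from the query: a deletion
            j = i
            while j < ncols and a[j] == "-":
                j += 1
            allele = b[i:j]
            events.append(
                MutationEvent(
                    kind="deletion",
                    locus_name=locus.name,
                    category=locus.category,
                    region_label=locus.region_label,
                    pos_ref=ref_pos + 1,
                    ref_allele=allele,
                    alt_allele="",
                    size_bp=len(allele),
                )
            )
            ref_pos += len(allele)
            i = j
        else:
            # query bases absent from the reference: an insertion before ref_pos
            j = i
            while j < ncols and b[j] == "-":
                j += 1
            allele = a[i:j]
            events.append(
                MutationEvent(
                    kind="insertion",
                    locus_name=locus.name,
                    category=locus.category,
                    region_label=locus.region_label,
                    pos_ref=ref_pos + 1,
                    ref_allele="",
                    alt_allele=allele,
                    size_bp=len(allele),
                )
            )
            i = j
    return events


# ---------------------------------------------------------------------------
# repeat association of large indels
# ---------------------------------------------------------------------------

def _smallest_period(s: str) -> int:
    """Smallest period of s via the KMP failure function."""
    n = len(s)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    return n - fail[-1] if n else 0


def is_tandem_array(allele: str) -> bool:
    """True when the allele is >= 2 exact copies of a unit <= half its length."""
    p = _smallest_period(allele)
    return p <= len(allele) // 2 and len(allele) % p == 0


def repeat_association(
    ev: MutationEvent,
    reference: Plastome,
    min_match: int = 10,
    window: int | None = None,
) -> tuple[bool, dict]:
    """Test whether a large indel is a repeat expansion or contraction.

    True when the indel allele (or its reverse complement) shares an exact
    match of length >= min(min_match, size) with the sequence flanking the
    event site within ``window`` bp (default max(100, 3*size)), or when the
    allele is itself a tandem repeat array.  Evidence reports the matching
    coordinates or the internal-tandem unit.
    """
    if ev.kind not in ("insertion", "deletion"):
        raise EventError("repeat_association applies to indel events only")
    allele = ev.alt_allele if ev.kind == "insertion" else ev.ref_allele
    size = len(allele)
    if size <= 10:
        raise EventError("repeat association is assessed for indels larger than 10 bp")
    if window is None:
        window = max(100, 3 * size)

    if is_tandem_array(allele):
        return True, {"rule": "internal_tandem", "unit": allele[: _smallest_period(allele)]}

    pos0 = ev.pos_ref - 1  # 0-based
    if ev.kind == "deletion":
        left = reference.fetch(max(0, pos0 - window), pos0)
        right = reference.fetch(pos0 + size, min(reference.length_bp, pos0 + size + window))
    else:
        left = reference.fetch(max(0, pos0 - window), pos0)
        right = reference.fetch(pos0, min(reference.length_bp, pos0 + window))
    flank = left + "|" + right  # separator prevents spurious cross-boundary matches

    m = min(min_match, size)
    for probe_name, probe in (("forward", allele), ("revcomp", revcomp(allele))):
        for i in range(0, size - m + 1):
            sub = probe[i : i + m]
            hit = flank.find(sub)
            if hit >= 0:
                return True, {
                    "rule": "flank_match",
                    "orientation": probe_name,
                    "match_len": m,
                    "allele_offset": i,
                    "flank_offset": hit,
                }
    return False, {"rule": "none"}


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------

def events_table(events: list[MutationEvent]) -> pd.DataFrame:
    """Events as a tidy table ordered by reference position."""
    rows = [
        {
            "kind": e.kind,
            "locus": e.locus_name,
            "category": e.category,
            "region": e.region_label,
            "pos_ref": e.pos_ref,
            "ref": e.ref_allele,
            "alt": e.alt_allele,
            "size_bp": e.size_bp,
            "ts_tv": e.ts_tv,
            "repeat_associated": e.repeat_associated,
        }
        for e in events
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "kind", "locus", "category", "region", "pos_ref", "ref", "alt",
            "size_bp", "ts_tv", "repeat_associated",
        ],
    )
    return df.sort_values(["pos_ref", "kind"], kind="stable").reset_index(drop=True)


def tabulate_events(events: list[MutationEvent]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region x kind and category x kind count tables (all cells present)."""
    def crosstab(attr: str, row_order) -> pd.DataFrame:
        tab = pd.DataFrame(0, index=list(row_order), columns=list(KIND_ORDER))
        for e in events:
            tab.loc[getattr(e, attr), e.kind] += 1
        tab["indel"] = tab["insertion"] + tab["deletion"]
        tab["total"] = tab["SNP"] + tab["indel"]
        return tab

    return crosstab("region_label", REGION_ORDER), crosstab("category", CATEGORY_ORDER)


def large_indel_table(events: list[MutationEvent], min_size: int = 11) -> pd.DataFrame:
    """Inventory of indels of at least ``min_size`` bp, ordered by position."""
    rows = [
        {
            "size_bp": e.size_bp,
            "start_position": e.pos_ref,
            "location": e.locus_name,
            "type": e.kind,
            "repeat_associated": e.repeat_associated,
        }
        for e in sorted(events, key=lambda e: e.pos_ref)
        if e.kind in ("insertion", "deletion") and e.size_bp >= min_size
    ]
    return pd.DataFrame(
        rows, columns=["size_bp", "start_position", "location", "type", "repeat_associated"]
    )


# ---------------------------------------------------------------------------
# VCF export
# ---------------------------------------------------------------------------

def write_vcf(events: list[MutationEvent], reference: Plastome, path) -> None:
    """Minimal VCF 4.2 export; indels carry the conventional anchor base."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={reference.id},length={reference.length_bp}>",
        '##INFO=<ID=LOCUS,Number=1,Type=String,Description="Containing locus">',
        '##INFO=<ID=KIND,Number=1,Type=String,Description="Event kind">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for e in sorted(events, key=lambda e: e.pos_ref):
        if e.kind == "SNP":
            pos, ref, alt = e.pos_ref, e.ref_allele, e.alt_allele
        elif e.kind == "deletion":
            pos = e.pos_ref - 1
            anchor = reference.seq[pos - 1] if pos >= 1 else "N"
            ref, alt = anchor + e.ref_allele, anchor
        else:
            pos = e.pos_ref - 1
            anchor = reference.seq[pos - 1] if pos >= 1 else "N"
            ref, alt = anchor, anchor + e.alt_allele
        info = f"LOCUS={e.locus_name.replace(' ', '_')};KIND={e.kind}"
        lines.append(f"{reference.id}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
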