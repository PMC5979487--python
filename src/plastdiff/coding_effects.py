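"""Synonymous/nonsynonymous classification of CDS-located SNPs.

SNPs falling in CDS exons are mapped onto the spliced, strand-oriented
coding sequence, the affected codon is substituted, and both codons are
translated with the plastid/bacterial genetic code (NCBI translation
table 11) to decide the effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .mutation_scan import MutationEvent
from .plastome_io import Feature, Plastome, revcomp

PLASTID_TABLE = 11
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class CodingError(ValueError):
    pass


@dataclass
class CodingSnpCall:
    """Effect call for one CDS-located SNP."""

    event: MutationEvent
    gene: str
    codon_index: int  # 1-based codon number in the coding sequence
    codon_pos: int  # 1, 2 or 3
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect: str  # synonymous | nonsynonymous
    nonsense: bool = False


def spliced_cds(genome: Plastome, cds: Feature) -> str:
    """Spliced coding sequence in reading orientation (minus-strand genes
    are reverse-complemented)."""
    seq = "".join(genome.seq[s:e] for s, e in cds.exons)
    return revcomp(seq) if cds.strand == "-" else seq


def _plus_offset_in_splice(cds: Feature, pos0: int) -> int:
    """Offset of genomic position ``pos0`` within the plus-strand splice."""
    off = 0
    for s, e in cds.exons:
        if s <= pos0 < e:
            return off + (pos0 - s)
        off += e - s
    raise CodingError(f"position {pos0 + 1} is not inside a CDS exon of {cds.name}")


def map_to_codon(ev: MutationEvent, cds: Feature, genome: Plastome) -> tuple[int, int, str]:
    """Locate a SNP on the codon grid of a CDS.

    Returns (codon_index, codon_pos, ref_codon), all in coding orientation.
    Rejects SNPs outside the CDS exons (including intron positions) and CDSs
    whose spliced length is not a multiple of 3.
    """
    if ev.kind != "SNP":
        raise CodingError("only SNP events map to codons")
    if cds.spliced_length % 3 != 0:
        raise CodingError(f"CDS {cds.name} spliced length {cds.spliced_length} is not a multiple of 3")
    pos0 = ev.pos_ref - 1
    plus_off = _plus_offset_in_splice(cds, pos0)
    splice = spliced_cds(genome, cds)
    g = len(splice) - 1 - plus_off if cds.strand == "-" else plus_off
    codon_index = g // 3 + 1
    codon_pos = g % 3 + 1
    ref_codon = splice[3 * (codon_index - 1) : 3 * codon_index]
    return codon_index, codon_pos, ref_codon


def translate_codon(codon: str, table: int = PLASTID_TABLE) -> str:
    if "N" in codon:
        raise CodingError(f"codon {codon!r} contains N")
    return str(Seq(codon).translate(table=table))


def classify_effect(
    ref_codon: str, alt_codon: str, table: int = PLASTID_TABLE
) -> tuple[str, bool]:
    """(effect, nonsense_flag) for a single-position codon change."""
    diffs = [i for i in range(3) if ref_codon[i] != alt_codon[i]]
    if len(diffs) != 1:
        raise CodingError("codons must differ at exactly one position")
    ref_aa = translate_codon(ref_codon, table)
    alt_aa = translate_codon(alt_codon, table)
    effect = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
    nonsense = alt_aa == "*" and ref_aa != "*"
    return effect, nonsense


def call_coding_snp(ev: MutationEvent, cds: Feature, genome: Plastome) -> CodingSnpCall:
    codon_index, codon_pos, ref_codon = map_to_codon(ev, cds, genome)
    ref_base, alt_base = ev.ref_allele, ev.alt_allele
    if cds.strand == "-":
        ref_base, alt_base = _COMPLEMENT[ref_base], _COMPLEMENT[alt_base]
    if ref_codon[codon_pos - 1] != ref_base:
        raise CodingError(
            f"reference allele {ev.ref_allele} does not match CDS {cds.name} "
            f"codon {codon_index} position {codon_pos}"
        )
    alt_codon = ref_codon[: codon_pos - 1] + alt_base + ref_codon[codon_pos:]
    effect, nonsense = classify_effect(ref_codon, alt_codon)
    return CodingSnpCall(
        event=ev,
        gene=cds.name,
        codon_index=codon_index,
        codon_pos=codon_pos,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=translate_codon(ref_codon),
        alt_aa=translate_codon(alt_codon),
        effect=effect,
        nonsense=nonsense,
    )


def cds_feature_at(genome: Plastome, pos0: int) -> Feature | None:
    """The CDS whose exons contain a 0-based position, if any."""
    for f in genome.features_of_type("CDS"):
        for s, e in f.exons:
            if s <= pos0 < e:
                return f
    return None


def annotate_coding_snps(
    events: list[MutationEvent], reference: Plastome
) -> list[CodingSnpCall]:
    """Classify every SNP that falls inside a CDS exon of the reference."""
    calls = []
    for ev in events:
        if ev.kind != "SNP":
            continue
        cds = cds_feature_at(reference, ev.pos_ref - 1)
        if cds is not None:
            calls.append(call_coding_snp(ev, cds, reference))
    return calls


def coding_calls_table(calls: list[CodingSnpCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "pos_ref": c.event.pos_ref,
                "codon_index": c.codon_index,
                "codon_pos": c.codon_pos,
                "ref_codon": c.ref_codon,
                "alt_codon": c.alt_codon,
                "ref_aa": c.ref_aa,
                "alt_aa": c.alt_aa,
                "effect": c.effect,
                "ts_tv": c.event.ts_tv,
                "nonsense": c.nonsense,
            }
            for c in sorted(calls, key=lambda c: c.event.pos_ref)
        ],
        columns=[
            "gene", "pos_ref", "codon_index", "codon_pos", "ref_codon", "alt_codon",
            "ref_aa", "alt_aa", "effect", "ts_tv", "nonsense",
        ],
    )
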