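"""Per-locus proportion-of-variation statistic and marker selection.

For each homologous locus the proportion of variation is
``(NS + ID) / L * 100`` where NS is the SNP count, ID the indel event count
and L the aligned length in columns (gap columns included).  Percentages are
rounded half-up to two decimals wherever they are printed.  Candidate
markers are loci in a PCR-friendly length window whose percentage exceeds a
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .aligner import PairwiseAlignment
from .mutation_scan import MutationEvent


class VariabilityError(ValueError):
    pass


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as used in printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def vc_percent(n_vc: int, aligned_length: int) -> float:
    """Proportion of variable characters, half-up rounded to 2 decimals."""
    if aligned_length <= 0:
        raise VariabilityError("aligned length must be positive")
    return round_half_up(n_vc / aligned_length * 100.0)


@dataclass
class VariabilityRecord:
    """Variability of one locus: aligned length, event counts, VC%."""

    locus_name: str
    category: str
    region_label: str
    L: int  # aligned length in columns
    NS: int  # SNP count
    ID: int  # indel event count
    position: int = 0  # reference start, for genome-order profiles

    @property
    def vc_count(self) -> int:
        return self.NS + self.ID

    @property
    def vc_percent(self) -> float:
        return vc_percent(self.vc_count, self.L)

    @property
    def vc_percent_raw(self) -> float:
        return self.vc_count / self.L * 100.0


def score_locus(
    aln: PairwiseAlignment,
    events: list[MutationEvent],
    locus_name: str,
    category: str,
    region_label: str,
    position: int = 0,
) -> VariabilityRecord:
    """Build the variability record of one aligned locus pair."""
    L = len(aln)
    if L == 0:
        raise VariabilityError(f"locus {locus_name!r}: empty alignment")
    ns = sum(1 for e in events if e.kind == "SNP")
    nid = sum(1 for e in events if e.kind in ("insertion", "deletion"))
    return VariabilityRecord(locus_name, category, region_label, L, ns, nid, position)


@dataclass
class MarkerSelection:
    """Ranked marker candidates passing the length and variability filter."""

    records: list[VariabilityRecord]
    min_len: int
    max_len: int
    min_vc_percent: float

    @property
    def n_selected(self) -> int:
        return len(self.records)


def rank_and_select(
    records: list[VariabilityRecord],
    min_len: int = 200,
    max_len: int = 1500,
    min_vc_percent: float = 0.25,
    n: int = 20,
) -> MarkerSelection:
    """Select up to ``n`` marker loci.

    Filters to min_len <= L <= max_len and vc_percent strictly greater than
    ``min_vc_percent``; ranks by vc_percent descending, ties broken by larger
    aligned length then by name.
    """
    eligible = [
        r for r in records if min_len <= r.L <= max_len and r.vc_percent > min_vc_percent
    ]
    eligible.sort(key=lambda r: (-r.vc_percent, -r.L, r.locus_name))
    return MarkerSelection(eligible[:n], min_len, max_len, min_vc_percent)


def variability_profile(records: list[VariabilityRecord]) -> tuple[pd.DataFrame, dict]:
    """Genome-ordered variability table plus summary statistics.

    The summary (min/max/mean VC%) is computed over polymorphic loci only
    (vc_count > 0); the mean averages unrounded proportions and rounds once.
    Band counts partition polymorphic loci at 0.10% and 1.00%.
    """
    ordered = sorted(records, key=lambda r: (r.position, r.locus_name))
    table = pd.DataFrame(
        {
            "locus": [r.locus_name for r in ordered],
            "category": [r.category for r in ordered],
            "region": [r.region_label for r in ordered],
            "position": [r.position + 1 for r in ordered],
            "aligned_length": [r.L for r in ordered],
            "n_snp": [r.NS for r in ordered],
            "n_indel": [r.ID for r in ordered],
            "n_vc": [r.vc_count for r in ordered],
            "vc_percent": [r.vc_percent for r in ordered],
        }
    )
    poly = [r for r in ordered if r.vc_count > 0]
    raw = [r.vc_percent_raw for r in poly]
    summary = {
        "n_loci": len(ordered),
        "n_polymorphic": len(poly),
        "min_vc_percent": round_half_up(min(raw)) if raw else 0.0,
        "max_vc_percent": round_half_up(max(raw)) if raw else 0.0,
        "mean_vc_percent": round_half_up(sum(raw) / len(raw)) if raw else 0.0,
        "band_below_010": sum(1 for r in poly if r.vc_percent < 0.10),
        "band_010_to_100": sum(1 for r in poly if 0.10 <= r.vc_percent <= 1.00),
        "band_above_100": sum(1 for r in poly if r.vc_percent > 1.00),
    }
    return table, summary


def selection_table(sel: MarkerSelection) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus": [r.locus_name for r in sel.records],
            "aligned_length": [r.L for r in sel.records],
            "n_vc": [r.vc_count for r in sel.records],
            "vc_percent": [r.vc_percent for r in sel.records],
        }
    )
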