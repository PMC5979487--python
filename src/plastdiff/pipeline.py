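"""End-to-end plastome comparison: from two annotated genomes to report tables.

``run_compare`` orchestrates the full analysis: genome summaries, synteny
check, locus pairing, per-locus global alignment, mutation-event calling,
coding-effect classification, repeat association of large indels, SSR
mining, and the variability/marker-selection tables.  ``run_validate``
scores a comparison run against a simulation truth manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .aligner import colinearity_check, global_align, left_normalize_indels
from .coding_effects import CodingSnpCall, annotate_coding_snps, coding_calls_table
from .locus_catalog import LocusPair, extract_loci, pair_loci
from .mutation_scan import (
    MutationEvent,
    events_table,
    large_indel_table,
    repeat_association,
    tabulate_events,
    write_vcf,
)
from .plastome_io import Plastome, compare_summaries, summarize
from .ssr_scan import (
    call_polymorphic,
    find_ssrs,
    match_ssrs,
    polymorphic_table,
    ssr_table,
)
from .variability import (
    VariabilityRecord,
    rank_and_select,
    score_locus,
    selection_table,
    variability_profile,
    round_half_up,
)

logger = logging.getLogger(__name__)

LARGE_INDEL_MIN_BP = 11


@dataclass
class CompareParams:
    """All analysis thresholds in one place (study defaults)."""

    align_params: tuple[float, float, float, float] = (2.0, -3.0, -5.0, -2.0)
    marker_min_len: int = 200
    marker_max_len: int = 1500
    marker_min_vc_percent: float = 0.25
    marker_n: int = 20
    ssr_thresholds: dict = field(
        default_factory=lambda: {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    )
    repeat_min_match: int = 10
    colinearity_k: int = 25


@dataclass
class CompareReport:
    """Everything one comparison run produces."""

    genome_a: Plastome
    genome_b: Plastome
    summary_table: pd.DataFrame
    colinear: bool
    events: list[MutationEvent]
    coding_calls: list[CodingSnpCall]
    records: list[VariabilityRecord]
    region_kind: pd.DataFrame
    category_kind: pd.DataFrame
    unmatched_loci: list
    ssrs_a: list
    ssrs_b: list
    ssr_pairs: list
    polymorphic_ssrs: list
    selection: object
    profile_table: pd.DataFrame
    profile_summary: dict
    totals: dict


def run_compare(
    genome_a: Plastome, genome_b: Plastome, params: CompareParams | None = None
) -> CompareReport:
    """Compare two annotated plastomes; genome B anchors the coordinates
    (the previously-published-reference role)."""
    params = params or CompareParams()
    t0 = time.perf_counter()

    sum_a, sum_b = summarize(genome_a), summarize(genome_b)
    summary_table = compare_summaries(sum_a, sum_b)

    colinear, _anchors = colinearity_check(genome_a, genome_b, k=params.colinearity_k)
    if not colinear:
        logger.warning("genomes are not colinear; locus pairing may be unreliable")

    loci_a = extract_loci(genome_a, include_introns=False)
    loci_b = extract_loci(genome_b, include_introns=False)
    pairs, unmatched = pair_loci(loci_a, genome_a, loci_b, genome_b)
    if unmatched:
        logger.warning("%d loci had no partner and were excluded", len(unmatched))

    events: list[MutationEvent] = []
    records: list[VariabilityRecord] = []
    for pair in pairs:
        aln = left_normalize_indels(
            global_align(pair.seq_a, pair.seq_b, params.align_params)
        )
        from .mutation_scan import call_events

        evs = call_events(aln, pair)
        # region labels by event position (more precise than the locus
        # midpoint for boundary-spanning spacers)
        for ev in evs:
            ev.region_label = genome_b.region_of(ev.pos_ref - 1)
        events.extend(evs)
        records.append(
            score_locus(aln, evs, pair.name, pair.category, pair.region_label,
                        position=pair.interval_b[0])
        )

    for ev in events:
        if ev.kind in ("insertion", "deletion") and ev.size_bp > 10:
            ev.repeat_associated, _ = repeat_association(
                ev, genome_b, min_match=params.repeat_min_match
            )

    coding_calls = annotate_coding_snps(events, genome_b)
    region_kind, category_kind = tabulate_events(events)

    ssrs_a = find_ssrs(genome_a, params.ssr_thresholds, loci=loci_a)
    ssrs_b = find_ssrs(genome_b, params.ssr_thresholds, loci=loci_b)
    ssr_pairs, unmatched_ssr_a, _unmatched_ssr_b = match_ssrs(ssrs_a, ssrs_b)
    polymorphic = call_polymorphic(ssr_pairs)

    selection = rank_and_select(
        records,
        min_len=params.marker_min_len,
        max_len=params.marker_max_len,
        min_vc_percent=params.marker_min_vc_percent,
        n=params.marker_n,
    )
    profile_table, profile_summary = variability_profile(records)

    n_snp = sum(1 for e in events if e.kind == "SNP")
    n_indel = len(events) - n_snp
    totals = {
        "genome_a_bp": genome_a.length_bp,
        "genome_b_bp": genome_b.length_bp,
        "size_difference_bp": genome_a.length_bp - genome_b.length_bp,
        "colinear": bool(colinear),
        "n_loci": len(pairs),
        "n_polymorphic_loci": sum(1 for r in records if r.vc_count > 0),
        "n_events": len(events),
        "n_snp": n_snp,
        "n_indel": n_indel,
        "n_insertion": sum(1 for e in events if e.kind == "insertion"),
        "n_deletion": sum(1 for e in events if e.kind == "deletion"),
        "n_large_indel": sum(
            1 for e in events if e.kind != "SNP" and e.size_bp >= LARGE_INDEL_MIN_BP
        ),
        "n_cds_snp": len(coding_calls),
        "n_cds_snp_synonymous": sum(1 for c in coding_calls if c.effect == "synonymous"),
        "n_cds_transition": sum(1 for c in coding_calls if c.event.ts_tv == "transition"),
        "n_cds_transversion": sum(1 for c in coding_calls if c.event.ts_tv == "transversion"),
        "snp_density_per_kb": round_half_up(n_snp / (genome_a.length_bp / 1000.0)),
        "n_ssr_a": len(ssrs_a),
        "n_ssr_b": len(ssrs_b),
        "n_ssr_shared": len(ssr_pairs),
        "n_ssr_polymorphic": len(polymorphic),
        "n_markers_selected": selection.n_selected,
        "mean_vc_percent": profile_summary["mean_vc_percent"],
    }
    logger.info("compare finished in %.2f s", time.perf_counter() - t0)
    return CompareReport(
        genome_a=genome_a,
        genome_b=genome_b,
        summary_table=summary_table,
        colinear=colinear,
        events=events,
        coding_calls=coding_calls,
        records=records,
        region_kind=region_kind,
        category_kind=category_kind,
        unmatched_loci=unmatched,
        ssrs_a=ssrs_a,
        ssrs_b=ssrs_b,
        ssr_pairs=ssr_pairs,
        polymorphic_ssrs=polymorphic,
        selection=selection,
        profile_table=profile_table,
        profile_summary=profile_summary,
        totals=totals,
    )


def write_report(report: CompareReport, outdir: Path | str) -> None:
    """Write the report bundle (TSVs, VCF, JSON totals) to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.summary_table.to_csv(out / "genome_summary.tsv", sep="\t", index=False)
    events_table(report.events).to_csv(out / "events.tsv", sep="\t", index=False)
    large_indel_table(report.events).to_csv(out / "large_indels.tsv", sep="\t", index=False)
    report.region_kind.to_csv(out / "events_by_region.tsv", sep="\t")
    report.category_kind.to_csv(out / "events_by_category.tsv", sep="\t")
    coding_calls_table(report.coding_calls).to_csv(out / "coding_snps.tsv", sep="\t", index=False)
    report.profile_table.to_csv(out / "variability.tsv", sep="\t", index=False)
    selection_table(report.selection).to_csv(out / "markers.tsv", sep="\t", index=False)
    ssr_table(report.ssrs_a).to_csv(out / "ssrs_a.tsv", sep="\t", index=False)
    ssr_table(report.ssrs_b).to_csv(out / "ssrs_b.tsv", sep="\t", index=False)
    polymorphic_table(report.polymorphic_ssrs).to_csv(
        out / "polymorphic_ssrs.tsv", sep="\t", index=False
    )
    write_vcf(report.events, report.genome_b, out / "events.vcf")
    (out / "totals.json").write_text(json.dumps(report.totals, indent=1))


# ---------------------------------------------------------------------------
# validation against a truth manifest
# ---------------------------------------------------------------------------

def run_validate(report: CompareReport, manifest) -> dict:
    """Precision/recall of event recovery and classification agreement
    against a simulation truth manifest."""
    truth = manifest.event_keys()
    called = {e.key() for e in report.events}
    tp = truth & called
    precision = len(tp) / len(called) if called else 1.0
    recall = len(tp) / len(truth) if truth else 1.0

    truth_by_key = {e.key(): e for e in manifest.events}
    n_checked = n_region_ok = n_locus_ok = 0
    n_ts_ok = n_ts = 0
    for ev in report.events:
        t = truth_by_key.get(ev.key())
        if t is None:
            continue
        n_checked += 1
        n_region_ok += int(ev.region_label == t.region_label)
        n_locus_ok += int(ev.locus_name == t.locus_name)
        if ev.kind == "SNP":
            n_ts += 1
            n_ts_ok += int(ev.ts_tv == t.ts_tv)

    effect_truth = {
        e.key(): e.effect for e in manifest.events if e.kind == "SNP" and e.effect != "NA"
    }
    n_eff = n_eff_ok = 0
    for call in report.coding_calls:
        t_eff = effect_truth.get(call.event.key())
        if t_eff is None:
            continue
        n_eff += 1
        n_eff_ok += int(call.effect == t_eff)

    n_poly_truth = manifest.n_polymorphic_ssr
    metrics = {
        "n_planted": len(truth),
        "n_called": len(called),
        "event_precision": precision,
        "event_recall": recall,
        "region_label_agreement": n_region_ok / n_checked if n_checked else 1.0,
        "locus_agreement": n_locus_ok / n_checked if n_checked else 1.0,
        "ts_tv_agreement": n_ts_ok / n_ts if n_ts else 1.0,
        "effect_agreement": n_eff_ok / n_eff if n_eff else 1.0,
        "n_coding_calls_checked": n_eff,
        "ssr_polymorphic_planted": n_poly_truth,
        "ssr_polymorphic_called": len(report.polymorphic_ssrs),
        "ssr_polymorphic_recovered": float(len(report.polymorphic_ssrs) == n_poly_truth),
    }
    metrics["all_perfect"] = all(
        metrics[k] == 1.0
        for k in (
            "event_precision", "event_recall", "region_label_agreement",
            "ts_tv_agreement", "effect_agreement", "ssr_polymorphic_recovered",
        )
    )
    return metrics
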