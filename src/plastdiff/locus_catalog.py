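"""Decompose plastomes into genic/intergenic loci and pair them across genomes.

Gene loci span the full gene (exons plus introns); intergenic spacers are the
maximal gaps between consecutive gene spans along the plus strand, named
"upstreamGene-downstreamGene"; intron loci are the gaps between consecutive
exons of one feature.  Loci falling inside the inverted repeat are analysed
once (the IRa copy) with region label "IR", so event totals count IR
mutations a single time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .plastome_io import Plastome

logger = logging.getLogger(__name__)

CATEGORIES = ("gene", "intergenic_spacer", "intron")


class CatalogError(ValueError):
    pass


@dataclass
class Locus:
    """One analysable fragment of a plastome (gene, spacer or intron)."""

    name: str
    category: str
    region_label: str  # LSC | SSC | IR
    interval: tuple[int, int]  # 0-based half-open; end may exceed L for the wrap spacer
    strand: str = "NA"

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class LocusPair:
    """Homologous locus with both genomes' sequences."""

    name: str
    category: str
    region_label: str
    seq_a: str
    seq_b: str
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]


def _region_label(p: Plastome, interval: tuple[int, int]) -> str:
    mid = (interval[0] + interval[1]) // 2 % p.length_bp
    return p.region_of(mid)


def _inside(iv: tuple[int, int], region: tuple[int, int]) -> bool:
    return region[0] <= iv[0] and iv[1] <= region[1]


def extract_loci(p: Plastome, include_introns: bool = True) -> list[Locus]:
    """Build the locus catalog of one plastome.

    Genes inside IRb are dropped (their IRa twins are kept); overlapping gene
    spans produce no spacer between them and are logged.  The spacer closing
    the circle (after the last gene, through the origin when the first gene
    does not start at 0) is emitted with an interval whose end may exceed the
    genome length; sequence access wraps.
    """
    genes = sorted(p.features_of_type("gene"), key=lambda f: f.span)
    if not genes:
        raise CatalogError("plastome has no gene features")
    irb = p.regions["IRb"]

    loci: list[Locus] = []
    kept = [g for g in genes if not _inside(g.span, irb)]
    for g in kept:
        loci.append(Locus(g.name, "gene", _region_label(p, g.span), g.span, g.strand))
        if include_introns and g.has_introns:
            for k, ((_, e0), (s1, _)) in enumerate(zip(g.exons, g.exons[1:]), start=1):
                if s1 > e0:
                    loci.append(
                        Locus(f"{g.name} intron {k}", "intron", _region_label(p, (e0, s1)), (e0, s1), g.strand)
                    )

    # spacers between consecutive gene spans (all genes, so IRb genes still
    # delimit spacers correctly); spacers inside IRb are then dropped
    for g0, g1 in zip(genes, genes[1:]):
        s, e = g0.span[1], g1.span[0]
        if e < s:
            logger.warning("gene spans overlap: %s and %s; no spacer emitted", g0.name, g1.name)
            continue
        if e == s:
            continue
        if _inside((s, e), irb):
            continue
        loci.append(Locus(f"{g0.name}-{g1.name}", "intergenic_spacer", _region_label(p, (s, e)), (s, e)))

    # wrap spacer: from the last gene end through the origin to the first gene
    last, first = genes[-1], genes[0]
    s = last.span[1]
    e = p.length_bp + first.span[0]
    if e > s and e - s < p.length_bp:
        loci.append(
            Locus(f"{last.name}-{first.name}", "intergenic_spacer", _region_label(p, (s, e)), (s, e))
        )
    return loci


def locus_sequence(p: Plastome, locus: Locus) -> str:
    return p.fetch(*locus.interval)


def pair_loci(
    loci_a: list[Locus],
    plastome_a: Plastome,
    loci_b: list[Locus],
    plastome_b: Plastome,
) -> tuple[list[LocusPair], list[Locus]]:
    """Match loci across genomes by (name, category).

    Returns the pairs plus the list of loci present in only one catalog;
    unmatched loci are reported, never silently dropped.  Duplicate
    (name, category) keys within one catalog are rejected.
    """
    def index(loci: list[Locus]) -> dict[tuple[str, str], Locus]:
        out: dict[tuple[str, str], Locus] = {}
        dups = []
        for lc in loci:
            key = (lc.name, lc.category)
            if key in out:
                dups.append(lc.name)
            out[key] = lc
        if dups:
            raise CatalogError(f"duplicate loci in catalog: {sorted(set(dups))}")
        return out

    ia, ib = index(loci_a), index(loci_b)
    pairs: list[LocusPair] = []
    unmatched: list[Locus] = []
    for key in ia:
        if key in ib:
            la, lb = ia[key], ib[key]
            pairs.append(
                LocusPair(
                    name=la.name,
                    category=la.category,
                    region_label=lb.region_label,
                    seq_a=locus_sequence(plastome_a, la),
                    seq_b=locus_sequence(plastome_b, lb),
                    interval_a=la.interval,
                    interval_b=lb.interval,
                )
            )
        else:
            unmatched.append(ia[key])
    unmatched.extend(ib[key] for key in ib if key not in ia)
    pairs.sort(key=lambda pr: pr.interval_b)
    return pairs, unmatched


def catalog_table(loci: list[Locus]) -> pd.DataFrame:
    """BED-like locus table (1-based inclusive start for reporting)."""
    return pd.DataFrame(
        {
            "name": [lc.name for lc in loci],
            "category": [lc.category for lc in loci],
            "region": [lc.region_label for lc in loci],
            "start": [lc.interval[0] + 1 for lc in loci],
            "end": [lc.interval[1] for lc in loci],
            "strand": [lc.strand for lc in loci],
        }
    )


def export_gff3(loci: list[Locus], genome_id: str, path) -> None:
    type_map = {"gene": "gene", "intergenic_spacer": "region", "intron": "intron"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for lc in sorted(loci, key=lambda x: x.interval):
            strand = lc.strand if lc.strand in "+-" else "."
            fh.write(
                f"{genome_id}\tplastdiff\t{type_map[lc.category]}\t{lc.interval[0] + 1}\t"
                f"{lc.interval[1]}\t.\t{strand}\t.\tID={lc.name.replace(' ', '_')};"
                f"region={lc.region_label}\n"
            )
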