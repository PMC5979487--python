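"""Plastome sequences, annotations and the quadripartite genome model.

A chloroplast genome is modelled as a circular DNA sequence partitioned into
the four canonical regions (LSC, IRb, SSC, IRa) plus a feature annotation
(genes, CDSs, tRNAs, rRNAs with exon structure).  Coordinates are 0-based
half-open internally; every report writer emits 1-based inclusive positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

REGION_NAMES = ("LSC", "IRb", "SSC", "IRa")
FEATURE_TYPES = ("gene", "CDS", "tRNA", "rRNA")
VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class PlastomeError(ValueError):
    """Raised for malformed plastome input (sequence, annotation or regions)."""


@dataclass
class Feature:
    """One annotated feature with its exon structure.

    ``exons`` is an ordered list of 0-based half-open intervals on the plus
    strand of the (unwrapped) genome; a multi-exon feature implies introns.
    """

    name: str
    ftype: str
    strand: str
    exons: list[tuple[int, int]]
    notes: str = ""

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise PlastomeError(f"feature {self.name!r}: unknown type {self.ftype!r}")
        if self.strand not in ("+", "-"):
            raise PlastomeError(f"feature {self.name!r}: strand must be + or -")
        exons = [(int(s), int(e)) for s, e in self.exons]
        for s, e in exons:
            if e <= s:
                raise PlastomeError(f"feature {self.name!r}: empty exon [{s},{e})")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise PlastomeError(f"feature {self.name!r}: exons overlap or are unordered")
        self.exons = exons

    @property
    def has_introns(self) -> bool:
        return len(self.exons) > 1

    @property
    def span(self) -> tuple[int, int]:
        """Full genomic span from first exon start to last exon end."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class Plastome:
    """A circular plastome: sequence, quadripartite partition and features."""

    id: str
    seq: str
    regions: dict[str, tuple[int, int]]
    features: list[Feature] = field(default_factory=list)
    ir_mismatches: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise PlastomeError("empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise PlastomeError(f"sequence contains invalid characters: {sorted(bad)}")
        self._check_regions()
        self._check_features()
        ira = self.fetch(*self.regions["IRa"])
        irb = self.fetch(*self.regions["IRb"])
        self.ir_mismatches = _hamming_or_big(revcomp(irb), ira)

    # -- validation -------------------------------------------------------
    def _check_regions(self) -> None:
        if set(self.regions) != set(REGION_NAMES):
            raise PlastomeError(f"regions must be exactly {REGION_NAMES}")
        ivs = sorted((int(s), int(e)) for s, e in self.regions.values())
        if ivs[0][0] != 0 or ivs[-1][1] != len(self.seq):
            raise PlastomeError("region intervals must cover [0, length)")
        for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 != e0:
                raise PlastomeError("region intervals must tile the genome without gaps/overlaps")
        self.regions = {k: (int(s), int(e)) for k, (s, e) in self.regions.items()}

    def _check_features(self) -> None:
        n = len(self.seq)
        for f in self.features:
            s, e = f.span
            if s < 0 or e > n:
                raise PlastomeError(
                    f"feature {f.name!r} interval [{s},{e}) out of genome bounds [0,{n})"
                )

    # -- accessors --------------------------------------------------------
    @property
    def length_bp(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Sequence slice with circular wrap-around when end > length."""
        n = len(self.seq)
        if end <= n:
            return self.seq[start:end]
        return self.seq[start:] + self.seq[: end - n]

    def region_of(self, pos: int) -> str:
        """Region label at a 0-based position; IRa/IRb both report 'IR'."""
        for name, (s, e) in self.regions.items():
            if s <= pos % len(self.seq) < e:
                return "IR" if name.startswith("IR") else name
        raise PlastomeError(f"position {pos} outside genome")

    def features_of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.ftype == ftype]


def _hamming_or_big(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(1 for x, y in zip(a, b) if x != y)


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["name", "ftype", "strand", "exon_starts", "exon_ends", "notes"]


def _read_feature_tsv(path: Path) -> tuple[list[Feature], dict | None]:
    """Read the 6-column feature table (1-based inclusive coordinates).

    Rows with ftype ``region`` carry the quadripartite partition; their name
    must be one of LSC/IRb/SSC/IRa.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise PlastomeError(f"feature table missing columns: {missing}")
    feats: list[Feature] = []
    regions: dict[str, tuple[int, int]] = {}
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).split(",") if x != ""]
        ends = [int(x) for x in str(row.exon_ends).split(",") if x != ""]
        if len(starts) != len(ends):
            raise PlastomeError(f"feature {row.name!r}: exon_starts/exon_ends length mismatch")
        exons = [(s - 1, e) for s, e in zip(starts, ends)]  # 1-based incl -> 0-based half-open
        if row.ftype == "region":
            if row.name not in REGION_NAMES:
                raise PlastomeError(f"unknown region name {row.name!r}")
            regions[row.name] = exons[0]
        else:
            feats.append(Feature(row.name, row.ftype, row.strand, exons, notes=row.notes))
    return feats, (regions or None)


def _read_genbank_features(path: Path) -> tuple[list[Feature], str]:
    rec = SeqIO.read(str(path), "genbank")
    feats: list[Feature] = []
    for f in rec.features:
        if f.type not in FEATURE_TYPES:
            continue
        name = f.qualifiers.get("gene", f.qualifiers.get("locus_tag", ["?"]))[0]
        strand = "-" if f.location.strand == -1 else "+"
        exons = sorted((int(p.start), int(p.end)) for p in f.location.parts)
        feats.append(Feature(name, f.type, strand, exons))
    return feats, str(rec.seq).upper()


def write_feature_tsv(p: Plastome, path: Path) -> None:
    """Write features plus region rows as the documented 6-column table."""
    rows = []
    for name in REGION_NAMES:
        s, e = p.regions[name]
        rows.append((name, "region", "+", str(s + 1), str(e), ""))
    for f in p.features:
        rows.append(
            (
                f.name,
                f.ftype,
                f.strand,
                ",".join(str(s + 1) for s, _ in f.exons),
                ",".join(str(e) for _, e in f.exons),
                f.notes,
            )
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_plastome(p: Plastome, fasta_path: Path, annotation_path: Path) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{p.id}\n")
        for i in range(0, len(p.seq), 70):
            fh.write(p.seq[i : i + 70] + "\n")
    write_feature_tsv(p, Path(annotation_path))


# ---------------------------------------------------------------------------
# IR auto-detection
# ---------------------------------------------------------------------------

def detect_inverted_repeats(seq: str, min_len: int = 10_000) -> dict[str, tuple[int, int]]:
    """Locate the quadripartite partition from the longest reverse-complement
    repeat pair of length >= ``min_len``.

    The single-copy stretch with the greater length is labelled LSC.  The IR
    copy immediately downstream of the LSC (plus strand) is IRb, matching the
    conventional LSC-IRb-SSC-IRa layout.
    """
    n = len(seq)
    rc = revcomp(seq)
    k = max(12, min(64, min_len // 4))
    index: dict[str, list[int]] = {}
    for i in range(0, n - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    # seed matches between seq and revcomp(seq), grouped by diagonal
    best: tuple[int, int, int] | None = None  # (length, i_seq, j_rc)
    seen_diag: set[int] = set()
    for j in range(0, n - k + 1, k):
        for i in index.get(rc[j : j + k], ()):
            d = i - j
            if d in seen_diag:
                continue
            seen_diag.add(d)
            # extend the exact match around (i, j)
            s_i, s_j = i, j
            while s_i > 0 and s_j > 0 and seq[s_i - 1] == rc[s_j - 1]:
                s_i -= 1
                s_j -= 1
            e_i, e_j = i + k, j + k
            while e_i < n and e_j < n and seq[e_i] == rc[e_j]:
                e_i += 1
                e_j += 1
            length = e_i - s_i
            if best is None or length > best[0]:
                best = (length, s_i, s_j)
    if best is None or best[0] < min_len:
        raise PlastomeError(f"no inverted repeat pair of length >= {min_len} found")
    length, i0, j0 = best
    first = (i0, i0 + length)  # copy on the forward strand
    other = (n - (j0 + length), n - j0)  # its reverse-complement partner
    ir1, ir2 = sorted([first, other])
    if ir1[1] > ir2[0]:
        raise PlastomeError("detected inverted repeat copies overlap; not a quadripartite genome")
    # the two single-copy stretches: between the copies, and through the origin
    mid = (ir1[1], ir2[0])
    if ir1[0] > 0 and ir2[1] < n:
        raise PlastomeError(
            "single-copy sequence flanks the repeat pair on both sides; rotate the "
            "genome so a single-copy region begins at position 0"
        )
    outer = (ir2[1], n) if ir2[1] < n else (0, ir1[0])
    sc_big, sc_small = sorted([mid, outer], key=lambda iv: iv[1] - iv[0], reverse=True)
    lsc, ssc = sc_big, sc_small
    # IRb immediately follows the LSC along the plus strand (circularly)
    if ir1[0] == lsc[1] % n:
        irb, ira = ir1, ir2
    else:
        irb, ira = ir2, ir1
    return {"LSC": lsc, "IRb": irb, "SSC": ssc, "IRa": ira}


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_plastome(
    fasta_path: Path | str,
    annotation_path: Path | str | None = None,
    region_spec: dict[str, tuple[int, int]] | str = "auto",
    min_ir_len: int = 10_000,
    genome_id: str | None = None,
) -> Plastome:
    """Build a validated :class:`Plastome` from a FASTA plus an annotation.

    ``annotation_path`` may be a GenBank flat file or the 6-column TSV feature
    table (which may itself carry region rows).  ``region_spec`` is either a
    dict of the four intervals or ``"auto"``, in which case the IRs are
    inferred as the longest pair of exact reverse-complement repeats of at
    least ``min_ir_len`` bp.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise PlastomeError(f"FASTA must contain exactly one record, found {len(records)}")
    seq = str(records[0].seq).upper()
    rec_id = genome_id or records[0].id

    features: list[Feature] = []
    tsv_regions = None
    if annotation_path is not None:
        apath = Path(annotation_path)
        head = apath.read_text()[:5000]
        if head.startswith("LOCUS"):
            features, _ = _read_genbank_features(apath)
        else:
            features, tsv_regions = _read_feature_tsv(apath)

    if isinstance(region_spec, dict):
        regions = region_spec
    elif tsv_regions is not None:
        regions = tsv_regions
    else:
        regions = detect_inverted_repeats(seq, min_len=min_ir_len)
    return Plastome(rec_id, seq, regions, features)


# ---------------------------------------------------------------------------
# genome summary
# ---------------------------------------------------------------------------

@dataclass
class GenomeSummary:
    """Headline statistics for one plastome (sizes, gene counts, GC, coding)."""

    genome_id: str
    genome_size_bp: int
    lsc_bp: int
    ssc_bp: int
    ir_bp: int
    n_genes: int
    n_genes_unique: int
    n_cds: int
    n_cds_unique: int
    n_trna: int
    n_trna_unique: int
    n_rrna: int
    n_rrna_unique: int
    gc_percent: float
    coding_percent: float


def summarize(p: Plastome) -> GenomeSummary:
    """Compute the standard genome-comparison summary.

    GC% counts G+C over the full length (N bases count in the denominator
    only); coding% is the union of CDS exon bases over the genome length, so
    IR-duplicated genes are not double counted.
    """
    def counts(ftype: str) -> tuple[int, int]:
        fs = p.features_of_type(ftype)
        return len(fs), len({f.name for f in fs})

    n_gene, u_gene = counts("gene")
    n_cds, u_cds = counts("CDS")
    n_trna, u_trna = counts("tRNA")
    n_rrna, u_rrna = counts("rRNA")
    gc = 100.0 * (p.seq.count("G") + p.seq.count("C")) / p.length_bp

    coding = set()
    for f in p.features_of_type("CDS"):
        for s, e in f.exons:
            coding.update(range(s, e))
    coding_pct = 100.0 * len(coding) / p.length_bp

    def rlen(name: str) -> int:
        s, e = p.regions[name]
        return e - s

    return GenomeSummary(
        genome_id=p.id,
        genome_size_bp=p.length_bp,
        lsc_bp=rlen("LSC"),
        ssc_bp=rlen("SSC"),
        ir_bp=rlen("IRa"),
        n_genes=n_gene,
        n_genes_unique=u_gene,
        n_cds=n_cds,
        n_cds_unique=u_cds,
        n_trna=n_trna,
        n_trna_unique=u_trna,
        n_rrna=n_rrna,
        n_rrna_unique=u_rrna,
        gc_percent=round(gc, 2),
        coding_percent=round(coding_pct, 2),
    )


_SUMMARY_FIELDS = [
    ("genome_size_bp", "Genome size (bp)"),
    ("lsc_bp", "LSC length (bp)"),
    ("ssc_bp", "SSC length (bp)"),
    ("ir_bp", "IRa/IRb length (bp)"),
    ("n_genes", "Number of genes"),
    ("n_genes_unique", "Number of genes (unique)"),
    ("n_cds", "Number of protein-coding genes"),
    ("n_cds_unique", "Number of protein-coding genes (unique)"),
    ("n_trna", "Number of tRNA genes"),
    ("n_trna_unique", "Number of tRNA genes (unique)"),
    ("n_rrna", "Number of rRNA genes"),
    ("n_rrna_unique", "Number of rRNA genes (unique)"),
    ("gc_percent", "GC content (%)"),
    ("coding_percent", "Protein-coding regions (%)"),
]


def compare_summaries(a: GenomeSummary, b: GenomeSummary) -> pd.DataFrame:
    """Two-column genome comparison table with per-field deltas (a - b)."""
    rows = []
    for attr, label in _SUMMARY_FIELDS:
        va, vb = getattr(a, attr), getattr(b, attr)
        rows.append({"item": label, a.genome_id: va, b.genome_id: vb, "delta": round(va - vb, 2)})
    return pd.DataFrame(rows)
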