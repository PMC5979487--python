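"""Simulated plastome pairs with planted, manifest-recorded mutations.

Generates an annotated quadripartite genome ("genome B", playing the role of
the previously published reference), then derives "genome A" by applying an
exact list of planted edits: SNPs (with a transition bias and, by default,
synonymous-only placement inside CDSs), small and large indels (large ones
planted as repeat expansions/contractions), and SSR tract length changes.
Every planted change is recorded in a :class:`TruthManifest` so each pipeline
stage can be validated against known ground truth.

Edits inside the inverted repeat are planted on the IRa copy (the copy the
analysis pipeline keeps) and mirrored into IRb, preserving the
IRa == revcomp(IRb) identity in both genomes.  Mutation positions are
recorded in genome-B coordinates, left-normalized with the same convention
the event caller uses, so recovered events can be compared to the manifest
by exact identity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coding_effects import call_coding_snp, cds_feature_at
from .locus_catalog import Locus, extract_loci
from .mutation_scan import MutationEvent, classify_ts_tv
from .plastome_io import Feature, Plastome, revcomp, write_plastome

_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
# codon prefixes whose third position is four-fold degenerate (table 11)
FOURFOLD_PREFIXES = {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}
_STOPS = {"TAA", "TAG", "TGA"}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

# margins keeping planted edits away from locus/region boundaries so that
# left-normalization cannot carry an event across a boundary
_BOUNDARY_MARGIN = 30
_RESERVE_PAD = 25
_SHIFT_ALLOWANCE = 20  # headroom for leftward indel normalization shifts
_MONO_THRESHOLD = 10  # detection threshold for mononucleotide tracts


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-scale defaults: a ~160 kb quadripartite genome diverging by
    75 SNPs and 80 indels, with 31 detectable SSR tracts of which 8 are
    length-polymorphic (all mononucleotide, as observed in the real pair)."""

    seed: int = 0
    genome_len: int = 160_000
    lsc_frac: float = 0.53
    ssc_frac: float = 0.09
    ir_frac: float = 0.19
    gc_content: float = 0.38
    n_genes: int = 90  # genes tiled into LSC/SSC/IRb; IRa twins are mirrored extras
    intron_gene_fraction: float = 0.12
    trna_fraction: float = 0.18
    rrna_fraction: float = 0.05
    gene_len_range: tuple[int, int] = (300, 1500)
    trna_len_range: tuple[int, int] = (70, 90)
    intron_len_range: tuple[int, int] = (150, 400)
    spacer_len_range: tuple[int, int] = (150, 600)
    n_snp: int = 75
    ts_fraction: float = 0.85  # 34 transitions / 40 coding SNPs
    coding_snp_mode: str = "synonymous_only"  # or "any"
    snp_cds_fraction: float = 0.53
    snp_genic_noncoding_fraction: float = 0.26
    n_indel: int = 80
    large_indel_fraction: float = 0.25  # 20 of 80 events exceed 10 bp
    large_indel_max: int = 120
    large_insertion_fraction: float = 0.75  # 15 insertions : 5 deletions
    repeat_indel_fraction: float = 1.0  # all large indels repeat-associated
    small_indel_max: int = 10
    n_ssr_seeded: int = 31  # detectable tracts (an IR seed counts once per copy)
    n_ssr_ir_pairs: int = 2
    n_ssr_below_threshold: int = 4
    n_ssr_polymorphic: int = 8  # polymorphic tracts (an IR pair counts twice)
    n_ssr_polymorphic_ir_pairs: int = 1
    min_event_spacing: int = 25

    def __post_init__(self) -> None:
        for name in ("lsc_frac", "ssc_frac", "ir_frac", "gc_content", "intron_gene_fraction",
                     "ts_fraction", "snp_cds_fraction", "snp_genic_noncoding_fraction",
                     "large_indel_fraction", "large_insertion_fraction", "repeat_indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0,1], got {v}")
        if abs(self.lsc_frac + self.ssc_frac + 2 * self.ir_frac - 1.0) > 1e-9:
            raise SimulationError("region fractions must satisfy lsc + ssc + 2*ir = 1")
        for name in ("n_snp", "n_indel", "n_genes", "n_ssr_seeded", "n_ssr_polymorphic"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.coding_snp_mode not in ("any", "synonymous_only"):
            raise SimulationError("coding_snp_mode must be 'any' or 'synonymous_only'")
        if self.n_ssr_polymorphic - 2 * self.n_ssr_polymorphic_ir_pairs < 0:
            raise SimulationError("n_ssr_polymorphic too small for the requested IR pairs")
        if self.n_ssr_seeded - 2 * self.n_ssr_ir_pairs < self.n_poly_sc:
            raise SimulationError("not enough single-copy SSR seeds for the polymorphic set")
        if self.n_slippage + self.n_large > self.n_indel:
            raise SimulationError("large + slippage indels exceed the indel budget")

    @property
    def n_poly_sc(self) -> int:
        return self.n_ssr_polymorphic - 2 * self.n_ssr_polymorphic_ir_pairs

    @property
    def n_slippage(self) -> int:
        """SSR slippage edits (drawn from the indel budget): one per
        single-copy polymorphic tract plus one per polymorphic IR pair."""
        return self.n_poly_sc + self.n_ssr_polymorphic_ir_pairs

    @property
    def n_large(self) -> int:
        return int(round(self.n_indel * self.large_indel_fraction))


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A miniature genome (12 kb) with the same structure and default event
    spacing, for fast many-seed validation sweeps."""
    params = dict(
        seed=seed,
        genome_len=14_000,
        lsc_frac=0.52,
        ssc_frac=0.12,
        ir_frac=0.18,
        n_genes=12,
        gene_len_range=(240, 900),
        n_snp=8,
        n_indel=8,
        large_indel_max=40,
        n_ssr_seeded=6,
        n_ssr_ir_pairs=1,
        n_ssr_below_threshold=2,
        n_ssr_polymorphic=3,
        n_ssr_polymorphic_ir_pairs=1,
    )
    params.update(overrides)
    return SimConfig(**params)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

@dataclass
class PlantedEvent:
    """One planted mutation, in genome-B coordinates (0-based, left-normalized)."""

    kind: str  # SNP | insertion | deletion
    pos: int
    ref: str
    alt: str
    locus_name: str = ""
    category: str = ""
    region_label: str = ""
    ts_tv: str = "NA"
    effect: str = "NA"  # synonymous | nonsynonymous | NA
    repeat_associated: object = None
    ssr_slippage: bool = False

    def key(self) -> tuple:
        return (self.kind, self.pos + 1, self.ref, self.alt)


@dataclass
class PlantedSSR:
    motif: str  # motif as it reads on the planted (B) strand copy
    start: int  # 0-based tract start in genome B
    end: int
    len_b: int
    len_a: int
    region_label: str = ""
    in_ir: bool = False
    polymorphic: bool = False


@dataclass
class TruthManifest:
    """Ground truth of one simulated pair."""

    events: list[PlantedEvent] = field(default_factory=list)
    ssrs: list[PlantedSSR] = field(default_factory=list)

    def event_keys(self) -> set[tuple]:
        return {e.key() for e in self.events}

    @property
    def n_snp(self) -> int:
        return sum(1 for e in self.events if e.kind == "SNP")

    @property
    def n_indel(self) -> int:
        return sum(1 for e in self.events if e.kind != "SNP")

    @property
    def n_polymorphic_ssr(self) -> int:
        """Detected-polymorphic-tract count (an IR tract counts per copy)."""
        return sum(2 if s.in_ir else 1 for s in self.ssrs if s.polymorphic)

    @property
    def n_detectable_ssr(self) -> int:
        return sum(2 if s.in_ir else 1 for s in self.ssrs)

    def to_json(self, path) -> None:
        payload = {
            "events": [dataclasses.asdict(e) for e in self.events],
            "ssrs": [dataclasses.asdict(s) for s in self.ssrs],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            events=[PlantedEvent(**e) for e in payload["events"]],
            ssrs=[PlantedSSR(**s) for s in payload["ssrs"]],
        )


# ---------------------------------------------------------------------------
# low-level sequence helpers
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def _random_codons(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    out: list[str] = []
    while len(out) < n_codons:
        batch = _random_seq(rng, 3 * (n_codons - len(out) + 4), gc)
        out.extend(
            c for c in (batch[i : i + 3] for i in range(0, len(batch) - 2, 3))
            if c not in _STOPS
        )
    return "".join(out[:n_codons])


_CLEANUP_THRESHOLDS = {1: 8, 2: 5, 3: 4, 4: 4, 5: 4, 6: 4}


def _break_repeats(seq: str, rng: np.random.Generator) -> str:
    """Substitute bases so the background carries no near-threshold SSR
    tracts; planted tracts are added afterwards and stay unique."""
    from .ssr_scan import _raw_tracts  # deferred to avoid an import cycle

    chars = list(seq)
    for _ in range(5):
        dirty = False
        s = "".join(chars)
        for u, thr in _CLEANUP_THRESHOLDS.items():
            for start, n_units, motif in _raw_tracts(s, u, thr):
                mid = start + (n_units * u) // 2
                banned = {chars[mid]}
                if mid > 0:
                    banned.add(chars[mid - 1])
                if mid + 1 < len(chars):
                    banned.add(chars[mid + 1])
                options = [b for b in "ACGT" if b not in banned] or ["A"]
                chars[mid] = options[int(rng.integers(len(options)))]
                dirty = True
        if not dirty:
            break
    return "".join(chars)


def _normalize_edit(seq: str, pos: int, allele: str) -> tuple[int, str]:
    """Left-align an indel edit against the reference sequence (the classic
    variant-normalization shift: while the last allele base equals the base
    before the site, rotate the allele right-to-left)."""
    while pos > 0 and allele and allele[-1] == seq[pos - 1]:
        allele = seq[pos - 1] + allele[:-1]
        pos -= 1
    return pos, allele


def _mirror_point(x: int, src: tuple[int, int], dst: tuple[int, int]) -> int:
    """Map an insertion point / interval boundary between the two IR copies."""
    return dst[0] + (src[1] - x)


def _mirror_interval(iv: tuple[int, int], src, dst) -> tuple[int, int]:
    return (_mirror_point(iv[1], src, dst), _mirror_point(iv[0], src, dst))


# ---------------------------------------------------------------------------
# spec-level planting operations (also used directly by tests)
# ---------------------------------------------------------------------------

def plant_repeat_indel(
    seq: str, size: int, site: int, kind: str = "insertion"
) -> tuple[str, PlantedEvent]:
    """Apply a repeat expansion (duplicate the left flank) or contraction
    (delete one unit of an existing tandem pair) to a raw sequence.

    Returns the modified sequence and the planted-event record with
    ``repeat_associated=True``.  Expansions require ``site >= size``;
    contractions require an exact tandem pair at ``site``.
    """
    if not 10 < size <= 120:
        raise SimulationError(f"repeat indel size must be in (10, 120], got {size}")
    if kind == "insertion":
        if site < size:
            raise SimulationError("expansion site must leave room for the duplicated flank")
        allele = seq[site - size : site]
        new = seq[:site] + allele + seq[site:]
    elif kind == "deletion":
        if seq[site : site + size] != seq[site + size : site + 2 * size]:
            raise SimulationError("contraction requires an exact tandem pair at the site")
        allele = seq[site : site + size]
        new = seq[:site] + seq[site + size :]
    else:
        raise SimulationError(f"unknown indel kind {kind!r}")
    pos, norm_allele = _normalize_edit(seq, site, allele)
    record = PlantedEvent(
        kind=kind,
        pos=pos,
        ref="" if kind == "insertion" else norm_allele,
        alt=norm_allele if kind == "insertion" else "",
        repeat_associated=True,
    )
    return new, record


def fourfold_third_positions(genome_seq: str, cds: Feature) -> list[int]:
    """Genomic 0-based positions of four-fold degenerate third codon
    positions of a CDS (strand-aware)."""
    gpos: list[int] = []
    for s, e in cds.exons:
        gpos.extend(range(s, e))
    splice = "".join(genome_seq[s:e] for s, e in cds.exons)
    if cds.strand == "-":
        gpos = gpos[::-1]
        splice = revcomp(splice)
    out = []
    for i in range(0, len(splice) - 2, 3):
        if splice[i : i + 2] in FOURFOLD_PREFIXES:
            out.append(gpos[i + 2])
    return out


def plant_synonymous_snp(
    seq: str, cds: Feature, rng: np.random.Generator, ts_fraction: float = 0.85
) -> tuple[str, PlantedEvent]:
    """Substitute one four-fold degenerate third position of a CDS; the
    change is synonymous by construction.  Transition with probability
    ``ts_fraction``."""
    sites = fourfold_third_positions(seq, cds)
    if not sites:
        raise SimulationError(f"CDS {cds.name} has no four-fold degenerate site")
    pos = int(sites[int(rng.integers(len(sites)))])
    ref = seq[pos]
    if rng.random() < ts_fraction:
        alt = _TS_PARTNER[ref]
    else:
        alt = _TV_PARTNERS[ref][int(rng.integers(2))]
    new = seq[:pos] + alt + seq[pos + 1 :]
    return new, PlantedEvent(
        kind="SNP", pos=pos, ref=ref, alt=alt,
        ts_tv=classify_ts_tv(ref, alt), effect="synonymous",
    )


# ---------------------------------------------------------------------------
# placement bookkeeping
# ---------------------------------------------------------------------------

class _Registry:
    """Reserved genomic intervals with a minimum-gap collision check."""

    def __init__(self) -> None:
        self.reserved: list[tuple[int, int]] = []

    def free(self, start: int, end: int, gap: int) -> bool:
        return all(end + gap <= s or e + gap <= start for s, e in self.reserved)

    def reserve(self, start: int, end: int) -> None:
        self.reserved.append((start, end))


def _sample_in_windows(
    rng: np.random.Generator,
    windows: list[tuple[int, int]],
    span: int,
    registry: _Registry,
    gap: int,
    tries: int = 400,
) -> int | None:
    usable = [(s, e) for s, e in windows if e - s >= span]
    if not usable:
        return None
    weights = np.array([e - s - span + 1 for s, e in usable], dtype=float)
    weights /= weights.sum()
    for _ in range(tries):
        wi = int(rng.choice(len(usable), p=weights))
        s, e = usable[wi]
        pos = int(rng.integers(s, e - span + 1))
        if registry.free(pos, pos + span, gap):
            return pos
    return None


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

@dataclass
class _GeneSpec:
    name: str
    gtype: str  # coding | trna | rrna
    strand: str
    exons: list[tuple[int, int]]  # global B coordinates


def _build_region(
    rng: np.random.Generator,
    cfg: SimConfig,
    region_len: int,
    n_target: int,
    offset: int,
    prefix: str,
    counter: dict[str, int],
) -> tuple[str, list[_GeneSpec], list[tuple[int, int]]]:
    """Tile one region with alternating spacers and genes.

    Returns (sequence, gene specs in global coords, spacer intervals)."""
    min_spacer = max(100, cfg.spacer_len_range[0])

    built: list[dict] = []
    total = 0
    for _ in range(n_target):
        r = rng.random()
        if r < cfg.trna_fraction:
            gtype = "trna"
            seq = _random_seq(rng, int(rng.integers(*cfg.trna_len_range)), cfg.gc_content)
            parts = [("exon", seq)]
        elif r < cfg.trna_fraction + cfg.rrna_fraction:
            gtype = "rrna"
            seq = _random_seq(rng, int(rng.integers(200, 1200)), cfg.gc_content)
            parts = [("exon", seq)]
        else:
            gtype = "coding"
            lo, hi = cfg.gene_len_range
            n_codons = int(rng.integers(lo // 3, hi // 3))
            coding = "ATG" + _random_codons(rng, n_codons, cfg.gc_content) + "TAA"
            if rng.random() < cfg.intron_gene_fraction and len(coding) > 60:
                cut = int(rng.integers(20, len(coding) - 20))
                intron = _random_seq(rng, int(rng.integers(*cfg.intron_len_range)), cfg.gc_content)
                parts = [("exon", coding[:cut]), ("intron", intron), ("exon", coding[cut:])]
            else:
                parts = [("exon", coding)]
        strand = "+" if rng.random() < 0.5 else "-"
        glen = sum(len(s) for _, s in parts)
        if total + glen + (len(built) + 2) * min_spacer > region_len:
            break
        built.append({"gtype": gtype, "strand": strand, "parts": parts})
        total += glen

    n = len(built)
    spacer_budget = region_len - total
    # every spacer gets the minimum; the surplus is split by random weights
    surplus = spacer_budget - (n + 1) * min_spacer
    w = rng.random(n + 1) + 0.25
    spacer_lens = min_spacer + np.floor(w / w.sum() * surplus).astype(int)
    spacer_lens[-1] += spacer_budget - int(spacer_lens.sum())

    seq_parts: list[str] = []
    gene_specs: list[_GeneSpec] = []
    spacer_ivs: list[tuple[int, int]] = []
    cursor = offset
    for k, g in enumerate(built):
        slen = int(spacer_lens[k])
        seq_parts.append(_random_seq(rng, slen, cfg.gc_content))
        spacer_ivs.append((cursor, cursor + slen))
        cursor += slen
        if g["strand"] == "+" or g["gtype"] != "coding":
            genomic_parts = list(g["parts"])
        else:
            # minus strand: the genome plus strand carries the reverse
            # complement, with the 3'-most coding part first
            genomic_parts = [
                (kind, revcomp(s) if kind == "exon" else s)
                for kind, s in reversed(g["parts"])
            ]
        exons = []
        for kind, s in genomic_parts:
            if kind == "exon":
                exons.append((cursor, cursor + len(s)))
            seq_parts.append(s)
            cursor += len(s)
        counter[g["gtype"]] += 1
        name = {
            "coding": f"{prefix}g{counter['coding']:03d}",
            "trna": f"trn{counter['trna']:03d}",
            "rrna": f"rrn{counter['rrna']:03d}",
        }[g["gtype"]]
        gene_specs.append(_GeneSpec(name, g["gtype"], g["strand"], exons))
    slen = int(spacer_lens[n])
    seq_parts.append(_random_seq(rng, slen, cfg.gc_content))
    spacer_ivs.append((cursor, cursor + slen))
    cursor += slen
    assert cursor - offset == region_len
    return "".join(seq_parts), gene_specs, spacer_ivs


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def simulate_pair(
    cfg: SimConfig, outdir: Path | str | None = None
) -> tuple[Plastome, Plastome, TruthManifest]:
    """Generate (genome A, genome B, truth manifest) for one seed.

    Genome B is built first; genome A is genome B with exactly the planted
    edits applied.  Identical seeds give bit-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)

    ir_len = int(round(cfg.genome_len * cfg.ir_frac))
    ssc_len = int(round(cfg.genome_len * cfg.ssc_frac))
    lsc_len = cfg.genome_len - ssc_len - 2 * ir_len
    lsc_iv = (0, lsc_len)
    irb_iv = (lsc_len, lsc_len + ir_len)
    ssc_iv = (lsc_len + ir_len, lsc_len + ir_len + ssc_len)
    ira_iv = (cfg.genome_len - ir_len, cfg.genome_len)

    content_lens = {"LSC": lsc_len, "IRb": ir_len, "SSC": ssc_len}
    total_content = sum(content_lens.values())
    targets = {
        k: max(1, int(round(cfg.n_genes * v / total_content))) for k, v in content_lens.items()
    }

    counter = {"coding": 0, "trna": 0, "rrna": 0}
    seqs: dict[str, str] = {}
    gene_specs: list[_GeneSpec] = []
    spacer_ivs: dict[str, list[tuple[int, int]]] = {}
    for name, iv, prefix in (("LSC", lsc_iv, "l"), ("IRb", irb_iv, "i"), ("SSC", ssc_iv, "s")):
        seq, genes, spacers = _build_region(
            rng, cfg, iv[1] - iv[0], targets[name], iv[0], prefix, counter
        )
        seqs[name] = _break_repeats(seq, rng)
        gene_specs.extend(genes)
        spacer_ivs[name] = spacers

    b_chars = list(seqs["LSC"] + seqs["IRb"] + seqs["SSC"])
    registry = _Registry()

    def shrink(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
        return [
            (s + _BOUNDARY_MARGIN, e - _BOUNDARY_MARGIN)
            for s, e in ivs
            if e - s > 2 * _BOUNDARY_MARGIN + 40
        ]

    # the leading LSC spacer belongs to the origin-spanning (wrap) locus and
    # is excluded from planting.  Only *interior* IRb spacers are used for IR
    # seeds/windows: their loci (and the IRb mirrors of IRa edits) fall fully
    # inside IRb and are dropped by the IR deduplication, so IR events are
    # counted exactly once; boundary-crossing spacers would be counted twice.
    sc_windows = shrink(spacer_ivs["LSC"][1:] + spacer_ivs["SSC"])
    irb_spacer_ivs = spacer_ivs["IRb"][1:-1]
    irb_windows = shrink(irb_spacer_ivs)

    # -- SSR seeding ------------------------------------------------------
    planted_ssrs: list[PlantedSSR] = []

    def seed_ssr(windows, in_ir: bool, force_mono: bool) -> PlantedSSR:
        if force_mono or rng.random() < 0.8:
            motif = "AT"[int(rng.integers(2))]
            n_units = int(rng.integers(10, 16))
        else:
            unit_len = int(rng.integers(2, 4))
            motif = "".join("ACGT"[int(rng.integers(4))] for _ in range(unit_len))
            while len(set(motif)) < 2:  # primitive motif needed
                motif = "".join("ACGT"[int(rng.integers(4))] for _ in range(unit_len))
            n_units = int(rng.integers(6, 9)) if unit_len == 2 else int(rng.integers(5, 7))
        tract = motif * n_units
        span = len(tract) + 2  # one guard base each side
        pos = _sample_in_windows(rng, windows, span, registry, gap=_RESERVE_PAD)
        if pos is None:
            raise SimulationError(
                "could not place all SSR seeds; reduce counts or enlarge the genome"
            )
        start = pos + 1
        # guard bases prevent the tract extending into the background
        left_guard = [b for b in "ACGT" if b != motif[0]][0]
        right_guard = [b for b in "ACGT" if b != motif[-1]][-1]
        b_chars[pos] = left_guard
        for k, c in enumerate(tract):
            b_chars[start + k] = c
        b_chars[start + len(tract)] = right_guard
        registry.reserve(pos - _RESERVE_PAD, start + len(tract) + 1 + _RESERVE_PAD)
        if in_ir:
            miv = _mirror_interval((pos, start + len(tract) + 1), irb_iv, ira_iv)
            registry.reserve(miv[0] - _RESERVE_PAD, miv[1] + _RESERVE_PAD)
        ssr = PlantedSSR(
            motif=motif, start=start, end=start + len(tract),
            len_b=len(tract), len_a=len(tract), in_ir=in_ir,
        )
        planted_ssrs.append(ssr)
        return ssr

    n_sc_seeds = cfg.n_ssr_seeded - 2 * cfg.n_ssr_ir_pairs
    sc_poly = [seed_ssr(sc_windows, False, True) for _ in range(cfg.n_poly_sc)]
    for _ in range(n_sc_seeds - cfg.n_poly_sc):
        seed_ssr(sc_windows, False, False)
    ir_poly = [seed_ssr(irb_windows, True, True) for _ in range(cfg.n_ssr_polymorphic_ir_pairs)]
    for _ in range(cfg.n_ssr_ir_pairs - cfg.n_ssr_polymorphic_ir_pairs):
        seed_ssr(irb_windows, True, False)
    for s in sc_poly + ir_poly:
        s.polymorphic = True

    # below-threshold decoys (never detectable, never polymorphic)
    for _ in range(cfg.n_ssr_below_threshold):
        motif = "AT"[int(rng.integers(2))]
        tract = motif * int(rng.integers(6, _MONO_THRESHOLD - 1))
        pos = _sample_in_windows(rng, sc_windows, len(tract) + 2, registry, gap=_RESERVE_PAD)
        if pos is None:
            break
        guard = [b for b in "ACGT" if b != motif][0]
        b_chars[pos] = guard
        for k, c in enumerate(tract):
            b_chars[pos + 1 + k] = c
        b_chars[pos + 1 + len(tract)] = guard
        registry.reserve(pos - _RESERVE_PAD, pos + len(tract) + 2 + _RESERVE_PAD)

    # -- large indel planning (single-copy regions only) ------------------
    n_large_ins = int(round(cfg.n_large * cfg.large_insertion_fraction))
    n_large_del = cfg.n_large - n_large_ins
    edits: list[dict] = []

    for _ in range(n_large_del):
        size = int(rng.integers(11, cfg.large_indel_max + 1))
        repeat = rng.random() < cfg.repeat_indel_fraction
        span = 2 * size if repeat else size
        pos = _sample_in_windows(
            rng, sc_windows, span, registry,
            gap=cfg.min_event_spacing + _SHIFT_ALLOWANCE,
        )
        if pos is None:
            raise SimulationError("could not place all large deletions; reduce counts")
        if repeat:
            unit = "".join(b_chars[pos : pos + size])
            b_chars[pos + size : pos + 2 * size] = list(unit)
            edits.append({"kind": "deletion", "pos": pos + size, "ref": unit, "alt": "",
                          "repeat": True})
        else:
            edits.append({"kind": "deletion", "pos": pos,
                          "ref": "".join(b_chars[pos : pos + size]), "alt": "",
                          "repeat": False})
        registry.reserve(pos - _SHIFT_ALLOWANCE - _RESERVE_PAD, pos + span + _RESERVE_PAD)

    pending_ins: list[dict] = []  # alleles read after the B sequence is final
    for _ in range(n_large_ins):
        size = int(rng.integers(11, cfg.large_indel_max + 1))
        repeat = rng.random() < cfg.repeat_indel_fraction
        pos = _sample_in_windows(
            rng, sc_windows, size, registry,
            gap=cfg.min_event_spacing + _SHIFT_ALLOWANCE,
        )
        if pos is None:
            raise SimulationError("could not place all large insertions; reduce counts")
        pending_ins.append({"site": pos + size, "size": size, "repeat": repeat})
        registry.reserve(pos - _SHIFT_ALLOWANCE - _RESERVE_PAD, pos + size + _RESERVE_PAD)

    # keep the planted partition maximal: the first SSC base must not extend
    # the inverted repeat (it would pair with the last SSC base)
    first_ssc, last_ssc = ssc_iv[0], ssc_iv[1] - 1
    if b_chars[first_ssc] == _COMP[b_chars[last_ssc]]:
        b_chars[first_ssc] = [
            c for c in "ACGT"
            if c != _COMP[b_chars[last_ssc]] and c != b_chars[first_ssc + 1]
        ][0]

    # -- assemble genome B ------------------------------------------------
    sc_part = "".join(b_chars)
    irb_seq = sc_part[irb_iv[0] : irb_iv[1]]
    b_seq = sc_part + revcomp(irb_seq)
    assert len(b_seq) == cfg.genome_len

    for p in pending_ins:
        site, size = p["site"], p["size"]
        allele = b_seq[site - size : site] if p["repeat"] else _random_seq(rng, size, cfg.gc_content)
        edits.append({"kind": "insertion", "pos": site, "ref": "", "alt": allele,
                      "repeat": p["repeat"]})

    features: list[Feature] = []
    ftype_map = {"coding": "CDS", "trna": "tRNA", "rrna": "rRNA"}
    for g in gene_specs:
        features.append(Feature(g.name, "gene", g.strand, list(g.exons)))
        features.append(Feature(g.name, ftype_map[g.gtype], g.strand, list(g.exons)))
    for g in [g for g in gene_specs if irb_iv[0] <= g.exons[0][0] < irb_iv[1]]:
        m_exons = sorted(_mirror_interval(iv, irb_iv, ira_iv) for iv in g.exons)
        strand = "-" if g.strand == "+" else "+"
        features.append(Feature(g.name, "gene", strand, m_exons))
        features.append(Feature(g.name, ftype_map[g.gtype], strand, m_exons))

    regions_b = {"LSC": lsc_iv, "IRb": irb_iv, "SSC": ssc_iv, "IRa": ira_iv}
    genome_b = Plastome("simB", b_seq, regions_b, features)
    if genome_b.ir_mismatches != 0:
        raise SimulationError("internal error: IR copies diverged during construction")

    # -- editable windows for SNPs / small indels -------------------------
    ira_windows = [_mirror_interval(iv, irb_iv, ira_iv) for iv in shrink(irb_spacer_ivs)]
    spacer_windows = sc_windows + ira_windows

    genic_nc_windows: list[tuple[int, int]] = []
    for f in genome_b.features:
        if irb_iv[0] <= f.exons[0][0] < irb_iv[1]:
            continue
        if f.ftype == "gene" and f.has_introns:
            for (_, e0), (s1, _) in zip(f.exons, f.exons[1:]):
                if s1 - e0 > 40:
                    genic_nc_windows.append((e0 + 20, s1 - 20))
        if f.ftype == "tRNA":
            s, e = f.span
            if e - s > 30:
                genic_nc_windows.append((s + 15, e - 15))

    cds_feats = [
        f for f in genome_b.features_of_type("CDS")
        if not (irb_iv[0] <= f.exons[0][0] < irb_iv[1])
    ]
    cds_sites: list[int] = []
    for f in cds_feats:
        if cfg.coding_snp_mode == "synonymous_only":
            cds_sites.extend(fourfold_third_positions(b_seq, f))
        else:
            for s, e in f.exons:
                cds_sites.extend(range(s, e))
    rng.shuffle(cds_sites)

    # -- SNPs -------------------------------------------------------------
    def place_snp_at(pos: int, transition: bool | None = None) -> bool:
        if not registry.free(pos, pos + 1, cfg.min_event_spacing):
            return False
        ref = b_seq[pos]
        if transition is None:
            transition = rng.random() < cfg.ts_fraction
        if transition:
            alt = _TS_PARTNER[ref]
        else:
            alt = _TV_PARTNERS[ref][int(rng.integers(2))]
        edits.append({"kind": "SNP", "pos": pos, "ref": ref, "alt": alt, "repeat": None})
        registry.reserve(pos, pos + 1)
        return True

    n_cds_snp = int(round(cfg.n_snp * cfg.snp_cds_fraction))
    n_genic_nc_snp = int(round(cfg.n_snp * cfg.snp_genic_noncoding_fraction))
    n_spacer_snp = cfg.n_snp - n_cds_snp - n_genic_nc_snp

    # coding SNPs carry an exact transition count (round(ts_fraction * n)),
    # matching the reported ratio as a count rather than a coin-flip average
    n_cds_ts = int(round(cfg.ts_fraction * n_cds_snp))
    ts_flags = [True] * n_cds_ts + [False] * (n_cds_snp - n_cds_ts)
    rng.shuffle(ts_flags)
    placed = 0
    for pos in cds_sites:
        if placed >= n_cds_snp:
            break
        if place_snp_at(int(pos), transition=ts_flags[placed]):
            placed += 1
    if placed < n_cds_snp:
        raise SimulationError("not enough CDS sites for the requested coding SNPs")

    for want, windows in ((n_genic_nc_snp, genic_nc_windows), (n_spacer_snp, spacer_windows)):
        if not windows:
            windows = spacer_windows
        for _ in range(want):
            pos = _sample_in_windows(rng, windows, 1, registry, gap=cfg.min_event_spacing)
            if pos is None:
                pos = _sample_in_windows(rng, spacer_windows, 1, registry,
                                         gap=cfg.min_event_spacing)
            if pos is None:
                raise SimulationError("could not place all SNPs; reduce counts")
            assert place_snp_at(pos)

    # -- small indels ------------------------------------------------------
    n_small = cfg.n_indel - cfg.n_large - cfg.n_slippage
    for _ in range(n_small):
        size = int(rng.integers(1, cfg.small_indel_max + 1))
        windows = genic_nc_windows if (rng.random() < 0.4 and genic_nc_windows) else spacer_windows
        gap = cfg.min_event_spacing + _SHIFT_ALLOWANCE
        if rng.random() < 0.5:
            pos = _sample_in_windows(rng, windows, size, registry, gap=gap)
            if pos is None:
                pos = _sample_in_windows(rng, spacer_windows, size, registry, gap=gap)
            if pos is None:
                raise SimulationError("could not place all small indels; reduce counts")
            edits.append({"kind": "deletion", "pos": pos, "ref": b_seq[pos : pos + size],
                          "alt": "", "repeat": None})
            registry.reserve(pos - _SHIFT_ALLOWANCE, pos + size)
        else:
            pos = _sample_in_windows(rng, windows, 1, registry, gap=gap)
            if pos is None:
                pos = _sample_in_windows(rng, spacer_windows, 1, registry, gap=gap)
            if pos is None:
                raise SimulationError("could not place all small indels; reduce counts")
            edits.append({"kind": "insertion", "pos": pos, "ref": "",
                          "alt": _random_seq(rng, size, cfg.gc_content), "repeat": None})
            registry.reserve(pos - _SHIFT_ALLOWANCE, pos + 1)

    # -- SSR slippage ------------------------------------------------------
    def slip(ssr: PlantedSSR, motif_b: str, start_b: int) -> None:
        delta = int(rng.integers(1, 4))
        max_del = ssr.len_b - _MONO_THRESHOLD
        if max_del >= 1 and rng.random() < 0.5:
            delta = min(delta, max_del)
            allele = motif_b * delta
            edits.append({"kind": "deletion", "pos": start_b, "ref": allele, "alt": "",
                          "repeat": None, "slip": True})
            ssr.len_a = ssr.len_b - delta
        else:
            allele = motif_b * delta
            edits.append({"kind": "insertion", "pos": start_b, "ref": "", "alt": allele,
                          "repeat": None, "slip": True})
            ssr.len_a = ssr.len_b + delta

    for s in sc_poly:
        slip(s, s.motif, s.start)
    for s in ir_poly:
        # edit the IRa mirror copy (the analysed one); its motif is complemented
        m_iv = _mirror_interval((s.start, s.end), irb_iv, ira_iv)
        slip(s, _COMP[s.motif], m_iv[0])

    # -- normalize, annotate, build the manifest --------------------------
    catalog = [
        lc for lc in extract_loci(genome_b, include_introns=False)
        if lc.interval[1] <= genome_b.length_bp
    ]

    def containing_locus(pos: int) -> Locus | None:
        for lc in catalog:
            if lc.interval[0] <= pos < lc.interval[1]:
                return lc
        return None

    manifest = TruthManifest(ssrs=planted_ssrs)
    for ed in edits:
        pos, ref, alt = ed["pos"], ed["ref"], ed["alt"]
        if ed["kind"] == "insertion":
            pos, alt = _normalize_edit(b_seq, pos, alt)
        elif ed["kind"] == "deletion":
            pos, ref = _normalize_edit(b_seq, pos, ref)
        ed["pos"], ed["ref"], ed["alt"] = pos, ref, alt
        lc = containing_locus(pos)
        pe = PlantedEvent(
            kind=ed["kind"],
            pos=pos,
            ref=ref,
            alt=alt,
            locus_name=lc.name if lc else "",
            category=lc.category if lc else "",
            region_label=genome_b.region_of(pos),
            ts_tv=classify_ts_tv(ref, alt) if ed["kind"] == "SNP" else "NA",
            repeat_associated=ed.get("repeat"),
            ssr_slippage=bool(ed.get("slip")),
        )
        if ed["kind"] == "SNP":
            cds = cds_feature_at(genome_b, pos)
            if cds is not None:
                ev = MutationEvent("SNP", pe.locus_name, pe.category, pe.region_label,
                                   pos + 1, ref, alt, 1, pe.ts_tv)
                pe.effect = call_coding_snp(ev, cds, genome_b).effect
        manifest.events.append(pe)

    _check_spacing(manifest.events, cfg.min_event_spacing)

    genome_a = _apply_edits(genome_b, [
        {"kind": e.kind, "pos": e.pos, "ref": e.ref, "alt": e.alt} for e in manifest.events
    ])

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_plastome(genome_a, out / "genomeA.fasta", out / "genomeA.features.tsv")
        write_plastome(genome_b, out / "genomeB.fasta", out / "genomeB.features.tsv")
        manifest.to_json(out / "manifest.json")
    return genome_a, genome_b, manifest


def _check_spacing(events: list[PlantedEvent], spacing: int) -> None:
    ivs = sorted((e.pos, e.pos + max(1, len(e.ref))) for e in events)
    for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
        if s1 - e0 < spacing:
            raise SimulationError(
                f"planted events closer than min_event_spacing after normalization "
                f"({e0} vs {s1}); re-run with a different seed or fewer events"
            )


def _apply_edits(genome_b: Plastome, edits: list[dict]) -> Plastome:
    """Derive genome A by applying planted edits plus their IR mirrors."""
    ira_iv = genome_b.regions["IRa"]
    irb_iv = genome_b.regions["IRb"]
    b_seq = genome_b.seq

    effective: list[dict] = []
    for ed in edits:
        effective.append(dict(ed))
        pos = ed["pos"]
        if ira_iv[0] <= pos < ira_iv[1]:
            if ed["kind"] == "SNP":
                effective.append({
                    "kind": "SNP",
                    "pos": _mirror_point(pos, ira_iv, irb_iv) - 1,
                    "ref": _COMP[ed["ref"]],
                    "alt": _COMP[ed["alt"]],
                })
            elif ed["kind"] == "insertion":
                effective.append({
                    "kind": "insertion",
                    "pos": _mirror_point(pos, ira_iv, irb_iv),
                    "ref": "",
                    "alt": revcomp(ed["alt"]),
                })
            else:
                span = len(ed["ref"])
                effective.append({
                    "kind": "deletion",
                    "pos": _mirror_point(pos + span, ira_iv, irb_iv),
                    "ref": revcomp(ed["ref"]),
                    "alt": "",
                })

    chars = list(b_seq)
    for ed in sorted(effective, key=lambda d: -d["pos"]):
        pos = ed["pos"]
        if ed["kind"] == "SNP":
            assert chars[pos] == ed["ref"], "planted SNP reference mismatch"
            chars[pos] = ed["alt"]
        elif ed["kind"] == "insertion":
            chars[pos:pos] = list(ed["alt"])
        else:
            span = len(ed["ref"])
            assert "".join(chars[pos : pos + span]) == ed["ref"], "planted deletion mismatch"
            del chars[pos : pos + span]
    a_seq = "".join(chars)

    # coordinate lift B -> A (edit intervals never contain feature/region
    # boundaries, by placement margins)
    deltas = []
    for ed in effective:
        if ed["kind"] == "insertion":
            deltas.append((ed["pos"], len(ed["alt"])))
        elif ed["kind"] == "deletion":
            deltas.append((ed["pos"] + len(ed["ref"]), -len(ed["ref"])))
    deltas.sort()
    dpos = np.array([p for p, _ in deltas], dtype=np.int64)
    dcum = np.cumsum([d for _, d in deltas]) if deltas else np.array([], dtype=np.int64)

    def lift(x: int) -> int:
        i = int(np.searchsorted(dpos, x, side="right"))
        return x + (int(dcum[i - 1]) if i > 0 else 0)

    a_features = [
        Feature(f.name, f.ftype, f.strand, [(lift(s), lift(e)) for s, e in f.exons], f.notes)
        for f in genome_b.features
    ]
    a_regions = {k: (lift(s), lift(e)) for k, (s, e) in genome_b.regions.items()}
    genome_a = Plastome("simA", a_seq, a_regions, a_features)
    if genome_a.ir_mismatches != 0:
        raise SimulationError("internal error: IR mirroring broke the repeat identity")
    return genome_a


def apply_manifest(genome_b: Plastome, manifest: TruthManifest) -> str:
    """Re-derive genome A's sequence from genome B plus the manifest (the
    round-trip identity used to validate the simulator itself)."""
    edits = [
        {"kind": e.kind, "pos": e.pos, "ref": e.ref, "alt": e.alt} for e in manifest.events
    ]
    return _apply_edits(genome_b, edits).seq
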