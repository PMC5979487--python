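"""Microsatellite (SSR) detection and cross-genome polymorphic cpSSR mining.

Detection follows the standard chloroplast MISA-style thresholds: a tract is
reported when it contains at least 10 units for mononucleotide motifs, 6 for
dinucleotide and 5 for tri- through hexanucleotide motifs.  Tracts are exact
head-to-tail repetitions (trailing partial units excluded) of a primitive
motif; overlapping candidates are resolved greedily by tract length.  Two
genomes' SSRs are matched by canonical motif plus near-identical 20-bp
flanks, and matched pairs with unequal tract lengths are the polymorphic
cpSSR markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plastome_io import Plastome, revcomp

DEFAULT_THRESHOLDS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
FLANK_LEN = 20
MAX_FLANK_MISMATCHES = 2


class SSRError(ValueError):
    pass


def canonical_rotation(motif: str) -> str:
    """Lexicographically minimal rotation (reverse complement NOT folded in,
    so (A) and (T) stay distinct)."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def is_primitive(motif: str) -> bool:
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


@dataclass
class SSRLocus:
    """One detected microsatellite tract."""

    motif: str
    canonical_motif: str
    unit_len: int
    n_units: int
    interval: tuple[int, int]  # 0-based half-open, full units only
    flank_left: str
    flank_right: str
    region_label: str
    location_name: str = ""

    @property
    def tract_len_bp(self) -> int:
        return self.interval[1] - self.interval[0]


def _raw_tracts(seq: str, unit_len: int, min_units: int):
    """Maximal exact tracts of a given unit length (may overlap across unit
    lengths); yields (start, n_units, motif).

    A tract is the full-unit prefix of a maximal stretch with exact period
    ``unit_len``; trailing partial units are excluded."""
    n = len(seq)
    if n < 2 * unit_len:
        return
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    eq = (arr[unit_len:] == arr[:-unit_len]).astype(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], eq, [0]))))
    for k in range(0, len(edges), 2):
        i, j = int(edges[k]), int(edges[k + 1])  # eq holds on [i, j)
        n_units = (j - i + unit_len) // unit_len
        if n_units < min_units:
            continue
        motif = seq[i : i + unit_len]
        if "N" not in motif and is_primitive(motif):
            yield i, n_units, motif


def find_ssrs(
    genome: Plastome,
    thresholds: dict[int, int] | None = None,
    loci=None,
) -> list[SSRLocus]:
    """Detect SSR tracts in one plastome.

    Overlapping candidates (e.g. a mono run inside a longer di tract) are
    resolved greedily: longer tract wins, ties go to the smaller start.  IR
    twin tracts are reported per copy with their own region labels.  When a
    locus catalog is supplied each SSR is annotated with its containing
    locus name.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    seq = genome.seq
    candidates = []
    for u, m in sorted(thr.items()):
        for start, n_units, motif in _raw_tracts(seq, u, m):
            candidates.append((start, n_units * u, motif))
    # greedy resolution: longest tract first, then leftmost
    candidates.sort(key=lambda c: (-c[1], c[0]))
    taken: list[tuple[int, int]] = []
    chosen = []
    for start, tlen, motif in candidates:
        iv = (start, start + tlen)
        if any(iv[0] < e and s < iv[1] for s, e in taken):
            continue
        taken.append(iv)
        chosen.append((start, tlen, motif))
    chosen.sort()

    out = []
    n = len(seq)
    for start, tlen, motif in chosen:
        u = len(motif)
        left = seq[max(0, start - FLANK_LEN) : start]
        if start - FLANK_LEN < 0:  # circular flank
            left = seq[start - FLANK_LEN :] + seq[:start]
        end = start + tlen
        right = seq[end : end + FLANK_LEN]
        if end + FLANK_LEN > n:
            right = seq[end:] + seq[: (end + FLANK_LEN) % n]
        ssr = SSRLocus(
            motif=motif,
            canonical_motif=canonical_rotation(motif),
            unit_len=u,
            n_units=tlen // u,
            interval=(start, end),
            flank_left=left,
            flank_right=right,
            region_label=genome.region_of((start + end) // 2),
        )
        if loci is not None:
            mid = (start + end) // 2
            for lc in loci:
                s, e = lc.interval
                if s <= mid < e or s <= mid + n < e:
                    ssr.location_name = lc.name
                    break
        out.append(ssr)
    return out


# ---------------------------------------------------------------------------
# cross-genome matching
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(1 for x, y in zip(a, b) if x != y)


def match_ssrs(
    ssrs_a: list[SSRLocus], ssrs_b: list[SSRLocus]
) -> tuple[list[tuple[SSRLocus, SSRLocus]], list[SSRLocus], list[SSRLocus]]:
    """One-to-one matching of SSR loci across two genomes.

    A pair is a candidate when canonical motifs are equal and each 20-bp
    flank aligns with at most 2 mismatches (no indels).  Candidates are
    assigned best-flank-identity first, ties by genomic distance; a tie
    between two free partners of identical quality is ambiguous and rejected.
    Returns (matched pairs, unmatched in A, unmatched in B).
    """
    edges = []
    for i, x in enumerate(ssrs_a):
        for j, y in enumerate(ssrs_b):
            if x.canonical_motif != y.canonical_motif:
                continue
            ml = _hamming(x.flank_left, y.flank_left)
            mr = _hamming(x.flank_right, y.flank_right)
            if ml <= MAX_FLANK_MISMATCHES and mr <= MAX_FLANK_MISMATCHES:
                dist = abs(x.interval[0] - y.interval[0])
                edges.append((ml + mr, dist, i, j))
    edges.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for k, (mm, dist, i, j) in enumerate(edges):
        if i in used_a or j in used_b:
            continue
        # an equally good competing edge sharing an endpoint is ambiguous
        for mm2, dist2, i2, j2 in edges[k + 1 :]:
            if (mm2, dist2) != (mm, dist):
                break
            if (i2 == i and j2 not in used_b) or (j2 == j and i2 not in used_a):
                raise SSRError(
                    f"ambiguous SSR match: A[{ssrs_a[i].interval[0] + 1}] / "
                    f"B[{ssrs_b[j].interval[0] + 1}] vs A[{ssrs_a[i2].interval[0] + 1}] / "
                    f"B[{ssrs_b[j2].interval[0] + 1}] (motif {ssrs_a[i].motif})"
                )
        used_a.add(i)
        used_b.add(j)
        pairs.append((ssrs_a[i], ssrs_b[j]))
    unmatched_a = [x for i, x in enumerate(ssrs_a) if i not in used_a]
    unmatched_b = [y for j, y in enumerate(ssrs_b) if j not in used_b]
    pairs.sort(key=lambda p: p[0].interval)
    return pairs, unmatched_a, unmatched_b


@dataclass
class PolymorphicSSR:
    """A matched SSR pair with different tract lengths in the two genomes."""

    ssr_a: SSRLocus
    ssr_b: SSRLocus

    @property
    def len_a(self) -> int:
        return self.ssr_a.tract_len_bp

    @property
    def len_b(self) -> int:
        return self.ssr_b.tract_len_bp

    @property
    def length_variation(self) -> str:
        lo, hi = sorted((self.len_a, self.len_b))
        return f"{lo}–{hi}"


def call_polymorphic(pairs: list[tuple[SSRLocus, SSRLocus]]) -> list[PolymorphicSSR]:
    """Matched pairs whose tract lengths differ between the genomes."""
    return [PolymorphicSSR(a, b) for a, b in pairs if a.tract_len_bp != b.tract_len_bp]


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def ssr_table(ssrs: list[SSRLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif": [f"({s.motif})" for s in ssrs],
            "unit_len": [s.unit_len for s in ssrs],
            "n_units": [s.n_units for s in ssrs],
            "tract_len_bp": [s.tract_len_bp for s in ssrs],
            "start": [s.interval[0] + 1 for s in ssrs],
            "end": [s.interval[1] for s in ssrs],
            "location": [s.location_name for s in ssrs],
            "region": [s.region_label for s in ssrs],
        }
    )


def polymorphic_table(poly: list[PolymorphicSSR]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif": [f"({p.ssr_a.motif})" for p in poly],
            "length_variation_bp": [p.length_variation for p in poly],
            "location": [p.ssr_a.location_name for p in poly],
            "region": [p.ssr_a.region_label for p in poly],
        }
    )
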