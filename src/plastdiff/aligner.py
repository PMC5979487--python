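"""Global pairwise alignment of homologous plastome loci.

Implements Needleman–Wunsch with affine gap penalties (Gotoh three-state DP)
and deterministic traceback, indel left-normalization for stable event
coordinates inside repeats, and a k-mer-anchor colinearity check between
whole genomes.

Scoring model: a gap of length k costs ``gap_open + k * gap_extend``; N is
scored 0 against any base (neither match nor mismatch) and columns containing
N are ignored by downstream event calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .plastome_io import Plastome, revcomp

DEFAULT_PARAMS = (2.0, -3.0, -5.0, -2.0)  # match, mismatch, gap_open, gap_extend

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_NEG = -1.0e18


class AlignmentError(ValueError):
    pass


@dataclass
class PairwiseAlignment:
    """A gapped global alignment of two sequences.

    ``aligned_a`` and ``aligned_b`` are equal-length strings over
    {A,C,G,T,N,-}; no column is a gap in both rows.
    """

    aligned_a: str
    aligned_b: str
    score: float
    params: tuple[float, float, float, float] = DEFAULT_PARAMS

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace("-", "")

    def __len__(self) -> int:
        return len(self.aligned_a)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.uint8)
    except KeyError as exc:
        raise AlignmentError(f"sequence contains invalid character {exc.args[0]!r}") from None


@njit(cache=True)
def _gotoh(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover - numba
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # ends with a-base over gap ("up")
    Y = np.full((n + 1, m + 1), _NEG)  # ends with gap over b-base ("left")
    # traceback: predecessor state per cell per state (0=M,1=X,2=Y)
    tM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tY = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + i * gap_extend
        tX[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Y[0, j] = gap_open + j * gap_extend
        tY[0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            if ai == 4 or bj == 4:
                s = 0.0
            elif ai == bj:
                s = match
            else:
                s = mismatch
            # M: diagonal move; tie preference M > X > Y
            best = M[i - 1, j - 1]
            st = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                st = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                st = 2
            M[i, j] = best + s
            tM[i, j] = st
            # X: consume a[i-1] against a gap
            open_x = M[i - 1, j] + gap_open + gap_extend
            ext_x = X[i - 1, j] + gap_extend
            open_xy = Y[i - 1, j] + gap_open + gap_extend
            best = open_x
            st = 0
            if ext_x > best:
                best = ext_x
                st = 1
            if open_xy > best:
                best = open_xy
                st = 2
            X[i, j] = best
            tX[i, j] = st
            # Y: consume b[j-1] against a gap
            open_y = M[i, j - 1] + gap_open + gap_extend
            open_yx = X[i, j - 1] + gap_open + gap_extend
            ext_y = Y[i, j - 1] + gap_extend
            best = open_y
            st = 0
            if open_yx > best:
                best = open_yx
                st = 1
            if ext_y > best:
                best = ext_y
                st = 2
            Y[i, j] = best
            tY[i, j] = st
    # final state, tie preference M > X > Y
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    # traceback: emit move codes (0 diag, 1 up, 2 left), reversed
    moves = np.empty(n + m, dtype=np.uint8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            moves[k] = 0
            state = tM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            moves[k] = 1
            state = tX[i, j]
            i -= 1
        else:
            moves[k] = 2
            state = tY[i, j]
            j -= 1
        k += 1
    return score, moves[:k][::-1].copy()


def global_align(
    seq_a: str,
    seq_b: str,
    params: tuple[float, float, float, float] = DEFAULT_PARAMS,
) -> PairwiseAlignment:
    """Optimal global alignment of two DNA sequences under affine gaps.

    Traceback ties are broken deterministically, preferring diagonal over up
    (gap in ``seq_b``) over left (gap in ``seq_a``).
    """
    if not seq_a or not seq_b:
        raise AlignmentError("cannot align empty sequences")
    a = _encode(seq_a.upper())
    b = _encode(seq_b.upper())
    score, moves = _gotoh(a, b, *(float(x) for x in params))
    out_a = []
    out_b = []
    i = j = 0
    for mv in moves:
        if mv == 0:
            out_a.append(seq_a[i])
            out_b.append(seq_b[j])
            i += 1
            j += 1
        elif mv == 1:
            out_a.append(seq_a[i])
            out_b.append("-")
            i += 1
        else:
            out_a.append("-")
            out_b.append(seq_b[j])
            j += 1
    return PairwiseAlignment("".join(out_a), "".join(out_b), float(score), tuple(params))


def score_alignment(aligned_a: str, aligned_b: str, params=DEFAULT_PARAMS) -> float:
    """Recompute the affine-gap score of a gapped pair from its strings."""
    match, mismatch, gap_open, gap_extend = params
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" and y == "-":
            raise AlignmentError("column is gap in both rows")
        if x == "-":
            if not in_gap_a:
                score += gap_open
            score += gap_extend
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            if not in_gap_b:
                score += gap_open
            score += gap_extend
            in_gap_a, in_gap_b = False, True
        else:
            in_gap_a = in_gap_b = False
            if x == "N" or y == "N":
                score += 0.0
            elif x == y:
                score += match
            else:
                score += mismatch
    return score


# ---------------------------------------------------------------------------
# indel left-normalization
# ---------------------------------------------------------------------------

def _shift_gaps_left(gapped: list[str], other: list[str]) -> bool:
    """Shift every gap run in ``gapped`` maximally left; returns True on change.

    A run may step left past a column whose ``other`` base equals the base the
    run would expose at its right edge, which preserves the match/mismatch
    structure and thus the score.
    """
    changed = False
    n = len(gapped)
    i = 0
    while i < n:
        if gapped[i] != "-":
            i += 1
            continue
        s = i
        e = i
        while e < n and gapped[e] == "-":
            e += 1
        while s > 0 and gapped[s - 1] != "-" and other[s - 1] != "-" and other[s - 1] == other[e - 1]:
            gapped[e - 1] = gapped[s - 1]
            gapped[s - 1] = "-"
            s -= 1
            e -= 1
            changed = True
        i = e if e > i else i + 1
    return changed


def left_normalize_indels(aln: PairwiseAlignment) -> PairwiseAlignment:
    """Return an equivalent alignment with every gap run shifted maximally left.

    Idempotent; the ungapped sequences are preserved exactly and the score is
    recomputed from the normalized strings.
    """
    a = list(aln.aligned_a)
    b = list(aln.aligned_b)
    while True:
        ch1 = _shift_gaps_left(a, b)
        ch2 = _shift_gaps_left(b, a)
        if not (ch1 or ch2):
            break
    na, nb = "".join(a), "".join(b)
    return PairwiseAlignment(na, nb, score_alignment(na, nb, aln.params), aln.params)


def is_left_normalized(aln: PairwiseAlignment) -> bool:
    norm = left_normalize_indels(aln)
    return norm.aligned_a == aln.aligned_a and norm.aligned_b == aln.aligned_b


# ---------------------------------------------------------------------------
# whole-genome colinearity
# ---------------------------------------------------------------------------

def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        counts[km] = counts.get(km, 0) + 1
        pos[km] = i
    return {km: p for km, p in pos.items() if counts[km] == 1}


def colinearity_check(
    genome_a: Plastome, genome_b: Plastome, k: int = 25, max_reverse_fraction: float = 0.01
) -> tuple[bool, pd.DataFrame]:
    """Check that two plastomes are syntenic (no rearrangements).

    Anchors are k-mers unique in both genomes (IR copies are therefore
    excluded automatically).  The genomes are colinear iff the shared anchors
    occur in the same relative order and no more than ``max_reverse_fraction``
    of genome A's unique k-mers match genome B only in reverse-complement
    orientation (which would indicate an inversion).
    """
    if k < 15:
        raise AlignmentError("anchor length k must be >= 15")
    ua = _unique_kmers(genome_a.seq, k)
    ub = _unique_kmers(genome_b.seq, k)
    shared = [(pa, ub[km], km) for km, pa in ua.items() if km in ub]
    shared.sort()
    table = pd.DataFrame(shared, columns=["pos_a", "pos_b", "kmer"])
    ordered = bool((table["pos_b"].diff().dropna() > 0).all()) if len(table) > 1 else True
    ub_rc = {revcomp(km) for km in ub}
    n_reverse = sum(1 for km in ua if km not in ub and km in ub_rc)
    no_inversion = n_reverse <= max_reverse_fraction * max(1, len(ua))
    return ordered and no_inversion and len(table) > 0, table
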