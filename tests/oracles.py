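"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's own algorithms: an exhaustive
recursive affine-gap aligner, a positional SSR tract scanner, and a
dictionary-based codon translation built from the NCBI table data.
"""

from __future__ import annotations

import functools

from Bio.Data import CodonTable

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]


def translate11(codon: str) -> str:
    """Amino acid (or '*') for a codon under the bacterial/plastid code,
    via the NCBI forward table rather than a translation routine."""
    if codon in _TABLE11.stop_codons:
        return "*"
    return _TABLE11.forward_table[codon]


def brute_force_affine_score(
    a: str, b: str, match=2.0, mismatch=-3.0, gap_open=-5.0, gap_extend=-2.0
) -> float:
    """Optimal global alignment score by exhaustive recursion.

    State: position in each sequence plus which row (if any) the previous
    column gapped, so affine gap runs are charged gap_open once.
    """

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        # state: 0 = previous column aligned, 1 = gap in b ("up"), 2 = gap in a
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            if a[i] == "N" or b[j] == "N":
                s = 0.0
            options.append(s + best(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open + gap_extend
            options.append(cost + best(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open + gap_extend
            options.append(cost + best(i, j + 1, 2))
        return max(options)

    result = best(0, 0, 0)
    best.cache_clear()
    return result


def brute_force_ssr_tracts(seq: str, unit_len: int, min_units: int):
    """All maximal primitive tracts of one unit length by positional scan."""
    out = []
    n = len(seq)
    for i in range(n - unit_len + 1):
        motif = seq[i : i + unit_len]
        # maximal on the left: the periodic stretch must not extend to i-1
        if i > 0 and seq[i - 1] == seq[i - 1 + unit_len]:
            continue
        j = i + unit_len
        while j < n and seq[j] == seq[j - unit_len]:
            j += 1
        n_units = (j - i) // unit_len
        if n_units < min_units or "N" in motif:
            continue
        if any(
            motif == motif[:p] * (unit_len // p)
            for p in range(1, unit_len)
            if unit_len % p == 0
        ):
            continue  # non-primitive motif
        out.append((i, n_units, motif))
    return out
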