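"""Independent brute-force oracles used by the alignment tests.

These enumerate every monotone alignment path explicitly (exponential
time, so only usable for tiny sequences) and are deliberately written
without any dynamic-programming recurrence, so they share no structure
with the implementation they check.
"""

from __future__ import annotations


def enumerate_global_score(a, b, substitution, gap_open, gap_extend):
    """Maximum affine-gap global alignment score by exhaustive enumeration.

    A gap of length L costs gap_open + (L-1)*gap_extend.  ``substitution``
    is a callable (x, y) -> score.
    """
    la, lb = len(a), len(b)
    best = [float("-inf")]

    def walk(i, j, last, score):
        if i == la and j == lb:
            if score > best[0]:
                best[0] = score
            return
        if i < la and j < lb:
            walk(i + 1, j + 1, "M", score + substitution(a[i], b[j]))
        if i < la:
            cost = gap_extend if last == "I" else gap_open
            walk(i + 1, j, "I", score - cost)
        if j < lb:
            cost = gap_extend if last == "D" else gap_open
            walk(i, j + 1, "D", score - cost)

    walk(0, 0, None, 0.0)
    return best[0]


def enumerate_local_score(a, b, substitution, gap_open, gap_extend):
    """Best local score: maximum global score over all substring pairs."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = enumerate_global_score(
                        a[i1:i2], b[j1:j2], substitution, gap_open, gap_extend
                    )
                    if s > best:
                        best = s
    return best


def nt_substitution(match=5.0, mismatch=-4.0):
    def sub(x, y):
        return match if (x == y and x != "N") else mismatch

    return sub


def blosum62_substitution():
    from Bio.Align import substitution_matrices

    matrix = substitution_matrices.load("BLOSUM62")

    def sub(x, y):
        return float(matrix[x, y])

    return sub
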