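"""Pairwise alignment kernels, translation utilities and e-value statistics.

Every similarity decision the pipeline makes — translated domain search,
80/80/80 reclassification of unclassified elements, and 5'/3'-LTR
comparison for insertion dating — is routed through the two entry points
here, :func:`global_align` (Needleman–Wunsch, affine gaps, end gaps
penalised) and :func:`local_align` (Smith–Waterman).  The dynamic
programme itself is delegated to :class:`Bio.Align.PairwiseAligner`;
this module owns the scoring conventions, coordinate bookkeeping and
identity/coverage accounting, which is where pipelines usually disagree.

Conventions
-----------
* Nucleotide scoring defaults to +5/-4 with gap open 10 / extend 0.5
  (EMBOSS-style).  ``N`` scores as a mismatch against everything,
  including another ``N`` — deliberately conservative so that masked or
  ambiguous sequence can never push an element over the 80/80/80
  identity threshold.
* Protein scoring defaults to BLOSUM62 with the same gap costs.
* A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
* All coordinates are 0-based half-open on the ungapped inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "AlignmentResult",
    "ScoringScheme",
    "global_align",
    "local_align",
    "translate",
    "six_frame",
    "revcomp",
    "evalue",
]

# Ungapped Karlin–Altschul constants for BLOSUM62 (fixed approximation;
# see evalue()).
_KA_LAMBDA = 0.3176
_KA_K = 0.134

_NT_ALPHABET = "ACGTN"
FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class ScoringScheme:
    """Scoring parameters for either nucleotide or protein alignment.

    ``kind`` selects the alphabet: ``"nucleotide"`` uses a simple
    match/mismatch matrix, ``"protein"`` a named substitution matrix
    (BLOSUM62 by default).  Gap penalties are positive costs.
    """

    kind: str = "nucleotide"
    match: float = 5.0
    mismatch: float = -4.0
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("nucleotide", "protein"):
            raise ValueError(f"unknown scoring kind: {self.kind!r}")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")


NT_SCHEME = ScoringScheme(kind="nucleotide")
PROTEIN_SCHEME = ScoringScheme(kind="protein")


@dataclass
class AlignmentResult:
    """One pairwise alignment with identity and coverage accounting.

    ``aligned_a``/``aligned_b`` are equal-length gapped strings.
    ``identity_pct`` is exact matches over all aligned columns
    (gap columns count against identity; there are no double-gap
    columns in a pairwise alignment).  ``query_cov_pct`` is the
    percentage of the full query ``a`` whose residues appear in the
    alignment.  ``aligned_bases`` counts columns where both rows carry
    a residue — the quantity the 80-bases leg of the 80/80/80 rule
    inspects.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    query_cov_pct: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    mode: str

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def aligned_bases(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x != "-" and y != "-"
        )


def _nt_matrix(scheme: ScoringScheme):
    return _nt_matrix_cached(scheme.match, scheme.mismatch)


@lru_cache(maxsize=8)
def _nt_matrix_cached(match: float, mismatch: float):
    m = substitution_matrices.Array(_NT_ALPHABET, dims=2)
    for x in _NT_ALPHABET:
        for y in _NT_ALPHABET:
            if x == y and x != "N":
                m[x, y] = match
            else:
                # N against anything (incl. N) is a mismatch.
                m[x, y] = mismatch
    return m


@lru_cache(maxsize=8)
def _protein_matrix(name: str):
    return substitution_matrices.load(name)


def _make_aligner(scheme: ScoringScheme, mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    if scheme.kind == "nucleotide":
        aligner.substitution_matrix = _nt_matrix(scheme)
    else:
        aligner.substitution_matrix = _protein_matrix(scheme.matrix_name)
    aligner.open_gap_score = -scheme.gap_open
    aligner.extend_gap_score = -scheme.gap_extend
    aligner.mode = mode
    return aligner


def _check_alphabet(seq: str, scheme: ScoringScheme, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty sequence cannot be aligned")
    seq = seq.upper()
    if scheme.kind == "nucleotide":
        bad = set(seq) - set(_NT_ALPHABET)
        if bad:
            raise ValueError(f"{name}: non-ACGTN characters {sorted(bad)}")
    return seq


def _identity_pct(aligned_a: str, aligned_b: str) -> float:
    n = len(aligned_a)
    if n == 0:
        return 0.0
    matches = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    return 100.0 * matches / n


def _result_from_biopython(alignment, a: str, mode: str) -> AlignmentResult:
    aligned_a = str(alignment[0])
    aligned_b = str(alignment[1])
    coords = alignment.coordinates
    q_start, q_end = int(coords[0, 0]), int(coords[0, -1])
    s_start, s_end = int(coords[1, 0]), int(coords[1, -1])
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        identity_pct=_identity_pct(aligned_a, aligned_b),
        query_cov_pct=100.0 * (q_end - q_start) / len(a),
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        mode=mode,
    )


def global_align(a: str, b: str, scheme: ScoringScheme = NT_SCHEME) -> AlignmentResult:
    """Optimal global (Needleman–Wunsch) alignment with affine gaps.

    End gaps are penalised, so both sequences are covered end to end.
    The first optimal traceback reported by the aligner is taken, which
    is deterministic for fixed inputs.
    """
    a = _check_alphabet(a, scheme, "a")
    b = _check_alphabet(b, scheme, "b")
    aligner = _make_aligner(scheme, "global")
    alignment = next(iter(aligner.align(a, b)))
    return _result_from_biopython(alignment, a, "global")


def local_align(
    a: str,
    b: str,
    scheme: ScoringScheme = NT_SCHEME,
    max_hits: int = 1,
    min_score: float = 1.0,
) -> list[AlignmentResult]:
    """Best local (Smith–Waterman) hits between ``a`` and ``b``.

    The optimal local alignment is reported first.  When ``max_hits``
    > 1, further non-overlapping hits are obtained by masking the query
    span of each reported hit (rewriting it to a symbol that scores as
    a mismatch everywhere) and re-running the search, BLAST-style.
    Hits below ``min_score`` are not reported; an empty list means no
    local similarity above that floor.
    """
    a = _check_alphabet(a, scheme, "a")
    b = _check_alphabet(b, scheme, "b")
    aligner = _make_aligner(scheme, "local")
    mask_char = "N" if scheme.kind == "nucleotide" else "X"
    hits: list[AlignmentResult] = []
    work = a
    for _ in range(max_hits):
        score = aligner.score(work, b)
        if score < min_score:
            break
        alignment = next(iter(aligner.align(work, b)))
        res = _result_from_biopython(alignment, a, "local")
        if res.q_end <= res.q_start:
            break
        hits.append(res)
        work = work[: res.q_start] + mask_char * (res.q_end - res.q_start) + work[res.q_end :]
    return hits


def revcomp(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def translate(nt: str, frame: int) -> str:
    """Translate ``nt`` in one of the six frames (+1..+3, -1..-3).

    Negative frames translate the reverse complement.  Stop codons are
    rendered as ``*``; a trailing partial codon is dropped.
    """
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    nt = nt.upper()
    if len(nt) < 3:
        raise ValueError("sequence shorter than one codon")
    if frame < 0:
        nt = revcomp(nt)
    offset = abs(frame) - 1
    sub = nt[offset : offset + 3 * ((len(nt) - offset) // 3)]
    return str(Seq(sub).translate(table=standard_dna_table))


def six_frame(nt: str) -> dict[int, str]:
    """All six translation frames of ``nt``, keyed by frame."""
    return {frame: translate(nt, frame) for frame in FRAMES}


def evalue(score: float, m: int, n: int, scheme: ScoringScheme = PROTEIN_SCHEME) -> float:
    """Karlin–Altschul expect value E = K·m·n·exp(−λS).

    Uses the published ungapped BLOSUM62 constants (λ = 0.3176,
    K = 0.134) as a fixed approximation for all schemes; the pipeline
    only uses e-values to threshold translated protein searches, where
    true hits sit orders of magnitude below the cutoff, so gapped
    recalibration is not warranted.
    """
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths m and n must be positive")
    if score < 0:
        raise ValueError("score must be non-negative")
    exponent = -_KA_LAMBDA * score
    return _KA_K * m * n * math.exp(exponent)
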