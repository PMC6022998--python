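"""Insertion-time estimation from 5'/3'-LTR divergence.

At insertion the two LTRs of an element are identical (both are copied
from the same template during reverse transcription), so their
divergence clocks the time since insertion.  The two LTRs are aligned
globally, the Kimura 2-parameter (K2P) distance K is computed over
gap-free columns, and the age follows from

    T = K / (2 r)

where r is the per-site, per-year substitution rate (default
1.3e-8, a plant average; configurable) and the factor 2 accounts for
both LTRs accumulating substitutions independently.

K2P separates transitions (purine<->purine, pyrimidine<->pyrimidine;
proportion P) from transversions (proportion Q):

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Columns containing a gap or an N are excluded from P and Q.  When the
log arguments are non-positive the distance is saturated and the
element is flagged rather than clamped, so saturated pairs never leak
into old-age histogram bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from . import align
from .align import NT_SCHEME

__all__ = [
    "InsertionTimeEstimate",
    "SaturatedDivergence",
    "NoLTRFound",
    "k2p_distance",
    "insertion_time",
    "date_element",
    "locate_ltr_pair",
    "full_length_filter",
    "bin_by_age",
]

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_VALID = {"A", "C", "G", "T"}


class SaturatedDivergence(ValueError):
    """LTR divergence too high for the K2P correction to be defined."""


class NoLTRFound(ValueError):
    """No terminal direct repeat meeting the search thresholds."""


@dataclass
class InsertionTimeEstimate:
    element_id: str
    lineage_or_category: str
    aligned_sites: int
    P: float
    Q: float
    K: float | None  # None when saturated
    rate: float
    T_years: float | None
    T_my: float | None
    bin_index: int | None
    saturated: bool = False


def k2p_distance(aligned_a: str, aligned_b: str) -> tuple[float, float, float]:
    """Kimura 2-parameter distance from two gapped, equal-length rows.

    Returns ``(P, Q, K)`` where P and Q are the transition and
    transversion proportions over gap-free (and N-free) columns.
    Raises :class:`SaturatedDivergence` when the correction is
    undefined, and ``ValueError`` when no comparable column exists.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    sites = transitions = transversions = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x not in _VALID or y not in _VALID:
            continue
        sites += 1
        if x == y:
            continue
        same_class = (x in _PURINES) == (y in _PURINES)
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("no gap-free comparable columns between the LTRs")
    P = transitions / sites
    Q = transversions / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDivergence(
            f"K2P undefined at P={P:.4f}, Q={Q:.4f} (divergence saturated)"
        )
    K = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return P, Q, K + 0.0  # normalize -0.0 for identical inputs


def insertion_time(K: float, rate: float) -> float:
    """Age in years: T = K / (2 rate)."""
    if K < 0:
        raise ValueError("K2P distance cannot be negative")
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    return K / (2.0 * rate)


def date_element(
    element_id: str,
    ltr5: str,
    ltr3: str,
    rate: float = 1.3e-8,
    label: str = "NONE",
    bin_width_my: float = 0.5,
) -> InsertionTimeEstimate:
    """Align the two LTRs of one element and date its insertion."""
    res = align.global_align(ltr5, ltr3, NT_SCHEME)
    try:
        P, Q, K = k2p_distance(res.aligned_a, res.aligned_b)
    except SaturatedDivergence:
        # P/Q are still computable; only the correction diverges.
        sites, P, Q = _raw_proportions(res.aligned_a, res.aligned_b)
        return InsertionTimeEstimate(
            element_id, label, sites, P, Q, None, rate, None, None, None, saturated=True
        )
    sites, _, _ = _raw_proportions(res.aligned_a, res.aligned_b)
    T = insertion_time(K, rate)
    T_my = T / 1e6
    return InsertionTimeEstimate(
        element_id,
        label,
        sites,
        P,
        Q,
        K,
        rate,
        T,
        T_my,
        int(T_my // bin_width_my),
    )


def _raw_proportions(aligned_a: str, aligned_b: str) -> tuple[int, float, float]:
    sites = ts = tv = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x not in _VALID or y not in _VALID:
            continue
        sites += 1
        if x != y:
            if (x in _PURINES) == (y in _PURINES):
                ts += 1
            else:
                tv += 1
    if sites == 0:
        return 0, 0.0, 0.0
    return sites, ts / sites, tv / sites


def locate_ltr_pair(
    full_seq: str,
    min_len: int = 100,
    max_len: int = 5000,
    min_identity: float = 70.0,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Locate the terminal direct repeat (the LTR pair) of an element.

    Only used when the input carries bare sequences without predictor
    coordinates.  The terminal ``max_len`` windows at each end are
    compared by local alignment; the best hit is accepted when it is at
    least ``min_len`` long on both copies, at ``min_identity`` percent
    identity, and the two spans do not overlap.  Returns 0-based
    half-open spans ``((s5, e5), (s3, e3))`` on the full sequence.
    """
    full_seq = full_seq.upper()
    n = len(full_seq)
    if n <= 2 * min_len:
        raise NoLTRFound(f"sequence of {n} bp too short for two {min_len}-bp LTRs")
    w = min(max_len, n // 2)
    prefix = full_seq[:w]
    suffix = full_seq[n - w :]
    # Seed-and-verify, anchored at both termini: a terminal direct
    # repeat of length L places prefix[i] against suffix[w - L + i],
    # i.e. all its shared k-mers lie on the dot-plot diagonal d = w - L.
    # Exact k-mer seeds vote for diagonals; candidate LTR lengths are
    # then verified by global alignment of the terminal slices.  This is
    # robust to repetitive internal sequence, which distracts an
    # unanchored local search.
    k = 12
    suffix_kmers: dict[str, list[int]] = {}
    for j in range(w - k + 1):
        suffix_kmers.setdefault(suffix[j : j + k], []).append(j)
    votes: dict[int, int] = {}
    for i in range(w - k + 1):
        for j in suffix_kmers.get(prefix[i : i + k], ()):
            d = j - i
            votes[d] = votes.get(d, 0) + 1
    candidates = sorted(votes, key=lambda d: (-votes[d], d))[:5]
    reasons = []
    for d in candidates:
        L = w - d
        if not (min_len <= L <= max_len) or 2 * L > n:
            reasons.append(f"candidate length {L} bp outside limits")
            continue
        res = align.global_align(full_seq[:L], full_seq[n - L :], NT_SCHEME)
        if res.identity_pct < min_identity:
            reasons.append(f"candidate length {L} bp at {res.identity_pct:.1f}% identity")
            continue
        return (0, L), (n - L, n)
    if not candidates:
        raise NoLTRFound("no shared seeds between terminal windows")
    raise NoLTRFound(
        "no terminal repeat meeting thresholds (" + "; ".join(reasons) + ")"
    )


def full_length_filter(
    copies: list,
    reference,
    min_identity: float = 80.0,
    min_cov: float = 100.0,
) -> list:
    """Keep copies that are full length with respect to their reference.

    A copy passes when its global alignment to the reference covers at
    least ``min_cov`` percent of the reference positions (100 by
    default — strict: every reference base must be aligned to a copy
    base) at ``min_identity`` percent nucleotide identity.  ``copies``
    and ``reference`` are objects with ``full_seq`` (e.g.
    ``PredictorRecord``) or plain strings.
    """
    ref_seq = getattr(reference, "full_seq", reference)
    kept = []
    for copy in copies:
        seq = getattr(copy, "full_seq", copy)
        res = align.global_align(seq, ref_seq, NT_SCHEME)
        covered = sum(
            1
            for x, y in zip(res.aligned_a, res.aligned_b)
            if x != "-" and y != "-"
        )
        coverage = 100.0 * covered / len(ref_seq)
        if coverage >= min_cov and res.identity_pct >= min_identity:
            kept.append(copy)
    return kept


def bin_by_age(
    estimates: list[InsertionTimeEstimate],
    bin_width_my: float = 0.5,
) -> pd.DataFrame:
    """Per-group age histogram in fixed-width million-year bins.

    Groups are the estimates' ``lineage_or_category`` labels.  Returns
    a tidy DataFrame with columns ``group``, ``bin_index``,
    ``bin_start_my``, ``bin_end_my``, ``count``, ``percent`` where
    percents sum to 100 within each group over dated records; saturated
    records are excluded from bins and reported in a separate
    ``SATURATED`` count column convention (group rows with
    ``bin_index == -1``).
    """
    rows = []
    dated = [e for e in estimates if not e.saturated]
    saturated = [e for e in estimates if e.saturated]
    groups = sorted({e.lineage_or_category for e in estimates})
    for group in groups:
        g_dated = [e for e in dated if e.lineage_or_category == group]
        counts: dict[int, int] = {}
        for e in g_dated:
            idx = int(e.T_my // bin_width_my)
            counts[idx] = counts.get(idx, 0) + 1
        total = len(g_dated)
        for idx in sorted(counts):
            rows.append(
                {
                    "group": group,
                    "bin_index": idx,
                    "bin_start_my": idx * bin_width_my,
                    "bin_end_my": (idx + 1) * bin_width_my,
                    "count": counts[idx],
                    "percent": 100.0 * counts[idx] / total,
                }
            )
        n_sat = sum(1 for e in saturated if e.lineage_or_category == group)
        if n_sat:
            rows.append(
                {
                    "group": group,
                    "bin_index": -1,
                    "bin_start_my": float("nan"),
                    "bin_end_my": float("nan"),
                    "count": n_sat,
                    "percent": float("nan"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["group", "bin_index", "bin_start_my", "bin_end_my", "count", "percent"],
    )
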