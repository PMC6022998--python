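"""Translated protein-domain annotation of candidate LTR-RT elements.

Each element is translated in all six frames and searched by exact
local (Smith–Waterman) alignment against a reference library of the
six canonical retroelement domains — GAG (capsid), AP (aspartic
protease), RT (reverse transcriptase), RNASEH (ribonuclease H),
INT (integrase) and ENV (envelope).  Reference headers carry the
superfamily code (RLC = Copia, RLG = Gypsy), lineage and family, so a
hit simultaneously tells the classifier *which* domain is present and
*whose* it looks like.

Reference FASTA header dialect: ``DOMAIN_CODE_LINEAGE_FAMILY`` joined
by underscores, e.g. ``RT_RLG_Del_Peabody``.  Structural domains that
carry no superfamily signal (e.g. a generic GAG) may use ``NONE`` for
code/lineage/family, or omit the trailing fields.

No heuristic seeding is used: element libraries are small enough
(10^2–10^4 elements against dozens of references) that exact dynamic
programming over every frame/reference pair is affordable and keeps
results exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from . import align
from .align import FRAMES, AlignmentResult, PROTEIN_SCHEME
from .seqio import PipelineConfig, PredictorRecord, read_fasta

__all__ = [
    "DOMAIN_KINDS",
    "SUPERFAMILY_CODES",
    "ReferenceDomain",
    "DomainHit",
    "load_reference_library",
    "scan_domains",
    "best_hit_per_domain",
]

DOMAIN_KINDS = ("GAG", "AP", "RT", "RNASEH", "INT", "ENV")
SUPERFAMILY_CODES = ("RLC", "RLG", "NONE")

_AA_OK = set("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass(frozen=True)
class ReferenceDomain:
    ref_id: str
    domain_kind: str
    superfamily_code: str
    lineage: str  # "NONE" when unlabelled
    family: str
    aa_seq: str


@dataclass
class DomainHit:
    """One translated-search match of an element region to a reference.

    ``element_nt_start``/``end`` are 0-based half-open forward-strand
    coordinates of the matched region on the element, regardless of
    frame sign; ``frame`` is the translation frame the match was found
    in (+1..+3 forward, -1..-3 reverse complement).
    """

    element_id: str
    domain_kind: str
    superfamily_code: str
    lineage: str
    family: str
    score: float
    evalue: float
    frame: int
    element_nt_start: int
    element_nt_end: int
    ref_id: str
    aa_alignment: AlignmentResult


def _parse_header(header: str) -> tuple[str, str, str, str]:
    parts = header.split("_")
    if len(parts) < 2:
        raise ValueError(
            f"reference header {header!r} does not match DOMAIN_CODE_LINEAGE_FAMILY"
        )
    domain, code = parts[0].upper(), parts[1].upper()
    if domain not in DOMAIN_KINDS:
        raise ValueError(f"reference header {header!r}: unknown domain token {domain!r}")
    if code not in SUPERFAMILY_CODES:
        raise ValueError(f"reference header {header!r}: unknown superfamily code {code!r}")
    lineage = parts[2] if len(parts) > 2 else "NONE"
    family = parts[3] if len(parts) > 3 else "NONE"
    return domain, code, lineage, family


def load_reference_library(fasta_path) -> list[ReferenceDomain]:
    """Load a lineage-labelled reference domain library from FASTA."""
    records = read_fasta_protein(fasta_path)
    library = []
    for rec_id, aa_seq in records:
        domain, code, lineage, family = _parse_header(rec_id)
        bad = set(aa_seq) - _AA_OK
        if bad:
            raise ValueError(f"reference {rec_id}: non-amino-acid characters {sorted(bad)}")
        library.append(
            ReferenceDomain(
                ref_id=rec_id,
                domain_kind=domain,
                superfamily_code=code,
                lineage=lineage,
                family=family,
                aa_seq=aa_seq,
            )
        )
    return library


def read_fasta_protein(path) -> list[tuple[str, str]]:
    """Minimal protein FASTA reader (ids + upper-cased sequences)."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq).upper()))
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def _aa_span_to_nt(frame: int, aa_start: int, aa_end: int, nt_len: int) -> tuple[int, int]:
    """Map an amino-acid span in a translation frame back to forward-strand nt."""
    offset = abs(frame) - 1
    lo = offset + 3 * aa_start
    hi = offset + 3 * aa_end
    if frame > 0:
        return lo, hi
    return nt_len - hi, nt_len - lo


def scan_domains(
    element: PredictorRecord,
    library: list[ReferenceDomain],
    cfg: PipelineConfig | None = None,
) -> list[DomainHit]:
    """Six-frame exact local search of one element against the library.

    For every (frame, reference) pair the optimal local protein
    alignment is computed; hits are kept when their Karlin–Altschul
    e-value is at or below ``cfg.evalue_cutoff`` and their raw score at
    least ``cfg.min_raw_score`` (a floor guarding against short
    spurious maxima on tiny search spaces).  The returned list is
    sorted by score (desc), then element start (asc), then reference id.
    """
    cfg = cfg or PipelineConfig()
    if not library:
        raise ValueError("empty reference library")
    nt = element.full_seq
    if len(nt) < 3:
        warnings.warn(f"{element.element_id}: element shorter than one codon; no scan")
        return []
    frames = align.six_frame(nt)
    total_ref_aa = sum(len(r.aa_seq) for r in library)
    hits: list[DomainHit] = []
    for frame in FRAMES:
        aa = frames[frame]
        if not aa:
            continue
        for ref in library:
            found = align.local_align(
                aa, ref.aa_seq, PROTEIN_SCHEME, max_hits=1, min_score=cfg.min_raw_score
            )
            if not found:
                continue
            res = found[0]
            ev = align.evalue(res.score, len(aa), total_ref_aa, PROTEIN_SCHEME)
            if ev > cfg.evalue_cutoff:
                continue
            nt_start, nt_end = _aa_span_to_nt(frame, res.q_start, res.q_end, len(nt))
            hits.append(
                DomainHit(
                    element_id=element.element_id,
                    domain_kind=ref.domain_kind,
                    superfamily_code=ref.superfamily_code,
                    lineage=ref.lineage,
                    family=ref.family,
                    score=res.score,
                    evalue=ev,
                    frame=frame,
                    element_nt_start=nt_start,
                    element_nt_end=nt_end,
                    ref_id=ref.ref_id,
                    aa_alignment=res,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.element_nt_start, h.ref_id))
    return hits


def best_hit_per_domain(hits: list[DomainHit]) -> dict[str, DomainHit]:
    """Best-scoring hit for each domain kind present among ``hits``.

    Ties are broken by lower e-value, then smaller element start, then
    lexicographic reference id, so the result is independent of input
    order.
    """
    best: dict[str, DomainHit] = {}
    for hit in hits:
        cur = best.get(hit.domain_kind)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[hit.domain_kind] = hit
    return best


def _hit_rank(hit: DomainHit):
    return (-hit.score, hit.evalue, hit.element_nt_start, hit.ref_id)
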