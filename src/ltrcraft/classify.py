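"""Superfamily/lineage classification of LTR-RT elements.

The decision tree, applied to the best domain hits of one element:

1. **Chimera check** — if the enzymatic domains (RT, INT, RNaseH)
   carry *both* superfamily codes (RLC and RLG), the element is a
   possible chimera and goes to NO_CLASS.  This check runs first so
   that neither superfamily wins arbitrarily.
2. **Autonomous** — at least one of RT/INT/RNaseH with a single
   superfamily code classifies the element as GYPSY (RLG) or COPIA
   (RLC); a lineage is then assigned from the hit labels.
3. **Domain-free** — no domain hits at all: TRIM if the element is
   shorter than the TRIM/LARD cutoff (2000 bp by default), LARD if it
   is at least that long.
4. **TR-GAG** — only a GAG domain, or GAG plus AP.
5. Anything else (ENV-only, AP-only, ...) falls through to NO_CLASS.

Non-autonomous categories (TRIM, LARD, TR_GAG) never carry a lineage.

Unclassified elements get a second chance through the 80/80/80 rule:
each NO_CLASS element is locally aligned against every classified
element, and if the best donor alignment covers >=80% of the
unclassified element, at >=80% nucleotide identity, over >=80 aligned
bases, the element inherits the donor's category and lineage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from . import align
from .align import NT_SCHEME
from .domains import DomainHit
from .seqio import PipelineConfig, PredictorRecord

__all__ = [
    "CATEGORIES",
    "ClassificationResult",
    "Reclassification",
    "classify_element",
    "assign_lineage",
    "reclassify_80_80_80",
]

CATEGORIES = ("GYPSY", "COPIA", "TRIM", "LARD", "TR_GAG", "NO_CLASS")
AUTONOMOUS_DOMAINS = frozenset({"RT", "INT", "RNASEH"})


@dataclass
class Reclassification:
    donor_id: str
    identity_pct: float
    coverage_pct: float
    aligned_bp: int


@dataclass
class ClassificationResult:
    element_id: str
    category: str
    lineage: str = "NONE"
    evidence: list[tuple[str, str, str]] = field(default_factory=list)
    reclassified_from: Reclassification | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.lineage != "NONE" and self.category not in ("GYPSY", "COPIA"):
            raise ValueError("only autonomous superfamilies carry a lineage")


def _evidence(rule: str, best_hits: dict[str, DomainHit]) -> tuple[str, str, str]:
    domains = ",".join(sorted(best_hits)) or "-"
    labels = ",".join(
        sorted({f"{h.superfamily_code}/{h.lineage}" for h in best_hits.values()})
    ) or "-"
    return (rule, domains, labels)


def assign_lineage(best_hits: dict[str, DomainHit]) -> str:
    """Lineage vote for an element already assigned a superfamily.

    The RT hit's lineage wins when present (RT is the most conserved
    and reliably labelled domain); otherwise the majority lineage among
    the INT and RNaseH hits, ties resolved in favour of the
    highest-scoring hit's lineage.
    """
    rt = best_hits.get("RT")
    if rt is not None and rt.lineage != "NONE":
        return rt.lineage
    voters = [best_hits[d] for d in ("INT", "RNASEH") if d in best_hits]
    voters = [h for h in voters if h.lineage != "NONE"]
    if not voters:
        return "NONE"
    counts: dict[str, int] = {}
    for h in voters:
        counts[h.lineage] = counts.get(h.lineage, 0) + 1
    top = max(counts.values())
    contenders = {lin for lin, c in counts.items() if c == top}
    if len(contenders) == 1:
        return contenders.pop()
    best = max((h for h in voters if h.lineage in contenders), key=lambda h: h.score)
    return best.lineage


def classify_element(
    element: PredictorRecord,
    best_hits: dict[str, DomainHit],
    cfg: PipelineConfig | None = None,
) -> ClassificationResult:
    """Apply the decision tree to one element (total and deterministic)."""
    cfg = cfg or PipelineConfig()
    eid = element.element_id
    enzymatic = {d: h for d, h in best_hits.items() if d in AUTONOMOUS_DOMAINS}
    codes = {h.superfamily_code for h in enzymatic.values()} - {"NONE"}

    if enzymatic and codes >= {"RLC", "RLG"}:
        return ClassificationResult(
            eid, "NO_CLASS", evidence=[_evidence("chimeric-both-superfamilies", best_hits)]
        )
    if enzymatic and len(codes) == 1:
        category = "GYPSY" if codes == {"RLG"} else "COPIA"
        return ClassificationResult(
            eid,
            category,
            lineage=assign_lineage(best_hits),
            evidence=[_evidence("autonomous-single-superfamily", best_hits)],
        )
    if not best_hits:
        if element.element_length < cfg.trim_lard_cutoff_bp:
            return ClassificationResult(eid, "TRIM", evidence=[_evidence("no-domains-short", {})])
        return ClassificationResult(eid, "LARD", evidence=[_evidence("no-domains-long", {})])
    kinds = set(best_hits)
    if kinds == {"GAG"} or kinds == {"GAG", "AP"}:
        return ClassificationResult(eid, "TR_GAG", evidence=[_evidence("gag-only", best_hits)])
    return ClassificationResult(
        eid, "NO_CLASS", evidence=[_evidence("uncovered-domain-set", best_hits)]
    )


def reclassify_80_80_80(
    no_class: list[tuple[PredictorRecord, ClassificationResult]],
    classified: list[tuple[PredictorRecord, ClassificationResult]],
    cfg: PipelineConfig | None = None,
    min_identity: float = 80.0,
    min_coverage: float = 80.0,
    min_aligned_bp: int = 80,
) -> list[ClassificationResult]:
    """Second-pass similarity rescue of unclassified elements.

    Each NO_CLASS element is locally aligned against every classified
    element; the best donor is accepted when the alignment covers at
    least ``min_coverage`` percent of the *unclassified* element, at
    ``min_identity`` percent nucleotide identity, over at least
    ``min_aligned_bp`` aligned bases.  Donors of any classified
    category (autonomous or not) are eligible.  Ties between donors are
    broken by alignment score, then donor id, so the outcome does not
    depend on donor ordering.  Idempotent: rerunning changes nothing.
    """
    cfg = cfg or PipelineConfig()
    results = []
    if not classified:
        if no_class:
            warnings.warn("80/80/80 reclassification skipped: no classified donors")
        return [res for _, res in no_class]
    for query, res in no_class:
        if res.category != "NO_CLASS":
            results.append(res)
            continue
        best = None  # (score, donor_id, donor_res, hit)
        for donor, donor_res in classified:
            hits = align.local_align(query.full_seq, donor.full_seq, NT_SCHEME, max_hits=1)
            if not hits:
                continue
            hit = hits[0]
            key = (-hit.score, donor_res.element_id)
            if best is None or key < best[0]:
                best = (key, donor_res, hit)
        if best is None:
            results.append(res)
            continue
        _, donor_res, hit = best
        # coverage is measured on the unclassified element: the span of
        # its residues inside the local alignment.
        coverage = hit.query_cov_pct
        ok = (
            hit.identity_pct >= min_identity
            and coverage >= min_coverage
            and hit.aligned_bases >= min_aligned_bp
        )
        if not ok:
            results.append(res)
            continue
        results.append(
            ClassificationResult(
                element_id=res.element_id,
                category=donor_res.category,
                lineage=donor_res.lineage,
                evidence=res.evidence
                + [
                    (
                        "reclassified-80/80/80",
                        f"donor={donor_res.element_id}",
                        f"identity={hit.identity_pct:.2f},coverage={coverage:.2f},"
                        f"aligned_bp={hit.aligned_bases}",
                    )
                ],
                reclassified_from=Reclassification(
                    donor_id=donor_res.element_id,
                    identity_pct=hit.identity_pct,
                    coverage_pct=coverage,
                    aligned_bp=hit.aligned_bases,
                ),
            )
        )
    return results
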