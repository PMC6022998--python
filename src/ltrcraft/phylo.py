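"""RT-domain extraction, multiple alignment and distance trees.

The reverse transcriptase (RT) domain is the most conserved part of
the LTR-RT polyprotein and therefore the marker of choice for
within-genome retroelement phylogenies.  For every autonomous element
the best RT hit's nucleotide span is translated in its frame; the
translation is kept only if it is strictly longer than the mode
threshold (200 aa for element libraries, 150 aa for genome-level RT
mining).  A translation containing an internal stop codon is truncated
at the stop and kept if the remainder still passes.

Retained RT proteins are multiply aligned with MAFFT, pairwise
p-distances are computed over mutually ungapped columns, and a
neighbor-joining tree is built with lineage-annotated leaf labels
(``elementID#category#lineage``).  Negative NJ branch-length estimates
are clamped to zero and flagged.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import align
from .classify import ClassificationResult
from .domains import DomainHit
from .seqio import PipelineConfig, PredictorRecord

__all__ = [
    "RTDomainSequence",
    "PhyloTree",
    "extract_rt",
    "progressive_msa",
    "distance_matrix",
    "nj_tree",
    "leaf_label",
]


@dataclass
class RTDomainSequence:
    element_id: str
    aa_seq: str
    length_aa: int
    source_frame: int
    nt_span: tuple[int, int]
    lineage_label: str
    mode: str  # element | genome


@dataclass
class PhyloTree:
    newick: str
    leaf_labels: list[str]
    clamped_branches: int = 0


@dataclass
class RTRejection:
    element_id: str
    reason: str
    length_aa: int


def extract_rt(
    element: PredictorRecord,
    rt_best_hit: DomainHit,
    cfg: PipelineConfig | None = None,
    mode: str = "element",
) -> RTDomainSequence | RTRejection:
    """Translate the RT-hit span of one element, applying the length filter.

    The minimum length is *strict*: an exactly-threshold translation is
    rejected ("larger than" 200/150 residues).
    """
    cfg = cfg or PipelineConfig()
    if mode not in ("element", "genome"):
        raise ValueError(f"unknown mode {mode!r}")
    threshold = cfg.rt_min_aa_element if mode == "element" else cfg.rt_min_aa_genome
    nt = element.full_seq
    start, end = rt_best_hit.element_nt_start, rt_best_hit.element_nt_end
    span_nt = nt[start:end]
    if rt_best_hit.frame < 0:
        span_nt = align.revcomp(span_nt)
    aa = align.translate(span_nt, 1) if len(span_nt) >= 3 else ""
    aa = aa.rstrip("*")
    if "*" in aa:
        aa = aa.split("*", 1)[0]
    if len(aa) <= threshold:
        return RTRejection(
            element.element_id,
            f"translated RT of {len(aa)} aa not larger than {threshold} aa ({mode} mode)",
            len(aa),
        )
    return RTDomainSequence(
        element_id=element.element_id,
        aa_seq=aa,
        length_aa=len(aa),
        source_frame=rt_best_hit.frame,
        nt_span=(start, end),
        lineage_label=rt_best_hit.lineage,
        mode=mode,
    )


def leaf_label(element_id: str, result: ClassificationResult) -> str:
    return f"{element_id}#{result.category}#{result.lineage}"


def progressive_msa(seqs: dict[str, str]) -> dict[str, str]:
    """Multiple protein alignment via MAFFT (progressive, deterministic).

    ``seqs`` maps label -> amino-acid sequence; the returned dict maps
    the same labels (input order preserved) to equal-length gapped
    rows, each of which degaps back to its input.
    """
    if len(seqs) < 2:
        raise ValueError("multiple alignment needs at least 2 sequences")
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft executable not found on PATH")
    labels = list(seqs)
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fa"
        with open(inp, "w") as fh:
            # numeric keys avoid any label-mangling by the aligner
            for i, label in enumerate(labels):
                fh.write(f">s{i}\n{seqs[label]}\n")
        proc = subprocess.run(
            ["mafft", "--quiet", "--anysymbol", "--retree", "2", str(inp)],
            capture_output=True,
            text=True,
            check=True,
        )
    rows: dict[str, str] = {}
    current = None
    chunks: list[str] = []
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            if current is not None:
                rows[current] = "".join(chunks)
            current = line[1:].strip()
            chunks = []
        else:
            chunks.append(line.strip())
    if current is not None:
        rows[current] = "".join(chunks)
    out = {label: rows[f"s{i}"].upper() for i, label in enumerate(labels)}
    widths = {len(v) for v in out.values()}
    if len(widths) != 1:
        raise RuntimeError("aligner returned rows of unequal length")
    for label in labels:
        if out[label].replace("-", "") != seqs[label].upper():
            raise RuntimeError(f"alignment row for {label!r} does not degap to its input")
    return out


def distance_matrix(msa: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    """Pairwise protein p-distances over mutually ungapped columns."""
    labels = list(msa)
    rows = [msa[label] for label in labels]
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sites = diffs = 0
            for x, y in zip(rows[i], rows[j]):
                if x == "-" or y == "-":
                    continue
                sites += 1
                if x != y:
                    diffs += 1
            d = diffs / sites if sites else 0.0
            dist[i, j] = dist[j, i] = d
    return dist, labels


def nj_tree(dist: np.ndarray, labels: list[str]) -> PhyloTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Saitou–Nei agglomeration with the standard Q criterion;
    deterministic tie-breaking (the lexicographically smallest index
    pair among minimal-Q pairs is joined).  Negative branch-length
    estimates are clamped to zero and counted in ``clamped_branches``.
    Returns an unrooted tree as a trifurcating-root newick string.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if len(labels) != n:
        raise ValueError("labels do not match matrix size")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    clamped = 0

    def fmt(length: float) -> str:
        nonlocal clamped
        if length < 0:
            clamped += 1
            length = 0.0
        return f"{length:.6f}"

    nodes = [_escape(label) for label in labels]
    D = dist.copy()
    active = list(range(n))
    if n == 2:
        half = D[0, 1] / 2.0
        newick = f"({nodes[0]}:{fmt(half)},{nodes[1]}:{fmt(half)});"
        return PhyloTree(newick, labels, clamped)

    subtrees = dict(enumerate(nodes))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        # Q(i,j) = (m-2) d(i,j) - r_i - r_j
        Q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        best = np.argwhere(Q == Q.min())
        # Q[i,j] and Q[j,i] can differ in the last ulp (broadcast
        # subtraction order), so normalize orientation before tie-break
        ai, aj = min({(int(min(p)), int(max(p))) for p in best})  # smallest pair
        i, j = active[ai], active[aj]
        d_ij = D[i, j]
        li = 0.5 * d_ij + (totals[ai] - totals[aj]) / (2.0 * (m - 2))
        lj = d_ij - li
        new = D.shape[0]
        # grow the matrix by one row/col for the new internal node
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new, k] = D[k, new] = 0.5 * (D[i, k] + D[j, k] - d_ij)
        subtrees[new] = f"({subtrees[i]}:{fmt(li)},{subtrees[j]}:{fmt(lj)})"
        active = [k for k in active if k not in (i, j)] + [new]
    a, b, c = active
    # three-point formulas for the final star
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    newick = (
        f"({subtrees[a]}:{fmt(la)},{subtrees[b]}:{fmt(lb)},{subtrees[c]}:{fmt(lc)});"
    )
    return PhyloTree(newick, labels, clamped)


def _escape(label: str) -> str:
    if any(c in label for c in "(),:;' \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label
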