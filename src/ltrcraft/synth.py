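"""Synthetic LTR-RT elements and reference libraries with known truth.

Every pipeline stage can be exercised offline against fixtures whose
category, lineage and insertion age are known by construction:

* :func:`make_reference_library` emits a lineage-labelled protein
  library (one random protein per domain kind per lineage, 150–400 aa)
  standing in for a curated domain database.  Random proteins from
  different lineages share only chance identity (<40%), so lineage
  assignment on synthetic data is unambiguous.
* :func:`simulate_element` builds one element: an ancestral LTR
  (``TG``...``CA`` termini), an internal region carrying the requested
  domains as exact back-translations of the library proteins, the LTR
  copied to both termini, and finally each LTR mutated independently
  with per-site substitution probability ``rate * T_years`` at
  transition:transversion ratio kappa.  The expected pairwise LTR
  divergence is therefore ``K* = 2 * rate * T`` — the same identity
  the dating module inverts.

Substitutions are drawn i.i.d. per site without multiple-hit
bookkeeping; at the divergences simulated here (K <= ~0.1) the K2P
correction remains accurate to well under the sampling noise.
Back-translation uses one fixed codon per amino acid, so fixtures are
byte-reproducible from (spec, seed).  Indel evolution, nested
insertions and solo-LTR recombination are not modelled.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .domains import DOMAIN_KINDS, ReferenceDomain
from .seqio import PredictorRecord, emit_predictor_report, write_fasta, write_tabular
from .seqio import GenomicSequence
from . import align

__all__ = [
    "GYPSY_LINEAGES",
    "COPIA_LINEAGES",
    "ElementSpec",
    "make_reference_library",
    "write_reference_library",
    "simulate_element",
    "simulate_dataset",
    "emit_predictor_report",
]

# Canonical plant LTR-RT lineages and an example family name for each.
GYPSY_LINEAGES = {
    "Del": "Peabody",
    "Reina": "Reina1",
    "CRM": "CRM1",
    "Galadriel": "Galadriel1",
    "TAT": "Tat4",
    "Athila": "Athila4",
}
COPIA_LINEAGES = {
    "Tork": "Tnt1",
    "Retrofit": "Retrofit1",
    "Oryco": "Osr4",
    "SIRE": "Sire1",
    "Bianca": "Bianca1",
}

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# One fixed codon per amino acid for deterministic back-translation.
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "AGA",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

# Superfamily code per lineage.
_CODE = {**{lin: "RLG" for lin in GYPSY_LINEAGES}, **{lin: "RLC" for lin in COPIA_LINEAGES}}


@dataclass
class ElementSpec:
    """Blueprint for one synthetic element.

    ``internal_domains`` lists the domain kinds embedded 5'->3' in the
    internal region; categories constrain it (TRIM/LARD embed none,
    TR_GAG only GAG or GAG+AP).  ``age_my`` is the true insertion age
    driving LTR divergence.
    """

    category: str
    lineage: str = "NONE"
    age_my: float = 1.0
    ltr_len: int = 500
    internal_domains: tuple[str, ...] = ("GAG", "AP", "RT", "RNASEH", "INT")
    internal_pad_bp: int = 150
    target_length: int | None = None
    substitution_rate: float = 1.3e-8
    kappa: float = 2.0
    rng_seed: int = 0

    def validate(self) -> "ElementSpec":
        if self.age_my < 0:
            raise ValueError("age_my must be >= 0")
        if self.ltr_len < 50:
            raise ValueError("ltr_len must be >= 50")
        if self.category in ("TRIM", "LARD") and self.internal_domains:
            raise ValueError(f"{self.category} elements carry no coding domains")
        if self.category == "TR_GAG" and not (
            set(self.internal_domains) == {"GAG"}
            or set(self.internal_domains) == {"GAG", "AP"}
        ):
            raise ValueError("TR_GAG elements embed only GAG or GAG+AP")
        if self.category == "TRIM" and self.target_length is not None and self.target_length >= 2000:
            raise ValueError("TRIM elements must be shorter than 2000 bp")
        if self.category == "LARD" and self.target_length is not None and self.target_length < 2000:
            raise ValueError("LARD elements must be at least 2000 bp")
        for d in self.internal_domains:
            if d not in DOMAIN_KINDS:
                raise ValueError(f"unknown domain kind {d!r}")
        return self


def _random_protein(rng: random.Random, min_len: int = 150, max_len: int = 400) -> str:
    return "".join(rng.choice(_AA20) for _ in range(rng.randint(min_len, max_len)))


def make_reference_library(
    lineages: list[str],
    seed: int,
    env_lineages: tuple[str, ...] = ("SIRE",),
) -> list[ReferenceDomain]:
    """One random reference protein per domain kind per lineage.

    ENV (an envelope-like ORF, present only in some lineages) is
    emitted only for ``env_lineages``.
    """
    rng = random.Random(seed)
    library = []
    for lineage in lineages:
        if lineage not in _CODE:
            raise ValueError(f"unknown lineage {lineage!r}")
        code = _CODE[lineage]
        family = {**GYPSY_LINEAGES, **COPIA_LINEAGES}[lineage]
        kinds = ["GAG", "AP", "RT", "RNASEH", "INT"]
        if lineage in env_lineages:
            kinds.append("ENV")
        for kind in kinds:
            library.append(
                ReferenceDomain(
                    ref_id=f"{kind}_{code}_{lineage}_{family}",
                    domain_kind=kind,
                    superfamily_code=code,
                    lineage=lineage,
                    family=family,
                    aa_seq=_random_protein(rng),
                )
            )
    return library


def write_reference_library(library: list[ReferenceDomain], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ref in library:
            fh.write(f">{ref.ref_id}\n")
            for i in range(0, len(ref.aa_seq), 60):
                fh.write(ref.aa_seq[i : i + 60] + "\n")


def back_translate(aa_seq: str) -> str:
    return "".join(_CODON[a] for a in aa_seq)


def _random_nt(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate(seq: str, p_sub: float, kappa: float, rng: random.Random) -> str:
    """Substitute each site independently with probability ``p_sub``.

    Given a substitution, a transition is drawn with probability
    kappa/(kappa+2) and each of the two transversions with probability
    1/(kappa+2).
    """
    if p_sub <= 0:
        return seq
    p_ts = kappa / (kappa + 2.0)
    out = []
    for base in seq:
        if base in _TRANSITION and rng.random() < p_sub:
            if rng.random() < p_ts:
                out.append(_TRANSITION[base])
            else:
                out.append(rng.choice(_TRANSVERSIONS[base]))
        else:
            out.append(base)
    return "".join(out)


def _library_index(library: list[ReferenceDomain]):
    return {(r.domain_kind, r.lineage): r for r in library}


def simulate_element(
    spec: ElementSpec,
    library: list[ReferenceDomain] | None = None,
    element_id: str = "synth_0",
) -> tuple[PredictorRecord, dict]:
    """Build one element and its ground-truth record."""
    spec.validate()
    rng = random.Random(spec.rng_seed)
    if spec.internal_domains:
        if library is None:
            raise ValueError("a reference library is required to embed domains")
        index = _library_index(library)
    # ancestral LTR with canonical TG...CA termini
    ltr = "TG" + _random_nt(rng, spec.ltr_len - 4) + "CA"
    parts: list[str] = []
    for kind in spec.internal_domains:
        key = (kind, spec.lineage)
        if key not in index:
            raise ValueError(f"library has no {kind} reference for lineage {spec.lineage!r}")
        parts.append(_random_nt(rng, spec.internal_pad_bp))
        parts.append(back_translate(index[key].aa_seq))
    parts.append(_random_nt(rng, spec.internal_pad_bp))
    internal = "".join(parts)
    if spec.target_length is not None:
        needed = spec.target_length - 2 * spec.ltr_len - len(internal)
        if needed < 0:
            raise ValueError(
                f"target_length {spec.target_length} too small for "
                f"{2 * spec.ltr_len + len(internal)} bp of LTRs+domains"
            )
        internal += _random_nt(rng, needed)
    # independent divergence of the two LTR copies
    t_years = spec.age_my * 1e6
    p_sub = spec.substitution_rate * t_years
    if p_sub >= 0.75:
        raise ValueError("requested age implies saturated LTRs; unsupported")
    ltr5 = mutate(ltr, p_sub, spec.kappa, rng)
    ltr3 = mutate(ltr, p_sub, spec.kappa, rng)
    full = ltr5 + internal + ltr3
    identity = align.global_align(ltr5, ltr3).identity_pct
    record = PredictorRecord(
        element_id=element_id,
        full_seq=full,
        ltr5_seq=ltr5,
        ltr3_seq=ltr3,
        ltr_identity=identity,
        element_length=len(full),
        source_tag="report",
    ).validate()
    truth = {
        "element_id": element_id,
        "category": spec.category,
        "lineage": spec.lineage if spec.category in ("GYPSY", "COPIA") else "NONE",
        "age_my": spec.age_my,
        "ltr_len": spec.ltr_len,
        "domains": ",".join(spec.internal_domains) or "-",
    }
    return record, truth


DEFAULT_MIXTURE = {"GYPSY": 20, "COPIA": 16, "TRIM": 8, "LARD": 8, "TR_GAG": 8}
DEFAULT_GYPSY = ("Del", "CRM")
DEFAULT_COPIA = ("Tork", "SIRE")


def simulate_dataset(
    n: int,
    seed: int,
    mixture: dict[str, int] | None = None,
    age_range_my: tuple[float, float] = (0.0, 3.0),
    ltr_len: int = 500,
    gypsy_lineages: tuple[str, ...] = DEFAULT_GYPSY,
    copia_lineages: tuple[str, ...] = DEFAULT_COPIA,
    library: list[ReferenceDomain] | None = None,
) -> tuple[list[PredictorRecord], list[dict], list[ReferenceDomain]]:
    """Simulate a mixed cohort of elements with ground truth.

    ``mixture`` gives exact per-category counts (scaled from the
    default 60-element mixture when omitted); ages are drawn uniformly
    from ``age_range_my``.  Returns (records, truth rows, library).
    """
    if mixture is None:
        total = sum(DEFAULT_MIXTURE.values())
        mixture = {k: round(v * n / total) for k, v in DEFAULT_MIXTURE.items()}
        drift = n - sum(mixture.values())
        mixture["GYPSY"] += drift
    if sum(mixture.values()) != n:
        raise ValueError("mixture counts must sum to n")
    if library is None:
        library = make_reference_library(
            list(gypsy_lineages) + list(copia_lineages), seed=seed
        )
    rng = random.Random(seed)
    records, truths = [], []
    idx = 0
    for category in sorted(mixture):
        for _ in range(mixture[category]):
            age = rng.uniform(*age_range_my)
            if category == "GYPSY":
                lineage = gypsy_lineages[idx % len(gypsy_lineages)]
                domains: tuple[str, ...] = ("GAG", "AP", "RT", "RNASEH", "INT")
            elif category == "COPIA":
                lineage = copia_lineages[idx % len(copia_lineages)]
                domains = ("GAG", "AP", "INT", "RT", "RNASEH")
            elif category == "TR_GAG":
                lineage = gypsy_lineages[idx % len(gypsy_lineages)]
                domains = ("GAG",) if idx % 2 == 0 else ("GAG", "AP")
            else:
                lineage = "NONE"
                domains = ()
            spec = ElementSpec(
                category=category,
                lineage=lineage,
                age_my=age,
                ltr_len=ltr_len,
                internal_domains=domains,
                target_length=1500 if category == "TRIM" else (2600 if category == "LARD" else None),
                rng_seed=rng.randrange(2**31),
            )
            if category == "TRIM":
                spec.ltr_len = min(ltr_len, 400)
            rec, truth = simulate_element(spec, library, element_id=f"synth_{idx:04d}")
            records.append(rec)
            truths.append(truth)
            idx += 1
    return records, truths, library


def write_fixtures(
    records: list[PredictorRecord],
    truths: list[dict],
    library: list[ReferenceDomain],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write FASTA + predictor report + truth TSV + reference library."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "elements.fasta",
        "report": outdir / "predictor_report.txt",
        "truth": outdir / "truth.tsv",
        "library": outdir / "reference_domains.faa",
    }
    write_fasta(
        [GenomicSequence(r.element_id, r.full_seq) for r in records], paths["fasta"]
    )
    emit_predictor_report(records, paths["report"])
    write_tabular(
        truths,
        paths["truth"],
        columns=["element_id", "category", "lineage", "age_my", "ltr_len", "domains"],
    )
    write_reference_library(library, paths["library"])
    return paths
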