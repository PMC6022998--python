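"""Readers and writers for every format the pipeline touches.

Formats handled here:

* FASTA — element libraries, reference domain proteins, per-category
  outputs (via Biopython's ``SeqIO``).
* Predictor report dialect v1 — a plain-text, block-per-element format
  carrying the features structural LTR predictors emit: full element
  sequence, both LTR sequences, LTR identity and length.  Blocks are
  separated by blank lines; each line is ``KEY value`` with keys
  ``ELEMENT_ID``, ``LENGTH``, ``LTR_IDENTITY``, ``LTR5_SEQ``,
  ``LTR3_SEQ``, ``FULL_SEQ``.
* Config — ``key=value`` lines with ``#`` comments, keys matching
  :class:`PipelineConfig` fields.
* TSV tables and Newick trees (outputs).

Nucleotide text is folded to upper case on input; characters outside
``ACGTN`` (soft-masked lower case, IUPAC ambiguity codes) are mapped to
``N`` unless ``strict_alphabet`` is set in the config, in which case
they are rejected.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicSequence",
    "PredictorRecord",
    "PipelineConfig",
    "MalformedRecord",
    "read_fasta",
    "write_fasta",
    "parse_predictor_report",
    "emit_predictor_report",
    "parse_config",
    "write_tabular",
    "read_tabular",
    "write_newick",
]

_NT_OK = set("ACGTN")


class MalformedRecord(ValueError):
    """A predictor-report block violates a structural invariant."""


@dataclass
class GenomicSequence:
    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PredictorRecord:
    """One predicted full-length LTR-RT element with its two LTRs.

    ``ltr5_seq`` must occur at the 5' terminus of ``full_seq`` and
    ``ltr3_seq`` at the 3' terminus; ``ltr_identity`` is the
    predictor-reported percent identity between the two LTRs.
    """

    element_id: str
    full_seq: str
    ltr5_seq: str
    ltr3_seq: str
    ltr_identity: float
    element_length: int
    source_tag: str = "report"

    def validate(self) -> "PredictorRecord":
        if self.element_length != len(self.full_seq):
            raise MalformedRecord(
                f"{self.element_id}: LENGTH {self.element_length} != "
                f"len(FULL_SEQ) {len(self.full_seq)}"
            )
        if not (0.0 <= self.ltr_identity <= 100.0):
            raise MalformedRecord(
                f"{self.element_id}: LTR_IDENTITY {self.ltr_identity} outside [0, 100]"
            )
        if not self.full_seq.startswith(self.ltr5_seq):
            raise MalformedRecord(f"{self.element_id}: LTR5_SEQ is not a 5' prefix of FULL_SEQ")
        if not self.full_seq.endswith(self.ltr3_seq):
            raise MalformedRecord(f"{self.element_id}: LTR3_SEQ is not a 3' suffix of FULL_SEQ")
        if self.source_tag not in ("report", "fasta", "internal-scan"):
            raise MalformedRecord(f"{self.element_id}: bad source_tag {self.source_tag!r}")
        return self


@dataclass
class PipelineConfig:
    """All tunable thresholds, with their pipeline defaults.

    ``substitution_rate`` is the per-site, per-year base substitution
    rate used to convert LTR divergence into an insertion age
    (default 1.3e-8, a plant average); ``trim_lard_cutoff_bp`` splits
    coding-domain-free elements into TRIM (<2000 bp) and LARD
    (>=2000 bp); ``rt_min_aa_element``/``rt_min_aa_genome`` are the
    strict minimum lengths (in residues) for a translated RT domain in
    element-library and genome-mining modes.
    """

    input_mode: str = "report"  # report | fasta
    input_path: str = ""
    library_path: str = ""
    result_dir: str = "results"
    verbose: bool = False
    clean_mode: bool = False
    strict_alphabet: bool = False
    evalue_cutoff: float = 1e-4
    trim_lard_cutoff_bp: int = 2000
    rt_min_aa_element: int = 200
    rt_min_aa_genome: int = 150
    substitution_rate: float = 1.3e-8
    apply_808080: bool = True
    bin_width_my: float = 0.5
    min_raw_score: float = 100.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for key in (
            "evalue_cutoff",
            "trim_lard_cutoff_bp",
            "rt_min_aa_element",
            "rt_min_aa_genome",
            "substitution_rate",
            "bin_width_my",
        ):
            if getattr(self, key) <= 0:
                raise ValueError(f"config: {key} must be > 0")


def sanitize_nt(seq: str, strict: bool = False, name: str = "sequence") -> str:
    """Upper-case ``seq`` and map non-ACGTN characters to N (or reject)."""
    seq = seq.upper()
    if set(seq) <= _NT_OK:
        return seq
    if strict:
        bad = sorted(set(seq) - _NT_OK)
        raise ValueError(f"{name}: characters outside ACGTN: {bad}")
    return "".join(c if c in _NT_OK else "N" for c in seq)


def read_fasta(path: str | Path, strict_alphabet: bool = False) -> list[GenomicSequence]:
    """Read a nucleotide FASTA file, preserving record order."""
    path = Path(path)
    records: list[GenomicSequence] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not str(rec.seq):
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        seen[rec.id] = seen.get(rec.id, 0) + 1
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(
            GenomicSequence(
                id=rec.id,
                seq=sanitize_nt(str(rec.seq), strict_alphabet, rec.id),
                description=desc,
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"{path}: duplicate sequence ids: {dups}")
    return records


def write_fasta(
    records: Iterable[GenomicSequence], path: str | Path, line_width: int = 60
) -> None:
    records = list(records)
    path = Path(path)
    for rec in records:
        if any(c.isspace() for c in rec.id):
            raise ValueError(f"FASTA id may not contain whitespace: {rec.id!r}")
    if not records:
        warnings.warn(f"writing empty FASTA file {path}", stacklevel=2)
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), line_width):
                fh.write(rec.seq[i : i + line_width] + "\n")


_REPORT_KEYS = ("ELEMENT_ID", "LENGTH", "LTR_IDENTITY", "LTR5_SEQ", "LTR3_SEQ", "FULL_SEQ")


def parse_predictor_report(
    path: str | Path, strict_alphabet: bool = False
) -> list[PredictorRecord]:
    """Parse a predictor-report (dialect v1) file into validated records."""
    path = Path(path)
    text = path.read_text()
    records: list[PredictorRecord] = []
    for block in text.split("\n\n"):
        lines = [ln.strip() for ln in block.splitlines() if ln.strip() and not ln.startswith("#")]
        if not lines:
            continue
        fields: dict[str, str] = {}
        for ln in lines:
            parts = ln.split(None, 1)
            if len(parts) != 2:
                raise MalformedRecord(f"{path}: cannot parse report line {ln!r}")
            key, value = parts
            if key not in _REPORT_KEYS:
                raise MalformedRecord(f"{path}: unknown report key {key!r}")
            if key in fields:
                raise MalformedRecord(f"{path}: duplicate key {key!r} in one block")
            fields[key] = value
        missing = [k for k in _REPORT_KEYS if k not in fields]
        if missing:
            raise MalformedRecord(f"{path}: block missing keys {missing}")
        try:
            length = int(fields["LENGTH"])
            identity = float(fields["LTR_IDENTITY"])
        except ValueError as exc:
            raise MalformedRecord(f"{path}: {exc}") from exc
        rec = PredictorRecord(
            element_id=fields["ELEMENT_ID"],
            full_seq=sanitize_nt(fields["FULL_SEQ"], strict_alphabet, fields["ELEMENT_ID"]),
            ltr5_seq=sanitize_nt(fields["LTR5_SEQ"], strict_alphabet, fields["ELEMENT_ID"]),
            ltr3_seq=sanitize_nt(fields["LTR3_SEQ"], strict_alphabet, fields["ELEMENT_ID"]),
            ltr_identity=identity,
            element_length=length,
            source_tag="report",
        ).validate()
        records.append(rec)
    ids = [r.element_id for r in records]
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise MalformedRecord(f"{path}: duplicate element ids: {dups}")
    return records


def emit_predictor_report(records: Iterable[PredictorRecord], path: str | Path) -> None:
    """Write records in the predictor-report dialect (round-trips with the parser)."""
    path = Path(path)
    blocks = []
    for rec in records:
        rec.validate()
        blocks.append(
            "\n".join(
                [
                    f"ELEMENT_ID {rec.element_id}",
                    f"LENGTH {rec.element_length}",
                    f"LTR_IDENTITY {rec.ltr_identity:.4f}",
                    f"LTR5_SEQ {rec.ltr5_seq}",
                    f"LTR3_SEQ {rec.ltr3_seq}",
                    f"FULL_SEQ {rec.full_seq}",
                ]
            )
        )
    path.write_text("\n\n".join(blocks) + ("\n" if blocks else ""))


_BOOL_KEYS = {"verbose", "clean_mode", "strict_alphabet", "apply_808080"}
_INT_KEYS = {"trim_lard_cutoff_bp", "rt_min_aa_element", "rt_min_aa_genome", "rng_seed"}
_FLOAT_KEYS = {"evalue_cutoff", "substitution_rate", "bin_width_my", "min_raw_score"}
_STR_KEYS = {"input_mode", "input_path", "library_path", "result_dir"}


def parse_config(path: str | Path) -> PipelineConfig:
    """Parse a key=value config file; unset keys take their defaults."""
    path = Path(path)
    overrides: dict[str, object] = {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        try:
            if key in _BOOL_KEYS:
                if value.lower() not in ("true", "false", "1", "0", "yes", "no"):
                    raise ValueError(f"not a boolean: {value!r}")
                overrides[key] = value.lower() in ("true", "1", "yes")
            elif key in _INT_KEYS:
                overrides[key] = int(value)
            elif key in _FLOAT_KEYS:
                overrides[key] = float(value)
            else:
                overrides[key] = value
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad value for {key}: {exc}") from exc
    return PipelineConfig(**overrides)


def write_tabular(rows: list[dict], path: str | Path, columns: list[str] | None = None) -> None:
    """Write dict rows as a TSV with a header line (header-only if no rows)."""
    path = Path(path)
    if columns is None:
        if not rows:
            raise ValueError("columns required when writing an empty table")
        columns = list(rows[0].keys())
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")


def read_tabular(path: str | Path) -> list[dict]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty table")
    columns = lines[0].split("\t")
    return [dict(zip(columns, ln.split("\t"))) for ln in lines[1:]]


def write_newick(newick: str, path: str | Path) -> None:
    """Write a newick string, enforcing the terminating semicolon."""
    newick = newick.strip()
    if not newick.endswith(";"):
        newick += ";"
    Path(path).write_text(newick + "\n")
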