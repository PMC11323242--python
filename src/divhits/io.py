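"""Plain-text I/O: SMILES files and the per-call evaluation log CSV.

The evaluation log is the audit trail of a benchmark run: one row per
scoring-function evaluation (including cache hits), from which every
result — diverse-hit counts, budget curves, rank tables — is recomputed
post hoc.  The CSV round-trip is lossless: floats are written with
shortest round-trip ``repr`` so a written log re-reads bit-exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .chem import DEFAULT_FP_CONFIG, FingerprintConfig, MoleculeRecord, canonicalize

__all__ = [
    "ScoreRecord",
    "EvaluationLog",
    "LOG_COLUMNS",
    "read_smiles_file",
    "write_smiles_file",
    "write_log_csv",
    "read_log_csv",
]

LOG_COLUMNS = (
    "call_index",
    "elapsed_seconds",
    "canonical_smiles",
    "raw_oracle",
    "property_pass",
    "df_pass",
    "final_score",
)


@dataclass(frozen=True)
class ScoreRecord:
    """One scoring-function evaluation.

    ``canonical_smiles`` holds the canonical form for valid molecules and
    the raw proposal text for unparsable ones (``property_pass`` is then
    False, so such rows can never count as hits downstream).
    """

    call_index: int
    elapsed_seconds: float
    canonical_smiles: str
    raw_oracle: float
    property_pass: bool
    df_pass: bool
    final_score: float


@dataclass
class EvaluationLog:
    """Append-only sequence of :class:`ScoreRecord` with ordering invariants."""

    records: list[ScoreRecord] = field(default_factory=list)

    def append(self, rec: ScoreRecord) -> None:
        if self.records:
            last = self.records[-1]
            if rec.call_index <= last.call_index:
                raise ValueError("call_index must be strictly increasing")
            if rec.elapsed_seconds < last.elapsed_seconds:
                raise ValueError("elapsed_seconds must be non-decreasing")
        self.records.append(rec)

    def __iter__(self) -> Iterator[ScoreRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, EvaluationLog) and self.records == other.records


def read_smiles_file(
    path: str | Path, fp_config: FingerprintConfig = DEFAULT_FP_CONFIG
) -> list[MoleculeRecord]:
    """Read a line-oriented SMILES file.

    The first whitespace-separated token on each line is the SMILES; an
    optional second token is kept as the molecule name.  Blank lines are
    skipped; unparsable SMILES yield records with ``valid=False``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SMILES file not found: {path}")
    records: list[MoleculeRecord] = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            name = tokens[1] if len(tokens) > 1 else None
            records.append(canonicalize(tokens[0], fp_config, name=name))
    return records


def write_smiles_file(records: Iterable[MoleculeRecord | str], path: str | Path) -> None:
    """Write one SMILES (plus optional name) per line."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, str):
                fh.write(rec + "\n")
            else:
                smi = rec.canonical_smiles if rec.valid else rec.input_smiles
                fh.write(smi + (f" {rec.name}" if rec.name else "") + "\n")


def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


def _parse_bool(s: str, path: Path, line_no: int) -> bool:
    if s == "true":
        return True
    if s == "false":
        return False
    raise ValueError(f"{path}:{line_no}: expected boolean 'true'/'false', got {s!r}")


def write_log_csv(log: EvaluationLog, path: str | Path) -> None:
    """Write the evaluation log; ``repr`` floats make the round-trip exact."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(LOG_COLUMNS)
        for r in log:
            w.writerow(
                [
                    r.call_index,
                    repr(r.elapsed_seconds),
                    r.canonical_smiles,
                    repr(r.raw_oracle),
                    _fmt_bool(r.property_pass),
                    _fmt_bool(r.df_pass),
                    repr(r.final_score),
                ]
            )


def read_log_csv(path: str | Path) -> EvaluationLog:
    """Read an evaluation log CSV written by :func:`write_log_csv`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"log CSV not found: {path}")
    log = EvaluationLog()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}:1: empty file, expected header {','.join(LOG_COLUMNS)}")
        if tuple(header) != LOG_COLUMNS:
            raise ValueError(
                f"{path}:1: malformed header {header!r}, expected {list(LOG_COLUMNS)}"
            )
        for line_no, row in enumerate(reader, start=2):
            if len(row) != len(LOG_COLUMNS):
                raise ValueError(f"{path}:{line_no}: expected {len(LOG_COLUMNS)} fields, got {len(row)}")
            log.append(
                ScoreRecord(
                    call_index=int(row[0]),
                    elapsed_seconds=float(row[1]),
                    canonical_smiles=row[2],
                    raw_oracle=float(row[3]),
                    property_pass=_parse_bool(row[4], path, line_no),
                    df_pass=_parse_bool(row[5], path, line_no),
                    final_score=float(row[6]),
                )
            )
    return log
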