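"""Readers and writers for the on-disk formats the pipeline touches.

Supported formats: FASTA query sequences, PSI-BLAST ASCII position-specific
scoring matrices (the modern 44-column dialect), PSIPRED ``.ss2`` secondary
structure probability files, two-column binding-label annotations, and the
TSV prediction output.

Positions are 1-based in every on-disk file and 0-based in memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from Bio import SeqIO

#: Column order of the 20 log-odds columns in a PSI-BLAST ASCII PSSM.
PSSM_RESIDUE_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard codes tolerated in input sequences.
AMBIGUOUS_AA = "XBZU"

VALID_AA = set(STANDARD_AA) | set(AMBIGUOUS_AA)


class FormatError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


@dataclass
class ProteinRecord:
    """A protein sequence with optional per-residue binding labels.

    Labels are binary: 1 marks a vitamin-binding residue, 0 a non-binding
    one.  When present, the label vector has exactly one entry per residue.
    """

    id: str
    sequence: str
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_AA
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue code(s) {sorted(bad)}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if len(self.labels) != len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: {len(self.labels)} labels for "
                    f"{len(self.sequence)} residues"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProfileMatrix:
    """An L x 20 PSSM, either raw integer log-odds or logistic-normalized.

    ``residues`` carries the residue letters read from the profile file so
    callers can cross-check them against the FASTA sequence.
    """

    values: np.ndarray
    normalized: bool = False
    residue_order: str = PSSM_RESIDUE_ORDER
    residues: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError(f"profile must be L x 20, got {self.values.shape}")
        if self.normalized:
            if not ((self.values > 0) & (self.values < 1)).all():
                raise ValueError("normalized profile values must lie strictly in (0,1)")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class SSProbMatrix:
    """An L x 3 matrix of secondary-structure class probabilities.

    Columns are (coil C, helix H, strand E), in that order.  Probabilities
    are consumed exactly as emitted by the upstream predictor; rows are not
    renormalized.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError(f"SS matrix must be L x 3, got {self.values.shape}")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("SS probabilities must lie in [0,1]")

    def __len__(self) -> int:
        return self.values.shape[0]


def read_fasta(path) -> List[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord` (no labels)."""
    path = Path(path)
    records: List[ProteinRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def read_psiblast_pssm(path) -> ProfileMatrix:
    """Parse a PSI-BLAST ASCII PSSM into a raw :class:`ProfileMatrix`.

    Only the first 20 numeric columns (the log-odds block) are consumed;
    the weighted-percentage block and trailing statistics are ignored.
    """
    path = Path(path)
    rows: List[List[float]] = []
    letters: List[str] = []
    expected_pos = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 22:
                continue
            if not parts[0].isdigit():
                continue
            pos = int(parts[0])
            if pos != expected_pos:
                raise FormatError(
                    f"{path}:{lineno}: position {pos}, expected {expected_pos}"
                )
            if len(parts) < 2 + 20:
                raise FormatError(f"{path}:{lineno}: truncated PSSM row")
            try:
                row = [float(v) for v in parts[2 : 2 + 20]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric PSSM cell ({exc})")
            rows.append(row)
            letters.append(parts[1])
            expected_pos += 1
    if not rows:
        raise FormatError(f"{path}: no PSSM rows found")
    return ProfileMatrix(
        values=np.array(rows, dtype=float),
        normalized=False,
        residues="".join(letters),
    )


def read_psipred_ss2(path) -> SSProbMatrix:
    """Parse a PSIPRED ``.ss2`` file into an L x 3 (C, H, E) matrix."""
    path = Path(path)
    rows: List[List[float]] = []
    with open(path) as fh:
        first = fh.readline()
        if "PSIPRED" not in first:
            warnings.warn(f"{path}: missing PSIPRED VFORMAT header; parsing anyway")
            fh.seek(0)
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            try:
                probs = [float(v) for v in parts[3:6]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric probability ({exc})")
            if any(p < 0 or p > 1 for p in probs):
                raise FormatError(f"{path}:{lineno}: probability outside [0,1]")
            rows.append(probs)
    if not rows:
        raise FormatError(f"{path}: no ss2 rows found")
    return SSProbMatrix(values=np.array(rows, dtype=float))


def read_labels(path) -> Dict[str, np.ndarray]:
    """Read a two-column (id, 0/1-string) annotation file."""
    path = Path(path)
    out: Dict[str, np.ndarray] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'id labelstring'")
            rid, labstr = parts
            if set(labstr) - {"0", "1"}:
                raise FormatError(f"{path}:{lineno}: labels must be 0/1 characters")
            if rid in out:
                raise FormatError(f"{path}:{lineno}: duplicate id {rid!r}")
            out[rid] = np.array([int(c) for c in labstr], dtype=np.int8)
    return out


def attach_labels(records: Iterable[ProteinRecord], labels: Dict[str, np.ndarray]) -> List[ProteinRecord]:
    """Attach label vectors to records, checking lengths; returns new records."""
    out = []
    for rec in records:
        if rec.id not in labels:
            raise ValueError(f"no labels for sequence {rec.id!r}")
        lab = labels[rec.id]
        if len(lab) != len(rec):
            raise ValueError(
                f"record {rec.id!r}: label length {len(lab)} != sequence length {len(rec)}"
            )
        out.append(ProteinRecord(id=rec.id, sequence=rec.sequence, labels=lab))
    return out


def write_predictions(
    records: Sequence[ProteinRecord],
    scores: Dict[str, np.ndarray],
    calls: Dict[str, np.ndarray],
    path,
) -> None:
    """Write a per-residue prediction table.

    Columns: sequence_id, position (1-based), residue, score, call.  Rows
    follow input record order, then position.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sequence_id\tposition\tresidue\tscore\tcall\n")
        for rec in records:
            s = np.asarray(scores[rec.id], dtype=float)
            c = np.asarray(calls[rec.id], dtype=int)
            if len(s) != len(rec) or len(c) != len(rec):
                raise ValueError(
                    f"record {rec.id!r}: scores/calls length mismatch with sequence"
                )
            for i, (sc, cl) in enumerate(zip(s, c)):
                fh.write(f"{rec.id}\t{i + 1}\t{rec.sequence[i]}\t{sc:.6f}\t{cl}\n")
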