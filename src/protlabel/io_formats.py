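"""Reading and writing of external formats and label-derivation rules.

Formats handled here:

* FASTA sequence files (through Bio.SeqIO);
* FASTA-like label files — a header line ``>id`` followed by a label string
  over the task alphabet, aligned position-by-position with the companion
  sequence file ('.' marks unlabeled positions);
* PSI-BLAST ASCII position-specific scoring matrices (the ``-Q`` output
  layout: header lines, then one row per residue with 20 integer log-odds
  columns);
* tab-separated prediction output (protein id, 1-based position, residue,
  predicted label, per-class posteriors);
* YAML/JSON run configuration.

Also implements the label-derivation rules used to build the standard
datasets: the 8-to-3 state secondary-structure reduction and binary solvent
accessibility thresholding (absolute threshold 15 A^2; relative threshold
0.15 of the per-protein maximum).
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from scipy.special import expit

from .alphabets import (
    AMINO_ACIDS,
    DSSP8,
    DSSP8_TO_3,
    UNLABELED,
    sanitize_sequence,
    validate_labels,
)
from .exceptions import AlignmentError, FormatError

logger = logging.getLogger(__name__)

# Per-residue arrays are 0-based internally; all reports are 1-based.


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence over the residue dictionary."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LabelSequence:
    """Per-residue labels for one protein; '.' marks unlabeled positions."""

    id: str
    labels: str

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ProfileMatrix:
    """PSI-BLAST profile for one protein: raw log-odds and their (0,1) image."""

    raw: np.ndarray          # L x 20 integer log-odds
    scaled: np.ndarray = field(init=False)  # L x 20, open interval (0,1)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw)
        if self.raw.ndim != 2 or self.raw.shape[1] != 20:
            raise FormatError(
                f"profile must be L x 20, got shape {self.raw.shape}"
            )
        self.scaled = scale_profile(self.raw)

    def __len__(self) -> int:
        return self.raw.shape[0]


def scale_profile(raw: np.ndarray) -> np.ndarray:
    """Map raw log-odds scores into (0,1) with the logistic 1/(1+e^-x).

    Strictly increasing and bounded; a zero score maps to exactly 0.5.
    """
    return expit(np.asarray(raw, dtype=float))


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords.

    Sequences are uppercased and characters outside the residue dictionary
    are mapped to 'X'.  An empty file or a record with an empty sequence is
    a format error.
    """
    records = [
        ProteinRecord(rec.id, sanitize_sequence(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_labels(
    path: str | Path,
    alphabet: Sequence[str],
    sequences: Mapping[str, str] | None = None,
) -> dict[str, LabelSequence]:
    """Read a FASTA-like label file into a map id -> LabelSequence.

    Every label character must belong to the task alphabet or be the
    unlabeled marker '.'.  If *sequences* is given, each labeling must match
    its companion sequence length.
    """
    out: dict[str, LabelSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        labels = str(rec.seq)
        validate_labels(labels, tuple(alphabet))
        if sequences is not None:
            if rec.id not in sequences:
                raise AlignmentError(f"labels for unknown protein {rec.id!r}")
            if len(labels) != len(sequences[rec.id]):
                raise AlignmentError(
                    f"{rec.id!r}: {len(labels)} labels vs "
                    f"{len(sequences[rec.id])} residues"
                )
        out[rec.id] = LabelSequence(rec.id, labels)
    if not out:
        raise FormatError(f"no label records found in {path}")
    return out


def write_labels(labelings: Iterable[LabelSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lab in labelings:
            fh.write(f">{lab.id}\n{lab.labels}\n")


# --- PSI-BLAST ASCII PSSM -------------------------------------------------

_PSSM_HEADER = (
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapped real matches to pseudocounts"
)


def read_pssm(path: str | Path, expected_length: int | None = None) -> ProfileMatrix:
    """Read a PSI-BLAST ASCII PSSM into a ProfileMatrix.

    Accepts the standard psiblast ``-Q`` layout: any number of header lines,
    a column-header line listing the amino acids, then one row per residue
    beginning with the 1-based position and the residue letter followed by
    (at least) 20 integer log-odds columns.  Extra trailing columns (the
    observed-percentage block) are ignored.
    """
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 22:
                continue
            if not parts[0].isdigit():
                continue
            values = parts[2:]
            if len(values) < 20:
                raise FormatError(
                    f"{path}: PSSM row {parts[0]} has {len(values)} score "
                    "columns, expected 20"
                )
            try:
                rows.append([int(v) for v in values[:20]])
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer PSSM entry") from exc
    if not rows:
        raise FormatError(f"{path}: no PSSM rows found")
    raw = np.array(rows, dtype=np.int64)
    if expected_length is not None and raw.shape[0] != expected_length:
        raise AlignmentError(
            f"{path}: PSSM has {raw.shape[0]} rows, sequence has "
            f"{expected_length} residues"
        )
    return ProfileMatrix(raw)


def write_pssm(record: ProteinRecord, profile: ProfileMatrix, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII layout (log-odds block only)."""
    if len(profile) != len(record):
        raise AlignmentError(
            f"{record.id}: profile rows {len(profile)} != length {len(record)}"
        )
    cols = " ".join(f"{a:>3}" for a in AMINO_ACIDS)
    with open(path, "w") as fh:
        fh.write("\n" + _PSSM_HEADER + "\n")
        fh.write(f"          {cols}\n")
        for i, (res, row) in enumerate(zip(record.sequence, profile.raw), start=1):
            scores = " ".join(f"{int(v):>3}" for v in row)
            fh.write(f"{i:>5} {res} {scores}  " + " ".join(["0"] * 20) + "\n")


_BLOSUM62_PROFILE_CACHE: np.ndarray | None = None


def blosum62_profile(record: ProteinRecord) -> ProfileMatrix:
    """Fallback profile when no PSSM is available for a protein.

    PSI-BLAST itself falls back to the plain substitution matrix when a
    query has no homologs, so we substitute each residue's BLOSUM62 column
    (zeros for 'X').
    """
    global _BLOSUM62_PROFILE_CACHE
    if _BLOSUM62_PROFILE_CACHE is None:
        from .metrics import BLOSUM62

        _BLOSUM62_PROFILE_CACHE = BLOSUM62
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    raw = np.zeros((len(record), 20), dtype=np.int64)
    for i, res in enumerate(record.sequence):
        j = aa_index.get(res)
        if j is not None:
            raw[i] = _BLOSUM62_PROFILE_CACHE[j]
    return ProfileMatrix(raw)


# --- label-derivation rules -----------------------------------------------


def reduce_dssp_alphabet(labels8: LabelSequence) -> LabelSequence:
    """Reduce 8-state secondary structure to 3 states the standard way.

    H, G, I -> H (helices); E, B -> E (strands); T, S, L -> C (coil).
    Unlabeled positions are preserved.
    """
    out = []
    for c in labels8.labels:
        if c == UNLABELED:
            out.append(c)
        elif c in DSSP8_TO_3:
            out.append(DSSP8_TO_3[c])
        elif c in "HEC":
            out.append(c)  # idempotent on the reduced alphabet
        else:
            raise FormatError(f"{labels8.id!r}: {c!r} not in {''.join(DSSP8)}")
    return LabelSequence(labels8.id, "".join(out))


ABS_ACCESSIBILITY_THRESHOLD = 15.0   # A^2, absolute surface area
REL_ACCESSIBILITY_THRESHOLD = 0.15   # fraction of the per-protein maximum


def label_accessibility(
    acc: Sequence[float], mode: str, protein_id: str = ""
) -> LabelSequence:
    """Binarize per-residue solvent-accessible surface areas.

    mode='absolute': accessible ('A') iff area > 15 A^2.
    mode='relative': accessible iff area / per-protein max > 0.15.
    Thresholds are strict; boundary values are labeled buried ('B').
    """
    values = np.asarray(acc, dtype=float)
    if np.any(values < 0):
        raise FormatError("negative accessibility value")
    if mode == "absolute":
        ratios = values
        threshold = ABS_ACCESSIBILITY_THRESHOLD
    elif mode == "relative":
        peak = values.max() if len(values) else 0.0
        if peak == 0.0:
            logger.warning(
                "protein %r has zero maximum accessibility; all buried",
                protein_id,
            )
            return LabelSequence(protein_id, "B" * len(values))
        ratios = values / peak
        threshold = REL_ACCESSIBILITY_THRESHOLD
    else:
        raise FormatError(f"unknown accessibility mode {mode!r}")
    labels = "".join("A" if v > threshold else "B" for v in ratios)
    return LabelSequence(protein_id, labels)


# --- predictions and configs ----------------------------------------------


def write_predictions(
    path: str | Path,
    record: ProteinRecord,
    labels: LabelSequence,
    posteriors: np.ndarray,
    alphabet: Sequence[str],
    append: bool = False,
) -> None:
    """Write per-residue predictions as TSV (1-based positions)."""
    posteriors = np.asarray(posteriors)
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if not append:
            header = ["protein", "pos", "residue", "label"]
            header += [f"p_{c}" for c in alphabet]
            fh.write("\t".join(header) + "\n")
        for i, (res, lab) in enumerate(zip(record.sequence, labels.labels)):
            probs = "\t".join(repr(float(p)) for p in posteriors[i])
            fh.write(f"{record.id}\t{i + 1}\t{res}\t{lab}\t{probs}\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON; JSON is a YAML subset) configuration mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def dump_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
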