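"""Amino-acid dictionary and label alphabets.

The residue dictionary holds the 20 canonical amino acids in alphabetical
one-letter order, an 'X' symbol for unknown/non-standard residues, and a
dedicated padding symbol used at sequence boundaries by the sliding-window
feature extractor.  The padding symbol has its own learned embedding column
and an all-zero profile row.
"""

from __future__ import annotations

import numpy as np

from .exceptions import FormatError

#: The 20 canonical amino acids, alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Unknown-residue symbol.  Any character outside the dictionary maps here.
UNKNOWN: str = "X"

#: Boundary padding symbol (never occurs in real sequences).
PAD: str = "^"

#: Full residue dictionary, in fixed column order for the embedding table.
SYMBOLS: tuple[str, ...] = tuple(AMINO_ACIDS) + (UNKNOWN, PAD)

#: Symbol -> column index in the embedding table.
SYMBOL_INDEX: dict[str, int] = {s: i for i, s in enumerate(SYMBOLS)}

PAD_INDEX: int = SYMBOL_INDEX[PAD]
UNKNOWN_INDEX: int = SYMBOL_INDEX[UNKNOWN]

#: Unlabeled-position marker in label strings.
UNLABELED: str = "."

# 8-state secondary-structure alphabet assigned from 3D structure
# (H = alpha helix, B = isolated beta bridge, E = extended strand,
#  G = 3-10 helix, I = pi helix, T = turn, S = bend, L = loop).
DSSP8: tuple[str, ...] = tuple("HBEGITSL")

# Standard 8 -> 3 state reduction: helices to H, strands/bridges to E,
# everything else to coil.
DSSP8_TO_3: dict[str, str] = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "L": "C",
}

#: Named label alphabets for the standard prediction tasks.
TASK_ALPHABETS: dict[str, tuple[str, ...]] = {
    "ss": tuple("HEC"),            # 3-state secondary structure
    "dssp": DSSP8,                 # 8-state secondary structure
    "saa": tuple("AB"),            # absolute solvent accessibility
    "sar": tuple("AB"),            # relative solvent accessibility
    "sp": tuple("SON"),            # signal peptide detection
    "tm": tuple("SOIMRN"),         # SP+TM topology
    "cc": tuple("Nabcdefg"),       # coiled-coil heptad register
    "dna": tuple("NB"),            # DNA-binding residues
    "ppi": tuple("NP"),            # protein-binding residues
}


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a residue string to dictionary indices (unknowns to 'X')."""
    return np.array(
        [SYMBOL_INDEX.get(c, UNKNOWN_INDEX) for c in sequence], dtype=np.int64
    )


def sanitize_sequence(sequence: str) -> str:
    """Uppercase and replace out-of-dictionary characters with 'X'."""
    up = sequence.upper()
    return "".join(c if c in SYMBOL_INDEX and c != PAD else UNKNOWN for c in up)


def validate_labels(labels: str, alphabet: tuple[str, ...] | str) -> None:
    """Raise FormatError if *labels* uses characters outside alphabet + '.'."""
    allowed = set(alphabet) | {UNLABELED}
    bad = sorted(set(labels) - allowed)
    if bad:
        raise FormatError(
            f"label characters {bad!r} not in alphabet {sorted(set(alphabet))!r}"
        )


def encode_labels(labels: str, alphabet: tuple[str, ...] | str) -> np.ndarray:
    """Map a label string to class indices; unlabeled '.' becomes -1."""
    validate_labels(labels, alphabet)
    index = {c: i for i, c in enumerate(alphabet)}
    return np.array([index.get(c, -1) for c in labels], dtype=np.int64)
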