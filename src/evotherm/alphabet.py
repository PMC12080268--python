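"""Residue alphabets and integer encoding.

The default alphabet is the 21-state convention used throughout direct
coupling analysis: the gap character first (state 0), then the twenty
proteinogenic amino acids in alphabetical one-letter order. Models and
alignments may carry a reduced alphabet (useful for small synthetic
systems), but state 0 is always the gap.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = GAP + AMINO_ACIDS

#: Non-canonical residue codes mapped to gap (ambiguity codes, rare residues).
NON_CANONICAL = set("BZXJUO*")


def encode(sequences, alphabet: str = PROTEIN_ALPHABET) -> np.ndarray:
    """Encode an iterable of equal-length residue strings to an int8 matrix.

    Non-canonical residues are mapped to the gap state with a logged count.
    Unknown characters outside ``NON_CANONICAL`` raise ``ValueError``.
    """
    lookup = {c: i for i, c in enumerate(alphabet)}
    rows = []
    n_noncanonical = 0
    for seq in sequences:
        row = np.empty(len(seq), dtype=np.int8)
        for j, c in enumerate(seq.upper()):
            if c in lookup:
                row[j] = lookup[c]
            elif c == ".":
                row[j] = lookup[GAP]
            elif c in NON_CANONICAL:
                row[j] = lookup[GAP]
                n_noncanonical += 1
            else:
                raise ValueError(f"unknown residue character {c!r}")
        rows.append(row)
    if n_noncanonical:
        logger.warning(
            "mapped %d non-canonical residue(s) to gap", n_noncanonical
        )
    if rows and any(len(r) != len(rows[0]) for r in rows):
        raise ValueError("ragged rows: sequences differ in length")
    return np.vstack(rows) if rows else np.empty((0, 0), dtype=np.int8)


def decode(matrix: np.ndarray, alphabet: str = PROTEIN_ALPHABET) -> list[str]:
    """Decode an integer matrix back to residue strings."""
    chars = np.asarray(list(alphabet))
    return ["".join(chars[row]) for row in np.atleast_2d(matrix)]
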