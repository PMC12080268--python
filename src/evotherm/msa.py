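"""Multiple sequence alignment IO, filtering, reweighting and statistics.

This module prepares an alignment of homologs for Potts-model inference the
way DCA pipelines do: parse (FASTA / A2M / Stockholm), map columns onto the
ungapped focus (wild-type) sequence, drop gappy sequences and columns,
down-weight redundant homologs by identity clustering, and compute the
weighted single- and pairwise amino-acid frequencies the model is constrained
to reproduce.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .alphabet import GAP, PROTEIN_ALPHABET, decode, encode

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "SequenceWeights",
    "FrequencyTables",
    "read_alignment",
    "write_alignment",
    "filter_alignment",
    "filter_report",
    "compute_weights",
    "compute_frequencies",
]


@dataclasses.dataclass
class Alignment:
    """A focus-mapped alignment.

    ``matrix`` holds integer state codes (state 0 = gap), one row per
    sequence. ``column_map`` gives, for every retained column, the 1-based
    position in the ungapped focus sequence; it is strictly increasing and
    the focus row is gapless in every retained column.
    """

    ids: list[str]
    matrix: np.ndarray
    focus_id: str
    column_map: np.ndarray
    alphabet: str = PROTEIN_ALPHABET

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.column_map = np.asarray(self.column_map, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (sequences x columns)")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("ids and matrix row count differ")
        if self.ids.count(self.focus_id) != 1:
            raise ValueError(
                f"focus id {self.focus_id!r} must occur exactly once"
            )
        if self.column_map.shape[0] != self.matrix.shape[1]:
            raise ValueError("column_map length must equal alignment width")
        if self.length and np.any(np.diff(self.column_map) <= 0):
            raise ValueError("column_map must be strictly increasing")
        if np.any(self.focus_row == 0):
            raise ValueError("focus row must be gapless in retained columns")

    @property
    def n_seqs(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def q(self) -> int:
        return len(self.alphabet)

    @property
    def focus_index(self) -> int:
        return self.ids.index(self.focus_id)

    @property
    def focus_row(self) -> np.ndarray:
        return self.matrix[self.focus_index]

    def sequences(self) -> list[str]:
        """Rows as residue strings."""
        return decode(self.matrix, self.alphabet)

    def gap_fractions(self, axis: int = 1) -> np.ndarray:
        """Per-sequence (axis=1) or per-column (axis=0) gap fraction."""
        return (self.matrix == 0).mean(axis=axis)


@dataclasses.dataclass
class SequenceWeights:
    """Identity-clustering weights: weight(s) = 1 / |{t : id(s,t) >= 1-theta}|."""

    weights: np.ndarray
    theta: float
    n_eff: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in (0, 1]")
        if abs(self.weights.sum() - self.n_eff) > 1e-9:
            raise ValueError("n_eff must equal the sum of weights")


@dataclasses.dataclass
class FrequencyTables:
    """Weighted empirical frequencies, optionally mixed with uniform pseudocount.

    ``f_i`` has shape (L, q); ``f_ij`` has shape (L, L, q, q) with
    ``f_ij[i, j, k, l]`` the weighted probability of states (k, l) at
    positions (i, j).
    """

    f_i: np.ndarray
    f_ij: np.ndarray
    pseudocount_lambda: float


def _strip_inserts(seq: str) -> str:
    """Remove A2M/Stockholm insert states (lowercase letters and '.')."""
    return "".join(c for c in seq if not (c.islower() or c == "."))


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    focus_id: str | None = None,
) -> Alignment:
    """Read and focus-map an alignment.

    Supported formats: ``fasta`` (plain aligned FASTA), ``a2m`` (lowercase /
    '.' insert states removed so all rows align on match columns), and
    ``stockholm``. Non-standard residues are mapped to the gap state with a
    logged count. Columns in which the focus sequence is gapped are dropped
    and ``column_map`` is built over the ungapped focus sequence.
    """
    if format not in {"fasta", "a2m", "stockholm"}:
        raise ValueError(f"unknown alignment format {format!r}")
    parse_as = "fasta" if format == "a2m" else format
    records = list(SeqIO.parse(str(path), parse_as))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    if format in {"a2m", "stockholm"}:
        seqs = [_strip_inserts(s) for s in seqs]
    if focus_id is None:
        focus_id = ids[0]
    if ids.count(focus_id) != 1:
        raise ValueError(f"focus id {focus_id!r} must occur exactly once")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"ragged rows: lengths {sorted(lengths)}")
    matrix = encode(seqs)
    return _focus_map(ids, matrix, focus_id, PROTEIN_ALPHABET)


def _focus_map(
    ids: list[str], matrix: np.ndarray, focus_id: str, alphabet: str
) -> Alignment:
    """Drop columns gapped in the focus row; map survivors to focus positions."""
    focus = matrix[ids.index(focus_id)]
    keep = focus != 0
    column_map = np.arange(1, int(keep.sum()) + 1)
    return Alignment(ids, matrix[:, keep], focus_id, column_map, alphabet)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write the alignment as aligned FASTA."""
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.sequences()):
            fh.write(f">{sid}\n{seq}\n")


def filter_alignment(
    aln: Alignment,
    max_seq_gap: float = 0.5,
    max_col_gap: float = 0.3,
) -> Alignment:
    """Remove gappy sequences, then gappy columns.

    Sequences with gap fraction > ``max_seq_gap`` are removed first (the
    focus sequence is never removed); columns with gap fraction over the
    surviving rows > ``max_col_gap`` are removed second, and ``column_map``
    is updated. The defaults are the common DCA post-processing thresholds
    (50% sequence gaps, 30% column gaps).
    """
    for name, frac in (("max_seq_gap", max_seq_gap), ("max_col_gap", max_col_gap)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {frac}")
    seq_gaps = aln.gap_fractions(axis=1)
    keep_rows = seq_gaps <= max_seq_gap
    keep_rows[aln.focus_index] = True
    if aln.n_seqs > 1 and keep_rows.sum() <= 1:
        raise ValueError("sequence filtering removed all non-focus rows")
    matrix = aln.matrix[keep_rows]
    ids = [sid for sid, k in zip(aln.ids, keep_rows) if k]
    col_gaps = (matrix == 0).mean(axis=0)
    keep_cols = col_gaps <= max_col_gap
    return Alignment(
        ids,
        matrix[:, keep_cols],
        aln.focus_id,
        aln.column_map[keep_cols],
        aln.alphabet,
    )


def filter_report(aln: Alignment, max_seq_gap: float = 0.5) -> str:
    """Tab-delimited per-sequence report: sequence_id, gap_fraction, kept."""
    lines = ["sequence_id\tgap_fraction\tkept"]
    for sid, frac in zip(aln.ids, aln.gap_fractions(axis=1)):
        kept = sid == aln.focus_id or frac <= max_seq_gap
        lines.append(f"{sid}\t{frac:.4f}\t{str(kept).lower()}")
    return "\n".join(lines) + "\n"


def compute_weights(
    aln: Alignment, theta: float = 0.2, chunk: int = 512
) -> SequenceWeights:
    """Down-weight redundant sequences by identity clustering.

    A sequence's weight is the reciprocal of the number of alignment rows
    (itself included) whose fractional identity to it is at least
    ``1 - theta``; ``n_eff`` is the sum of weights. ``theta = 0.2`` (80%
    identity clusters) is the standard DCA choice.
    """
    if not 0.0 <= theta < 1.0:
        raise ValueError(f"theta must lie in [0, 1), got {theta}")
    if aln.n_seqs == 0:
        raise ValueError("empty alignment")
    n, L = aln.matrix.shape
    counts = np.zeros(n, dtype=np.int64)
    cutoff = 1.0 - theta
    # chunked pairwise identity to keep memory at O(chunk * n * L)
    for start in range(0, n, chunk):
        block = aln.matrix[start : start + chunk]
        ident = (block[:, None, :] == aln.matrix[None, :, :]).mean(axis=2)
        counts[start : start + chunk] = (ident >= cutoff - 1e-12).sum(axis=1)
    weights = 1.0 / counts
    return SequenceWeights(weights=weights, theta=theta, n_eff=float(weights.sum()))


def compute_frequencies(
    aln: Alignment,
    w: SequenceWeights,
    pseudocount_lambda: float = 0.0,
) -> FrequencyTables:
    """Weighted empirical frequencies, mixed with the uniform distribution.

    f_i = (1 - lambda) f_i^emp + lambda / q and
    f_ij = (1 - lambda) f_ij^emp + lambda / q^2. At lambda = 0 the pair
    table marginalizes exactly to the single-site table.
    """
    if w.weights.shape[0] != aln.n_seqs:
        raise ValueError("weights do not match alignment rows")
    lam = float(pseudocount_lambda)
    if not 0.0 <= lam < 1.0:
        raise ValueError("pseudocount_lambda must lie in [0, 1)")
    n, L = aln.matrix.shape
    q = aln.q
    wn = w.weights / w.weights.sum()
    one_hot = np.zeros((n, L, q), dtype=float)
    rows = np.arange(n)[:, None]
    cols = np.arange(L)[None, :]
    one_hot[rows, cols, aln.matrix] = 1.0
    f_i = np.einsum("s,slk->lk", wn, one_hot)
    f_ij = np.einsum("s,sik,sjl->ijkl", wn, one_hot, one_hot)
    f_i = (1.0 - lam) * f_i + lam / q
    f_ij = (1.0 - lam) * f_ij + lam / q**2
    return FrequencyTables(f_i=f_i, f_ij=f_ij, pseudocount_lambda=lam)
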