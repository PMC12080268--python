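"""Variant scoring, enumeration, ranking and epistasis decomposition.

Variants are named in protein-engineering convention ("Q289G",
"S180T/Q289G"; 1-based positions on the ungapped wild-type sequence).
Sequence-based scores are statistical-energy differences
dE = E(variant) - E(wild type) under a Potts model (positive = favored);
structure-based scores are run-averaged ddG tables produced upstream
(negative = predicted stabilizing), ingested rather than computed.
"""

from __future__ import annotations

import dataclasses
import io
import logging
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS
from .potts import PottsModel, energy

logger = logging.getLogger(__name__)

__all__ = [
    "Variant",
    "VariantScore",
    "EpistasisRecord",
    "parse_variant",
    "score_variant",
    "enumerate_and_rank",
    "epistasis_decompose",
    "ingest_ddg_runs",
    "stabilizing_only",
    "scores_to_frame",
]

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclasses.dataclass(frozen=True)
class Variant:
    """An ordered set of substitutions (position, wt_aa, mut_aa)."""

    substitutions: tuple[tuple[int, str, str], ...]

    def __post_init__(self) -> None:
        subs = tuple(sorted(self.substitutions, key=lambda s: s[0]))
        object.__setattr__(self, "substitutions", subs)
        positions = [p for p, _, _ in subs]
        if len(set(positions)) != len(positions):
            raise ValueError(f"duplicate positions in variant {self.name}")
        for pos, wt, mut in subs:
            if wt not in AMINO_ACIDS or mut not in AMINO_ACIDS:
                raise ValueError(f"non-amino-acid state in {wt}{pos}{mut}")
            if wt == mut:
                raise ValueError(f"substitution {wt}{pos}{mut} is synonymous")

    @property
    def name(self) -> str:
        return "/".join(f"{wt}{pos}{mut}" for pos, wt, mut in self.substitutions)

    @property
    def order(self) -> int:
        return len(self.substitutions)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def parse_variant(name: str) -> Variant:
    """Parse "A123B" or "A123B/C456D" (any number of substitutions)."""
    subs = []
    for part in name.strip().split("/"):
        m = _SUB_RE.match(part.strip())
        if not m:
            raise ValueError(f"cannot parse substitution {part!r}")
        subs.append((int(m.group(2)), m.group(1), m.group(3)))
    return Variant(tuple(subs))


@dataclasses.dataclass
class VariantScore:
    """A ranked variant with either a dE or an aggregated ddG score."""

    variant: Variant
    delta_e: float | None = None
    ddg_mean: float | None = None
    ddg_sem: float | None = None
    rank: int | None = None


@dataclasses.dataclass
class EpistasisRecord:
    """dE-level decomposition of a double: dE_ab = dE_a + dE_b + coupling_gap."""

    double: Variant
    delta_e_double: float
    delta_e_a: float
    delta_e_b: float

    @property
    def coupling_gap(self) -> float:
        return self.delta_e_double - self.delta_e_a - self.delta_e_b


def _state_index(model: PottsModel, aa: str) -> int:
    idx = model.alphabet.find(aa)
    if idx <= 0:
        raise ValueError(f"state {aa!r} not a modeled amino acid")
    return idx


def _check_wt(model: PottsModel, pos: int, wt: str, col: int) -> None:
    wt_code = int(model.focus_seq[col])
    if model.alphabet[wt_code] != wt:
        raise ValueError(
            f"wild-type mismatch at position {pos}: variant says {wt}, "
            f"focus sequence has {model.alphabet[wt_code]}"
        )


def score_variant(model: PottsModel, v: Variant) -> float:
    """dE(variant, wild type), computed incrementally.

    Only terms touching substituted positions are evaluated; the result is
    exactly energy(mutant) - energy(wild type). Raises ``KeyError`` for a
    position that was filtered out of the model.
    """
    if model.focus_seq is None:
        raise ValueError("model has no focus sequence")
    sigma = model.focus_seq.astype(np.int64)
    cols, muts, wts = [], [], []
    for pos, wt, mut in v.substitutions:
        col = model.position_index(pos)
        _check_wt(model, pos, wt, col)
        cols.append(col)
        wts.append(int(sigma[col]))
        muts.append(_state_index(model, mut))
    de = 0.0
    in_sub = np.zeros(model.L, dtype=bool)
    in_sub[cols] = True
    others = np.nonzero(~in_sub)[0]
    for col, w, m in zip(cols, wts, muts):
        de += model.h[col, m] - model.h[col, w]
        if others.size:
            de += (
                model.J[col, others, m, sigma[others]]
                - model.J[col, others, w, sigma[others]]
            ).sum()
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            de += (
                model.J[cols[a], cols[b], muts[a], muts[b]]
                - model.J[cols[a], cols[b], wts[a], wts[b]]
            )
    return float(de)


def _single_effects(model: PottsModel) -> np.ndarray:
    """dE for every (model column, mutant state); wt column entries are 0."""
    sigma = model.focus_seq.astype(np.int64)
    jidx = np.arange(model.L)
    # J[i, j, a, sigma_j]; advanced axes (j, sigma_j) land first -> (j, i, a)
    coupled = model.J[:, jidx, :, sigma].sum(axis=0)
    field = model.h + coupled  # effective field h_i(a) + sum_j J_ij(a, sigma_j)
    return field - field[np.arange(model.L), sigma][:, None]


def enumerate_and_rank(
    model: PottsModel, order: str = "single", top_k: int = 20
) -> list[VariantScore]:
    """Enumerate all single or double substitutions and return the top_k by dE.

    Sorting is by dE descending with ties broken by (position, mutant amino
    acid); ranks are 1-based and dense (equal dE shares a rank). Gap states
    are never proposed. If ``top_k`` exceeds the enumeration size everything
    is returned with a logged warning.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if order not in {"single", "double"}:
        raise ValueError("order must be 'single' or 'double'")
    if model.focus_seq is None:
        raise ValueError("model has no focus sequence")
    sigma = model.focus_seq.astype(np.int64)
    single = _single_effects(model)
    aa_states = np.arange(1, model.q)  # exclude gap

    def mk_variant(col: int, state: int) -> tuple[int, str, str]:
        return (
            int(model.positions[col]),
            model.alphabet[int(sigma[col])],
            model.alphabet[int(state)],
        )

    candidates: list[tuple[float, tuple, Variant]] = []
    if order == "single":
        for i in range(model.L):
            for a in aa_states:
                if a == sigma[i]:
                    continue
                sub = mk_variant(i, int(a))
                v = Variant((sub,))
                key = (sub[0], sub[2])
                candidates.append((float(single[i, a]), key, v))
        total = model.L * (len(aa_states) - 1)
    else:
        keep = max(top_k, 1)
        for i in range(model.L):
            for j in range(i + 1, model.L):
                gap = (
                    model.J[i, j]
                    - model.J[i, j, :, sigma[j]][:, None]
                    - model.J[i, j, sigma[i], :][None, :]
                    + model.J[i, j, sigma[i], sigma[j]]
                )
                de = single[i][:, None] + single[j][None, :] + gap
                de = de[aa_states][:, aa_states]
                mask = (aa_states != sigma[i])[:, None] & (
                    aa_states != sigma[j]
                )[None, :]
                flat = np.flatnonzero(mask)
                vals = de.ravel()[flat]
                take = min(keep, vals.size)
                best = flat[np.argpartition(-vals, take - 1)[:take]]
                for idx in best:
                    a = int(aa_states[idx // len(aa_states)])
                    b = int(aa_states[idx % len(aa_states)])
                    sub_i, sub_j = mk_variant(i, a), mk_variant(j, b)
                    v = Variant((sub_i, sub_j))
                    key = (sub_i[0], sub_i[2], sub_j[0], sub_j[2])
                    candidates.append((float(de[idx // len(aa_states), idx % len(aa_states)]), key, v))
        n_aa = len(aa_states) - 1
        total = model.L * (model.L - 1) // 2 * n_aa * n_aa
    if top_k > total:
        logger.warning(
            "top_k=%d exceeds enumeration size %d; returning all", top_k, total
        )
    candidates.sort(key=lambda c: (-c[0], c[1]))
    out: list[VariantScore] = []
    rank = 0
    prev = None
    for de, _, v in candidates[: min(top_k, total)]:
        if prev is None or de != prev:
            rank += 1
        prev = de
        out.append(VariantScore(variant=v, delta_e=de, rank=rank))
    return out


def epistasis_decompose(
    source: PottsModel | Mapping[str, float], double: Variant
) -> EpistasisRecord:
    """Decompose a double's dE into its two singles plus a coupling gap.

    ``source`` is either a fitted Potts model (scores computed on the fly;
    the gap then equals the four-term coupling difference) or a mapping of
    variant name -> dE that must contain the double and both singles.
    """
    if double.order != 2:
        raise ValueError("epistasis decomposition needs a double variant")
    (p1, w1, m1), (p2, w2, m2) = double.substitutions
    a = Variant(((p1, w1, m1),))
    b = Variant(((p2, w2, m2),))
    if isinstance(source, PottsModel):
        de_ab = score_variant(source, double)
        de_a = score_variant(source, a)
        de_b = score_variant(source, b)
    else:
        try:
            de_ab = float(source[double.name])
            de_a = float(source[a.name])
            de_b = float(source[b.name])
        except KeyError as exc:
            raise KeyError(
                f"missing constituent score {exc.args[0]!r} for {double.name}"
            ) from exc
    return EpistasisRecord(
        double=double, delta_e_double=de_ab, delta_e_a=de_a, delta_e_b=de_b
    )


def ingest_ddg_runs(
    table: str | Path | pd.DataFrame, sep: str = r"\s+|,|\t"
) -> list[VariantScore]:
    """Aggregate per-run ddG predictions into ranked per-variant scores.

    Expects columns (variant, run_index, ddg); any whitespace/comma/tab
    delimited text, a path, or a DataFrame. Per variant: mean over runs and
    SEM = sample standard deviation / sqrt(n runs) (0 for a single run).
    Output is sorted ascending by mean ddG (most stabilizing first), ties
    broken by variant name, with dense 1-based ranks.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        text = (
            table if isinstance(table, str) and "\n" in table
            else Path(table).read_text()
        )
        df = pd.read_csv(io.StringIO(text), sep=sep, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"variant", "run_index", "ddg"}
    if not required.issubset(df.columns):
        raise ValueError(f"ddG table must have columns {sorted(required)}")
    if df.duplicated(subset=["variant", "run_index"]).any():
        dup = df[df.duplicated(subset=["variant", "run_index"])].iloc[0]
        raise ValueError(
            f"duplicate run {dup['run_index']} for variant {dup['variant']}"
        )
    df["ddg"] = pd.to_numeric(df["ddg"], errors="raise")
    agg = df.groupby("variant")["ddg"].agg(["mean", "std", "count"])
    agg["sem"] = (agg["std"] / np.sqrt(agg["count"])).fillna(0.0)
    agg = agg.sort_values(["mean", "variant"], kind="mergesort")
    out: list[VariantScore] = []
    rank = 0
    prev = None
    for name, row in agg.iterrows():
        if prev is None or row["mean"] != prev:
            rank += 1
        prev = row["mean"]
        out.append(
            VariantScore(
                variant=parse_variant(str(name)),
                ddg_mean=float(row["mean"]),
                ddg_sem=float(row["sem"]),
                rank=rank,
            )
        )
    return out


def stabilizing_only(scores: list[VariantScore]) -> list[VariantScore]:
    """Keep predicted-stabilizing variants (mean ddG < 0)."""
    return [s for s in scores if s.ddg_mean is not None and s.ddg_mean < 0]


def scores_to_frame(scores: list[VariantScore]) -> pd.DataFrame:
    """Score list as a writable table (rank, variant, score columns)."""
    rows = []
    for s in scores:
        row = {"rank": s.rank, "variant": s.variant.name}
        if s.delta_e is not None:
            row["delta_e"] = s.delta_e
        if s.ddg_mean is not None:
            row["ddg_mean"] = s.ddg_mean
            row["ddg_sem"] = s.ddg_sem
        rows.append(row)
    return pd.DataFrame(rows)
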