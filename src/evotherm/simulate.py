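"""Synthetic-data generators with recorded ground truth.

Every generator returns ``(data, SyntheticTruth)`` where the truth object
carries the exact generating parameters and seed; regeneration from the
same parameters and seed is bit-identical. Pipelines never read the truth
(blind analysis) — only tests and the acceptance harness do.

Generators:

* :func:`sample_msa` — alignments drawn from a known Potts model by
  single-site Gibbs sampling (p(sigma) proportional to exp E(sigma)),
* :func:`make_melting_curve` — two-state unfolding with linear pre-/post-
  transition baselines and additive Gaussian noise,
* :func:`make_decay_series` — first-order residual-activity decay with
  multiplicative (CV-style) replicate noise,
* :func:`make_plate` — replicated assay plates with known fold-changes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import softmax

from .msa import Alignment
from .potts import PottsModel
from .thermal import DecaySeries, MeltingCurve

__all__ = [
    "SyntheticTruth",
    "sample_msa",
    "make_melting_curve",
    "make_decay_series",
    "make_plate",
]


@dataclasses.dataclass
class SyntheticTruth:
    """Ground-truth parameters of a generated dataset."""

    generator: str
    parameters: dict
    seed: int

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_jsonable)

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _default_focus(model: PottsModel) -> np.ndarray:
    """Gapless focus for models without one: per-site argmax over amino acids."""
    return (np.argmax(model.h[:, 1:], axis=1) + 1).astype(np.int8)


def sample_msa(
    model: PottsModel,
    n_sequences: int,
    burn_in: int = 50,
    thin: int = 1,
    seed: int = 0,
) -> tuple[Alignment, SyntheticTruth]:
    """Draw sequences from a Potts model by single-site Gibbs sampling.

    ``n_sequences`` independent chains are initialized uniformly at random
    and advanced for ``burn_in + thin`` full sweeps; each chain contributes
    its final state, so samples are independent across rows. The model's
    focus sequence is prepended as row "focus" so the result is a valid
    focus-mapped alignment.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if burn_in < 1 or thin < 1:
        raise ValueError("burn_in and thin must be >= 1")
    rng = np.random.default_rng(seed)
    L, q = model.L, model.q
    S = rng.integers(0, q, size=(n_sequences, L), dtype=np.int64)
    jidx = np.arange(L)
    for _ in range(burn_in + thin):
        for i in range(L):
            # conditional logits: h_i(a) + sum_j J_ij(a, sigma_j)
            contrib = model.J[i][jidx[None, :], :, S].sum(axis=1)
            z = model.h[i][None, :] + contrib
            p = softmax(z, axis=1)
            u = rng.random(n_sequences)
            S[:, i] = (p.cumsum(axis=1) > u[:, None]).argmax(axis=1)
    focus = (
        model.focus_seq if model.focus_seq is not None else _default_focus(model)
    )
    matrix = np.vstack([focus[None, :], S]).astype(np.int8)
    ids = ["focus"] + [f"sample_{i}" for i in range(n_sequences)]
    aln = Alignment(
        ids=ids,
        matrix=matrix,
        focus_id="focus",
        column_map=model.positions.copy(),
        alphabet=model.alphabet,
    )
    truth = SyntheticTruth(
        generator="sample_msa",
        parameters={
            "n_sequences": n_sequences,
            "burn_in": burn_in,
            "thin": thin,
            "L": L,
            "q": q,
        },
        seed=seed,
    )
    return aln, truth


def make_melting_curve(
    tm: float,
    width: float = 2.0,
    pre: tuple[float, float] = (1.0, 0.0),
    post: tuple[float, float] = (2.0, 0.0),
    noise_sd: float = 0.0,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[MeltingCurve, SyntheticTruth]:
    """Two-state unfolding curve on a temperature grid (default 20-95 degC).

    signal(T) = pre(T) (1 - theta) + post(T) theta with the two-state
    logistic theta(T) = 1 / (1 + exp(-(T - tm)/width)); ``pre`` and
    ``post`` are (intercept, slope) baselines; Gaussian noise of standard
    deviation ``noise_sd`` (signal units) is added.
    """
    if grid is None:
        grid = np.arange(20.0, 96.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    if not grid[0] <= tm <= grid[-1]:
        raise ValueError(f"tm={tm} outside the scanned range {grid[0]}-{grid[-1]}")
    rng = np.random.default_rng(seed)
    theta = 1.0 / (1.0 + np.exp(-(grid - tm) / width))
    sig = (pre[0] + pre[1] * grid) * (1 - theta) + (post[0] + post[1] * grid) * theta
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=grid.shape)
    truth = SyntheticTruth(
        generator="make_melting_curve",
        parameters={
            "tm": tm,
            "width": width,
            "pre": list(pre),
            "post": list(post),
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return MeltingCurve(temperatures=grid, signal=sig), truth


def make_decay_series(
    t_half: float,
    a0: float = 100.0,
    times: np.ndarray | None = None,
    n_replicates: int = 3,
    noise_frac: float = 0.05,
    seed: int = 0,
) -> tuple[DecaySeries, SyntheticTruth]:
    """First-order residual-activity decay sampled at 75 degC-style intervals.

    Replicate values are a0 exp(-ln 2 t / t_half) (1 + N(0, noise_frac)),
    clipped at zero; the default grid is every 15 minutes over 0-150 min.
    """
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    if times is None:
        times = np.arange(0.0, 151.0, 15.0)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    clean = a0 * np.exp(-np.log(2) * times / t_half)
    noise = rng.normal(0.0, noise_frac, size=(n_replicates, times.size))
    activities = np.clip(clean[None, :] * (1.0 + noise), 0.0, None)
    truth = SyntheticTruth(
        generator="make_decay_series",
        parameters={
            "t_half": t_half,
            "a0": a0,
            "times": times,
            "n_replicates": n_replicates,
            "noise_frac": noise_frac,
        },
        seed=seed,
    )
    return DecaySeries(times=times, activities=activities), truth


def make_plate(
    true_folds: dict[str, float],
    wt_signal: float = 1.0,
    background: float = 0.1,
    n_replicates: int = 3,
    noise_frac: float = 0.05,
    seed: int = 0,
    condition: str = "T60",
    wt_name: str = "WT",
    background_name: str = "empty_vector",
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Replicated assay plate with known fold-changes relative to wild type.

    Each variant's clean signal is background + fold * (wt_signal -
    background); wild type (fold 1) and empty-vector background wells are
    always present. All wells get multiplicative noise (1 + N(0,
    noise_frac)).
    """
    if wt_signal <= background:
        raise ValueError("wt_signal must exceed background")
    if any(f < 0 for f in true_folds.values()):
        raise ValueError("folds must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []

    def add(variant: str, clean: float, is_background: bool) -> None:
        for rep in range(1, n_replicates + 1):
            value = clean * (1.0 + rng.normal(0.0, noise_frac))
            rows.append(
                {
                    "variant": variant,
                    "condition": condition,
                    "replicate": rep,
                    "signal": max(value, 0.0),
                    "is_background": is_background,
                }
            )

    add(background_name, background, True)
    add(wt_name, wt_signal, False)
    for variant, fold in true_folds.items():
        add(variant, background + fold * (wt_signal - background), False)
    truth = SyntheticTruth(
        generator="make_plate",
        parameters={
            "true_folds": dict(true_folds),
            "wt_signal": wt_signal,
            "background": background,
            "n_replicates": n_replicates,
            "noise_frac": noise_frac,
            "condition": condition,
        },
        seed=seed,
    )
    return pd.DataFrame(rows), truth
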