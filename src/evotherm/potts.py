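"""Potts (direct coupling analysis) model and pseudo-likelihood inference.

The model assigns every sequence sigma a statistical energy

    E(sigma) = sum_i h_i(sigma_i) + sum_{i<j} J_ij(sigma_i, sigma_j)

with the convention that the sequence probability is proportional to
exp(E), so *higher* energies are more favorable. Parameters are inferred
from a reweighted alignment by L2-regularized pseudo-likelihood
maximization: each site's conditional distribution given the rest of the
sequence is a multinomial logistic regression, fitted independently per
site (asymmetric estimates), after which couplings are symmetrized by
averaging and the model is converted to the zero-sum gauge.
"""

from __future__ import annotations

import dataclasses
import json
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax
from sklearn.base import BaseEstimator

from .alphabet import PROTEIN_ALPHABET
from .msa import Alignment, SequenceWeights, compute_weights

__all__ = [
    "PottsModel",
    "FitReport",
    "PottsPLM",
    "ModelFormatError",
    "energy",
    "fit_plm",
    "to_zero_sum_gauge",
    "save_model",
    "load_model",
    "coupling_norms",
]

MODEL_FORMAT = "evotherm-potts-1"


class ModelFormatError(RuntimeError):
    """Raised when a model file is truncated, corrupted or of a wrong version."""


@dataclasses.dataclass
class PottsModel:
    """Local biases ``h`` (L, q) and couplings ``J`` (L, L, q, q).

    ``J`` is stored densely with ``J[i, j, a, b] == J[j, i, b, a]`` and zero
    diagonal blocks. ``positions`` maps model columns to 1-based positions
    on the ungapped focus sequence; ``focus_seq`` is the wild type encoded
    over the model alphabet (state 0 = gap, never present in the focus).
    """

    h: np.ndarray
    J: np.ndarray
    alphabet: str = PROTEIN_ALPHABET
    positions: np.ndarray | None = None
    focus_seq: np.ndarray | None = None
    lambda_h: float = 0.01
    lambda_e: float | None = None
    gauge: str = "none"

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError("J must have shape (L, L, q, q) matching h")
        if len(self.alphabet) != q:
            raise ValueError("alphabet size must equal q")
        if self.positions is None:
            self.positions = np.arange(1, L + 1)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.shape != (L,):
            raise ValueError("positions must have length L")
        if self.focus_seq is not None:
            self.focus_seq = np.asarray(self.focus_seq, dtype=np.int8)
            if self.focus_seq.shape != (L,):
                raise ValueError("focus_seq must have length L")
            if np.any(self.focus_seq == 0):
                raise ValueError("focus_seq must not contain the gap state")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    def position_index(self, position: int) -> int:
        """Model column for a 1-based focus position (raises if unmodeled)."""
        idx = np.nonzero(self.positions == position)[0]
        if idx.size == 0:
            raise KeyError(
                f"unmodeled position {position}: filtered from the alignment"
            )
        return int(idx[0])


@dataclasses.dataclass
class FitReport:
    """Bookkeeping of a pseudo-likelihood fit.

    ``final_objective`` is the summed per-site penalized objective
    (sum_s w_s NLL_s + lambda_h ||h||^2 + lambda_e ||J||^2); lambdas are
    absolute, so refits are invariant to duplicating the alignment (n_eff
    unchanged) and scale consistently with n_eff: doubling every weight and
    both lambdas reproduces the same parameters.
    """

    n_iterations: int
    final_objective: float
    gradient_norm: float
    converged: bool
    n_eff: float
    lambda_h: float
    lambda_e: float
    seed: int
    tol: float
    objective_traces: list[list[float]] = dataclasses.field(default_factory=list)


def energy(model: PottsModel, sigma: np.ndarray | str) -> float:
    """Statistical energy E(sigma); higher is more favorable."""
    sigma = _encode_state(model, sigma)
    idx = np.arange(model.L)
    e_h = model.h[idx, sigma].sum()
    pair = model.J[idx[:, None], idx[None, :], sigma[:, None], sigma[None, :]]
    e_j = np.triu(pair, k=1).sum()
    return float(e_h + e_j)


def _encode_state(model: PottsModel, sigma: np.ndarray | str) -> np.ndarray:
    if isinstance(sigma, str):
        lookup = {c: i for i, c in enumerate(model.alphabet)}
        try:
            sigma = np.array([lookup[c] for c in sigma], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"unknown state {exc.args[0]!r}") from exc
    sigma = np.asarray(sigma, dtype=np.int64)
    if sigma.shape != (model.L,):
        raise ValueError(f"sequence length {sigma.size} != model L {model.L}")
    if sigma.min() < 0 or sigma.max() >= model.q:
        raise ValueError("sequence contains states outside the model alphabet")
    return sigma


def to_zero_sum_gauge(model: PottsModel) -> PottsModel:
    """Convert to the zero-sum gauge.

    In this gauge every h_i and every row/column of every coupling block
    sums to zero; all energy *differences* E(sigma) - E(tau) are preserved
    (the transform shifts E by a sequence-independent constant).
    """
    h, J = model.h, model.J
    L, q = model.L, model.q
    Jbar_ab = J.mean(axis=(2, 3), keepdims=True)        # (L, L, 1, 1)
    Jbar_b = J.mean(axis=3, keepdims=True)              # (L, L, q, 1) mean over b
    Jbar_a = J.mean(axis=2, keepdims=True)              # (L, L, 1, q) mean over a
    J_zs = J - Jbar_a - Jbar_b + Jbar_ab
    # absorb the removed row means into the fields: g_i(a) = h_i(a) + sum_j mean_b J_ij(a,b)
    g = h + (Jbar_b[:, :, :, 0] - Jbar_ab[:, :, 0, 0][:, :, None]).sum(axis=1)
    h_zs = g - g.mean(axis=1, keepdims=True)
    return dataclasses.replace(model, h=h_zs, J=J_zs, gauge="zero-sum")


def _site_objective(x, i, matrix, one_hot, w, lambda_h, lambda_e, L, q):
    """Penalized conditional NLL and gradient for site i (asymmetric fit)."""
    h_i = x[:q]
    K = x[q:].reshape(L - 1, q, q)
    others = np.delete(np.arange(L), i)
    X = one_hot[:, others, :]                        # (n, L-1, q)
    z = h_i + np.einsum("sjb,jab->sa", X, K)         # (n, q)
    lse = logsumexp(z, axis=1)
    y = matrix[:, i]
    nll = float(np.dot(w, lse - z[np.arange(len(y)), y]))
    obj = nll + lambda_h * np.dot(h_i, h_i) + lambda_e * np.dot(x[q:], x[q:])
    P = softmax(z, axis=1)
    P[np.arange(len(y)), y] -= 1.0
    Pw = P * w[:, None]
    g_h = Pw.sum(axis=0) + 2.0 * lambda_h * h_i
    g_K = np.einsum("sa,sjb->jab", Pw, X) + 2.0 * lambda_e * K
    return obj, np.concatenate([g_h, g_K.ravel()])


class PottsPLM(BaseEstimator):
    """Pseudo-likelihood Potts model estimator (plmc-style, asymmetric).

    Parameters
    ----------
    lambda_h : float
        L2 strength on the local biases (default 0.01).
    lambda_e : float or "auto"
        L2 strength on the couplings; "auto" resolves to 0.2 * (L - 1)
        where L is the number of modeled sites.
    theta : float
        Identity-clustering threshold used when no precomputed weights are
        supplied to :meth:`fit`.
    tol : float
        Gradient infinity-norm tolerance for convergence.
    max_iter : int
        Per-site L-BFGS iteration cap.
    seed : int
        Controls optimizer initialization. The default initialization is
        zeros, so fitting is deterministic; the seed is recorded for
        provenance.

    Attributes
    ----------
    model_ : PottsModel
        Fitted, zero-sum-gauge model.
    report_ : FitReport
        Optimization metadata.
    """

    def __init__(
        self,
        lambda_h: float = 0.01,
        lambda_e: float | str = "auto",
        theta: float = 0.2,
        tol: float = 1e-5,
        max_iter: int = 500,
        seed: int = 0,
    ):
        self.lambda_h = lambda_h
        self.lambda_e = lambda_e
        self.theta = theta
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, aln: Alignment, weights: SequenceWeights | None = None):
        if aln.n_seqs == 0:
            raise ValueError("empty alignment")
        if aln.length < 2:
            raise ValueError("need at least 2 modeled sites")
        if self.lambda_h <= 0:
            raise ValueError("lambda_h must be positive")
        if weights is None:
            weights = compute_weights(aln, theta=self.theta)
        if weights.weights.shape[0] != aln.n_seqs:
            raise ValueError("weights do not match alignment rows")
        L, q = aln.length, aln.q
        lambda_e = (
            0.2 * (L - 1) if self.lambda_e == "auto" else float(self.lambda_e)
        )
        matrix = aln.matrix.astype(np.int64)
        n = aln.n_seqs
        w = weights.weights
        one_hot = np.zeros((n, L, q))
        one_hot[np.arange(n)[:, None], np.arange(L)[None, :], matrix] = 1.0

        h = np.zeros((L, q))
        K_all = np.zeros((L, L, q, q))  # K_all[i, j] = couplings from site-i fit
        n_iter = 0
        grad_norm = 0.0
        final_obj = 0.0
        traces: list[list[float]] = []
        for i in range(L):
            x0 = np.zeros(q + (L - 1) * q * q)
            trace: list[float] = []

            def cb(xk, i=i):
                trace.append(
                    _site_objective(
                        xk, i, matrix, one_hot, w, self.lambda_h, lambda_e, L, q
                    )[0]
                )

            res = minimize(
                _site_objective,
                x0,
                args=(i, matrix, one_hot, w, self.lambda_h, lambda_e, L, q),
                method="L-BFGS-B",
                jac=True,
                callback=cb,
                options={"maxiter": self.max_iter, "gtol": self.tol, "ftol": 0.0},
            )
            h[i] = res.x[:q]
            others = np.delete(np.arange(L), i)
            K_all[i, others] = res.x[q:].reshape(L - 1, q, q)
            n_iter += res.nit
            grad_norm = max(grad_norm, float(np.abs(res.jac).max()))
            final_obj += float(res.fun)
            traces.append(trace)

        # symmetrize the two asymmetric estimates of every coupling block
        J = 0.5 * (K_all + K_all.transpose(1, 0, 3, 2))
        focus_seq = aln.focus_row.copy()
        model = PottsModel(
            h=h,
            J=J,
            alphabet=aln.alphabet,
            positions=aln.column_map.copy(),
            focus_seq=focus_seq,
            lambda_h=self.lambda_h,
            lambda_e=lambda_e,
        )
        self.model_ = to_zero_sum_gauge(model)
        self.report_ = FitReport(
            n_iterations=n_iter,
            final_objective=final_obj,
            gradient_norm=grad_norm,
            converged=bool(grad_norm <= self.tol),
            n_eff=weights.n_eff,
            lambda_h=self.lambda_h,
            lambda_e=lambda_e,
            seed=self.seed,
            tol=self.tol,
            objective_traces=traces,
        )
        return self

    def score_samples(self, sequences) -> np.ndarray:
        """Statistical energies of encoded sequences (rows) under ``model_``."""
        return np.array([energy(self.model_, s) for s in sequences])


def fit_plm(
    aln: Alignment,
    w: SequenceWeights | None = None,
    lambda_h: float = 0.01,
    lambda_e: float | str = "auto",
    tol: float = 1e-5,
    max_iter: int = 500,
    seed: int = 0,
) -> tuple[PottsModel, FitReport]:
    """Functional wrapper over :class:`PottsPLM`."""
    est = PottsPLM(
        lambda_h=lambda_h, lambda_e=lambda_e, tol=tol, max_iter=max_iter, seed=seed
    ).fit(aln, weights=w)
    return est.model_, est.report_


def save_model(model: PottsModel, path: str | Path) -> None:
    """Save as an .npz container with a JSON metadata header."""
    meta = {
        "format": MODEL_FORMAT,
        "alphabet": model.alphabet,
        "lambda_h": model.lambda_h,
        "lambda_e": model.lambda_e,
        "gauge": model.gauge,
    }
    arrays = {
        "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        "h": model.h,
        "J": model.J,
        "positions": model.positions,
    }
    if model.focus_seq is not None:
        arrays["focus_seq"] = model.focus_seq
    np.savez(str(path), **arrays)


def load_model(path: str | Path) -> PottsModel:
    """Load a model written by :func:`save_model`; validates the format tag."""
    try:
        with np.load(str(path)) as data:
            try:
                meta = json.loads(bytes(data["meta"]).decode())
            except (KeyError, json.JSONDecodeError) as exc:
                raise ModelFormatError(f"corrupted model header in {path}") from exc
            if meta.get("format") != MODEL_FORMAT:
                raise ModelFormatError(
                    f"unsupported model format {meta.get('format')!r}"
                )
            return PottsModel(
                h=data["h"],
                J=data["J"],
                alphabet=meta["alphabet"],
                positions=data["positions"],
                focus_seq=data["focus_seq"] if "focus_seq" in data else None,
                lambda_h=meta["lambda_h"],
                lambda_e=meta["lambda_e"],
                gauge=meta["gauge"],
            )
    except (zipfile.BadZipFile, ValueError, OSError, EOFError) as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc


def coupling_norms(model: PottsModel, gap_state: bool = True) -> pd.DataFrame:
    """Per-pair Frobenius norms of the zero-sum-gauge couplings.

    Returns a DataFrame with 1-based focus positions ``i < j`` and the norm
    ||J_ij||_F. With ``gap_state=False`` the gap row/column is excluded
    before taking the norm.
    """
    zs = model if model.gauge == "zero-sum" else to_zero_sum_gauge(model)
    rows = []
    for i in range(model.L):
        for j in range(i + 1, model.L):
            block = zs.J[i, j]
            if not gap_state:
                block = block[1:, 1:]
            rows.append(
                (int(model.positions[i]), int(model.positions[j]),
                 float(np.linalg.norm(block)))
            )
    return pd.DataFrame(rows, columns=["i", "j", "norm"])
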