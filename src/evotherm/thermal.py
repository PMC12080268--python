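"""Thermal-resistance characterization: activity, melting, decay, correlation.

Implements the experimental-analysis stages of a thermostability campaign:

* plate-assay normalization (background-subtracted activity relative to
  wild type, SEM over biological replicates),
* classification of a variant against wild type on a combined-SEM z score,
* hit rates,
* melting-temperature extraction from two-state unfolding curves
  (smoothed-derivative maximum, with a sigmoid two-state fit as
  cross-check),
* first-order thermal-deactivation fits (half-life t1/2 = ln 2 / k),
* Spearman rank correlation for stability-activity tradeoff analysis,
* experimental epistasis deviations for double substitutions.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats
from sklearn.base import BaseEstimator

__all__ = [
    "ActivityResult",
    "MeltingCurve",
    "MeltingFit",
    "DecaySeries",
    "DecayFit",
    "StabilityRecord",
    "normalize_activity",
    "classify_vs_wt",
    "hit_rate",
    "MeltingCurveModel",
    "fit_melting",
    "FirstOrderDecay",
    "fit_decay",
    "delta_tm",
    "correlate_spearman",
    "experimental_epistasis",
]

PLATE_COLUMNS = ["variant", "condition", "replicate", "signal", "is_background"]


@dataclasses.dataclass
class ActivityResult:
    """Background-subtracted activity of a variant relative to wild type."""

    variant: str
    fold_vs_wt: float
    sem: float
    condition: str
    inactive: bool = False


@dataclasses.dataclass
class MeltingCurve:
    """A thermal unfolding scan (temperatures in deg C, strictly increasing)."""

    temperatures: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperatures.shape != self.signal.shape:
            raise ValueError("temperatures and signal must have equal length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclasses.dataclass
class MeltingFit:
    """Result of Tm extraction; ``tm`` is None when no transition was found."""

    tm: float | None
    method: str
    transition_found: bool
    slope: float | None = None
    baselines: tuple[float, float] | None = None
    rmse: float | None = None


@dataclasses.dataclass
class DecaySeries:
    """Residual-activity time course; ``activities`` is (replicates, times)."""

    times: np.ndarray
    activities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.activities = np.atleast_2d(np.asarray(self.activities, dtype=float))
        if self.activities.shape[1] != self.times.shape[0]:
            raise ValueError("activities must have one column per time point")
        if np.any(self.activities < 0):
            raise ValueError("activities must be nonnegative")


@dataclasses.dataclass
class DecayFit:
    """First-order deactivation fit A(t) = A0 exp(-k t)."""

    k: float | None
    a0: float | None
    half_life: float | None
    se_k: float | None
    se_half_life: float | None
    decay_found: bool


@dataclasses.dataclass
class StabilityRecord:
    """Per-variant stability summary used by report generation."""

    variant: str
    tm: float | None = None
    tm_sem: float | None = None
    delta_tm: float | None = None
    delta_tm_sem: float | None = None
    half_life: float | None = None
    half_life_se: float | None = None
    fold_activity: float | None = None
    fold_sem: float | None = None
    label: str | None = None


def normalize_activity(
    plate: pd.DataFrame, wt_name: str, propagate_wt: bool = False
) -> list[ActivityResult]:
    """Normalize plate absorbances to wild type, per condition.

    ``plate`` is long-form with columns (variant, condition, replicate,
    signal, is_background). Per condition the mean empty-vector background
    is subtracted from every replicate; a variant's fold is its mean
    background-subtracted signal divided by the wild type's, with SEM from
    the variant's replicate scatter (wild-type uncertainty optionally
    propagated). A variant whose replicates never exceed background is
    flagged inactive with fold 0.
    """
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table missing columns {missing}")
    out: list[ActivityResult] = []
    for condition, sub in plate.groupby("condition", sort=False):
        bg = sub.loc[sub["is_background"], "signal"]
        if bg.empty:
            raise ValueError(f"no background wells for condition {condition!r}")
        bg_mean = float(bg.mean())
        samples = sub[~sub["is_background"]]
        if wt_name not in set(samples["variant"]):
            raise ValueError(f"wild type {wt_name!r} absent for {condition!r}")
        wt_net = samples.loc[samples["variant"] == wt_name, "signal"] - bg_mean
        wt_mean = float(wt_net.mean())
        if wt_mean <= 0:
            raise ValueError(f"wild-type signal does not exceed background")
        wt_sem = float(wt_net.sem()) if len(wt_net) > 1 else 0.0
        for variant, grp in samples.groupby("variant", sort=False):
            net = grp["signal"] - bg_mean
            mean = float(net.mean())
            sem = float(net.sem()) if len(net) > 1 else 0.0
            inactive = bool((grp["signal"] <= bg_mean).all())
            fold = max(mean, 0.0) / wt_mean if inactive else mean / wt_mean
            fold_sem = sem / wt_mean
            if propagate_wt:
                fold_sem = math.hypot(fold_sem, abs(fold) * wt_sem / wt_mean)
            out.append(
                ActivityResult(
                    variant=str(variant),
                    fold_vs_wt=fold,
                    sem=fold_sem,
                    condition=str(condition),
                    inactive=inactive,
                )
            )
    return out


def classify_vs_wt(
    value: float,
    sem: float,
    wt_value: float,
    wt_sem: float,
    z_threshold: float = 2.0,
) -> str:
    """Classify a measurement against wild type on a combined-SEM z score.

    z = (value - wt) / sqrt(sem^2 + wt_sem^2); "improved" for z >= threshold,
    "reduced" for z <= -threshold, otherwise "similar". Equal values with
    zero SEMs are "similar".
    """
    if sem < 0 or wt_sem < 0:
        raise ValueError("SEMs must be nonnegative")
    diff = value - wt_value
    denom = math.hypot(sem, wt_sem)
    if denom == 0:
        if diff == 0:
            return "similar"
        return "improved" if diff > 0 else "reduced"
    z = diff / denom
    if z >= z_threshold:
        return "improved"
    if z <= -z_threshold:
        return "reduced"
    return "similar"


def hit_rate(n_improved: int, n_tested: int) -> float:
    """Percentage of tested variants classified improved."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if not 0 <= n_improved <= n_tested:
        raise ValueError("need 0 <= n_improved <= n_tested")
    return 100.0 * n_improved / n_tested


def _two_state(T, tm, width, pre0, pre1, post0, post1):
    theta = 1.0 / (1.0 + np.exp(-(T - tm) / width))
    return (pre0 + pre1 * T) * (1 - theta) + (post0 + post1 * T) * theta


class MeltingCurveModel(BaseEstimator):
    """Tm extraction from a two-state unfolding curve.

    method="derivative" (default): Savitzky-Golay smoothing followed by the
    maximum of the first derivative, refined by quadratic interpolation of
    the three points around the peak (sub-grid precision on a 1 degC scan).
    method="sigmoid": nonlinear two-state fit with linear pre-/post-
    transition baselines; Tm is the transition midpoint. A derivative peak
    on the scan boundary means no transition: ``transition_found_`` is
    False and ``tm_`` is None.
    """

    def __init__(self, method: str = "derivative", smooth_window: int = 9):
        self.method = method
        self.smooth_window = smooth_window

    def fit(self, temperatures, signal_values):
        curve = MeltingCurve(np.asarray(temperatures), np.asarray(signal_values))
        if curve.temperatures.size < 10:
            raise ValueError("need at least 10 points spanning the transition")
        if self.method not in {"derivative", "sigmoid"}:
            raise ValueError(f"unknown method {self.method!r}")
        T, y = curve.temperatures, curve.signal
        if y[-1] < y[0]:  # falling transition: analyze the mirrored signal
            y = -y
        window = min(self.smooth_window, y.size if y.size % 2 else y.size - 1)
        window = max(window, 5)
        dT = float(np.median(np.diff(T)))
        deriv = signal.savgol_filter(
            y, window_length=window, polyorder=3, deriv=1, delta=dT
        )
        # search away from the filter's edge artifacts
        hw = window // 2
        interior = np.arange(hw, deriv.size - hw)
        peak = int(interior[np.argmax(deriv[interior])])
        d_int = deriv[interior]
        mad = float(np.median(np.abs(d_int - np.median(d_int))))
        prominent = deriv[peak] > np.median(d_int) + 4 * 1.4826 * mad
        if peak <= interior[0] or peak >= interior[-1] or not prominent:
            self.tm_ = None
            self.transition_found_ = False
            self.fit_ = MeltingFit(None, self.method, False)
            return self
        # sub-grid refinement: quadratic vertex fitted over the half-maximum
        # neighborhood of the derivative peak (symmetric for two-state curves)
        base = np.median(d_int)
        half = base + 0.5 * (deriv[peak] - base)
        lo = peak
        while lo - 1 >= interior[0] and deriv[lo - 1] >= half:
            lo -= 1
        hi = peak
        while hi + 1 <= interior[-1] and deriv[hi + 1] >= half:
            hi += 1
        sel = slice(max(lo, peak - 8), min(hi, peak + 8) + 1)
        if sel.stop - sel.start >= 3:
            a, b, _ = np.polyfit(T[sel], deriv[sel], 2)
            tm_deriv = float(-b / (2 * a)) if a < 0 else float(T[peak])
        else:
            tm_deriv = float(T[peak])
        if not T[sel][0] <= tm_deriv <= T[sel][-1]:
            tm_deriv = float(T[peak])
        tm_deriv = float(np.clip(tm_deriv, T[0], T[-1]))
        if self.method == "derivative":
            self.tm_ = tm_deriv
            self.transition_found_ = True
            self.fit_ = MeltingFit(tm_deriv, "derivative", True, slope=float(deriv[peak]))
            return self
        width0 = max((T[-1] - T[0]) / 30.0, 0.5)
        p0 = [tm_deriv, width0, y[0], 0.0, y[-1], 0.0]
        popt, pcov = optimize.curve_fit(_two_state, T, y, p0=p0, maxfev=20000)
        tm = float(popt[0])
        if not T[0] <= tm <= T[-1]:
            self.tm_ = None
            self.transition_found_ = False
            self.fit_ = MeltingFit(None, "sigmoid", False)
            return self
        rmse = float(np.sqrt(np.mean((_two_state(T, *popt) - y) ** 2)))
        self.tm_ = tm
        self.transition_found_ = True
        self.fit_ = MeltingFit(
            tm,
            "sigmoid",
            True,
            slope=float(popt[1]),
            baselines=(float(popt[2]), float(popt[4])),
            rmse=rmse,
        )
        return self


def fit_melting(curve: MeltingCurve, method: str = "derivative") -> MeltingFit:
    """Functional wrapper over :class:`MeltingCurveModel`."""
    est = MeltingCurveModel(method=method).fit(curve.temperatures, curve.signal)
    return est.fit_


class FirstOrderDecay(BaseEstimator):
    """Single-exponential thermal deactivation, A(t) = A0 exp(-k t).

    Fitted by nonlinear least squares on the replicate means; the half-life
    is t1/2 = ln 2 / k with a delta-method standard error from the fit
    covariance. A non-decaying series (fitted k <= 0) is flagged instead of
    reporting a half-life.
    """

    def __init__(self):
        pass

    def fit(self, times, activities):
        series = DecaySeries(np.asarray(times), np.asarray(activities))
        if series.times.size < 3 or 0.0 not in series.times:
            raise ValueError("need >= 3 time points including t = 0")
        t = series.times
        mean = series.activities.mean(axis=0)
        a0_guess = max(mean[t.argmin()], mean.max(), 1e-12)
        pos = mean > 0
        if pos.sum() >= 2:
            slope = np.polyfit(t[pos], np.log(mean[pos]), 1)[0]
            k_guess = max(-slope, 1e-6)
        else:
            k_guess = 1e-2
        popt, pcov = optimize.curve_fit(
            lambda tt, a0, k: a0 * np.exp(-k * tt),
            t,
            mean,
            p0=[a0_guess, k_guess],
            maxfev=20000,
        )
        a0, k = float(popt[0]), float(popt[1])
        se_k = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else None
        if k <= 0:
            self.fit_ = DecayFit(None, a0, None, None, None, False)
            self.half_life_ = None
            return self
        half_life = math.log(2) / k
        se_half = math.log(2) * se_k / k**2 if se_k is not None else None
        self.fit_ = DecayFit(k, a0, half_life, se_k, se_half, True)
        self.half_life_ = half_life
        self.k_ = k
        self.a0_ = a0
        return self


def fit_decay(series: DecaySeries) -> DecayFit:
    """Functional wrapper over :class:`FirstOrderDecay`."""
    est = FirstOrderDecay().fit(series.times, series.activities)
    return est.fit_


def delta_tm(
    tm: float, tm_sem: float, wt_tm: float, wt_tm_sem: float
) -> tuple[float, float]:
    """Tm difference to wild type with propagated SEM."""
    for v in (tm, wt_tm):
        if v is None or not np.isfinite(v):
            raise ValueError("both melting temperatures must be present")
    return tm - wt_tm, math.hypot(tm_sem, wt_tm_sem)


def correlate_spearman(x, y) -> tuple[float, float]:
    """Spearman's rho with a two-sided t-approximation p-value (n - 2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need equal-length inputs with at least 4 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def experimental_epistasis(
    double_metric: float,
    single_a: float,
    single_b: float,
    wt: float,
    mode: str = "additive",
) -> float:
    """Deviation of a double's measured effect from its singles' combination.

    additive: (double - wt) - [(a - wt) + (b - wt)]; multiplicative (for
    fold-changes, wt fold = 1): double - a * b. Positive deviations are
    positive (synergistic) epistasis, negative deviations negative
    epistasis.
    """
    for v in (double_metric, single_a, single_b, wt):
        if v is None or not np.isfinite(v):
            raise ValueError("all four measurements must be present")
    if mode == "additive":
        return (double_metric - wt) - ((single_a - wt) + (single_b - wt))
    if mode == "multiplicative":
        return double_metric - single_a * single_b
    raise ValueError(f"unknown epistasis mode {mode!r}")
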