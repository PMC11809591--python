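"""Labeling-kinetics curve fitting and group statistics.

Molar 13C time courses C13C(t) are fitted per replicate culture with the
standard logistic

    I(t) = i_max / (1 + exp(-a * (t - t_mid)))

whose maximum slope — the maximum assimilation rate A13C — has the closed form
i_max * a / 4, attained at the midpoint time t_mid. An exponential saturation
model I(t) = i_max * (1 - exp(-k t)) with initial slope k * i_max is offered
as the alternative rate estimate; it cannot represent the lag phase caused by
Ci diffusion and CBB-cycle redistribution, so the logistic is the default.

Fit acceptance follows the sigmoidal-classification conventions of dynamic
labeling analysis: many random initializations with best-SSE selection, a
threshold intensity ratio of 0.75 (the data must reach 75 % of the fitted
plateau) and a maximum allowed model intensity at t0 of ~0 (soft constraint
I(0) <= 5 % of i_max, since a logistic never reaches zero exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "FitConfig",
    "LabelingTimeSeries",
    "SigmoidalFit",
    "ExponentialFit",
    "WelchResult",
    "RegressionResult",
    "logistic",
    "fit_logistic",
    "fit_exponential",
    "compare_groups",
    "significance_stars",
    "correlate_instruments",
]


@dataclass(frozen=True)
class FitConfig:
    """Acceptance thresholds and restart budget of the sigmoidal fit.

    ``max_rise_intervals`` caps the fitted steepness at the sampling
    resolution: a logistic whose 5-to-95 % rise (2 ln 19 / a) is shorter than
    one sampling interval is indistinguishable from a step, so steeper values
    are unidentifiable and only inflate the maximum-slope estimate.
    """

    n_starts: int = 1000  # random initializations screened by SSE
    n_polish: int = 8  # best starts refined by local least squares
    threshold_ratio: float = 0.75  # data must reach this fraction of i_max
    t0_tolerance: float = 0.05  # max allowed I(0) as fraction of i_max
    t0_penalty_weight: float = 10.0
    max_rise_intervals: float = 1.0  # min 5-95 % rise time, in sampling intervals
    seed: int = 0


@dataclass
class LabelingTimeSeries:
    """One replicate time course of C13C (or E13C) for one positional group."""

    times: np.ndarray  # minutes, strictly increasing, first = 0
    values: np.ndarray
    group: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] != 0:
            raise ValueError("first time point must be 0 (pulse start)")


def logistic(t, i_max: float, a: float, t_mid: float):
    return i_max / (1.0 + np.exp(-a * (t - t_mid)))


@dataclass
class SigmoidalFit:
    i_max: float
    a: float  # steepness, 1/min
    t_mid: float  # midpoint time, min
    fit_class: str  # sigmoidal | ambiguous | no_signal
    sse: float
    group: str = ""
    replicate: str = ""

    @property
    def a13c(self) -> float:
        """Maximum slope of the logistic = i_max * a / 4 (the rate A13C)."""
        return self.i_max * self.a / 4.0

    def predict(self, t):
        return logistic(t, self.i_max, self.a, self.t_mid)


@dataclass
class ExponentialFit:
    i_max: float
    k: float  # 1/min
    fit_class: str
    sse: float
    group: str = ""
    replicate: str = ""

    @property
    def initial_slope(self) -> float:
        """First derivative k * i_max of i_max*(1 - exp(-k t)) at t = 0."""
        return self.k * self.i_max

    def predict(self, t):
        return self.i_max * (1.0 - np.exp(-self.k * np.asarray(t)))


def _no_signal(series: LabelingTimeSeries) -> bool:
    return bool(np.all(series.values <= 0) or np.max(np.abs(series.values)) == 0)


def _logistic_residuals(params, t, y, cfg: FitConfig):
    i_max, a, t_mid = params
    r = logistic(t, i_max, a, t_mid) - y
    # soft t0 constraint: model value at pulse start must be ~0
    violation = max(0.0, logistic(0.0, i_max, a, t_mid) - cfg.t0_tolerance * i_max)
    return np.append(r, cfg.t0_penalty_weight * violation)


def _heuristic_start(t, y):
    i_max = max(np.max(y), 1e-12)
    half = i_max / 2.0
    t_mid = float(np.interp(half, np.maximum.accumulate(y), t))
    t_mid = min(max(t_mid, t[1] * 0.5 if len(t) > 1 else 1.0), t[-1])
    a = 4.0 / max(t_mid, 1.0)
    return np.array([i_max, a, t_mid])


def fit_logistic(series: LabelingTimeSeries, cfg: FitConfig = FitConfig()) -> SigmoidalFit:
    """Multi-start logistic fit of one labeling time course.

    ``cfg.n_starts`` random parameter triples inside data-driven bounds are
    screened by penalized SSE; the best few plus a data-driven start are
    refined by bounded least squares, and the lowest-SSE solution wins. The
    repeated-restart agreement doubles as the robustness check of the
    sigmoidal classification.
    """
    t, y = series.times, series.values
    if len(t) < 5:
        raise ValueError("fit_logistic requires >= 5 time points")
    if _no_signal(series):
        return SigmoidalFit(0.0, 0.0, math.nan, "no_signal", 0.0,
                            series.group, series.replicate)
    vmax = float(np.max(y))
    min_gap = float(np.min(np.diff(t)))
    a_hi = min(5.0, 2.0 * math.log(19.0) / (cfg.max_rise_intervals * min_gap))
    lo = np.array([0.3 * vmax, 1e-3, 1e-6])
    hi = np.array([3.0 * vmax, a_hi, float(t[-1])])
    rng = np.random.default_rng(cfg.seed)
    starts = rng.uniform(lo, hi, size=(cfg.n_starts, 3))

    # vectorized penalized-SSE screening of all random starts
    tt = t[None, :]
    model0 = starts[:, 0:1] / (1.0 + np.exp(-starts[:, 1:2] * (tt - starts[:, 2:3])))
    sse = np.sum((model0 - y[None, :]) ** 2, axis=1)
    at0 = starts[:, 0] / (1.0 + np.exp(starts[:, 1] * starts[:, 2]))
    viol = np.maximum(0.0, at0 - cfg.t0_tolerance * starts[:, 0])
    sse += (cfg.t0_penalty_weight * viol) ** 2
    order = np.argsort(sse)[: cfg.n_polish]
    candidates = [starts[i] for i in order]
    candidates.append(np.clip(_heuristic_start(t, y), lo, hi))

    best = None
    for x0 in candidates:
        try:
            sol = least_squares(
                _logistic_residuals, x0, args=(t, y, cfg), bounds=(lo, hi),
                method="trf", max_nfev=200,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return SigmoidalFit(math.nan, math.nan, math.nan, "ambiguous", math.inf,
                            series.group, series.replicate)
    i_max, a, t_mid = best.x
    resid = logistic(t, i_max, a, t_mid) - y
    fit_sse = float(np.sum(resid**2))
    fit_class = "sigmoidal"
    if not best.success:
        fit_class = "ambiguous"
    elif vmax < cfg.threshold_ratio * i_max:
        # data never reach the threshold intensity ratio of the fitted plateau
        fit_class = "ambiguous"
    elif logistic(float(t[-1]), i_max, a, t_mid) < 0.95 * i_max:
        # plateau not reached inside the observation window (e.g. a ramp):
        # the sigmoidal classification is not supported by the data
        fit_class = "ambiguous"
    elif logistic(0.0, i_max, a, t_mid) > 2.0 * cfg.t0_tolerance * i_max:
        fit_class = "ambiguous"
    return SigmoidalFit(float(i_max), float(a), float(t_mid), fit_class, fit_sse,
                        series.group, series.replicate)


def fit_exponential(series: LabelingTimeSeries, cfg: FitConfig = FitConfig()) -> ExponentialFit:
    """Least-squares fit of the saturating exponential i_max*(1 - exp(-k t))."""
    t, y = series.times, series.values
    if _no_signal(series):
        return ExponentialFit(0.0, 0.0, "no_signal", 0.0, series.group, series.replicate)
    vmax = float(np.max(y))
    lo = np.array([0.3 * vmax, 1e-4])
    hi = np.array([3.0 * vmax, 5.0])

    def residuals(params):
        i_max, k = params
        return i_max * (1.0 - np.exp(-k * t)) - y

    rng = np.random.default_rng(cfg.seed)
    starts = [np.array([vmax, 0.1])] + list(rng.uniform(lo, hi, size=(16, 2)))
    best = None
    for x0 in starts:
        sol = least_squares(residuals, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    i_max, k = best.x
    fit_class = "sigmoidal" if best.success else "ambiguous"
    return ExponentialFit(float(i_max), float(k), fit_class,
                          float(2 * best.cost), series.group, series.replicate)


@dataclass
class WelchResult:
    t_statistic: float
    df: float
    p_value: float
    stars: str
    mean_a: float
    mean_b: float


def significance_stars(p: float) -> str:
    """Figure convention: * P<=0.05, ** P<=0.01, *** P<=0.001, else ns."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_groups(a, b) -> WelchResult:
    """Heteroscedastic two-tailed Student's t-test (Welch) between two groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("compare_groups requires >= 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb == 0:
        df, t, p = float(len(a) + len(b) - 2), 0.0, 1.0
    else:
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        t, p = float(res.statistic), float(res.pvalue)
    return WelchResult(t, float(df), p, significance_stars(p),
                       float(a.mean()), float(b.mean()))


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    intercept_stderr: float
    biased: bool  # slope deviates from 1 or intercept from 0 beyond ~95 % CI


def correlate_instruments(x, y, min_pairs: int = 10) -> RegressionResult:
    """OLS regression + r^2 of paired enrichment measurements.

    Flags systematic inter-instrument bias when the slope deviates from 1 or
    the intercept from 0 by more than ~2 standard errors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < min_pairs:
        raise ValueError(f"requires >= {min_pairs} pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return RegressionResult(math.nan, math.nan, math.nan, math.nan, math.nan, False)
    fit = stats.linregress(x, y)
    biased = (abs(fit.slope - 1.0) > 2.0 * fit.stderr
              or abs(fit.intercept) > 2.0 * fit.intercept_stderr)
    return RegressionResult(
        float(fit.slope), float(fit.intercept), float(fit.rvalue**2),
        float(fit.stderr), float(fit.intercept_stderr), bool(biased),
    )
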