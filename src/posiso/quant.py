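"""Calibration-based absolute quantification of 3PGA.

The NIA-corrected sum of isotopologue abundances of fragment 357 is the
quantifier (it is label-invariant, so one calibration serves a whole labeling
time course); fragments 459, 299 and 315 serve as qualifiers through pairwise
abundance-correlation checks. Sample abundances are normalized to the
13C6-sorbitol internal standard, mapped to ng through an ordinary
least-squares calibration line restricted to its linear range, converted to
nmol via the molar mass of 3PGA and referenced to OD750 * mL of culture.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MOLAR_MASS_3PGA",
    "CalibrationSeries",
    "CalibrationModel",
    "ConcentrationResult",
    "QuantConfig",
    "fit_calibration",
    "quantify",
    "replicate_rsd",
    "cross_fragment_consistency",
]

#: Free-acid 3-phosphoglyceric acid C3H7O7P, g/mol (= ng/nmol). Overridable:
#: commercial reference substance is a salt of stated purity.
MOLAR_MASS_3PGA = 186.06


@dataclass(frozen=True)
class QuantConfig:
    """Every factor of the ng -> nmol * OD750^-1 * mL^-1 conversion chain."""

    molar_mass: float = MOLAR_MASS_3PGA
    reference_purity: float = 1.0  # purity of the calibration reference substance
    extraction_factor: float = 1.0  # extract volume / injected volume bookkeeping


@dataclass
class CalibrationSeries:
    """Calibration points of one fragment: injected ng vs corrected abundance."""

    fragment_id: str
    amounts_ng: np.ndarray
    abundances: np.ndarray
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.amounts_ng = np.asarray(self.amounts_ng, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.amounts_ng.shape != self.abundances.shape:
            raise ValueError("amounts and abundances must have equal length")
        if np.any(self.amounts_ng <= 0):
            raise ValueError("injected amounts must be > 0")
        if len(np.unique(self.amounts_ng)) < 4:
            raise ValueError("calibration requires >= 4 distinct amounts")


@dataclass(frozen=True)
class CalibrationModel:
    """OLS line abundance = slope * ng + intercept, valid inside a ng window."""

    fragment_id: str
    slope: float
    intercept: float
    valid_range: tuple[float, float]
    r_squared: float

    def predict(self, ng: float) -> float:
        return self.slope * ng + self.intercept

    def invert(self, abundance: float) -> float:
        return (abundance - self.intercept) / self.slope

    def in_range(self, ng: float) -> bool:
        return self.valid_range[0] <= ng <= self.valid_range[1]


def _auto_linear_range(
    amounts: np.ndarray, abundances: np.ndarray, max_log_residual: float = 0.2
) -> tuple[float, float]:
    """Longest contiguous amount-window behaving as a proportional response.

    A window qualifies when the log-log slope of level-mean abundance vs
    amount is within 1 +- 0.1 *and* every level mean sits within
    ``max_log_residual`` of the power-law fit — the second condition rejects
    windows that sneak a saturation-plateau or noise-floor level past the
    slope test. Requires >= 4 distinct amounts inside the window.
    """
    positive = abundances > 0
    levels = np.unique(amounts[positive])
    means = np.array([abundances[(amounts == lv) & positive].mean() for lv in levels])
    log_lv, log_mean = np.log(levels), np.log(means)
    best: tuple[float, float] | None = None
    best_key = (-1, -math.inf)
    n = len(levels)
    for i in range(n):
        for j in range(i + 3, n):
            sl = slice(i, j + 1)
            fit = stats.linregress(log_lv[sl], log_mean[sl])
            resid = log_mean[sl] - (fit.slope * log_lv[sl] + fit.intercept)
            if abs(fit.slope - 1.0) <= 0.1 and np.max(np.abs(resid)) <= max_log_residual:
                key = (j - i, math.log(levels[j] / levels[i]))
                if key > best_key:
                    best_key = key
                    best = (float(levels[i]), float(levels[j]))
    if best is None:
        raise ValueError("no linear range found (log-log slope within 1 +- 0.1)")
    return best


def fit_calibration(
    series: CalibrationSeries,
    valid_range: tuple[float, float] | None = None,
) -> CalibrationModel:
    """OLS calibration line on the points inside the linear range.

    ``valid_range`` (ng) overrides the automatic detection; the user-declared
    range always wins.
    """
    amounts, abundances = series.amounts_ng, series.abundances
    if np.ptp(abundances) == 0:
        raise ValueError("degenerate calibration: all abundances identical")
    if valid_range is None:
        valid_range = _auto_linear_range(amounts, abundances)
    mask = (amounts >= valid_range[0]) & (amounts <= valid_range[1])
    if len(np.unique(amounts[mask])) < 4:
        raise ValueError("fewer than 4 distinct amounts inside the valid range")
    fit = stats.linregress(amounts[mask], abundances[mask])
    if fit.slope <= 0:
        raise ValueError("calibration slope must be > 0 within the valid range")
    return CalibrationModel(
        fragment_id=series.fragment_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        valid_range=valid_range,
        r_squared=float(fit.rvalue**2),
    )


@dataclass
class ConcentrationResult:
    sample_id: str
    c_3pga: float  # nmol * OD750^-1 * mL^-1
    normalized_abundance: float
    ng_equivalent: float
    in_range: bool


def quantify(
    sample_id: str,
    abundance: float,
    is_abundance: float,
    od_ml: float,
    model: CalibrationModel,
    config: QuantConfig = QuantConfig(),
) -> ConcentrationResult:
    """Absolute 3PGA concentration of one sample.

    ``abundance`` is the NIA-corrected isotopologue sum of the quantifier
    fragment; ``is_abundance`` the internal-standard abundance from the same
    run (calibration samples carry the internal standard too, so the
    normalization cancels); ``od_ml`` the OD750 * mL of harvested culture.
    """
    if is_abundance <= 0:
        raise ValueError(f"{sample_id}: internal-standard abundance must be > 0")
    if od_ml <= 0:
        raise ValueError(f"{sample_id}: od_ml must be > 0")
    normalized = abundance / is_abundance
    ng = model.invert(normalized)
    nmol = ng * config.reference_purity * config.extraction_factor / config.molar_mass
    return ConcentrationResult(
        sample_id=sample_id,
        c_3pga=max(nmol, 0.0) / od_ml,
        normalized_abundance=normalized,
        ng_equivalent=ng,
        in_range=model.in_range(ng),
    )


def replicate_rsd(values) -> float:
    """Relative standard deviation in percent (sample SD / mean * 100).

    NaN marker when the mean is zero.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("replicate_rsd requires >= 2 values")
    mean = v.mean()
    if mean == 0:
        return math.nan
    return float(v.std(ddof=1) / mean * 100.0)


def cross_fragment_consistency(
    abundances: pd.DataFrame, min_samples: int = 10
) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-sample fragment abundances.

    ``abundances``: samples x fragments (columns = fragment ids, e.g. 357,
    459 and the qualifier-only 299/315). Constant columns yield NaN (undefined
    marker); strongly negative r indicates inconsistency and is flagged.
    """
    if len(abundances) < min_samples:
        raise ValueError(f"requires >= {min_samples} samples")
    rows = []
    for a, b in itertools.combinations(abundances.columns, 2):
        x = abundances[a].to_numpy(dtype=float)
        y = abundances[b].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r = math.nan
        else:
            r = float(stats.pearsonr(x, y).statistic)
        rows.append({
            "fragment_a": a,
            "fragment_b": b,
            "pearson_r": r,
            "consistent": (r > 0.9) if not math.isnan(r) else False,
        })
    return pd.DataFrame(rows)
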