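"""Natural-isotope-abundance (NIA) and tracer-purity correction.

Deconvolves measured isotopologue abundance vectors into tracer-label count
distributions, following the standard correction-matrix formalism: column j of
the matrix is the theoretical observed pattern of a species carrying exactly j
tracer-derived labels (each present as 13C with probability = tracer purity),
convolved with the natural isotope patterns of the derivatization carbons and
— in ``full`` resolution mode — of all non-carbon elements. The inverse
problem is solved by non-negative least squares by default.

Outputs per measurement: the corrected label-count vector, its normalization
(relative isotopologue abundance, RIA), the corrected total abundance, and the
fractional enrichment E13C (average 13C fraction per labelable carbon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .chem import (
    AMBIENT_13C_FRACTION,
    FragmentSpec,
    isotope_table,
    natural_shift_distribution,
)

__all__ = [
    "CorrectionConfig",
    "IsotopologueMeasurement",
    "EnrichmentResult",
    "CorrectionError",
    "build_correction_matrix",
    "correct",
    "enrichment",
    "validity_range_check",
    "AbundanceLimits",
]


class CorrectionError(ValueError):
    """Correction impossible for this input (no signal, singular system...)."""


@dataclass(frozen=True)
class CorrectionConfig:
    """Settings of the NIA/tracer correction.

    tracer_purity
        Isotopic purity of the tracer (0.99 for the 99 % 13CO2 pulses).
    p13_natural
        Ambient 13C fraction (1.109 % default).
    resolution_mode
        ``full`` corrects for heavy isotopes of every element;
        ``carbon_only`` corrects only carbon NIA (high mass resolution
        separating e.g. Si isotopologues from 13C shifts).
    nonnegativity
        ``constrained-solve`` (NNLS, default) or ``clip`` (plain least squares,
        then negative components clipped to zero).
    """

    tracer_purity: float = 0.99
    p13_natural: float = AMBIENT_13C_FRACTION
    resolution_mode: str = "full"
    nonnegativity: str = "constrained-solve"

    def __post_init__(self) -> None:
        if not 0.0 < self.tracer_purity <= 1.0:
            raise ValueError("tracer_purity must be in (0, 1]")
        if self.resolution_mode not in ("full", "carbon_only"):
            raise ValueError("resolution_mode must be 'full' or 'carbon_only'")
        if self.nonnegativity not in ("constrained-solve", "clip"):
            raise ValueError("nonnegativity must be 'constrained-solve' or 'clip'")


@dataclass
class IsotopologueMeasurement:
    """Raw peak-abundance vector M+0 … M+k for one fragment in one sample."""

    sample_id: str
    fragment_id: str
    abundances: np.ndarray
    instrument_mode: str = "APCI"

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim != 1:
            raise ValueError("abundances must be a 1-D vector")
        if np.any(self.abundances < 0):
            raise ValueError(
                f"{self.sample_id}/{self.fragment_id}: negative abundance"
            )


@dataclass
class EnrichmentResult:
    """NIA/tracer-corrected distribution and derived quantities."""

    sample_id: str
    fragment_id: str
    corrected: np.ndarray  # label-count vector, M+0 … M+n_labelable
    ria: np.ndarray  # corrected, normalized to sum 1
    total: float  # sum of corrected abundances (arbitrary units)
    e13c: float  # fractional enrichment in [0, 1]
    flags: tuple[str, ...] = ()


def _binom(n: int, p: float) -> np.ndarray:
    from scipy.stats import binom

    return binom.pmf(np.arange(n + 1), n, p)


def build_correction_matrix(
    frag: FragmentSpec,
    cfg: CorrectionConfig = CorrectionConfig(),
    n_rows: int | None = None,
) -> np.ndarray:
    """Matrix mapping tracer-label-count fractions to observed isotopologues.

    Shape (n_rows, n_labelable + 1); ``n_rows`` defaults to n_labelable + 1
    but is typically set to the measured vector length, since Si-rich TMS
    fragments push significant natural M+1/M+2 intensity beyond M+n.
    Columns sum to <= 1 (mass truncated beyond the window) and to 1 as
    n_rows grows.
    """
    n_lab = frag.n_labelable_carbons
    n_cols = n_lab + 1
    if n_rows is None:
        n_rows = n_cols
    if n_rows < n_cols:
        raise CorrectionError(
            f"measured window ({n_rows}) shorter than label dimension ({n_cols})"
        )
    table = isotope_table(cfg.p13_natural)
    nat_rest = natural_shift_distribution(
        frag.formula,
        table=table,
        skip_carbon=n_lab,
        carbon_only=cfg.resolution_mode == "carbon_only",
    )
    matrix = np.zeros((n_rows, n_cols))
    for j in range(n_cols):
        labeled = _binom(j, cfg.tracer_purity) if j else np.array([1.0])
        unlabeled = _binom(n_lab - j, cfg.p13_natural) if n_lab - j else np.array([1.0])
        col = np.convolve(np.convolve(labeled, unlabeled), nat_rest)
        k = min(n_rows, len(col))
        matrix[:k, j] = col[:k]
    return matrix


def enrichment(corrected: np.ndarray, n_labelable: int) -> float:
    """Fractional enrichment E13C = sum(i * x_i) / (n * sum(x_i))."""
    x = np.asarray(corrected, dtype=float)
    if n_labelable < 1:
        raise ValueError("n_labelable must be >= 1")
    if np.any(x < 0):
        raise ValueError("corrected vector must be non-negative")
    total = x.sum()
    if total <= 0:
        raise CorrectionError("zero-sum vector: enrichment undefined")
    idx = np.arange(len(x))
    return float((idx * x).sum() / (n_labelable * total))


def correct(
    meas: IsotopologueMeasurement,
    frag: FragmentSpec,
    cfg: CorrectionConfig = CorrectionConfig(),
) -> EnrichmentResult:
    """NIA/tracer-purity correction of one measured isotopologue vector.

    Solves ``matrix @ x = measured`` for x >= 0 in the least-squares sense
    (rows = measured window, columns = label counts 0 … n_labelable).
    """
    b = meas.abundances
    if b.sum() <= 0:
        raise CorrectionError(f"{meas.sample_id}/{meas.fragment_id}: no signal")
    n_lab = frag.n_labelable_carbons
    if len(b) < n_lab + 1:
        raise CorrectionError(
            f"{meas.sample_id}/{meas.fragment_id}: measured vector length {len(b)} "
            f"< n_labelable + 1 = {n_lab + 1}"
        )
    matrix = build_correction_matrix(frag, cfg, n_rows=len(b))
    if cfg.nonnegativity == "constrained-solve":
        x, _ = nnls(matrix, b)
    else:
        x, *_ = np.linalg.lstsq(matrix, b, rcond=None)
        x = np.clip(x, 0.0, None)
    flags: list[str] = []
    total = float(x.sum())
    if total <= 0:
        raise CorrectionError(
            f"{meas.sample_id}/{meas.fragment_id}: corrected signal vanished"
        )
    ria = x / total
    e13c = enrichment(x, n_lab) if n_lab else 0.0
    return EnrichmentResult(
        sample_id=meas.sample_id,
        fragment_id=meas.fragment_id,
        corrected=x,
        ria=ria,
        total=total,
        e13c=e13c,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class AbundanceLimits:
    """Validated raw-abundance window of one fragment x instrument mode.

    Outside the window the NIA correction over-estimates E13C (noise floor at
    low abundance, detector saturation at high abundance); flagged samples are
    excluded from downstream enrichment analysis.
    """

    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low < 0 or self.high <= self.low:
            raise ValueError("require 0 <= low < high")


def validity_range_check(
    meas: IsotopologueMeasurement, limits: AbundanceLimits
) -> str:
    """Flag a measurement as ``ok``, ``below_range`` or ``saturated``."""
    total = float(meas.abundances.sum())
    if total < limits.low:
        return "below_range"
    if total > limits.high:
        return "saturated"
    return "ok"
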