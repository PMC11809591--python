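"""Carbon-positional enrichment of 3PGA from paired fragment measurements.

The fractional enrichment of a substructure equals the average enrichment of
its carbon positions, so pairing the complete-backbone feature (1,2,3-C3,
fragment 459) with the in-source fragment retaining 2,3-C2 (fragment 357)
gives the 1-C position by difference:

    E13C_{1,2,3-C3} = (E1 + E2 + E3) / 3
    E13C_{2,3-C2}   = (E2 + E3) / 2
    E13C_{1-C}      = 3 * E13C_{1,2,3-C3} - 2 * E13C_{2,3-C2}

The relative enrichment rel.E13C_{2,3-C2/1-C} (%) = E23 / E1 * 100 tracks the
redistribution of freshly assimilated carbon (1-C first, via RuBisCO) into the
2-C/3-C positions (via the CBB cycle); it cannot exceed 100 % during a
photosynthetic pulse. Molar 13C concentrations weight enrichments by carbon
count so that C13C_{1,2,3-C3} = C13C_{1-C} + C13C_{2,3-C2} holds exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "FLAG_OK",
    "FLAG_E1_OUT_OF_RANGE",
    "FLAG_REL_E_UNDEFINED",
    "FLAG_REL_E_EXCEEDS_100",
    "PairedEnrichment",
    "PositionalResult",
    "e1_from_pair",
    "e123_from_positions",
    "rel_e23_over_1",
    "positional_c13c",
    "adjust_to_reference",
    "analyze_pair",
    "analyze_table",
]

FLAG_OK = "ok"
FLAG_E1_OUT_OF_RANGE = "e1_out_of_range"
FLAG_REL_E_UNDEFINED = "rel_e_undefined"
FLAG_REL_E_EXCEEDS_100 = "rel_e_exceeds_100"

#: Below this 1-C enrichment the 2,3-C2/1-C ratio is meaningless (pre-pulse
#: samples have E1 ~ 0); an undefined marker (NaN) is returned instead.
REL_E_EPSILON = 0.01


def e1_from_pair(e123: float, e23: float) -> tuple[float, bool]:
    """1-C enrichment from the paired features: 3*e123 - 2*e23.

    Returns ``(e1, in_bounds)``. Because this is a difference of noisy
    quantities, e1 can fall outside [0, 1]; such values are returned as-is
    with ``in_bounds=False`` (never silently clamped — clamping would bias
    early-time points toward zero).
    """
    e1 = 3.0 * e123 - 2.0 * e23
    tol = 1e-12  # float dust from the constrained solve is not a range violation
    return e1, -tol <= e1 <= 1.0 + tol


def e123_from_positions(e1: float, e23: float) -> float:
    """Complete-backbone enrichment from positional values: (e1 + 2*e23)/3."""
    return (e1 + 2.0 * e23) / 3.0


def rel_e23_over_1(e23: float, e1: float, epsilon: float = REL_E_EPSILON) -> float:
    """Relative enrichment of 2,3-C2 vs 1-C in percent: e23/e1*100.

    Returns NaN (undefined marker — neither 0 nor infinity) when e1 <= epsilon.
    """
    if e1 <= epsilon:
        return math.nan
    return e23 / e1 * 100.0


def positional_c13c(
    e123: float, e23: float, e1: float, c_3pga: float
) -> tuple[float, float, float]:
    """Molar 13C concentrations (c13c_123, c13c_23, c13c_1).

    Carbon-count weighting (x3, x2, x1) makes the molar amounts additive:
    c13c_123 = c13c_1 + c13c_23 exactly, by the positional algebra. Units
    follow c_3pga (nmol * OD750^-1 * mL^-1 of metabolite -> nmol 13C ...).
    """
    if c_3pga < 0:
        raise ValueError("c_3pga must be >= 0")
    return 3.0 * e123 * c_3pga, 2.0 * e23 * c_3pga, 1.0 * e1 * c_3pga


def adjust_to_reference(
    e_target: float, e_reference_measured: float, e_reference_theoretical: float
) -> float:
    """Rescale a measured enrichment to a co-measured reference, in percent.

    Used to normalize E13C of a product metabolite to the theoretical
    saturation enrichment of its precursor (e.g. G6P adjusted to 100 % for
    13C6-glucose feeding, 33.3 % for 13C2-glucoses), correcting for tracer
    dilution by ambient intracellular carbon and for tracer purity.
    """
    if e_reference_measured <= 0:
        raise ValueError("reference enrichment must be > 0")
    return e_target / e_reference_measured * e_reference_theoretical


@dataclass(frozen=True)
class PairedEnrichment:
    """Paired E13C of the two 3PGA features from one sample."""

    sample_id: str
    e123: float
    e23: float
    flags: tuple[str, ...] = ()


@dataclass
class PositionalResult:
    sample_id: str
    e123: float
    e23: float
    e1: float
    rel_e_pct: float
    c_3pga: float
    c13c_123: float
    c13c_23: float
    c13c_1: float
    flags: tuple[str, ...]


def analyze_pair(
    pair: PairedEnrichment,
    c_3pga: float = math.nan,
    epsilon: float = REL_E_EPSILON,
) -> PositionalResult:
    """Full positional analysis of one paired measurement.

    ``c_3pga=NaN`` marks an enrichment-only sample (e.g. a time point without
    a paired concentration measurement); molar columns are then NaN.
    """
    flags = list(pair.flags)
    e1, in_bounds = e1_from_pair(pair.e123, pair.e23)
    if not in_bounds:
        flags.append(FLAG_E1_OUT_OF_RANGE)
    rel = rel_e23_over_1(pair.e23, e1, epsilon=epsilon)
    if math.isnan(rel) and pair.e23 >= 0:
        flags.append(FLAG_REL_E_UNDEFINED)
    elif rel > 100.0:
        # cannot happen during photosynthetic pulse labeling: 1-C labels first
        flags.append(FLAG_REL_E_EXCEEDS_100)
    if math.isnan(c_3pga):
        c123 = c23 = c1 = math.nan
    else:
        c123, c23, c1 = positional_c13c(pair.e123, pair.e23, e1, c_3pga)
    if not flags:
        flags.append(FLAG_OK)
    return PositionalResult(
        sample_id=pair.sample_id,
        e123=pair.e123,
        e23=pair.e23,
        e1=e1,
        rel_e_pct=rel,
        c_3pga=c_3pga,
        c13c_123=c123,
        c13c_23=c23,
        c13c_1=c1,
        flags=tuple(flags),
    )


def analyze_table(df: pd.DataFrame, epsilon: float = REL_E_EPSILON) -> pd.DataFrame:
    """Vectorized positional analysis of a tidy table.

    Requires columns ``sample_id``, ``e123``, ``e23``; optional ``c_3pga``
    (missing/NaN -> enrichment-only sample). Returns the tidy output schema
    with one row per sample and a semicolon-joined ``flags`` column.
    """
    required = {"sample_id", "e123", "e23"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for rec in df.to_dict("records"):
        pair = PairedEnrichment(
            sample_id=str(rec["sample_id"]),
            e123=float(rec["e123"]),
            e23=float(rec["e23"]),
        )
        c = float(rec.get("c_3pga", math.nan))
        res = analyze_pair(pair, c_3pga=c, epsilon=epsilon)
        out = {k: getattr(res, k) for k in (
            "sample_id", "e123", "e23", "e1", "rel_e_pct",
            "c_3pga", "c13c_123", "c13c_23", "c13c_1")}
        out["flags"] = ";".join(res.flags)
        for extra in ("time_min", "genotype", "condition", "replicate"):
            if extra in rec:
                out[extra] = rec[extra]
        rows.append(out)
    return pd.DataFrame(rows)
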