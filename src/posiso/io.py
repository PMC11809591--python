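"""Table I/O, validation and the end-to-end pipeline.

All tables are tidy/long CSV, UTF-8, '.' decimal. The explicit ``n.d.``
sentinel (not-detected, e.g. 2,3-C2 labeling of a CBB-deficient mutant) is
distinct from 0 and from missing values. Re-running on identical inputs
yields byte-identical outputs (fixed float formatting, sorted rows).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import positional, quant
from .chem import load_fragment_library
from .isocorrect import (
    AbundanceLimits,
    CorrectionConfig,
    IsotopologueMeasurement,
    correct,
    validity_range_check,
)
from .kinetics import FitConfig, LabelingTimeSeries, compare_groups, fit_logistic

__all__ = [
    "ND",
    "PipelineError",
    "read_measurements",
    "read_metadata",
    "read_calibration",
    "write_table",
    "run_pipeline",
]

ND = "n.d."

log = logging.getLogger("posiso")

REQUIRED_MEASUREMENT_COLUMNS = ("sample_id", "fragment_id", "isotopologue_index", "abundance")


class PipelineError(RuntimeError):
    """A pipeline stage failed; message carries stage and sample context."""


def read_measurements(path) -> list[IsotopologueMeasurement]:
    """Read and validate a long-format isotopologue measurement CSV.

    Errors name the offending row: missing column, negative abundance,
    duplicate (sample, fragment, index) key, or a gap in isotopologue indices.
    """
    df = pd.read_csv(path)
    missing = set(REQUIRED_MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    neg = df.index[df["abundance"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative abundance at row {neg[0] + 2}")
    dup = df.duplicated(["sample_id", "fragment_id", "isotopologue_index"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate key ({row['sample_id']}, {row['fragment_id']}, "
            f"M+{int(row['isotopologue_index'])})"
        )
    out = []
    for (sample_id, fragment_id), grp in df.groupby(
        ["sample_id", "fragment_id"], sort=True
    ):
        idx = np.sort(grp["isotopologue_index"].to_numpy(dtype=int))
        expected = np.arange(len(idx))
        if not np.array_equal(idx, expected):
            raise ValueError(
                f"{path}: gap in isotopologue indices for ({sample_id}, {fragment_id}): "
                f"found {idx.tolist()}"
            )
        vec = grp.sort_values("isotopologue_index")["abundance"].to_numpy(dtype=float)
        out.append(IsotopologueMeasurement(str(sample_id), str(fragment_id), vec))
    if not out:
        raise ValueError(f"{path}: no samples")
    return out


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sample_id", "od750_ml", "is_abundance"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    return df


def read_calibration(path) -> quant.CalibrationSeries:
    df = pd.read_csv(path)
    missing = {"fragment_id", "amount_ng", "abundance"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing calibration columns {sorted(missing)}")
    frag = df["fragment_id"].iloc[0]
    sub = df[df["fragment_id"] == frag]
    return quant.CalibrationSeries(
        fragment_id=str(frag),
        amounts_ng=sub["amount_ng"].to_numpy(dtype=float),
        abundances=sub["abundance"].to_numpy(dtype=float),
        replicates=sub["replicate"].to_numpy() if "replicate" in sub else None,
    )


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic CSV write: fixed float format, row order as given."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", na_rep="")


@dataclass
class RunConfig:
    """Everything an end-to-end run needs beyond the input tables."""

    correction: CorrectionConfig = CorrectionConfig()
    fit: FitConfig = FitConfig()
    quant: quant.QuantConfig = quant.QuantConfig()
    instrument_mode: str = "APCI"
    quantifier_fragment: str = "3PGA_357"
    e123_fragment: str = "3PGA_459"
    abundance_limits: dict[str, AbundanceLimits] = field(default_factory=dict)
    calibration_range: tuple[float, float] | None = None
    max_fit_time: float = 60.0  # min; later points excluded from rate fits
    seed: int = 0


def _correct_all(measurements, library, cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for meas in measurements:
        key = (meas.fragment_id, cfg.instrument_mode)
        frag = library.get(key)
        if frag is None:
            matches = [v for (fid, _), v in library.items() if fid == meas.fragment_id]
            if not matches:
                raise PipelineError(
                    f"correction stage: fragment {meas.fragment_id!r} "
                    f"(sample {meas.sample_id}) not in library"
                )
            frag = matches[0]
        try:
            res = correct(meas, frag, cfg.correction)
        except Exception as exc:
            raise PipelineError(
                f"correction stage failed for sample {meas.sample_id}, "
                f"fragment {meas.fragment_id}: {exc}"
            ) from exc
        flag = "ok"
        limits = cfg.abundance_limits.get(meas.fragment_id)
        if limits is not None:
            flag = validity_range_check(meas, limits)
            if flag != "ok":
                log.warning("excluding %s/%s from enrichment: %s",
                            meas.sample_id, meas.fragment_id, flag)
        rows.append({
            "sample_id": meas.sample_id,
            "fragment_id": meas.fragment_id,
            "total": res.total,
            "e13c": res.e13c,
            "range_flag": flag,
            **{f"ria_m{i}": v for i, v in enumerate(res.ria)},
        })
    return pd.DataFrame(rows).sort_values(["sample_id", "fragment_id"], ignore_index=True)


def _paired_table(enrich: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    e123 = enrich[enrich["fragment_id"] == cfg.e123_fragment]
    e23 = enrich[enrich["fragment_id"] == cfg.quantifier_fragment]
    merged = e123.merge(
        e23, on="sample_id", suffixes=("_123", "_23"), how="inner"
    )
    return pd.DataFrame({
        "sample_id": merged["sample_id"],
        "e123": merged["e13c_123"],
        "e23": merged["e13c_23"],
        "total_quantifier": merged["total_23"],
        "range_flag": np.where(
            (merged["range_flag_123"] == "ok") & (merged["range_flag_23"] == "ok"),
            "ok",
            merged["range_flag_123"].where(merged["range_flag_123"] != "ok",
                                           merged["range_flag_23"]),
        ),
    })


def run_pipeline(
    measurements: list[IsotopologueMeasurement],
    metadata: pd.DataFrame,
    calibration: quant.CalibrationSeries | None = None,
    cfg: RunConfig = RunConfig(),
    output_dir=None,
) -> dict[str, pd.DataFrame]:
    """Raw isotopologue tables -> enrichments, positional values, molar
    concentrations, kinetic fits and group tests.

    Samples flagged out of the validated abundance range are excluded from
    enrichment-derived outputs; samples without concentration data stay as
    enrichment-only rows. Deterministic given inputs + config.
    """
    if not measurements:
        raise PipelineError("input stage: no samples")
    library = load_fragment_library()
    enrich = _correct_all(measurements, library, cfg)

    paired = _paired_table(enrich, cfg)
    meta = metadata.copy()
    paired = paired.merge(meta, on="sample_id", how="left")

    model = None
    if calibration is not None:
        model = quant.fit_calibration(calibration, valid_range=cfg.calibration_range)

    conc_rows = []
    for rec in paired.to_dict("records"):
        c = math.nan
        in_range = False
        if model is not None and not math.isnan(rec.get("od750_ml", math.nan)):
            res = quant.quantify(
                rec["sample_id"], rec["total_quantifier"], rec["is_abundance"],
                rec["od750_ml"], model, cfg.quant,
            )
            c, in_range = res.c_3pga, res.in_range
        conc_rows.append({"sample_id": rec["sample_id"], "c_3pga": c,
                          "quant_in_range": in_range})
    conc = pd.DataFrame(conc_rows)
    paired = paired.merge(conc, on="sample_id", how="left")

    usable = paired[paired["range_flag"] == "ok"].copy()
    pos_in = usable[[c for c in ("sample_id", "e123", "e23", "c_3pga", "time_min",
                                 "genotype", "condition", "replicate")
                     if c in usable.columns]]
    pos = positional.analyze_table(pos_in)
    pos = pos.sort_values("sample_id", ignore_index=True)

    fits = _fit_rates(pos, cfg)
    tests = _group_tests(fits)
    results = {
        "enrichments": enrich,
        "positional": pos,
        "concentrations": paired[["sample_id", "c_3pga", "quant_in_range"]],
        "fits": fits,
        "tests": tests,
    }
    if output_dir is not None:
        out = Path(output_dir)
        for name, df in results.items():
            write_table(df, out / f"{name}.csv")
        manifest = {
            "seed": cfg.seed,
            "instrument_mode": cfg.instrument_mode,
            "tracer_purity": cfg.correction.tracer_purity,
            "n_samples": int(paired["sample_id"].nunique()),
            "config_hash": hashlib.sha256(
                repr((cfg.correction, cfg.fit, cfg.quant, cfg.instrument_mode,
                      cfg.calibration_range, cfg.max_fit_time, cfg.seed)).encode()
            ).hexdigest()[:16],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results


_POSITIONAL_VALUE_COLUMNS = {"1-C": "c13c_1", "2,3-C2": "c13c_23", "1,2,3-C3": "c13c_123"}
_POSITIONAL_E_COLUMNS = {"1-C": "e1", "2,3-C2": "e23", "1,2,3-C3": "e123"}


def _detected(pos: pd.DataFrame, genotype: str, condition: str, position: str,
              cfg: "RunConfig") -> bool:
    """Detection rule for a positional labeling signal.

    The pre-pulse t=0 samples of a genotype x condition group are unlabeled
    blanks, so their apparent enrichment estimates the noise floor. The
    late-course plateau must exceed the blank mean by 3x the measurement
    scatter (the larger of blank SD and plateau SD — few blanks alone
    estimate the floor poorly) for the position to count as detected.
    """
    column = _POSITIONAL_E_COLUMNS[position]
    grp = pos[(pos["genotype"] == genotype) & (pos["condition"] == condition)]
    blanks = grp.loc[grp["time_min"] == 0, column].dropna()
    plateau = grp.loc[
        (grp["time_min"] >= 0.5 * cfg.max_fit_time)
        & (grp["time_min"] <= cfg.max_fit_time), column].dropna()
    if blanks.empty or plateau.empty:
        return True  # no blank information: assume detected
    scatter = max(
        blanks.std(ddof=1) if len(blanks) > 1 else 0.0,
        plateau.std(ddof=1) if len(plateau) > 1 else 0.0,
    )
    return bool(plateau.mean() > blanks.mean() + 3.0 * scatter + 1e-12)


def _fit_rates(pos: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    needed = {"time_min", "genotype", "condition", "replicate"}
    if not needed <= set(pos.columns) or pos["c13c_123"].isna().all():
        return pd.DataFrame(columns=[
            "genotype", "condition", "replicate", "position", "model",
            "i_max", "a", "t_mid", "a13c", "fit_class", "sse"])
    rows = []
    flagged = pos["flags"].str.contains(positional.FLAG_E1_OUT_OF_RANGE)
    # A flagged t=0 sample is pre-pulse: its molar 13C is zero by definition,
    # so the time point is kept at 0 rather than dropped (dropping t0 would
    # leave the series without a pulse start). Later flagged points are
    # excluded from fits.
    data = pos.copy()
    prepulse = flagged & (data["time_min"] == 0)
    data.loc[prepulse, ["c13c_123", "c13c_23", "c13c_1"]] = 0.0
    data = data[~flagged | prepulse]
    for (genotype, condition, rep), grp in data.groupby(
        ["genotype", "condition", "replicate"], sort=True
    ):
        grp = grp[grp["time_min"] <= cfg.max_fit_time].sort_values("time_min")
        for position, column in _POSITIONAL_VALUE_COLUMNS.items():
            sub = grp.dropna(subset=[column])
            if len(sub) < 5:
                continue
            if not _detected(data, genotype, condition, position, cfg):
                # plateau enrichment does not exceed the pre-pulse blank
                # (mean + 3 SD of the t=0 samples): not detected
                rows.append({
                    "genotype": genotype, "condition": condition, "replicate": rep,
                    "position": position, "model": "logistic",
                    "i_max": math.nan, "a": math.nan, "t_mid": math.nan,
                    "a13c": ND, "fit_class": "no_signal", "sse": math.nan,
                })
                continue
            series = LabelingTimeSeries(
                sub["time_min"].to_numpy(), sub[column].to_numpy(),
                group=f"{genotype}/{condition}", replicate=str(rep),
            )
            fit = fit_logistic(series, cfg.fit)
            rows.append({
                "genotype": genotype, "condition": condition, "replicate": rep,
                "position": position, "model": "logistic",
                "i_max": fit.i_max, "a": fit.a, "t_mid": fit.t_mid,
                "a13c": fit.a13c if fit.fit_class != "no_signal" else ND,
                "fit_class": fit.fit_class, "sse": fit.sse,
            })
    return pd.DataFrame(rows)


def _group_tests(fits: pd.DataFrame) -> pd.DataFrame:
    if fits.empty:
        return pd.DataFrame(columns=[
            "condition", "position", "group_a", "group_b",
            "t_statistic", "df", "p_value", "stars"])
    usable = fits[(fits["fit_class"] == "sigmoidal") & (fits["a13c"] != ND)]
    rows = []
    for (condition, position), grp in usable.groupby(["condition", "position"], sort=True):
        genotypes = sorted(grp["genotype"].unique())
        for i, ga in enumerate(genotypes):
            for gb in genotypes[i + 1:]:
                a = grp[grp["genotype"] == ga]["a13c"].astype(float)
                b = grp[grp["genotype"] == gb]["a13c"].astype(float)
                if len(a) < 2 or len(b) < 2:
                    continue
                res = compare_groups(a, b)
                rows.append({
                    "condition": condition, "position": position,
                    "group_a": ga, "group_b": gb,
                    "t_statistic": res.t_statistic, "df": res.df,
                    "p_value": res.p_value, "stars": res.stars,
                })
    return pd.DataFrame(rows)
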