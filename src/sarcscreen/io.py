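"""Cohort-table I/O, run configuration, and the end-to-end study pipeline.

CSV is the interchange format.  Tape measurements (femur length, calf
circumference) are accepted in centimeters (the field convention, and the
default) or meters via an explicit units declaration and are stored
internally in meters.  ``run_study`` chains fit -> calibration -> internal
validation -> cutoff -> diagnostic accuracy -> construct validity for every
sex x criterion panel, isolating per-panel failures.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import accuracy, classifier, construct
from .ewgsop2 import RISK_FACTORS, SarcopeniaCriterion, reference_labels

__all__ = [
    "LENGTH_COLUMNS",
    "RunConfig",
    "MalformedTableError",
    "read_cohort_csv",
    "write_cohort_csv",
    "run_study",
]

logger = logging.getLogger(__name__)

#: Columns holding lengths, subject to cm/m conversion on ingest/egress.
LENGTH_COLUMNS = ("femur_length", "calf_circumference")

_NUMERIC_COLUMNS = (
    "start_frame", "end_frame", "fps", "femur_length", "calf_circumference",
    "body_mass", "age_years", "height_m", "weight_kg", "bmi", "handgrip_kg",
    "fivests_s", "asm_kg", "smi_kg_m2", "power_wkg",
)


class MalformedTableError(ValueError):
    """Too many unparseable rows to trust the table."""


class RunConfig(BaseModel):
    """Validated configuration for the study pipeline.

    Unknown keys are rejected.  ``criteria`` defaults to all four reference
    standards; ``seed`` governs every stochastic step (bootstrap).
    """

    model_config = ConfigDict(extra="forbid")

    criteria: list[str] = Field(
        default_factory=lambda: ["hg_asm", "hg_smi", "5sts_asm", "5sts_smi"]
    )
    units: Literal["cm", "m"] = "cm"
    ci_proportion: str = "wilson"
    ci_auc: str = "hanley-mcneil"
    cutoff_rule: str = "youden"
    bootstrap_B: int = Field(default=1000, ge=1)
    seed: int = classifier.DEFAULT_SEED
    cohort_path: str | None = None
    output_path: str | None = None
    construct_factors: list[str] = Field(default_factory=lambda: list(RISK_FACTORS))
    adjust_covariates: list[str] = Field(
        default_factory=lambda: ["age_years", "sex", "bmi"]
    )

    @field_validator("criteria")
    @classmethod
    def _valid_criteria(cls, v: list[str]) -> list[str]:
        for name in v:
            SarcopeniaCriterion.parse(name)  # raises with a helpful message
        return v


def read_cohort_csv(path, units: str = "cm") -> pd.DataFrame:
    """Read a cohort/trial table, convert lengths to meters, log missingness.

    Rows whose numeric fields fail to parse are collected and reported with
    line numbers; more than 10% malformed aborts with
    :class:`MalformedTableError`.
    """
    if units not in ("cm", "m"):
        raise ValueError(f"units must be 'cm' or 'm', got {units!r}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    bad_rows: dict[int, list[str]] = {}
    for col in df.columns:
        if col in _NUMERIC_COLUMNS:
            parsed = pd.to_numeric(df[col], errors="coerce")
            newly_bad = parsed.isna() & df[col].notna() & (df[col].str.strip() != "")
            for i in df.index[newly_bad]:
                bad_rows.setdefault(int(i) + 2, []).append(col)  # +2: header + 1-base
            df[col] = parsed
    if bad_rows:
        frac = len(bad_rows) / max(len(df), 1)
        msg = "; ".join(f"line {ln}: {cols}" for ln, cols in sorted(bad_rows.items())[:20])
        if frac > 0.10:
            raise MalformedTableError(
                f"{len(bad_rows)} of {len(df)} rows malformed (> 10%): {msg}"
            )
        logger.warning("malformed values treated as missing — %s", msg)
    for col in LENGTH_COLUMNS:
        if col in df.columns:
            values = df[col].astype(float)
            df[f"{col}_m"] = values / 100.0 if units == "cm" else values
            df = df.drop(columns=[col])
    for col in df.columns:
        if df[col].dtype == object and col not in ("participant_id", "sex"):
            lowered = df[col].str.strip().str.lower()
            if lowered.dropna().isin(["true", "false", "0", "1"]).all():
                df[col] = lowered.map({"true": True, "1": True, "false": False, "0": False})
    present = df.notna().mean()
    for col, frac in present.items():
        if frac < 1.0:
            logger.info("column %s: %.1f%% present", col, 100 * frac)
    return df


def write_cohort_csv(df: pd.DataFrame, path, units: str = "cm") -> None:
    """Write a cohort table; meter columns are emitted in *units*."""
    out = df.copy()
    for col in LENGTH_COLUMNS:
        mcol = f"{col}_m"
        if mcol in out.columns:
            out[col] = out[mcol] * (100.0 if units == "cm" else 1.0)
            out = out.drop(columns=[mcol])
    out.to_csv(path, index=False)


def _panel(
    cohort: pd.DataFrame,
    sex: str,
    criterion: SarcopeniaCriterion,
    config: RunConfig,
) -> dict:
    label_col = f"sarc_{criterion.label}"
    if label_col not in cohort.columns:
        cohort = cohort.copy()
        cohort[label_col] = reference_labels(cohort, criterion).astype("boolean")
    model = classifier.fit_model(cohort, sex, criterion, label_col=label_col)
    diag = classifier.bootstrap_optimism(
        model, cohort, B=config.bootstrap_B, seed=config.seed, label_col=label_col
    )
    model.cutoff_probability = classifier.select_cutoff(
        cohort=cohort, model=model, label_col=label_col, rule=config.cutoff_rule
    )
    sub = cohort[cohort["sex"] == sex].dropna(
        subset=["power_wkg", "calf_circumference_m", label_col]
    )
    y = sub[label_col].astype(int).to_numpy()
    probs = classifier.predict_probability(
        model, sub["power_wkg"].to_numpy(), sub["calf_circumference_m"].to_numpy()
    )
    idx_labels = (np.atleast_1d(probs) >= model.cutoff_probability).astype(int)
    table = accuracy.confusion_from_predictions(idx_labels, y)
    report = accuracy.metrics(table)
    report.ci = accuracy.confidence_intervals(
        table, accuracy.CIConfig(proportion=config.ci_proportion)
    )
    auc, auc_ci = accuracy.auc_mann_whitney(probs, y, ci_method=config.ci_auc)
    report.auc = 100 * auc
    report.ci["auc"] = (100 * auc_ci[0], 100 * auc_ci[1])
    return {
        "model": {
            "b0": model.b0,
            "b_power": model.b_power,
            "b_calf": model.b_calf,
            "cutoff_probability": model.cutoff_probability,
            "method": model.method,
            "n_fit": model.n_fit,
        },
        "internal_validation": {
            "apparent_c": diag.apparent_c,
            "optimism": diag.optimism,
            "corrected_c": diag.corrected_c,
            "hl_statistic": diag.hl_statistic,
            "hl_df": diag.hl_df,
            "hl_pvalue": diag.hl_pvalue,
            "n_bootstrap": diag.n_bootstrap,
            "n_skipped": diag.n_skipped,
        },
        "confusion": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
        "metrics": report.to_dict(),
        "metrics_rounded": report.rounded(),
    }


def _construct_validity(cohort: pd.DataFrame, config: RunConfig) -> dict:
    """Whole-cohort ORs of each risk factor / frailty by app status.

    App status here uses the panel models already applied per sex; callers
    pass a cohort carrying an ``app_sarcopenia`` column.
    """
    out: dict[str, dict] = {}
    factors = [f for f in config.construct_factors if f in cohort.columns]
    if "frail" in cohort.columns:
        factors.append("frail")
    for factor in factors:
        sub = cohort.dropna(subset=[factor, "app_sarcopenia"])
        exposed = sub[factor].astype(bool)
        case = sub["app_sarcopenia"].astype(bool)
        table = construct.ExposureTable(
            a=int((exposed & case).sum()),
            b=int((exposed & ~case).sum()),
            c=int((~exposed & case).sum()),
            d=int((~exposed & ~case).sum()),
        )
        entry = {"unadjusted": construct.unadjusted_or(table).to_dict()}
        try:
            entry["adjusted"] = construct.adjusted_or(
                sub, factor, label_col="app_sarcopenia",
                covariates=tuple(config.adjust_covariates),
            ).to_dict()
        except ValueError as exc:
            entry["adjusted"] = {"error": str(exc)}
        out[factor] = entry
    return out


def run_study(cohort: pd.DataFrame, config: RunConfig | None = None) -> dict:
    """The full two-objective pipeline on a cohort table.

    For each of the configured criteria and both sexes: fit the index-test
    model, internally validate (bootstrap optimism + Hosmer–Lemeshow), select
    the ROC cutoff, cross-tabulate against the reference standard, and emit
    the metric panel; then pool app labels across sexes per criterion for the
    construct-validity odds ratios.  A failing panel is recorded, not fatal.
    """
    config = config or RunConfig()
    bundle: dict = {
        "config": json.loads(config.model_dump_json()),
        "n": int(len(cohort)),
        "panels": {},
        "construct_validity": {},
        "errors": {},
    }
    for crit_name in config.criteria:
        criterion = SarcopeniaCriterion.parse(crit_name)
        app_labels = pd.Series(pd.NA, index=cohort.index, dtype="boolean")
        for sex in ("female", "male"):
            key = f"{sex}/{criterion.label}"
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    bundle["panels"][key] = _panel(cohort, sex, criterion, config)
                panel = bundle["panels"][key]
                model = classifier.LogisticSarcopeniaModel(
                    sex=sex, criterion=criterion, **{
                        k: panel["model"][k]
                        for k in ("b0", "b_power", "b_calf", "cutoff_probability")
                    }
                )
                mask = (cohort["sex"] == sex) & cohort["power_wkg"].notna() & cohort[
                    "calf_circumference_m"
                ].notna()
                probs = classifier.predict_probability(
                    model,
                    cohort.loc[mask, "power_wkg"].to_numpy(),
                    cohort.loc[mask, "calf_circumference_m"].to_numpy(),
                )
                app_labels[mask] = np.atleast_1d(probs) >= model.cutoff_probability
            except Exception as exc:  # a panel failure must not sink the study
                logger.error("panel %s failed: %s", key, exc)
                bundle["errors"][key] = f"{type(exc).__name__}: {exc}"
        try:
            pooled = cohort.copy()
            pooled["app_sarcopenia"] = app_labels.astype("boolean")
            pooled = pooled.dropna(subset=["app_sarcopenia"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bundle["construct_validity"][criterion.label] = _construct_validity(
                    pooled, config
                )
        except Exception as exc:
            bundle["errors"][f"construct/{criterion.label}"] = f"{type(exc).__name__}: {exc}"
    return bundle
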