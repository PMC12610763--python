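"""End-to-end orchestration: prepare -> score -> evaluate -> overlap ->
calibrate -> drivers, with one JSON report plus TSV tables.

Every stage logs input/output row counts into the cohort provenance and the
report; reruns with the same configuration and seed produce identical
output. When no phenotype file is given the packaged synthetic cohort is
generated (optionally scaled down) so the whole pipeline runs without any
external data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (Cohort, MissingPolicy, MissingPolicyMode, apply_missing_policy,
                     filter_individuals, filter_studies, read_phenotypes)
from .evaluation import (StratumSpec, compute_auc, driver_analysis, fit_association,
                         interaction_test, select_stratum, sensitivity_missingness)
from .gail import ANCESTRY_TO_POPULATION, load_gail_coefficients, score_gail_cohort
from .mroc import calibration_tests, decile_calibration
from .overlap import ThresholdGrid, enrichment_curve, unique_proportion_curves
from .projection import load_rate_table
from .prs import DEFAULT_BETA, read_dosage_matrix, read_weights, score_prs, score_prs_cohort
from .simulate import default_config, generate_cohort

logger = logging.getLogger("riskoverlap")

REPORT_SCHEMA_VERSION = "1"

DEFAULT_STRATA = tuple(
    StratumSpec(ancestry=a, disease=d, age_group=g)
    for a in ("European", "Asian")
    for d in ("invasive", "DCIS")
    for g in ("all", "lt50", "ge50")
)


@dataclass
class RunConfig:
    """Inputs and knobs of one full pipeline run."""

    phenotypes: str | None = None      # None -> synthetic cohort
    weights: str | None = None
    dosages: str | None = None
    rates: dict = field(default_factory=lambda: dict(ANCESTRY_TO_POPULATION))
    coefficients: str | None = None    # None -> packaged fixture
    missing_policy: str = "baseline"
    beta: float = DEFAULT_BETA
    band: tuple = (0.40, 0.60)
    baseline: str = "population-mean"
    grid: ThresholdGrid = field(default_factory=ThresholdGrid)
    enrichment_target: float = 2.0
    risk_unit: str = "pct-point"
    n_boot: int = 500
    seed: int = 0
    synthetic_scale: float = 1.0
    run_drivers: bool = True
    outdir: str | None = None

    def validate(self) -> None:
        for name in ("phenotypes", "weights", "dosages", "coefficients"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config field {name!r}: {path} does not exist")
        if not self.rates:
            raise ValueError("config field 'rates' (ancestry -> rate table) is required")


def _load_rates(config: RunConfig) -> dict:
    tables = {}
    for ancestry, source in config.rates.items():
        table = load_rate_table(source)
        tables[table.population] = table
    return tables


def _assoc_row(cohort: Cohort, stratum: StratumSpec, config: RunConfig) -> dict:
    row = {"stratum": stratum.label(), "ancestry": stratum.ancestry,
           "disease": stratum.disease, "age_group": stratum.age_group}
    for model, cols in (("PRS", ["prs_ar5"]), ("Gail", ["gail_ar5"]),
                        ("combined", ["prs_ar5", "gail_ar5"])):
        res = fit_association(cohort, cols, stratum, risk_unit=config.risk_unit)
        row[f"{model}_auc"] = res.auc
        row[f"{model}_auc_lo"], row[f"{model}_auc_hi"] = res.auc_ci
        for name, (point, lo, hi) in res.odds_ratios.items():
            tag = f"{model}_or_{name}" if model == "combined" else f"{model}_or"
            row[tag] = point
            row[f"{tag}_lo"], row[f"{tag}_hi"] = lo, hi
        row[f"{model}_n_cases"] = res.n_cases
        row[f"{model}_n_controls"] = res.n_controls
        if res.flags:
            row[f"{model}_flags"] = "; ".join(res.flags)
    if stratum.age_group == "all":
        for model, col in (("PRS", "prs_ar5"), ("Gail", "gail_ar5")):
            try:
                row[f"{model}_p_interaction"] = interaction_test(
                    cohort, col, stratum, risk_unit=config.risk_unit)
            except ValueError as exc:
                row[f"{model}_p_interaction_flag"] = str(exc)
    return row


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written to
    ``config.outdir`` when set)."""
    config.validate()
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "package_version": __version__,
                    "config": _jsonable(dataclasses.asdict(config)),
                    "stages": {}}

    # ---- prepare -------------------------------------------------------
    if config.phenotypes is not None:
        cohort = read_phenotypes(config.phenotypes)
    else:
        gen = default_config(seed=config.seed).scaled(config.synthetic_scale)
        cohort = generate_cohort(gen)
    n0 = len(cohort)
    cohort = filter_individuals(cohort)
    cohort = filter_studies(cohort)
    policy = MissingPolicy(MissingPolicyMode(config.missing_policy))
    resolved = apply_missing_policy(cohort, policy)
    report["stages"]["prepare"] = {"n_input": n0, "n_retained": len(cohort),
                                   "missing_policy": config.missing_policy,
                                   "log": list(resolved.provenance)}
    logger.info("prepare: %d -> %d subjects", n0, len(cohort))

    # ---- score ---------------------------------------------------------
    rates = _load_rates(config)
    coeffs = None
    if config.coefficients is not None:
        coeffs = {pop: load_gail_coefficients(pop, config.coefficients)
                  for pop in rates}
    scored = score_gail_cohort(resolved, rates, coeffs_by_population=coeffs)
    if config.weights is not None and config.dosages is not None:
        wset = read_weights(config.weights)
        dose = read_dosage_matrix(config.dosages)
        rep = score_prs(dose, wset)
        scored.data["prs_raw"] = scored.data["subject_id"].map(rep.raw).to_numpy()
        report["stages"]["score_prs_dosages"] = {
            "n_matched": rep.n_matched, "n_flipped": rep.n_flipped,
            "n_skipped": rep.n_skipped, "n_ambiguous": rep.n_ambiguous}
    scored, prs_params = score_prs_cohort(
        scored, rates, beta=config.beta, band=config.band, baseline=config.baseline)
    report["stages"]["score"] = {
        "n_scored_gail": int(np.isfinite(scored.data["gail_ar5"]).sum()),
        "n_scored_prs": int(np.isfinite(scored.data["prs_ar5"]).sum()),
        "prs_params": {a: {"mu_ctrl": p.mu_ctrl, "sd_ctrl": p.sd_ctrl,
                           "beta": p.beta}
                       for a, p in prs_params.items()},
        "median_ar5": {
            "gail": _median_by(scored, "gail_ar5"),
            "prs": _median_by(scored, "prs_ar5"),
        },
    }
    logger.info("score: gail+prs columns appended")

    # ---- evaluate ------------------------------------------------------
    strata = [s for s in DEFAULT_STRATA
              if _stratum_nonempty(scored, s)]
    assoc_rows = [_assoc_row(scored, s, config) for s in strata]
    report["stages"]["evaluate"] = {"associations": _jsonable(assoc_rows)}
    sens = sensitivity_missingness(
        cohort, rates,
        [s for s in strata if s.disease == "invasive" and s.age_group != "all"],
        coeffs_by_population=coeffs)
    report["stages"]["evaluate"]["missingness_sensitivity"] = _jsonable(
        sens.to_dict(orient="records"))
    logger.info("evaluate: %d strata", len(strata))

    # ---- overlap -------------------------------------------------------
    overlap_out = {"minimal_enrichment_thresholds": [], "unique_proportions": []}
    for stratum in strata:
        if stratum.age_group == "all":
            continue
        for model, col in (("PRS", "prs_ar5"), ("Gail", "gail_ar5")):
            curve, minimal = enrichment_curve(
                scored, col, stratum, grid=config.grid,
                target=config.enrichment_target)
            overlap_out["minimal_enrichment_thresholds"].append({
                "stratum": stratum.label(), "model": model,
                "minimal_threshold": minimal,
                "enrichment_at_hi": float(curve["enrichment"].iloc[-1]),
            })
        uniq = unique_proportion_curves(scored, "prs_ar5", "gail_ar5", stratum,
                                        grid=config.grid)
        overlap_out["unique_proportions"].append({
            "stratum": stratum.label(),
            "table": _jsonable(uniq.to_dict(orient="records"))})
    report["stages"]["overlap"] = _jsonable(overlap_out)
    logger.info("overlap: enrichment curves done")

    # ---- calibrate -----------------------------------------------------
    ref_spec = StratumSpec("European", "invasive", "ge50")
    calib = []
    for stratum in strata:
        if stratum.age_group == "all" or stratum.disease != "invasive":
            continue
        sub, y = select_stratum(scored, stratum)
        ref_sub, ref_y = select_stratum(scored, ref_spec)
        for model, col in (("PRS", "prs_ar5"), ("Gail", "gail_ar5")):
            res = calibration_tests(sub[col].to_numpy(float), y,
                                    n_boot=config.n_boot, seed=config.seed,
                                    reference=(ref_sub[col].to_numpy(float), ref_y))
            calib.append({"stratum": stratum.label(), "model": model,
                          "p_mean_calibration": res.p_mean_calibration,
                          "p_roc_equality": res.p_roc_equality,
                          "p_unified": res.p_unified,
                          "sup_distance": res.sup_distance})
    report["stages"]["calibrate"] = calib
    logger.info("calibrate: %d model/stratum cells", len(calib))

    # ---- drivers -------------------------------------------------------
    if config.run_drivers:
        drivers = {}
        for stratum in strata:
            if stratum.disease != "invasive" or stratum.age_group == "all":
                continue
            table = driver_analysis(cohort, rates, stratum,
                                    coeffs_by_population=coeffs)
            drivers[stratum.label()] = _jsonable(table.to_dict(orient="records"))
        report["stages"]["drivers"] = drivers
        logger.info("drivers: factor-subset AUCs done")

    if config.outdir is not None:
        _write_report(report, scored, config)
    return report


def _stratum_nonempty(cohort: Cohort, stratum: StratumSpec) -> bool:
    try:
        _, y = select_stratum(cohort, stratum)
    except Exception:
        return False
    return bool(y.sum()) and bool((~y).sum())


def _median_by(cohort: Cohort, column: str) -> dict:
    out = {}
    for (ancestry, status), grp in cohort.data.groupby(
            ["ancestry", "status"], observed=True):
        if len(grp):
            out[f"{ancestry}/{status}"] = float(np.nanmedian(grp[column]))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def _write_report(report: dict, scored: Cohort, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    scored.data.to_csv(outdir / "scored_cohort.tsv", sep="\t", index=False)
    pd.DataFrame(report["stages"]["evaluate"]["associations"]).to_csv(
        outdir / "associations.tsv", sep="\t", index=False)
    with open(outdir / "config_echo.json", "w", encoding="utf-8") as fh:
        json.dump(report["config"], fh, indent=2)
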