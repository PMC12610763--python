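"""Association and discrimination analyses on scored cohorts.

Odds ratios per unit of continuous five-year risk come from maximum-
likelihood logistic regression with Wald confidence intervals; AUCs use the
Mann-Whitney rank estimator (ties counted one half) with a DeLong-type
variance for the interval. Analyses are stratified by disease (invasive or
DCIS, each against the shared control pool), ancestry, and age group; an
age-by-score interaction is tested in a separate model with age continuous.

The driver analysis re-scores the Gail model on every non-empty subset of
its five factors (covariates outside the subset forced to missing, hence to
the reference level under the baseline policy) and reports the AUC per
subset, reproducing which factors carry the model's discrimination.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort, MissingPolicy, MissingPolicyMode, apply_missing_policy
from .gail import score_gail_cohort

__all__ = [
    "StratumSpec",
    "AssocResult",
    "select_stratum",
    "fit_association",
    "compute_auc",
    "interaction_test",
    "driver_analysis",
    "sensitivity_missingness",
]

GAIL_FACTORS = ("age_menarche", "age_first_birth", "n_relatives", "n_biopsies",
                "atypical_hyperplasia")


@dataclass(frozen=True)
class StratumSpec:
    """One analysis stratum: disease x ancestry x age group x control set."""

    ancestry: str = "European"
    disease: str = "invasive"          # 'invasive' or 'DCIS'
    age_group: str = "all"             # 'all', 'lt50', 'ge50'
    controls: str = "all"              # 'all' or 'population_based'

    def __post_init__(self) -> None:
        if self.disease not in ("invasive", "DCIS"):
            raise ValueError("disease must be 'invasive' or 'DCIS'")
        if self.age_group not in ("all", "lt50", "ge50"):
            raise ValueError("age_group must be 'all', 'lt50' or 'ge50'")
        if self.controls not in ("all", "population_based"):
            raise ValueError("controls must be 'all' or 'population_based'")

    def label(self) -> str:
        return f"{self.ancestry}/{self.disease}/{self.age_group}/{self.controls}"


@dataclass
class AssocResult:
    """Logistic-fit summary for one stratum and predictor set."""

    odds_ratios: dict          # name -> (point, lo, hi) per risk unit
    auc: float
    auc_ci: tuple
    n_cases: int
    n_controls: int
    p_interaction: float | None = None
    risk_unit: str = "pct-point"
    auc_method: str = "mann-whitney/delong"
    flags: list = dc_field(default_factory=list)

    @property
    def or_point(self) -> float:
        return next(iter(self.odds_ratios.values()))[0]

    @property
    def or_ci(self) -> tuple:
        point, lo, hi = next(iter(self.odds_ratios.values()))
        return (lo, hi)


def select_stratum(cohort: Cohort, stratum: StratumSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Rows of the cohort in the stratum plus binary case labels.

    Invasive analyses exclude DCIS subjects and vice versa; the control pool
    is shared. ``controls='population_based'`` keeps only population-sourced
    controls (cases are unaffected).
    """
    df = cohort.data
    mask = (df["ancestry"] == stratum.ancestry).to_numpy()
    mask &= df["status"].astype(str).isin(["control", stratum.disease]).to_numpy()
    if stratum.age_group == "lt50":
        mask &= (df["age"] < 50).to_numpy()
    elif stratum.age_group == "ge50":
        mask &= (df["age"] >= 50).to_numpy()
    if stratum.controls == "population_based":
        is_ctrl = (df["status"] == "control").to_numpy()
        mask &= ~is_ctrl | (df["control_source"] == "population").to_numpy()
    sub = df.loc[mask]
    labels = (sub["status"].astype(str) == stratum.disease).to_numpy()
    return sub, labels


def _scale_predictor(x: np.ndarray, risk_unit: str) -> np.ndarray:
    if risk_unit == "pct-point":
        return x * 100.0          # absolute-risk fraction -> percentage points
    if risk_unit == "per-sd":
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("constant predictor cannot be scaled per SD")
        return x / sd
    if risk_unit == "raw":
        return x
    raise ValueError("risk_unit must be 'pct-point', 'per-sd' or 'raw'")


def _fit_logit(X: np.ndarray, y: np.ndarray, names: list[str]):
    """ML logistic fit returning (result, flags); separation is flagged."""
    flags: list[str] = []
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        flags.append("rank-deficient design")
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with np.errstate(all="ignore"), warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.Logit(y.astype(float), Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and friends
        return None, flags + [f"fit failed: {type(exc).__name__}"]
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        flags.append("perfect separation detected")
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        flags.append("non-finite estimates (possible separation)")
    return res, flags


def fit_association(
    cohort: Cohort,
    predictors,
    stratum: StratumSpec,
    risk_unit: str = "pct-point",
) -> AssocResult:
    """OR (Wald 95% CI) and AUC for one or more risk columns in a stratum.

    ``predictors`` is a column name or list of names (a joint fit for the
    combined PRS+Gail rows). The AUC is the rank AUC of the fitted linear
    predictor, which for a single predictor equals the AUC of the predictor
    itself.
    """
    if isinstance(predictors, str):
        predictors = [predictors]
    sub, y = select_stratum(cohort, stratum)
    n_cases, n_controls = int(y.sum()), int((~y).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError(f"stratum {stratum.label()} lacks cases or controls")

    cols = []
    flags: list[str] = []
    for name in predictors:
        x = sub[name].to_numpy(float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"predictor {name!r} holds non-finite values")
        if x.std() == 0:
            flags.append(f"constant predictor {name!r}: OR undefined")
            cols.append(np.zeros_like(x))
        else:
            cols.append(_scale_predictor(x, risk_unit))
    X = np.column_stack(cols)

    ors: dict[str, tuple] = {}
    res, fit_flags = _fit_logit(X, y, predictors)
    flags.extend(fit_flags)
    if res is not None and not any("separation" in f or "failed" in f or
                                   "constant" in f for f in flags):
        ci = res.conf_int()
        for i, name in enumerate(predictors):
            beta, lo, hi = res.params[i + 1], ci[i + 1, 0], ci[i + 1, 1]
            ors[name] = (float(np.exp(beta)), float(np.exp(lo)), float(np.exp(hi)))
    else:
        for name in predictors:
            ors[name] = (np.nan, np.nan, np.nan)

    if res is not None and len(predictors) > 1:
        score = (sm.add_constant(X, has_constant="add") @ res.params)
    else:
        score = X[:, 0] if X.shape[1] else np.zeros(len(y))
    auc, auc_ci = compute_auc(score, y)
    return AssocResult(odds_ratios=ors, auc=auc, auc_ci=auc_ci,
                       n_cases=n_cases, n_controls=n_controls,
                       risk_unit=risk_unit, flags=flags)


def compute_auc(scores, labels) -> tuple[float, tuple]:
    """Rank (Mann-Whitney) AUC with ties counted 1/2, DeLong 95% CI.

    The variance uses the placement values of DeLong, DeLong and
    Clarke-Pearson; with a single case or control the variance is undefined
    and the CI degenerates to the point estimate.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    ranks_pos = stats.rankdata(pos)
    ranks_neg = stats.rankdata(neg)
    # Placements: fraction of the other class below each observation.
    v10 = (ranks_all[:m] - ranks_pos) / n          # per case
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m    # per control
    auc = float(v10.mean())
    if m > 1 and n > 1:
        var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
        half = 1.959963984540054 * np.sqrt(var)
        ci = (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))
    else:
        ci = (auc, auc)
    return auc, ci


def interaction_test(cohort: Cohort, predictor: str, stratum: StratumSpec,
                     risk_unit: str = "pct-point") -> float:
    """Wald p-value for score x age (continuous) interaction in a stratum."""
    base = StratumSpec(stratum.ancestry, stratum.disease, "all", stratum.controls)
    sub, y = select_stratum(cohort, base)
    age = sub["age"].to_numpy(float)
    if age.std() == 0:
        raise ValueError("no age variation: interaction inestimable")
    x = _scale_predictor(sub[predictor].to_numpy(float), risk_unit)
    X = np.column_stack([x, age, x * age])
    res, flags = _fit_logit(X, y, [predictor, "age", "interaction"])
    if res is None or any("separation" in f for f in flags):
        raise ValueError(f"interaction fit failed: {flags}")
    return float(res.pvalues[3])


def driver_analysis(
    cohort: Cohort,
    rates_by_population,
    stratum: StratumSpec,
    coeffs_by_population=None,
    factors=GAIL_FACTORS,
) -> pd.DataFrame:
    """AUC of the Gail score for every non-empty factor subset.

    Covariates outside the subset are forced to missing, hence to the
    reference level under the baseline policy, and the five-year risk is
    recomputed. Returns one row per subset (2^k - 1 of them) with columns
    ``factors``, ``includes_hyperplasia``, ``auc``, ``auc_lo``, ``auc_hi``.
    """
    rows = []
    for k in range(1, len(factors) + 1):
        for subset in itertools.combinations(factors, k):
            masked = cohort.copy()
            for col in factors:
                if col not in subset and col in masked.data.columns:
                    cats = masked.data[col].astype(str)
                    masked.data[col] = pd.Categorical(
                        ["unknown"] * len(cats),
                        categories=masked.data[col].cat.categories
                        if hasattr(masked.data[col], "cat") else None)
            masked = apply_missing_policy(masked, MissingPolicy(MissingPolicyMode.baseline))
            scored = score_gail_cohort(masked, rates_by_population,
                                       coeffs_by_population=coeffs_by_population)
            sub, y = select_stratum(scored, stratum)
            auc, ci = compute_auc(sub["gail_ar5"].to_numpy(float), y)
            rows.append({
                "factors": "+".join(subset),
                "n_factors": k,
                "includes_hyperplasia": "atypical_hyperplasia" in subset,
                "auc": auc, "auc_lo": ci[0], "auc_hi": ci[1],
            })
    return pd.DataFrame(rows)


def sensitivity_missingness(
    cohort: Cohort,
    rates_by_population,
    strata,
    coeffs_by_population=None,
) -> pd.DataFrame:
    """Paired Gail AUC table under the baseline vs highest-risk policies."""
    scored = {}
    for mode in (MissingPolicyMode.baseline, MissingPolicyMode.highest_risk):
        resolved = apply_missing_policy(cohort, MissingPolicy(mode))
        scored[mode.value] = score_gail_cohort(
            resolved, rates_by_population, coeffs_by_population=coeffs_by_population)
    rows = []
    for stratum in strata:
        row = {"stratum": stratum.label()}
        for mode, sc in scored.items():
            sub, y = select_stratum(sc, stratum)
            auc, ci = compute_auc(sub["gail_ar5"].to_numpy(float), y)
            row[f"auc_{mode}"] = auc
            row[f"auc_{mode}_lo"] = ci[0]
            row[f"auc_{mode}_hi"] = ci[1]
        rows.append(row)
    return pd.DataFrame(rows)
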