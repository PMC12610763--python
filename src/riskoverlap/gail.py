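"""Parsimonious Gail relative risk and five-year absolute risk.

The relative risk combines age at menarche, age at first live birth,
first-degree family history, number of breast biopsies (with an age-regime
switch at 50 years) and an atypical-hyperplasia multiplier applied only when
at least one biopsy was taken:

    rr = exp(b_men*MEN + (b_bio + b_bio50*1[age>=50])*BIO
             + b_flb*FLB + b_rel*REL + b_flbrel*FLB*REL) * m_AH

with the BCRAT-style integer codes documented in the packaged coefficient
table. Absolute risk projects rr against a population rate table with the
attributable-risk adjustment switched on.

Coefficient values are not part of this package's methodology: they ship as
a versioned, checksummed fixture transcribed from the published model, and
any user table with the same schema is accepted.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .projection import RateTable, project_absolute_risk, project_absolute_risk_vector

__all__ = [
    "GailCoefficients",
    "GailResult",
    "load_gail_coefficients",
    "gail_relative_risk",
    "gail_five_year_risk",
    "score_gail_cohort",
]

MENARCHE_CODE = {"ge14": 0, "12to13": 1, "lt12": 2}
BIOPSY_CODE = {"0": 0, "1": 1, "ge2": 2}
FIRST_BIRTH_CODE = {"lt20": 0, "20to24": 1, "25to29": 2, "nulliparous": 2, "ge30": 3}
RELATIVES_CODE = {"0": 0, "1": 1, "ge2": 2}

#: Default mapping from genetic ancestry to rate-table population.
ANCESTRY_TO_POPULATION = {"European": "White", "Asian": "Chinese"}


@dataclass(frozen=True)
class GailCoefficients:
    population: str
    beta_menarche: float
    beta_biopsies: float
    beta_biopsies_age_ge50: float
    beta_first_birth: float
    beta_relatives: float
    beta_first_birth_x_relatives: float
    hyperplasia_multiplier: dict
    one_minus_ar_lt50: float
    one_minus_ar_ge50: float
    version: str = "unversioned"
    checksum: str = ""


@dataclass(frozen=True)
class GailResult:
    rr: float
    ar5: float


def load_gail_coefficients(population: str, path=None) -> GailCoefficients:
    """Load the coefficient table for one population.

    Without ``path`` the packaged fixture is used. The file's SHA-256 is
    recorded on the returned object so runs are attributable to an exact
    coefficient version.
    """
    if path is None:
        ref = importlib.resources.files("riskoverlap.data") / "gail_coefficients.json"
        raw = ref.read_bytes()
    else:
        with open(path, "rb") as fh:
            raw = fh.read()
    doc = json.loads(raw.decode("utf-8"))
    try:
        entry = doc["populations"][population]
    except KeyError:
        raise ValueError(
            f"population {population!r} not in coefficient table "
            f"(available: {sorted(doc['populations'])})"
        ) from None
    return GailCoefficients(
        population=population,
        version=doc.get("version", "unversioned"),
        checksum=hashlib.sha256(raw).hexdigest(),
        **entry,
    )


def _require_known(value: str, field: str) -> str:
    if value == "unknown" and field != "atypical_hyperplasia":
        raise ValueError(
            f"{field} is 'unknown'; apply a missing-data policy before scoring"
        )
    return value


def gail_relative_risk(
    age: float,
    age_menarche: str,
    age_first_birth: str,
    n_relatives: str,
    n_biopsies: str,
    atypical_hyperplasia: str,
    coeffs: GailCoefficients,
) -> float:
    """Relative risk for one subject; requires policy-resolved covariates.

    Atypical hyperplasia may be ``unknown`` (no-effect multiplier 1.0); a
    subject with no biopsies gets multiplier 1.0 regardless of the
    hyperplasia field.
    """
    men = MENARCHE_CODE[_require_known(age_menarche, "age_menarche")]
    bio = BIOPSY_CODE[_require_known(n_biopsies, "n_biopsies")]
    flb = FIRST_BIRTH_CODE[_require_known(age_first_birth, "age_first_birth")]
    rel = RELATIVES_CODE[_require_known(n_relatives, "n_relatives")]
    if atypical_hyperplasia not in ("no", "yes", "unknown"):
        raise ValueError(f"undeclared hyperplasia level {atypical_hyperplasia!r}")

    beta_bio = coeffs.beta_biopsies + (coeffs.beta_biopsies_age_ge50 if age >= 50 else 0.0)
    log_rr = (
        coeffs.beta_menarche * men
        + beta_bio * bio
        + coeffs.beta_first_birth * flb
        + coeffs.beta_relatives * rel
        + coeffs.beta_first_birth_x_relatives * flb * rel
    )
    if bio == 0:
        mult = coeffs.hyperplasia_multiplier["no_biopsy"]
    else:
        mult = coeffs.hyperplasia_multiplier[atypical_hyperplasia]
    return float(np.exp(log_rr) * mult)


def gail_five_year_risk(
    age: float,
    age_menarche: str,
    age_first_birth: str,
    n_relatives: str,
    n_biopsies: str,
    atypical_hyperplasia: str,
    coeffs: GailCoefficients,
    rates: RateTable,
    horizon: float = 5.0,
) -> GailResult:
    """Relative and five-year absolute risk for one subject."""
    rr = gail_relative_risk(age, age_menarche, age_first_birth, n_relatives,
                            n_biopsies, atypical_hyperplasia, coeffs)
    proj = project_absolute_risk(rates, age, rr, horizon, use_ar_adjustment=True)
    return GailResult(rr=rr, ar5=proj.ar5)


def gail_relative_risk_vector(df: pd.DataFrame, coeffs: GailCoefficients) -> np.ndarray:
    """Vectorised relative risk over a policy-resolved cohort frame."""
    for col in ("age_menarche", "age_first_birth", "n_relatives", "n_biopsies"):
        if (df[col].astype(str) == "unknown").any():
            raise ValueError(
                f"{col} holds 'unknown'; apply a missing-data policy before scoring")
    men = df["age_menarche"].astype(str).map(MENARCHE_CODE).to_numpy(float)
    bio = df["n_biopsies"].astype(str).map(BIOPSY_CODE).to_numpy(float)
    flb = df["age_first_birth"].astype(str).map(FIRST_BIRTH_CODE).to_numpy(float)
    rel = df["n_relatives"].astype(str).map(RELATIVES_CODE).to_numpy(float)
    age = df["age"].to_numpy(float)
    beta_bio = coeffs.beta_biopsies + coeffs.beta_biopsies_age_ge50 * (age >= 50)
    log_rr = (coeffs.beta_menarche * men + beta_bio * bio
              + coeffs.beta_first_birth * flb + coeffs.beta_relatives * rel
              + coeffs.beta_first_birth_x_relatives * flb * rel)
    ah = df["atypical_hyperplasia"].astype(str).map(
        lambda v: coeffs.hyperplasia_multiplier.get(v, 1.0)).to_numpy(float)
    mult = np.where(bio == 0, coeffs.hyperplasia_multiplier["no_biopsy"], ah)
    return np.exp(log_rr) * mult


def score_gail_cohort(
    cohort: Cohort,
    rates_by_population: dict[str, RateTable],
    coeffs_by_population: dict[str, GailCoefficients] | None = None,
    ancestry_map: dict[str, str] | None = None,
    horizon: float = 5.0,
) -> Cohort:
    """Append ``gail_rr`` and ``gail_ar5`` columns to a policy-resolved cohort.

    Ancestry maps to a rate-table population (European -> White,
    Asian -> Chinese by default; overridable).
    """
    amap = dict(ANCESTRY_TO_POPULATION if ancestry_map is None else ancestry_map)
    if coeffs_by_population is None:
        coeffs_by_population = {pop: load_gail_coefficients(pop)
                                for pop in set(amap.values())}
    out = cohort.copy()
    df = out.data
    rr = np.full(len(df), np.nan)
    ar5 = np.full(len(df), np.nan)
    for ancestry, pop in amap.items():
        mask = (df["ancestry"] == ancestry).to_numpy()
        if not mask.any():
            continue
        sub = df.loc[mask]
        rr_sub = gail_relative_risk_vector(sub, coeffs_by_population[pop])
        ar5_sub = project_absolute_risk_vector(
            rates_by_population[pop], sub["age"].to_numpy(float), rr_sub,
            horizon=horizon, use_ar_adjustment=True)
        rr[mask] = rr_sub
        ar5[mask] = ar5_sub
    df["gail_rr"] = rr
    df["gail_ar5"] = ar5
    out.log(f"score_gail: scored {int(np.isfinite(ar5).sum())} subjects "
            f"(coefficient version "
            f"{next(iter(coeffs_by_population.values())).version})")
    return out
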