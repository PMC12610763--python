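"""Cohort data model, phenotype I/O, and inclusion / missing-data policies.

A cohort is a table of subjects with clinical Gail covariates (categorical,
with ``unknown`` as an explicit level), an optional raw polygenic sum score,
ancestry, disease status, and the source of controls. Ages are stored in one
field: age at interview for controls, age at diagnosis for cases.

Filtering mirrors consortium practice: subjects outside the age range where
Gail-type prediction is valid (30-80 years) are excluded, and whole
(study x disease-status) cells are dropped when at least two of the three
core covariates (menarche, first birth, family history) are unknown for at
least half the cell. Every filter appends counts to the cohort's provenance
log so row-count bookkeeping is auditable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "GAIL_COVARIATES",
    "Cohort",
    "MissingPolicy",
    "read_phenotypes",
    "filter_individuals",
    "filter_studies",
    "apply_missing_policy",
]

ANCESTRIES = ("European", "Asian")
STATUSES = ("control", "invasive", "DCIS")
CONTROL_SOURCES = ("population", "other", "not_applicable")

#: Declared levels of each categorical field; ``unknown`` is a real level,
#: never an empty cell after parsing.
LEVELS: dict[str, tuple[str, ...]] = {
    "ancestry": ANCESTRIES,
    "status": STATUSES,
    "control_source": CONTROL_SOURCES,
    "age_menarche": ("ge14", "12to13", "lt12", "unknown"),
    "age_first_birth": ("lt20", "20to24", "25to29", "nulliparous", "ge30", "unknown"),
    "n_relatives": ("0", "1", "ge2", "unknown"),
    "n_biopsies": ("0", "1", "ge2", "unknown"),
    "atypical_hyperplasia": ("no", "yes", "unknown"),
}

#: Covariates recoded by the missing-data policies (atypical hyperplasia is
#: handled by the engine's no-effect multiplier and is not recoded).
GAIL_COVARIATES = ("age_menarche", "age_first_birth", "n_relatives", "n_biopsies")

#: Input codes mapped to the ``unknown`` level by default (consortium files vary).
DEFAULT_UNKNOWN_CODES = ("", "NA", "na", "unknown", "888", "999")

REQUIRED_COLUMNS = (
    "subject_id", "study_id", "ancestry", "age", "status",
    "age_menarche", "age_first_birth", "n_relatives", "n_biopsies",
    "atypical_hyperplasia",
)

AGE_MIN, AGE_MAX = 30, 80


class MissingPolicyMode(str, Enum):
    baseline = "baseline"
    highest_risk = "highest_risk"


@dataclass(frozen=True)
class MissingPolicy:
    """Recode rule for unknown Gail covariates.

    ``baseline`` maps every unknown to the lowest-relative-risk category
    (the primary-analysis convention, relative risk 1 for an all-unknown
    subject); ``highest_risk`` maps to the highest-relative-risk category of
    each variable (the sensitivity-analysis convention).
    """

    mode: MissingPolicyMode = MissingPolicyMode.baseline

    @property
    def mapping(self) -> dict[str, str]:
        if self.mode == MissingPolicyMode.baseline:
            return {
                "age_menarche": "ge14",
                "age_first_birth": "lt20",
                "n_relatives": "0",
                "n_biopsies": "0",
            }
        # Highest-risk levels follow the argmax of the packaged coefficient
        # codes (first birth: ge30 carries the largest main-effect code).
        return {
            "age_menarche": "lt12",
            "age_first_birth": "ge30",
            "n_relatives": "ge2",
            "n_biopsies": "ge2",
        }


@dataclass
class Cohort:
    """Ordered subject table plus a free-text log of filters applied."""

    data: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = self.data["subject_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique()[:5]
            raise ValueError(f"duplicate subject_id values: {list(dupes)}")

    def __len__(self) -> int:
        return len(self.data)

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy(), list(self.provenance))

    def subset(self, mask: pd.Series, reason: str) -> "Cohort":
        removed = int((~mask).sum())
        out = Cohort(self.data.loc[mask].copy(), list(self.provenance))
        out.log(f"{reason}: removed {removed}, retained {len(out)}")
        return out


def _parse_categorical(series: pd.Series, column: str,
                       unknown_codes: Iterable[str]) -> pd.Series:
    levels = LEVELS[column]
    raw = series.astype("string").fillna("")
    cleaned = raw.str.strip()
    mapped = cleaned.where(~cleaned.isin(list(unknown_codes)), "unknown")
    bad = ~mapped.isin(levels)
    if bad.any():
        values = sorted(mapped[bad].unique()[:10])
        raise ValueError(
            f"column {column!r} holds undeclared level(s) {values}; "
            f"declared levels are {list(levels)}"
        )
    return pd.Categorical(mapped, categories=levels)


def read_phenotypes(
    path,
    delimiter: str = "\t",
    unknown_codes: Iterable[str] = DEFAULT_UNKNOWN_CODES,
) -> Cohort:
    """Read a delimited phenotype file into a :class:`Cohort`.

    The header must name the declared columns; ``control_source`` defaults
    to ``population`` when absent (enabling the population-based-controls
    sensitivity subset). Unparseable categorical values raise, they are
    never silently coerced. Non-numeric ages raise with the offending
    subject ids listed.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file missing mandatory column(s): {missing}")

    out = pd.DataFrame(index=df.index)
    out["subject_id"] = df["subject_id"].astype(str)
    out["study_id"] = df["study_id"].astype(str)

    age_raw = df["age"].str.strip()
    unknown_age = age_raw.isin(list(unknown_codes))
    age = pd.to_numeric(age_raw.where(~unknown_age, other=np.nan), errors="coerce")
    bad_age = age.isna() & ~unknown_age
    if bad_age.any():
        ids = out.loc[bad_age, "subject_id"].tolist()[:10]
        raise ValueError(f"non-numeric age for subject(s): {ids}")
    out["age"] = age

    for column in ("ancestry", "status", "age_menarche", "age_first_birth",
                   "n_relatives", "n_biopsies", "atypical_hyperplasia"):
        out[column] = _parse_categorical(df[column], column, unknown_codes)
    if "control_source" in df.columns:
        out["control_source"] = _parse_categorical(
            df["control_source"], "control_source", unknown_codes="")
    else:
        out["control_source"] = pd.Categorical(
            np.where(out["status"] == "control", "population", "not_applicable"),
            categories=CONTROL_SOURCES)

    if "prs_raw" in df.columns:
        prs_raw = df["prs_raw"].str.strip()
        out["prs_raw"] = pd.to_numeric(
            prs_raw.where(~prs_raw.isin(list(unknown_codes)), other=np.nan),
            errors="raise")
    else:
        out["prs_raw"] = np.nan

    # carry appended score columns (gail_rr, prs_z, ...) through round trips
    for column in df.columns:
        if column not in out.columns:
            out[column] = pd.to_numeric(df[column].replace("", np.nan),
                                        errors="coerce")

    cohort = Cohort(out.reset_index(drop=True))
    cohort.log(f"read_phenotypes: parsed {len(cohort)} subjects from {path}")
    return cohort


def write_phenotypes(cohort: Cohort, path, delimiter: str = "\t") -> None:
    """Write a cohort (including any appended score columns) back to text."""
    cohort.data.to_csv(path, sep=delimiter, index=False)


def filter_individuals(cohort: Cohort,
                       min_age: int = AGE_MIN, max_age: int = AGE_MAX) -> Cohort:
    """Retain subjects with known age inside [min_age, max_age].

    Idempotent; removal counts by reason are appended to the provenance log.
    """
    age = cohort.data["age"]
    known = age.notna()
    out = cohort.subset(known, "filter_individuals/unknown-age")
    in_range = (out.data["age"] >= min_age) & (out.data["age"] <= max_age)
    below = int((out.data["age"] < min_age).sum())
    above = int((out.data["age"] > max_age).sum())
    out = out.subset(in_range, f"filter_individuals/age-range [{min_age},{max_age}]")
    out.log(f"filter_individuals: {below} below {min_age}, {above} above {max_age}")
    return out


#: The three covariates whose per-cell missingness drives study exclusion.
STUDY_FILTER_COVARIATES = ("age_menarche", "age_first_birth", "n_relatives")


def filter_studies(cohort: Cohort, threshold: float = 0.5,
                   min_covariates: int = 2) -> Cohort:
    """Drop (study x status) cells with heavy core-covariate missingness.

    A cell is dropped when at least ``min_covariates`` of the three core
    covariates (menarche, first birth, family history) are ``unknown`` for a
    fraction >= ``threshold`` of its subjects (boundary counted as exceeding,
    i.e. "50% or more"). Exclusion is determined separately per study and
    per disease status. Only the ``unknown`` level counts as missing;
    structurally absent columns are not considered (they parse to unknown
    anyway and are then indistinguishable).
    """
    df = cohort.data
    if df.empty:
        out = cohort.copy()
        out.log("filter_studies: empty cohort, nothing to do")
        return out
    drop = pd.Series(False, index=df.index)
    dropped_cells: list[str] = []
    for (study, status), idx in df.groupby(
            ["study_id", "status"], observed=True).groups.items():
        cell = df.loc[idx]
        n_exceed = sum(
            (cell[cov] == "unknown").mean() >= threshold
            for cov in STUDY_FILTER_COVARIATES
        )
        if n_exceed >= min_covariates:
            drop.loc[idx] = True
            dropped_cells.append(f"{study}/{status} (n={len(idx)})")
    out = cohort.subset(~drop, "filter_studies/missingness>=50% on >=2 core covariates")
    if dropped_cells:
        out.log("filter_studies: dropped cells " + "; ".join(sorted(dropped_cells)))
    return out


def apply_missing_policy(cohort: Cohort, policy: MissingPolicy) -> Cohort:
    """Recode unknown Gail covariates per policy; known values never change."""
    out = cohort.copy()
    mapping = policy.mapping
    for column, target in mapping.items():
        col = out.data[column]
        out.data[column] = col.where(col != "unknown", target)
    out.log(f"apply_missing_policy: mode={policy.mode.value}")
    return out


def family_history_flag(cohort: Cohort) -> np.ndarray:
    """Binary first-degree family history: unknown is treated as no history."""
    rel = cohort.data["n_relatives"].astype(str).to_numpy()
    return np.isin(rel, ("1", "ge2"))
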