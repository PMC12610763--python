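"""Five-year absolute-risk projection from age-banded hazards.

Converts a subject's relative risk into an absolute risk of disease over a
projection horizon using a two-state competing-risks model with
piecewise-constant hazards: a breast-cancer incidence hazard ``h1`` and a
competing (non-breast-cancer) mortality hazard ``h2``, both banded by age.
Within each band the contribution to absolute risk has a closed form, so no
quadrature is needed and the result is exact for banded rate tables.

The attributable-risk complement ``1 - AR`` converts composite population
incidence into the baseline incidence of an all-reference-covariates woman
(Gail-type models); it is applied when ``use_ar_adjustment`` is set and must
be left off when the baseline hazard is handled externally (as the PRS
engine does via its population-mean constraint).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RateTable", "Projection", "load_rate_table", "project_absolute_risk"]


@dataclass(frozen=True)
class RateTable:
    """Age-banded incidence/mortality hazards for one population.

    Bands are half-open intervals ``[age_start, age_end)`` that must be
    contiguous, non-overlapping and cover at least [20, 90).
    """

    population: str
    age_start: np.ndarray  # int years, inclusive
    age_end: np.ndarray    # int years, exclusive
    h1: np.ndarray         # incidence hazard per person-year
    h2: np.ndarray         # competing mortality hazard per person-year
    one_minus_ar: np.ndarray  # attributable-risk complement in (0, 1]

    def __post_init__(self) -> None:
        a0 = np.asarray(self.age_start, dtype=float)
        a1 = np.asarray(self.age_end, dtype=float)
        h1 = np.asarray(self.h1, dtype=float)
        h2 = np.asarray(self.h2, dtype=float)
        omar = np.asarray(self.one_minus_ar, dtype=float)
        if not (len(a0) == len(a1) == len(h1) == len(h2) == len(omar)):
            raise ValueError("rate table columns have unequal lengths")
        if len(a0) == 0:
            raise ValueError("rate table is empty")
        order = np.argsort(a0)
        for name, arr in (("age_start", a0), ("age_end", a1), ("h1", h1),
                          ("h2", h2), ("one_minus_ar", omar)):
            object.__setattr__(self, name, arr[order])
        if np.any(self.age_end <= self.age_start):
            raise ValueError("bands must have age_end > age_start")
        if np.any(self.age_start[1:] != self.age_end[:-1]):
            raise ValueError("bands must be contiguous and non-overlapping")
        if np.any(self.h1 < 0) or np.any(self.h2 < 0):
            raise ValueError("hazards must be non-negative")
        if np.any((self.one_minus_ar <= 0) | (self.one_minus_ar > 1)):
            raise ValueError("one_minus_AR must lie in (0, 1]")

    @property
    def coverage(self) -> tuple[float, float]:
        return float(self.age_start[0]), float(self.age_end[-1])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, population: str | None = None) -> "RateTable":
        required = {"population", "age_start", "age_end", "h1", "h2", "one_minus_AR"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"rate table missing columns: {sorted(missing)}")
        if population is not None:
            df = df[df["population"] == population]
            if df.empty:
                raise ValueError(f"no rows for population {population!r}")
        pops = df["population"].unique()
        if len(pops) != 1:
            raise ValueError("rate table frame holds multiple populations; pass `population`")
        return cls(
            population=str(pops[0]),
            age_start=df["age_start"].to_numpy(),
            age_end=df["age_end"].to_numpy(),
            h1=df["h1"].to_numpy(),
            h2=df["h2"].to_numpy(),
            one_minus_ar=df["one_minus_AR"].to_numpy(),
        )


@dataclass(frozen=True)
class Projection:
    """Result of one absolute-risk projection."""

    age_start: float
    horizon: float
    rr: float
    ar5: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar5 <= 1.0):
            raise ValueError("absolute risk outside [0, 1]")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")


def load_rate_table(source: str, population: str | None = None) -> RateTable:
    """Load a rate table from a delimited file or a packaged fixture.

    ``source`` may be ``"White"`` or ``"Chinese"`` (packaged transcriptions)
    or a path to a TSV with columns population, age_start, age_end, h1, h2,
    one_minus_AR; '#' lines are comments.
    """
    packaged = {"White": "rates_white.tsv", "Chinese": "rates_chinese.tsv"}
    if source in packaged:
        ref = importlib.resources.files("riskoverlap.data") / packaged[source]
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t", comment="#")
        return RateTable.from_frame(df, population=source)
    df = pd.read_csv(source, sep=None, engine="python", comment="#")
    return RateTable.from_frame(df, population=population)


def _band_bounds(rates: RateTable, age: float, horizon: float) -> None:
    lo, hi = rates.coverage
    if age < lo or age + horizon > hi:
        raise ValueError(
            f"projection window [{age}, {age + horizon}] outside rate-table "
            f"coverage [{lo}, {hi})"
        )


def project_absolute_risk(
    rates: RateTable,
    age: float,
    rr: float,
    horizon: float = 5.0,
    use_ar_adjustment: bool = True,
) -> Projection:
    """Absolute risk of disease within ``horizon`` years from ``age``.

    With piecewise-constant hazards the probability of a breast-cancer event
    in sub-band k of length L_k is

        S_k * lam_k / (lam_k + h2_k) * (1 - exp(-(lam_k + h2_k) L_k)),

    where lam_k = rr * h1_k * (1-AR)_k (the AR factor only under
    ``use_ar_adjustment``) and S_k is the probability of being event-free
    (neither diagnosed nor dead) at the start of the sub-band. Bands with
    lam_k + h2_k = 0 contribute nothing.
    """
    if rr <= 0:
        raise ValueError("relative risk must be positive")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    _band_bounds(rates, age, horizon)

    # Split [age, age+horizon] at band edges.
    edges = np.unique(np.concatenate([
        [age, age + horizon],
        rates.age_start[(rates.age_start > age) & (rates.age_start < age + horizon)],
    ]))
    risk = 0.0
    surv = 1.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        idx = int(np.searchsorted(rates.age_start, lo, side="right") - 1)
        h1 = rates.h1[idx]
        if use_ar_adjustment:
            h1 = h1 * rates.one_minus_ar[idx]
        lam = rr * h1
        tot = lam + rates.h2[idx]
        length = hi - lo
        if tot > 0:
            risk += surv * (lam / tot) * -np.expm1(-tot * length)
            surv *= np.exp(-tot * length)
    return Projection(age_start=float(age), horizon=float(horizon), rr=float(rr),
                      ar5=float(risk))


def project_absolute_risk_vector(
    rates: RateTable,
    ages: np.ndarray,
    rrs: np.ndarray,
    horizon: float = 5.0,
    use_ar_adjustment: bool = True,
) -> np.ndarray:
    """Vectorised projection for arrays of (age, rr) against one rate table.

    Subjects are grouped by integer age so the per-band survival recursion
    runs once per distinct age; exact agreement with the scalar routine.
    """
    ages = np.asarray(ages, dtype=float)
    rrs = np.asarray(rrs, dtype=float)
    if ages.shape != rrs.shape:
        raise ValueError("ages and rrs must have the same shape")
    if np.any(rrs <= 0):
        raise ValueError("relative risks must be positive")
    out = np.empty_like(ages, dtype=float)
    for age in np.unique(ages):
        mask = ages == age
        _band_bounds(rates, age, horizon)
        edges = np.unique(np.concatenate([
            [age, age + horizon],
            rates.age_start[(rates.age_start > age) & (rates.age_start < age + horizon)],
        ]))
        rr = rrs[mask]
        risk = np.zeros(rr.shape)
        surv = np.ones(rr.shape)
        for lo, hi in zip(edges[:-1], edges[1:]):
            idx = int(np.searchsorted(rates.age_start, lo, side="right") - 1)
            h1 = rates.h1[idx]
            if use_ar_adjustment:
                h1 = h1 * rates.one_minus_ar[idx]
            lam = rr * h1
            tot = lam + rates.h2[idx]
            length = hi - lo
            nz = tot > 0
            contrib = np.zeros(rr.shape)
            contrib[nz] = (lam[nz] / tot[nz]) * -np.expm1(-tot[nz] * length)
            risk += surv * contrib
            surv *= np.exp(-tot * length)
        out[mask] = risk
    return out
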