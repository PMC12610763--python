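"""Polygenic risk score: dosage scoring, standardization, and absolute risk.

Scoring is a weighted sum of effect-allele dosages (sum-score convention).
Missing dosage entries are mean-imputed per variant from the observed
dosages of the whole dataset (equivalently 2 x effect-allele frequency),
matching the behaviour of standard scoring tools. Raw scores are
standardized against ancestry-specific control means/SDs, percentiles are
taken from the standard normal CDF, and the relative risk of a percentile is
the theoretical odds ratio against the 40-60th percentile band (the "general
population" band):

    rr(z) = exp(beta * z) / c,
    c = exp(beta^2/2) * [Phi(q_hi - beta) - Phi(q_lo - beta)] / (hi - lo),

where q = Phi^{-1} at the band edges and beta is the log odds ratio per SD
of PRS. For absolute risk the banded population incidence h1 is divided by
m = E[rr(Z)] (Z standard normal) so that the population-average incidence is
conserved; the mid-quintile-baseline alternative (h1 left unscaled) is
selectable. No attributable-risk adjustment is applied on this route.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .projection import RateTable, project_absolute_risk_vector

__all__ = [
    "WeightSet",
    "PRSParams",
    "ScoreReport",
    "read_weights",
    "read_dosage_matrix",
    "read_dosages_vcf",
    "score_prs",
    "standardize",
    "control_moments",
    "rr_vs_middle_quintile",
    "mean_relative_risk",
    "prs_five_year_risk",
    "score_prs_cohort",
]

#: Log odds ratio per SD of the 313-variant score, transcribed from its
#: development publication (overall breast cancer, OR 1.61 per SD).
DEFAULT_BETA = float(np.log(1.61))

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class WeightSet:
    """PGS-Catalog-style scoring weights (log-odds per effect-allele dose)."""

    variants: pd.DataFrame  # columns: variant_id, effect_allele, other_allele, weight
    label: str = ""

    def __post_init__(self) -> None:
        required = {"variant_id", "effect_allele", "other_allele", "weight"}
        missing = required - set(self.variants.columns)
        if missing:
            raise ValueError(f"weight table missing columns: {sorted(missing)}")
        if self.variants["variant_id"].duplicated().any():
            raise ValueError("duplicate variant ids in weight set")
        if not np.isfinite(self.variants["weight"].to_numpy(float)).all():
            raise ValueError("non-finite weights")

    def __len__(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class PRSParams:
    """Standardization and risk-conversion parameters for one ancestry."""

    mu_ctrl: float
    sd_ctrl: float
    beta: float = DEFAULT_BETA
    band: tuple[float, float] = (0.40, 0.60)

    def __post_init__(self) -> None:
        if self.sd_ctrl <= 0:
            raise ValueError("control SD must be positive")
        lo, hi = self.band
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("band must satisfy 0 <= lo < hi <= 1")


@dataclass
class ScoreReport:
    """Raw sum scores plus matching/flipping bookkeeping."""

    raw: pd.Series  # indexed by subject id
    n_matched: int
    n_flipped: int
    n_skipped: int
    skipped_variants: list = field(default_factory=list)
    n_ambiguous: int = 0
    ambiguous_variants: list = field(default_factory=list)


def read_weights(path, label: str = "") -> WeightSet:
    """Read a scoring file with '#' comment lines.

    Accepts PGS-Catalog column names (``rsID``, ``effect_allele``,
    ``other_allele``, ``effect_weight``) or the package's canonical names.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df = df.rename(columns={"rsID": "variant_id", "effect_weight": "weight"})
    df["weight"] = df["weight"].astype(float)
    return WeightSet(df[["variant_id", "effect_allele", "other_allele", "weight"]],
                     label=label or str(path))


def read_dosage_matrix(path) -> pd.DataFrame:
    """Read a variant x subject dosage TSV.

    Columns: ``variant_id``, ``effect_allele``, ``other_allele``, then one
    column per subject; empty cells are missing dosages.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index("variant_id")


def read_dosages_vcf(path) -> pd.DataFrame:
    """Read per-genotype dosages (FORMAT/DS) from a VCF into matrix form.

    ALT is taken as the effect allele of the dosage. Requires cyvcf2.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            gts = np.asarray([sum(g[:2]) if -1 not in g[:2] else np.nan
                              for g in var.genotypes], dtype=float)
        else:
            gts = np.asarray(ds, dtype=float).reshape(-1)
            gts = np.where(gts < 0, np.nan, gts)
        rows.append([var.ID or f"{var.CHROM}:{var.POS}", var.ALT[0], var.REF,
                     *gts.tolist()])
    df = pd.DataFrame(rows, columns=["variant_id", "effect_allele", "other_allele",
                                     *samples])
    return df.set_index("variant_id")


def score_prs(dosages: pd.DataFrame, weights: WeightSet,
              drop_ambiguous: bool = False) -> ScoreReport:
    """Weighted sum score per subject.

    Dosage rows are matched to weight variants by id; when the dosage file's
    effect/other alleles are swapped relative to the weight file, the dose is
    flipped to ``2 - dose``. Variants in the weight set absent from the
    dosages (or with irreconcilable alleles) are skipped and counted.
    Strand-ambiguous variants (A/T, C/G) are kept by default and reported, or
    dropped with ``drop_ambiguous``.
    """
    subject_cols = [c for c in dosages.columns
                    if c not in ("effect_allele", "other_allele")]
    mat = np.zeros((0, len(subject_cols)))
    used_weights: list[float] = []
    n_flipped = 0
    skipped: list = []
    ambiguous: list = []
    rows: list[np.ndarray] = []

    for _, wrow in weights.variants.iterrows():
        vid = wrow["variant_id"]
        if vid not in dosages.index:
            skipped.append((vid, "absent"))
            continue
        drow = dosages.loc[vid]
        ea, oa = str(drow["effect_allele"]), str(drow["other_allele"])
        dose = pd.to_numeric(drow[subject_cols], errors="coerce").to_numpy(float)
        if (ea.upper(), oa.upper()) in AMBIGUOUS_PAIRS:
            ambiguous.append(vid)
            if drop_ambiguous:
                continue
        if ea == wrow["effect_allele"] and oa == wrow["other_allele"]:
            pass
        elif ea == wrow["other_allele"] and oa == wrow["effect_allele"]:
            dose = 2.0 - dose
            n_flipped += 1
        else:
            skipped.append((vid, f"allele mismatch {ea}/{oa}"))
            continue
        if np.isnan(dose).any():
            observed = dose[~np.isnan(dose)]
            if observed.size == 0:
                skipped.append((vid, "all dosages missing"))
                continue
            dose = np.where(np.isnan(dose), observed.mean(), dose)
        rows.append(dose)
        used_weights.append(float(wrow["weight"]))

    if rows:
        mat = np.vstack(rows)
        raw = np.asarray(used_weights) @ mat
    else:
        raw = np.zeros(len(subject_cols))
    return ScoreReport(
        raw=pd.Series(raw, index=subject_cols, name="prs_raw"),
        n_matched=len(rows),
        n_flipped=n_flipped,
        n_skipped=len(skipped),
        skipped_variants=skipped,
        n_ambiguous=len(ambiguous),
        ambiguous_variants=ambiguous,
    )


def control_moments(raw: np.ndarray, is_control: np.ndarray) -> tuple[float, float]:
    """Control mean and SD of the raw score (ddof=1)."""
    ctrl = np.asarray(raw, float)[np.asarray(is_control, bool)]
    ctrl = ctrl[np.isfinite(ctrl)]
    if ctrl.size < 2:
        raise ValueError("need at least two control scores to standardize")
    return float(ctrl.mean()), float(ctrl.std(ddof=1))


def standardize(raw, params: PRSParams):
    """Standardized score and normal-CDF percentile."""
    z = (np.asarray(raw, float) - params.mu_ctrl) / params.sd_ctrl
    pct = stats.norm.cdf(z)
    return z, pct


def _band_constant(params: PRSParams) -> float:
    lo, hi = params.band
    beta = params.beta
    qlo, qhi = stats.norm.ppf(lo), stats.norm.ppf(hi)
    return float(np.exp(0.5 * beta * beta)
                 * (stats.norm.cdf(qhi - beta) - stats.norm.cdf(qlo - beta))
                 / (hi - lo))


def rr_vs_middle_quintile(z, params: PRSParams):
    """Theoretical odds ratio of score z relative to the reference band."""
    return np.exp(params.beta * np.asarray(z, float)) / _band_constant(params)


def mean_relative_risk(params: PRSParams) -> float:
    """m = E[rr(Z)] over standard-normal Z (= exp(beta^2/2) / c)."""
    return float(np.exp(0.5 * params.beta ** 2) / _band_constant(params))


def prs_five_year_risk(
    z,
    ages,
    params: PRSParams,
    rates: RateTable,
    horizon: float = 5.0,
    baseline: str = "population-mean",
):
    """Five-year absolute risk for standardized scores ``z`` at ``ages``.

    ``baseline='population-mean'`` rescales the incidence hazard by
    1/E[rr(Z)] so the cohort-average incidence reproduces the population
    rates; ``'mid-quintile'`` instead treats the reference band as carrying
    the raw population incidence.
    """
    z = np.atleast_1d(np.asarray(z, float))
    ages = np.broadcast_to(np.asarray(ages, float), z.shape)
    rr = rr_vs_middle_quintile(z, params)
    if baseline == "population-mean":
        eff = rr / mean_relative_risk(params)
    elif baseline == "mid-quintile":
        eff = rr
    else:
        raise ValueError("baseline must be 'population-mean' or 'mid-quintile'")
    return project_absolute_risk_vector(rates, ages, eff, horizon=horizon,
                                        use_ar_adjustment=False)


def score_prs_cohort(
    cohort: Cohort,
    rates_by_population: dict[str, RateTable],
    beta: float = DEFAULT_BETA,
    band: tuple[float, float] = (0.40, 0.60),
    ancestry_map: dict[str, str] | None = None,
    baseline: str = "population-mean",
    params_by_ancestry: dict[str, PRSParams] | None = None,
    horizon: float = 5.0,
) -> tuple[Cohort, dict[str, PRSParams]]:
    """Append ``prs_z``, ``prs_pct``, ``prs_rr``, ``prs_ar5`` to a cohort.

    Standardization parameters are estimated per ancestry from that
    ancestry's controls (or passed in precomputed, e.g. when applying
    control moments from a different run).
    """
    from .gail import ANCESTRY_TO_POPULATION

    amap = dict(ANCESTRY_TO_POPULATION if ancestry_map is None else ancestry_map)
    out = cohort.copy()
    df = out.data
    if df["prs_raw"].isna().all():
        raise ValueError("cohort has no raw PRS column; score dosages first")
    z_all = np.full(len(df), np.nan)
    pct_all = np.full(len(df), np.nan)
    rr_all = np.full(len(df), np.nan)
    ar5_all = np.full(len(df), np.nan)
    fitted: dict[str, PRSParams] = {}
    for ancestry, pop in amap.items():
        mask = (df["ancestry"] == ancestry).to_numpy()
        if not mask.any():
            continue
        raw = df.loc[mask, "prs_raw"].to_numpy(float)
        if params_by_ancestry is not None and ancestry in params_by_ancestry:
            params = params_by_ancestry[ancestry]
        else:
            is_ctrl = (df.loc[mask, "status"] == "control").to_numpy()
            mu, sd = control_moments(raw, is_ctrl)
            params = PRSParams(mu_ctrl=mu, sd_ctrl=sd, beta=beta, band=band)
        fitted[ancestry] = params
        z, pct = standardize(raw, params)
        z_all[mask] = z
        pct_all[mask] = pct
        rr_all[mask] = rr_vs_middle_quintile(z, params)
        ar5_all[mask] = prs_five_year_risk(
            z, df.loc[mask, "age"].to_numpy(float), params,
            rates_by_population[pop], horizon=horizon, baseline=baseline)
    df["prs_z"] = z_all
    df["prs_pct"] = pct_all
    df["prs_rr"] = rr_all
    df["prs_ar5"] = ar5_all
    out.log(f"score_prs: beta={beta:.4f}, band={band}, baseline={baseline}, "
            f"ancestries={sorted(fitted)}")
    return out, fitted
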