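"""Synthetic case-control cohort generator.

Emulates the statistical structure of the consortium cohort the analysis
was designed for: six (ancestry x status) cells with the published sample
sizes, per-cell age distributions matched to the published medians/IQRs,
Gail covariate categories (including explicit ``unknown`` levels) drawn at
the published per-cell frequencies, and a polygenic score that is standard
normal in controls and mean-shifted by ``prs_beta`` standard deviations in
cases (the liability-logit approximation to a logistic effect of size
``prs_beta`` per SD).

What this generator does NOT emulate: linkage disequilibrium, study-level
heterogeneity within ancestry, correlation between clinical covariates, or
informative control sampling. Passing tests on these cohorts therefore
demonstrates correctness of the machinery, not clinical validity on real
consortium data.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import LEVELS, Cohort
from .prs import DEFAULT_BETA, WeightSet

__all__ = [
    "CellConfig",
    "GeneratorConfig",
    "DosagePanel",
    "load_characteristics",
    "default_config",
    "generate_cohort",
    "generate_dosages",
    "generate_miscalibrated",
]

_IQR_TO_SD = 2.0 * stats.norm.ppf(0.75)  # 1.349: IQR of a normal in SD units

COVARIATES = ("age_menarche", "age_first_birth", "n_relatives", "n_biopsies",
              "atypical_hyperplasia")


def load_characteristics() -> dict:
    """Packaged per-cell counts, ages, and score summaries of the emulated cohort."""
    ref = importlib.resources.files("riskoverlap.data") / "cohort_characteristics.json"
    return json.loads(ref.read_text(encoding="utf-8"))


@dataclass(frozen=True)
class CellConfig:
    """Generator settings for one (ancestry x status) cell."""

    n: int
    age_median: float
    age_iqr: tuple[float, float]
    covariate_probs: dict            # covariate -> {level: probability}
    prs_shift_sd: float = 0.0        # standardized-scale mean shift vs controls

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("cell size must be non-negative")
        for cov, probs in self.covariate_probs.items():
            vals = np.asarray(list(probs.values()), float)
            if np.any(vals < 0) or not np.isclose(vals.sum(), 1.0, atol=1e-6):
                raise ValueError(f"probabilities for {cov} must be a distribution")
            undeclared = set(probs) - set(LEVELS[cov])
            if undeclared:
                raise ValueError(f"undeclared {cov} levels {sorted(undeclared)}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full cohort generator configuration.

    ``cells`` maps (ancestry, status) to a :class:`CellConfig`.
    ``prs_mu``/``prs_sd`` give the raw-score location/scale of each
    ancestry's controls; ``fh_or`` tilts family history further toward
    cases by reweighting category odds (1.0 leaves the per-cell published
    frequencies, which already encode the case enrichment, untouched).
    ``missing_extra`` adds MCAR unknowns on top of the published unknown
    frequencies; ``mnar_case_multiplier`` > 1 makes that extra missingness
    case-enriched (an MNAR direction for the sensitivity analysis).
    """

    cells: dict
    prs_mu: dict
    prs_sd: dict
    prs_beta: float = DEFAULT_BETA
    fh_or: float = 1.0
    missing_extra: dict = field(default_factory=dict)
    mnar_case_multiplier: float = 1.0
    age_range: tuple[int, int] = (30, 80)
    seed: int = 0

    def scaled(self, factor: float) -> "GeneratorConfig":
        """Same structure at ``factor`` times the cell sizes (rounded)."""
        cells = {key: replace(cfg, n=int(round(cfg.n * factor)))
                 for key, cfg in self.cells.items()}
        return replace(self, cells=cells)


def default_config(seed: int = 0) -> GeneratorConfig:
    """Configuration transcribed from the packaged cohort characteristics.

    Cell sizes, age medians/IQRs, covariate category frequencies and raw-
    score summaries all come from the published cohort table; the case PRS
    shift defaults to ``prs_beta`` standard deviations in every case cell.
    """
    doc = load_characteristics()
    cells: dict = {}
    prs_mu: dict = {}
    prs_sd: dict = {}
    for ancestry, by_status in doc["cells"].items():
        ctrl = by_status["control"]
        med, lo, hi = ctrl["prs_median_iqr"]
        prs_mu[ancestry] = float(med)
        prs_sd[ancestry] = float(hi - lo) / _IQR_TO_SD
        for status, cell in by_status.items():
            probs = {}
            for cov in COVARIATES:
                counts = cell[cov]
                total = sum(counts.values())
                if total == 0:
                    probs[cov] = {"unknown": 1.0}
                else:
                    probs[cov] = {lvl: cnt / total for lvl, cnt in counts.items()}
            a_med, a_lo, a_hi = cell["age_median_iqr"]
            cells[(ancestry, status)] = CellConfig(
                n=int(cell["n"]),
                age_median=float(a_med),
                age_iqr=(float(a_lo), float(a_hi)),
                covariate_probs=probs,
                prs_shift_sd=0.0 if status == "control" else DEFAULT_BETA,
            )
    return GeneratorConfig(cells=cells, prs_mu=prs_mu, prs_sd=prs_sd, seed=seed)


def _draw_ages(rng, cfg: CellConfig, lo: int, hi: int) -> np.ndarray:
    sd = (cfg.age_iqr[1] - cfg.age_iqr[0]) / _IQR_TO_SD
    ages = rng.normal(cfg.age_median, sd, size=cfg.n)
    # redraw outside the valid window rather than clip, to avoid edge atoms
    bad = (ages < lo) | (ages > hi)
    while bad.any():
        ages[bad] = rng.normal(cfg.age_median, sd, size=int(bad.sum()))
        bad = (ages < lo) | (ages > hi)
    return np.floor(ages).astype(int).clip(lo, hi)


def _tilt_fh(probs: dict, fh_or: float) -> dict:
    if fh_or == 1.0:
        return probs
    weights = {lvl: (fh_or if lvl in ("1", "ge2") else 1.0) * p
               for lvl, p in probs.items()}
    total = sum(weights.values())
    return {lvl: w / total for lvl, w in weights.items()}


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a cohort; byte-identical for identical config and seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    frames = []
    counter = 0
    for (ancestry, status) in sorted(config.cells):
        cfg = config.cells[(ancestry, status)]
        if cfg.n == 0:
            continue
        n = cfg.n
        ages = _draw_ages(rng, cfg, lo, hi)
        cols = {
            "subject_id": [f"S{counter + i:07d}" for i in range(n)],
            "study_id": f"{ancestry[:3].upper()}1",
            "ancestry": ancestry,
            "age": ages.astype(float),
            "status": status,
            "control_source": "population" if status == "control" else "not_applicable",
        }
        counter += n
        for cov in COVARIATES:
            probs = cfg.covariate_probs[cov]
            if cov == "n_relatives" and status != "control":
                probs = _tilt_fh(probs, config.fh_or)
            levels = list(probs)
            draw = rng.choice(len(levels), size=n, p=list(probs.values()))
            values = np.asarray(levels, object)[draw]
            extra = config.missing_extra.get(cov, 0.0)
            if extra > 0:
                rate = extra * (config.mnar_case_multiplier
                                if status != "control" else 1.0)
                values = np.where(rng.random(n) < min(rate, 1.0), "unknown", values)
            cols[cov] = pd.Categorical(values, categories=LEVELS[cov])
        z = rng.normal(cfg.prs_shift_sd, 1.0, size=n)
        cols["prs_raw"] = config.prs_mu[ancestry] + config.prs_sd[ancestry] * z
        frames.append(pd.DataFrame(cols))
    data = (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["subject_id"]))
    cohort = Cohort(data)
    cohort.log(f"generate_cohort: seed={config.seed}, n={len(cohort)}, "
               f"prs_beta={config.prs_beta:.4f}, fh_or={config.fh_or}")
    return cohort


@dataclass
class DosagePanel:
    """Variant x subject dosages with weights reproducing assigned scores."""

    dosages: pd.DataFrame   # index variant_id; effect/other allele + subject cols
    weights: WeightSet
    eaf: np.ndarray
    adjustment_variant: str | None = None


_BASES = ("A", "C", "G", "T")


def generate_dosages(
    cohort: Cohort,
    m: int = 50,
    seed: int = 0,
    missing_rate: float = 0.0,
    match_raw_scores: bool = True,
    weight_scale: float = 0.05,
) -> DosagePanel:
    """Hardy-Weinberg genotype panel whose weighted sum scores the cohort.

    ``m`` biallelic variants are drawn at uniform(0.05, 0.95) effect-allele
    frequencies with Hardy-Weinberg genotypes and N(0, weight_scale^2)
    weights. With ``match_raw_scores`` a final continuous-dosage adjustment
    variant (weight 1) absorbs the residual so that the weighted sum equals
    each subject's assigned ``prs_raw`` exactly; it is named
    ``rsADJUST`` and documented as synthetic plumbing, not a genotype.
    ``missing_rate`` masks Hardy-Weinberg entries at random (the adjustment
    variant is never masked).
    """
    if m < 1:
        raise ValueError("need at least one variant")
    rng = np.random.default_rng(seed)
    subjects = cohort.data["subject_id"].tolist()
    n = len(subjects)
    eaf = rng.uniform(0.05, 0.95, size=m)
    geno = rng.binomial(2, eaf[:, None], size=(m, n)).astype(float)
    weights = rng.normal(0.0, weight_scale, size=m)
    rows = []
    wrows = []
    for i in range(m):
        ea, oa = rng.choice(_BASES, size=2, replace=False)
        rows.append([f"rs{i + 1:05d}", ea, oa, *geno[i]])
        wrows.append([f"rs{i + 1:05d}", ea, oa, weights[i]])
    adj_name = None
    if match_raw_scores:
        target = cohort.data["prs_raw"].to_numpy(float)
        if np.isnan(target).any():
            raise ValueError("cohort prs_raw holds missing values; cannot match")
        residual = target - weights @ geno
        adj_name = "rsADJUST"
        rows.append([adj_name, "A", "G", *residual])
        wrows.append([adj_name, "A", "G", 1.0])
    dosages = pd.DataFrame(rows, columns=["variant_id", "effect_allele",
                                          "other_allele", *subjects])
    dosages = dosages.set_index("variant_id")
    if missing_rate > 0:
        mask = rng.random((m, n)) < missing_rate
        block = dosages.iloc[:m, 2:].to_numpy(float)
        block[mask] = np.nan
        dosages.iloc[:m, 2:] = block
    wdf = pd.DataFrame(wrows, columns=["variant_id", "effect_allele",
                                       "other_allele", "weight"])
    return DosagePanel(dosages=dosages,
                       weights=WeightSet(wdf, label="synthetic panel"),
                       eaf=eaf, adjustment_variant=adj_name)


def generate_miscalibrated(
    n: int,
    distortion: str = "none",
    scale: float = 0.5,
    shift: float = 0.0,
    base_risk: float = 0.10,
    spread: float = 1.0,
    seed: int = 0,
):
    """True risks, distorted predicted risks, and Bernoulli outcomes.

    True risks follow a logit-normal distribution centred on ``base_risk``
    with SD ``spread`` on the logit scale. ``distortion='scale'`` multiplies
    predicted risks by ``scale``; ``'shift'`` adds ``shift`` on the logit
    scale; ``'none'`` leaves them equal to the truth. Predictions are
    clipped to (0, 1).
    """
    rng = np.random.default_rng(seed)
    logit = rng.normal(np.log(base_risk / (1 - base_risk)), spread, size=n)
    true = 1.0 / (1.0 + np.exp(-logit))
    if distortion == "none":
        predicted = true.copy()
    elif distortion == "scale":
        predicted = np.clip(true * scale, 1e-12, 1 - 1e-12)
    elif distortion == "shift":
        predicted = 1.0 / (1.0 + np.exp(-(logit + shift)))
    else:
        raise ValueError("distortion must be 'none', 'scale' or 'shift'")
    outcomes = rng.random(n) < true
    return true, predicted, outcomes
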