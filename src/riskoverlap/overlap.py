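"""High-risk flags, Venn overlap, and case-enrichment across thresholds.

A subject is flagged high-risk by a risk model when her five-year absolute
risk reaches the threshold (inclusive: ar5 >= t, so a quoted threshold such
as 1.4% flags subjects at exactly that risk). The family-history flag is
binary (at least one affected first-degree relative; unknown counts as no
history) and does not vary with the threshold. For each threshold the 8
membership patterns over {PRS, Gail, FH} are counted (7 non-empty Venn
segments plus "none"), and the enrichment of a predictor is the flagged
fraction among cases divided by the flagged fraction among controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, family_history_flag
from .evaluation import StratumSpec, select_stratum

__all__ = [
    "ThresholdGrid",
    "OverlapResult",
    "flag_high_risk",
    "venn_segments",
    "enrichment_curve",
    "unique_proportion_curves",
]

#: Segment keys: one character per predictor, P=PRS, G=Gail, F=family history.
SEGMENTS = ("none", "P", "G", "F", "PG", "PF", "GF", "PGF")


@dataclass(frozen=True)
class ThresholdGrid:
    """Absolute-risk thresholds swept by the overlap analysis (fractions)."""

    lo: float = 0.005
    hi: float = 0.025
    step: float = 0.001

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi < 1):
            raise ValueError("need 0 < lo < hi < 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    def values(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.step))
        return self.lo + self.step * np.arange(n + 1)


@dataclass
class OverlapResult:
    threshold: float
    counts: dict          # segment -> count (sums to n)
    n: int
    unique_proportions: dict  # predictor -> fraction flagged by it alone
    enrichment: dict      # predictor -> case/control flagged-fraction ratio


def flag_high_risk(risks, threshold: float) -> np.ndarray:
    """Boundary-inclusive high-risk flag: ar5 >= threshold."""
    risks = np.asarray(risks, float)
    if np.any((risks < 0) | (risks > 1)):
        raise ValueError("risks must lie in [0, 1]")
    return risks >= threshold


def venn_segments(flags_p, flags_g, flags_f) -> dict:
    """Counts of the 8 membership patterns over {PRS, Gail, FH}."""
    p = np.asarray(flags_p, bool)
    g = np.asarray(flags_g, bool)
    f = np.asarray(flags_f, bool)
    if not (p.shape == g.shape == f.shape):
        raise ValueError("flag vectors must have equal length")
    pattern = p.astype(int) * 4 + g.astype(int) * 2 + f.astype(int)
    counts = np.bincount(pattern, minlength=8)
    order = {"none": 0, "F": 1, "G": 2, "GF": 3, "P": 4, "PF": 5, "PG": 6, "PGF": 7}
    return {seg: int(counts[order[seg]]) for seg in SEGMENTS}


def _flagged_fraction(flags: np.ndarray, mask: np.ndarray) -> float:
    return float(flags[mask].mean()) if mask.any() else np.nan


def enrichment_curve(
    cohort: Cohort,
    risk_column: str,
    stratum: StratumSpec,
    grid: ThresholdGrid = ThresholdGrid(),
    target: float = 2.0,
    definition: str = "flagged-fraction",
) -> tuple[pd.DataFrame, float | None]:
    """Per-threshold enrichment ratios plus the minimal threshold hitting
    ``target``.

    ``definition='flagged-fraction'`` is (cases flagged / cases) over
    (controls flagged / controls); ``'composition'`` is the case:control
    composition ratio within the flagged set, normalised by the stratum's
    case:control ratio. Zero flagged controls give +inf with counts kept in
    the table for context.
    """
    sub, y = select_stratum(cohort, stratum)
    risks = sub[risk_column].to_numpy(float)
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError("stratum needs both cases and controls")
    rows = []
    minimal = None
    for t in grid.values():
        flags = flag_high_risk(risks, t)
        ncase = int(flags[y].sum())
        nctrl = int(flags[~y].sum())
        frac_case = ncase / y.sum()
        frac_ctrl = nctrl / (~y).sum()
        if definition == "flagged-fraction":
            ratio = frac_case / frac_ctrl if frac_ctrl > 0 else (
                np.inf if frac_case > 0 else np.nan)
        elif definition == "composition":
            base = y.sum() / (~y).sum()
            ratio = (ncase / nctrl) / base if nctrl > 0 else (
                np.inf if ncase > 0 else np.nan)
        else:
            raise ValueError("definition must be 'flagged-fraction' or 'composition'")
        if minimal is None and np.isfinite(ratio) and ratio >= target:
            minimal = float(t)
        rows.append({"threshold": float(t), "n_cases_flagged": ncase,
                     "n_controls_flagged": nctrl, "frac_cases": frac_case,
                     "frac_controls": frac_ctrl, "enrichment": ratio})
    return pd.DataFrame(rows), minimal


def unique_proportion_curves(
    cohort: Cohort,
    risk_column_prs: str,
    risk_column_gail: str,
    stratum: StratumSpec,
    grid: ThresholdGrid = ThresholdGrid(),
) -> pd.DataFrame:
    """Long-format table of uniquely-flagged fractions per threshold.

    For each threshold and subgroup (cases, controls, all) the fraction
    flagged by exactly one of PRS, Gail, FH, derived from the Venn segment
    counts.
    """
    sub, y = select_stratum(cohort, stratum)
    risks_p = sub[risk_column_prs].to_numpy(float)
    risks_g = sub[risk_column_gail].to_numpy(float)
    fh = family_history_flag(Cohort(sub.reset_index(drop=True)))
    groups = {"all": np.ones(len(sub), bool), "cases": y, "controls": ~y}
    rows = []
    for t in grid.values():
        fp = flag_high_risk(risks_p, t)
        fg = flag_high_risk(risks_g, t)
        for gname, gmask in groups.items():
            n = int(gmask.sum())
            if n == 0:
                continue
            segs = venn_segments(fp[gmask], fg[gmask], fh[gmask])
            for method, seg in (("PRS", "P"), ("Gail", "G"), ("FH", "F")):
                rows.append({"threshold": float(t), "subgroup": gname,
                             "method": method, "fraction": segs[seg] / n})
    return pd.DataFrame(rows)


def overlap_at_threshold(
    cohort: Cohort,
    risk_column_prs: str,
    risk_column_gail: str,
    stratum: StratumSpec,
    threshold: float,
) -> OverlapResult:
    """Full Venn bookkeeping for one stratum and one threshold."""
    sub, y = select_stratum(cohort, stratum)
    fp = flag_high_risk(sub[risk_column_prs].to_numpy(float), threshold)
    fg = flag_high_risk(sub[risk_column_gail].to_numpy(float), threshold)
    fh = family_history_flag(Cohort(sub.reset_index(drop=True)))
    segs = venn_segments(fp, fg, fh)
    n = len(sub)
    unique = {"PRS": segs["P"] / n, "Gail": segs["G"] / n, "FH": segs["F"] / n}
    enrich = {}
    for name, flags in (("PRS", fp), ("Gail", fg), ("FH", fh)):
        fc = _flagged_fraction(flags, y)
        fk = _flagged_fraction(flags, ~y)
        enrich[name] = fc / fk if fk and fk > 0 else (np.inf if fc else np.nan)
    return OverlapResult(threshold=float(threshold), counts=segs, n=n,
                         unique_proportions=unique, enrichment=enrich)
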