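"""Model-based ROC (mROC) calibration assessment for case-control samples.

The mROC curve is the ROC a set of predicted risks would achieve if they
were perfectly calibrated: sweeping a cut c over the distinct predicted
values pi,

    TPR(c) = sum_{pi_i >= c} pi_i / sum_i pi_i,
    FPR(c) = sum_{pi_i >= c} (1 - pi_i) / sum_i (1 - pi_i).

Divergence between the empirical ROC (observed outcomes) and the mROC
signals miscalibration beyond case-mix differences. Three tests are run:

* mean calibration - normal test of sum(y) against sum(pi) with variance
  sum(pi (1-pi));
* ROC equality - sup vertical distance between the empirical and model
  curves, null distribution by parametric bootstrap regenerating outcomes
  as independent Bernoulli(pi);
* unified - Tippett (min-p style) combination of the two component
  statistics through their bootstrap null ECDFs.

In a case-control sample the event fraction does not estimate population
prevalence, so these tests speak to calibration relative to the sample's
case mix; predicted risks must be re-based before population-level claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "MROCResult",
    "model_based_roc",
    "empirical_roc",
    "roc_sup_distance",
    "calibration_tests",
    "decile_calibration",
]

_FPR_GRID = np.linspace(0.0, 1.0, 201)


@dataclass
class MROCResult:
    empirical_roc: np.ndarray      # (k, 2) array of (FPR, TPR)
    model_roc: np.ndarray
    p_mean_calibration: float
    p_roc_equality: float
    p_unified: float
    sup_distance: float
    mean_z: float
    n_boot: int
    seed: int
    reference_roc: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)


def _check_pi(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, float)
    if not np.all(np.isfinite(pi)) or np.any((pi < 0) | (pi > 1)):
        raise ValueError("predicted risks must be finite and in [0, 1]")
    if pi.sum() == 0 or (1 - pi).sum() == 0:
        raise ValueError("degenerate predicted risks (all 0 or all 1)")
    return pi


def model_based_roc(pi) -> np.ndarray:
    """(FPR, TPR) points of the ROC implied by predicted risks ``pi``."""
    pi = _check_pi(pi)
    order = np.argsort(-pi, kind="stable")
    ps = pi[order]
    # one point per distinct predicted value (ties enter together)
    ends = np.flatnonzero(np.diff(ps) != 0)
    ends = np.append(ends, len(ps) - 1)
    tpr = np.cumsum(ps)[ends] / ps.sum()
    fpr = np.cumsum(1 - ps)[ends] / (1 - ps).sum()
    curve = np.column_stack([np.concatenate([[0.0], fpr]),
                             np.concatenate([[0.0], tpr])])
    if np.allclose(curve[-1], [1.0, 1.0]):
        curve[-1] = [1.0, 1.0]
    else:
        curve = np.vstack([curve, [1.0, 1.0]])
    return curve


def empirical_roc(scores, labels) -> np.ndarray:
    """Standard ROC over distinct score cuts; tied scores enter together."""
    scores = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    npos, nneg = int(y.sum()), int((~y).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("both outcome classes must be present")
    order = np.argsort(-scores, kind="stable")
    ss, ys = scores[order], y[order]
    ends = np.flatnonzero(np.diff(ss) != 0)
    ends = np.append(ends, len(ss) - 1)
    tpr = np.cumsum(ys)[ends] / npos
    fpr = np.cumsum(~ys)[ends] / nneg
    curve = np.column_stack([np.concatenate([[0.0], fpr]),
                             np.concatenate([[0.0], tpr])])
    if curve[-1, 0] != 1.0 or curve[-1, 1] != 1.0:
        curve = np.vstack([curve, [1.0, 1.0]])
    return curve


def _interp_tpr(curve: np.ndarray, grid: np.ndarray) -> np.ndarray:
    fpr, tpr = curve[:, 0], curve[:, 1]
    # collapse vertical segments: keep the max TPR at each distinct FPR
    uniq, idx = np.unique(fpr[::-1], return_index=True)
    return np.interp(grid, uniq, tpr[::-1][idx])


def roc_sup_distance(curve_a: np.ndarray, curve_b: np.ndarray,
                     grid: np.ndarray = _FPR_GRID) -> float:
    """Sup vertical distance between two ROC curves on a common FPR grid."""
    return float(np.max(np.abs(_interp_tpr(curve_a, grid) - _interp_tpr(curve_b, grid))))


def _mean_calibration_z(pi: np.ndarray, y: np.ndarray) -> float:
    var = np.sum(pi * (1 - pi))
    if var == 0:
        return 0.0
    return float((y.sum() - pi.sum()) / np.sqrt(var))


def calibration_tests(
    predicted,
    labels,
    n_boot: int = 1000,
    seed: int = 0,
    reference: tuple | None = None,
) -> MROCResult:
    """Mean-calibration, ROC-equality, and unified calibration tests.

    ``reference`` optionally carries ``(scores, labels)`` of the reference
    stratum; its empirical ROC is attached to the result for overlay
    plotting. The bootstrap seed is recorded in the output.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    pi = _check_pi(predicted)
    y = np.asarray(labels, bool)
    if len(pi) != len(y):
        raise ValueError("predicted and labels must align")

    emp = empirical_roc(pi, y)
    mod = model_based_roc(pi)
    d_obs = roc_sup_distance(emp, mod)
    z_obs = _mean_calibration_z(pi, y)
    p_mean = float(2 * stats.norm.sf(abs(z_obs)))

    # Parametric bootstrap under Bernoulli(pi); the subject order by pi and
    # the tie structure are fixed, so the empirical curve of every draw is a
    # cumulative sum along the same sorted index.
    rng = np.random.default_rng(seed)
    order = np.argsort(-pi, kind="stable")
    ps = pi[order]
    ends = np.flatnonzero(np.diff(ps) != 0)
    ends = np.append(ends, len(ps) - 1)
    mod_tpr_grid = _interp_tpr(mod, _FPR_GRID)

    d_boot = np.empty(n_boot)
    z_boot = np.empty(n_boot)
    chunk = max(1, int(5_000_000 // max(len(pi), 1)))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        yb = rng.random((b, len(ps))) < ps  # Bernoulli(pi) in sorted order
        npos = yb.sum(axis=1)
        ok = (npos > 0) & (npos < len(ps))
        cy = np.cumsum(yb, axis=1)[:, ends]
        for i in range(b):
            if not ok[i]:
                d_boot[done + i] = 0.0
                z_boot[done + i] = 0.0
                continue
            tpr = cy[i] / npos[i]
            fpr = (ends + 1 - cy[i]) / (len(ps) - npos[i])
            curve = np.column_stack([np.concatenate([[0.0], fpr]),
                                     np.concatenate([[0.0], tpr])])
            emp_grid = _interp_tpr(curve, _FPR_GRID)
            d_boot[done + i] = np.max(np.abs(emp_grid - mod_tpr_grid))
            z_boot[done + i] = (yb[i].sum() - ps.sum()) / np.sqrt(
                np.sum(ps * (1 - ps)))
        done += b

    p_roc = float((1 + np.sum(d_boot >= d_obs)) / (n_boot + 1))
    # Tippett-style unified statistic: the larger of the two component
    # statistics' null ECDF positions.
    az = np.abs(z_boot)
    u_boot = np.maximum(
        stats.rankdata(az, method="max") / n_boot,
        stats.rankdata(d_boot, method="max") / n_boot,
    )
    u_obs = max(np.mean(az <= abs(z_obs)), np.mean(d_boot <= d_obs))
    p_unified = float((1 + np.sum(u_boot >= u_obs)) / (n_boot + 1))

    ref_curve = None
    if reference is not None:
        ref_curve = empirical_roc(*reference)
    return MROCResult(
        empirical_roc=emp, model_roc=mod,
        p_mean_calibration=p_mean, p_roc_equality=p_roc, p_unified=p_unified,
        sup_distance=d_obs, mean_z=z_obs, n_boot=n_boot, seed=seed,
        reference_roc=ref_curve,
        metadata={
            "roc_equality_statistic": "sup vertical distance on 201-point FPR grid",
            "null": "parametric bootstrap, outcomes ~ Bernoulli(predicted)",
            "unified": "Tippett combination via bootstrap null ECDFs",
        },
    )


def decile_calibration(predicted, labels, n_bins: int = 10,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Observed event fraction vs mean predicted risk by predicted-risk decile.

    Bins are equal-count by rank (sizes differ by at most one); with too few
    distinct predictions the effective number of bins shrinks and a
    ``degenerate`` flag is set on the affected rows. Binomial CIs are
    Wilson intervals.
    """
    pi = _check_pi(predicted)
    y = np.asarray(labels, bool)
    if len(pi) < 20:
        raise ValueError("need at least 20 subjects for decile calibration")
    # equal-count partition by rank; ties broken by position for exact sizes
    order = np.argsort(pi, kind="stable")
    bin_id = np.empty(len(pi), int)
    bin_id[order] = (np.arange(len(pi)) * n_bins) // len(pi)
    degenerate = len(np.unique(pi)) < n_bins
    rows = []
    for b in range(n_bins):
        mask = bin_id == b
        k, n = int(y[mask].sum()), int(mask.sum())
        lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
        rows.append({"decile": b + 1, "n": n,
                     "mean_predicted": float(pi[mask].mean()),
                     "observed_fraction": k / n,
                     "ci_lo": float(lo), "ci_hi": float(hi),
                     "degenerate": degenerate})
    return pd.DataFrame(rows)
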