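"""Pivot growth rate estimation from slope-intercept relationships.

Within an environment the fitted intercepts and slopes of the linear
global-epistasis model are related by

    a_me = -pivot_e * b_me + eta_me,

a through-origin regression of intercepts on slopes.  Its coefficient
gives the pivot growth rate — the background growth rate at which a
typical mutation's effect switches sign — and its residuals eta_me are
the pivot noise.  The model has no intercept term, so the regression is
through the origin; a diagnostic fit with an intercept is reported so a
material violation can be flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gefit import benjamini_hochberg

__all__ = [
    "PivotEstimate",
    "estimate_pivot",
    "estimate_pivots",
    "pivot_noise_summary",
    "compare_pivots",
]


@dataclass
class PivotEstimate:
    """Pivot growth rate of one environment with pivot-noise residuals."""

    environment: str
    pivot: float
    se: float
    residuals: pd.Series          # eta_me indexed by mutation
    n: int
    diagnostic_intercept: float   # from an ordinary fit with intercept
    diagnostic_intercept_p: float


def estimate_pivot(slopes, intercepts, mutations=None,
                   environment: str = "") -> PivotEstimate:
    """Through-origin least squares of intercepts on slopes.

    pivot = -sum(a*b) / sum(b^2); residuals eta = a + pivot * b; the SE
    follows through-origin regression theory with residual variance
    sum(eta^2)/(n-1).  Requires >= 3 mutations and at least one nonzero
    slope.
    """
    b = np.asarray(slopes, dtype=float)
    a = np.asarray(intercepts, dtype=float)
    if len(b) != len(a):
        raise ValueError("slopes and intercepts must have equal length")
    n = len(b)
    if n < 3:
        raise ValueError(f"pivot estimation needs >= 3 mutations, got {n}")
    ssb = float(b @ b)
    if ssb == 0.0:
        raise ValueError("all slopes are zero; pivot growth rate unidentifiable")
    pivot = -float(a @ b) / ssb
    eta = a + pivot * b
    dof = n - 1
    sigma2 = float(eta @ eta) / dof
    se = float(np.sqrt(sigma2 / ssb))

    # diagnostic: same regression with a free intercept
    if np.ptp(b) > 0 and np.ptp(a) > 0:
        diag = stats.linregress(b, a)
        c0 = float(diag.intercept)
        if diag.intercept_stderr > 0:
            p0 = float(2 * stats.t.sf(abs(c0 / diag.intercept_stderr), n - 2))
        else:
            p0 = 0.0 if c0 != 0 else 1.0
    else:
        c0, p0 = np.nan, np.nan

    if mutations is None:
        mutations = pd.RangeIndex(n)
    residuals = pd.Series(eta, index=pd.Index(mutations, name="mutation"),
                          name="eta")
    return PivotEstimate(environment=environment, pivot=pivot, se=se,
                         residuals=residuals, n=n,
                         diagnostic_intercept=c0, diagnostic_intercept_p=p0)


def estimate_pivots(fits: pd.DataFrame,
                    only_significant: bool = False) -> list[PivotEstimate]:
    """Pivot estimate per environment from an epistasis-fit table.

    With ``only_significant`` the regression is restricted to fits whose
    slope passed the BH-corrected t-test (robustness check); by default
    every successful fit enters regardless of slope significance.
    """
    sub = fits
    if only_significant:
        if "slope_significant" not in fits.columns:
            raise ValueError("fits table lacks a slope_significant column")
        sub = fits[fits["slope_significant"]]
    out = []
    for env, esub in sub.groupby("environment", sort=True):
        out.append(estimate_pivot(esub["slope"].to_numpy(),
                                  esub["intercept"].to_numpy(),
                                  mutations=esub["mutation"].to_numpy(),
                                  environment=env))
    if not out:
        raise ValueError("no environment has fits to estimate a pivot from")
    return out


def pivot_noise_summary(estimates: list[PivotEstimate]) -> tuple[pd.DataFrame, dict]:
    """Mean, SD and a Shapiro-Wilk normality p for the pivot-noise
    residuals, per environment and pooled."""
    rows, pooled = [], []
    for est in estimates:
        eta = est.residuals.to_numpy()
        pooled.append(eta)
        if len(eta) >= 3 and np.ptp(eta) > 0:
            sh_p = float(stats.shapiro(eta).pvalue)
        else:
            sh_p = np.nan
        rows.append({"environment": est.environment, "n": len(eta),
                     "mean": float(eta.mean()), "sd": float(eta.std(ddof=1)),
                     "shapiro_p": sh_p})
    allres = np.concatenate(pooled)
    pooled_summary = {
        "n": int(len(allres)),
        "mean": float(allres.mean()),
        "sd": float(allres.std(ddof=1)) if len(allres) > 1 else 0.0,
        "shapiro_p": float(stats.shapiro(allres).pvalue)
        if len(allres) >= 3 and np.ptp(allres) > 0 else np.nan,
    }
    return pd.DataFrame(rows), pooled_summary


def compare_pivots(estimates: list[PivotEstimate],
                   alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise z-tests for pivot differences across environments,
    BH-corrected over all pairs.  Raises on a single environment (the
    comparison is not applicable there)."""
    if len(estimates) < 2:
        raise ValueError("pivot comparison not applicable with fewer than 2 environments")
    rows = []
    for i in range(len(estimates)):
        for j in range(i + 1, len(estimates)):
            e1, e2 = estimates[i], estimates[j]
            denom = np.hypot(e1.se, e2.se)
            diff = e1.pivot - e2.pivot
            if denom == 0.0:
                z = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
                p = 1.0 if diff == 0.0 else 0.0
            else:
                z = diff / denom
                p = float(2 * stats.norm.sf(abs(z)))
            rows.append({"env1": e1.environment, "env2": e2.environment,
                         "delta": float(diff), "z": float(z), "p": p})
    out = pd.DataFrame(rows)
    rej, adj = benjamini_hochberg(out["p"].to_numpy(), alpha)
    out["p_bh"] = adj
    out["significant"] = rej
    return out
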