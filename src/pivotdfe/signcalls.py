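"""Sign classification of mutation effects and its summaries.

Each measured effect is called beneficial or deleterious when the normal
confidence interval around it (99% two-sided by default) excludes zero,
and neutral otherwise.  Summaries report per-context sign proportions,
per-mutation sign switching across contexts, linear regressions of the
sign proportions on background growth rate, and the rank-reshuffling
statistic across environments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .tables import EffectTable, GrowthRateTable
from .synthgen import GroundTruth

__all__ = [
    "classify_sign",
    "classify_table",
    "sign_summary",
    "regress_sign_proportions",
    "rank_reshuffle",
    "estimate_sign_fdr",
]

BENEFICIAL = "beneficial"
DELETERIOUS = "deleterious"
NEUTRAL = "neutral"


def classify_sign(effect, se, level: float = 0.99):
    """Classify effect(s) by whether the two-sided normal CI excludes 0.

    Returns ``(call, ci_lo, ci_hi)``; scalar in, scalar out.
    """
    effect = np.asarray(effect, dtype=float)
    se_arr = np.asarray(se, dtype=float)
    if np.any(se_arr < 0):
        raise ValueError("standard errors must be >= 0")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1), got {level!r}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = effect - z * se_arr
    hi = effect + z * se_arr
    call = np.where(lo > 0, BENEFICIAL, np.where(hi < 0, DELETERIOUS, NEUTRAL))
    if call.ndim == 0:
        return str(call), float(lo), float(hi)
    return call, lo, hi


def classify_table(effects: EffectTable, level: float = 0.99) -> pd.DataFrame:
    """Sign calls for every observed entry of an effect table.

    Missing entries are dropped (they carry no value to classify).
    """
    obs = effects.observed()
    call, lo, hi = classify_sign(obs["value"].to_numpy(), obs["se"].to_numpy(), level)
    out = obs[["mutation", "strain", "environment", "value", "se"]].copy()
    out["ci_lo"] = lo
    out["ci_hi"] = hi
    out["call"] = call
    return out


def sign_summary(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize sign calls.

    Returns
    -------
    context : DataFrame
        Per (strain, environment): number of observed mutations and the
        proportions of beneficial and deleterious calls (denominator =
        non-missing measurements in that context).
    mutation : DataFrame
        Per mutation: counts of beneficial/deleterious contexts, whether
        it is beneficial in at least one context and deleterious in at
        least one, and whether it switches sign.
    """
    if len(calls) == 0:
        raise ValueError("sign_summary requires a non-empty call table")
    grp = calls.groupby(["strain", "environment"], sort=True)
    context = grp["call"].agg(
        n="size",
        frac_beneficial=lambda s: (s == BENEFICIAL).mean(),
        frac_deleterious=lambda s: (s == DELETERIOUS).mean(),
    ).reset_index()

    mgrp = calls.groupby("mutation", sort=True)["call"]
    mutation = mgrp.agg(
        n="size",
        n_beneficial=lambda s: int((s == BENEFICIAL).sum()),
        n_deleterious=lambda s: int((s == DELETERIOUS).sum()),
    ).reset_index()
    mutation["ever_beneficial"] = mutation["n_beneficial"] > 0
    mutation["ever_deleterious"] = mutation["n_deleterious"] > 0
    mutation["sign_switching"] = mutation["ever_beneficial"] & mutation["ever_deleterious"]
    return context, mutation


def regress_sign_proportions(context: pd.DataFrame,
                             growth: GrowthRateTable) -> pd.DataFrame:
    """OLS of per-strain sign proportions on background growth rate.

    One regression per environment and per call type (beneficial,
    deleterious), with the t-test p-value for a zero slope.  Requires at
    least 3 strains per environment.
    """
    rates = growth.rates()
    merged = context.merge(
        rates.rename("lam").reset_index(), on=["strain", "environment"], how="inner")
    rows = []
    for env, sub in merged.groupby("environment", sort=True):
        if len(sub) < 3:
            raise ValueError(
                f"regress_sign_proportions needs >=3 strains in environment {env}, "
                f"got {len(sub)}")
        for kind in ("beneficial", "deleterious"):
            y = sub[f"frac_{kind}"].to_numpy()
            x = sub["lam"].to_numpy()
            if np.ptp(y) == 0.0:
                # constant proportions: slope 0, no evidence against it
                rows.append({"environment": env, "call": kind, "slope": 0.0,
                             "intercept": float(y[0]), "r2": 0.0, "p": 1.0,
                             "n": len(sub)})
                continue
            fit = stats.linregress(x, y)
            rows.append({"environment": env, "call": kind,
                         "slope": float(fit.slope), "intercept": float(fit.intercept),
                         "r2": float(fit.rvalue ** 2), "p": float(fit.pvalue),
                         "n": len(sub)})
    return pd.DataFrame(rows)


def rank_reshuffle(values: pd.DataFrame, item_col: str,
                   value_col: str = "value") -> tuple[float, pd.DataFrame]:
    """Fraction of items in the top 50% in >=1 environment and in the
    bottom 50% in >=1 other environment.

    ``values`` is tidy with columns (item_col, "environment", value_col).
    Within each environment items are split at the median rank: sorted by
    decreasing value with ties broken by item id, the first ceil(n/2)
    items form the top half (with odd counts the middle item belongs to
    the top half).  Items missing from an environment are ignored there.
    """
    envs = values["environment"].unique()
    if len(envs) < 2:
        raise ValueError("rank_reshuffle requires at least 2 environments")
    records = []
    for env, sub in values.groupby("environment", sort=True):
        sub = sub.sort_values([value_col, item_col],
                              ascending=[False, True], kind="mergesort")
        n = len(sub)
        n_top = -(-n // 2)  # ceil
        for i, item in enumerate(sub[item_col]):
            records.append({item_col: item, "environment": env,
                            "in_top": i < n_top})
    member = pd.DataFrame(records)
    per_item = member.groupby(item_col)["in_top"].agg(
        ever_top="any", ever_bottom=lambda s: (~s).any())
    both = per_item["ever_top"] & per_item["ever_bottom"]
    out = per_item.reset_index()
    out["reshuffled"] = both.to_numpy()
    return float(both.mean()), out


def estimate_sign_fdr(calls: pd.DataFrame, truth: GroundTruth) -> dict:
    """Empirical false discovery rate of non-neutral calls on synthetic data.

    A non-neutral call is false when the noise-free true effect is
    exactly zero or has the opposite sign.  Returns the FDR together
    with the discovery counts; FDR is 0 when there are no discoveries.
    """
    nonneutral = calls[calls["call"] != NEUTRAL]
    n_disc = len(nonneutral)
    if n_disc == 0:
        return {"fdr": 0.0, "n_discoveries": 0, "n_false": 0}
    true_eff = truth.true_effect_lookup()
    idx = pd.MultiIndex.from_frame(nonneutral[["mutation", "strain", "environment"]])
    tval = true_eff.reindex(idx).to_numpy()
    if np.isnan(tval).any():
        raise ValueError("ground truth lacks entries for some non-neutral calls")
    called_sign = np.where(nonneutral["call"].to_numpy() == BENEFICIAL, 1.0, -1.0)
    false = (tval == 0.0) | (np.sign(tval) != called_sign)
    n_false = int(false.sum())
    return {"fdr": n_false / n_disc, "n_discoveries": n_disc, "n_false": n_false}
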