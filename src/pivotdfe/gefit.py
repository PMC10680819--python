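"""Linear global-epistasis fits of mutation effects on background growth.

For each mutation m and environment e the measured effects across
background strains are regressed on the strains' growth rates,

    dlambda_mge = a_me + b_me * lambda_ge + xi_mge,

by ordinary least squares.  The slope b_me is the global-epistasis
coefficient, the residuals xi_mge are idiosyncratic epistasis.  The
module also tests slope equality across environments (Welch t-tests per
environment pair) and fits the parallel-lines "invariant slope" model
with one slope b_m per mutation and environment-specific intercepts.

Multiple-testing control is Benjamini-Hochberg throughout, with three
test families: model F-tests across mutations, slope/intercept t-tests
across all mutation x environment fits, and pairwise slope comparisons
across all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import EffectTable, GrowthRateTable

__all__ = [
    "benjamini_hochberg",
    "fit_mutation_env",
    "fit_all",
    "compare_slopes_pairwise",
    "fit_invariant_slope",
    "fit_invariant_all",
    "EpistasisFitResult",
]

MIN_STRAINS = 3  # two points always fit a line exactly


def benjamini_hochberg(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg step-up procedure.

    Returns ``(reject, p_adjusted)`` where ``p_adjusted[i] = min_{j:
    p(j) >= p(i)} m * p(j) / rank(j)`` capped at 1, and ``reject`` marks
    the hypotheses with adjusted p <= alpha (equivalently, those at or
    below the largest rank k with p(k) <= k * alpha / m).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if len(p) == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    p_adj = np.empty(m)
    p_adj[order] = adj_sorted
    reject = p_adj <= alpha
    return reject, p_adj


def fit_mutation_env(lam, dlam) -> dict:
    """OLS of one mutation's effects on growth rate in one environment.

    Returns slope/intercept with SEs, residual SD, R^2, the F-test of
    the regression against the intercept-only model (for simple
    regression F = t^2 and the p-values coincide), the intercept t-test
    p, and the residuals.  Requires >= 3 strains with varying growth.
    """
    x = np.asarray(lam, dtype=float)
    y = np.asarray(dlam, dtype=float)
    n = len(x)
    if n < MIN_STRAINS:
        raise ValueError(f"need >= {MIN_STRAINS} strains, got {n}")
    if np.ptp(x) == 0.0:
        raise ValueError("background growth rates are all identical; slope unidentifiable")
    if np.ptp(y) == 0.0:
        # constant effects: flat line, no evidence of global epistasis
        return {"n": n, "slope": 0.0, "intercept": float(y[0]),
                "se_slope": 0.0, "se_intercept": 0.0, "resid_sd": 0.0,
                "r2": 0.0, "f_stat": 0.0, "f_p": 1.0, "p_slope": 1.0,
                "p_intercept": 0.0 if y[0] != 0 else 1.0,
                "residuals": np.zeros(n)}
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    dof = n - 2
    resid_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    if fit.stderr > 0:
        f_stat = float((fit.slope / fit.stderr) ** 2)
        f_p = float(fit.pvalue)
    else:  # perfect fit
        f_stat = np.inf
        f_p = 0.0
    if fit.intercept_stderr > 0:
        p_int = float(2 * stats.t.sf(abs(fit.intercept / fit.intercept_stderr), dof))
    else:
        p_int = 0.0 if fit.intercept != 0 else 1.0
    return {"n": n, "slope": float(fit.slope), "intercept": float(fit.intercept),
            "se_slope": float(fit.stderr), "se_intercept": float(fit.intercept_stderr),
            "resid_sd": resid_sd, "r2": float(fit.rvalue ** 2),
            "f_stat": f_stat, "f_p": f_p, "p_slope": f_p, "p_intercept": p_int,
            "residuals": resid}


@dataclass
class EpistasisFitResult:
    """All per-(mutation, environment) fits plus mutation-level tests."""

    fits: pd.DataFrame            # one row per (mutation, environment)
    residuals: pd.DataFrame       # (mutation, environment, strain, resid)
    mutation_tests: pd.DataFrame  # pooled model F-test per mutation
    slope_intercept_corr: pd.DataFrame  # Pearson r of (b, a) per environment
    skipped: pd.DataFrame         # fits with too little data
    summary: dict


def _merge(effects: EffectTable, growth: GrowthRateTable) -> pd.DataFrame:
    obs = effects.observed()
    rates = growth.rates().rename("lam").reset_index()
    merged = obs.merge(rates, on=["strain", "environment"], how="inner")
    return merged


def fit_all(effects: EffectTable, growth: GrowthRateTable,
            alpha: float = 0.05) -> EpistasisFitResult:
    """Fit every mutation x environment with enough data and summarize.

    BH families: slope and intercept t-tests are corrected across all
    fits; the pooled model F-test (full per-environment-slopes model vs
    a single grand mean, per mutation) is corrected across mutations.
    """
    merged = _merge(effects, growth)
    fit_rows, resid_rows, skipped = [], [], []
    for (mut, env), sub in merged.groupby(["mutation", "environment"], sort=True):
        if len(sub) < MIN_STRAINS or np.ptp(sub["lam"].to_numpy()) == 0.0:
            skipped.append({"mutation": mut, "environment": env, "n": len(sub)})
            continue
        res = fit_mutation_env(sub["lam"].to_numpy(), sub["value"].to_numpy())
        residuals = res.pop("residuals")
        fit_rows.append({"mutation": mut, "environment": env, **res})
        resid_rows.append(pd.DataFrame({
            "mutation": mut, "environment": env,
            "strain": sub["strain"].to_numpy(), "resid": residuals}))
    if not fit_rows:
        raise ValueError("no mutation x environment combination has enough data")
    fits = pd.DataFrame(fit_rows)
    residuals = pd.concat(resid_rows, ignore_index=True)

    rej_b, adj_b = benjamini_hochberg(fits["p_slope"].to_numpy(), alpha)
    rej_a, adj_a = benjamini_hochberg(fits["p_intercept"].to_numpy(), alpha)
    fits["p_slope_bh"] = adj_b
    fits["slope_significant"] = rej_b
    fits["p_intercept_bh"] = adj_a
    fits["intercept_significant"] = rej_a

    mutation_tests = _pooled_model_tests(merged, fits, alpha)

    corr_rows = []
    for env, sub in fits.groupby("environment", sort=True):
        if len(sub) >= 3 and sub["slope"].std() > 0 and sub["intercept"].std() > 0:
            r, p = stats.pearsonr(sub["slope"], sub["intercept"])
        else:
            r, p = np.nan, np.nan
        corr_rows.append({"environment": env, "pearson_r": r, "p": p,
                          "n": len(sub)})
    corr = pd.DataFrame(corr_rows)

    sig = fits[fits["slope_significant"]]
    sig_int = fits[fits["intercept_significant"]]
    summary = {
        "n_fits": int(len(fits)),
        "n_skipped": int(len(skipped)),
        "n_slopes_significant": int(len(sig)),
        "frac_slopes_significant": float(len(sig) / len(fits)),
        "frac_negative_among_significant_slopes":
            float((sig["slope"] < 0).mean()) if len(sig) else np.nan,
        "n_intercepts_significant": int(len(sig_int)),
        "frac_positive_among_significant_intercepts":
            float((sig_int["intercept"] > 0).mean()) if len(sig_int) else np.nan,
        "n_mutations_tested": int(len(mutation_tests)),
        "frac_mutations_model_significant":
            float(mutation_tests["significant"].mean()) if len(mutation_tests) else np.nan,
        "mean_pooled_r2": float(mutation_tests["pooled_r2"].mean())
            if len(mutation_tests) else np.nan,
    }
    return EpistasisFitResult(
        fits=fits, residuals=residuals, mutation_tests=mutation_tests,
        slope_intercept_corr=corr,
        skipped=pd.DataFrame(skipped, columns=["mutation", "environment", "n"]),
        summary=summary)


def _pooled_model_tests(merged: pd.DataFrame, fits: pd.DataFrame,
                        alpha: float) -> pd.DataFrame:
    """Per-mutation F-test of the per-environment-lines model against a
    single grand mean, pooled over the mutation's measurements."""
    fitted = set(zip(fits["mutation"], fits["environment"]))
    rows = []
    for mut, sub in merged.groupby("mutation", sort=True):
        sub = sub[[ (mut, e) in fitted for e in sub["environment"] ]]
        if len(sub) == 0:
            continue
        k = sub["environment"].nunique()
        n = len(sub)
        p_full = 2 * k
        if n <= p_full:
            continue
        y = sub["value"].to_numpy()
        sst = float(((y - y.mean()) ** 2).sum())
        sse = 0.0
        for env, esub in sub.groupby("environment"):
            row = fits[(fits["mutation"] == mut) & (fits["environment"] == env)].iloc[0]
            pred = row["intercept"] + row["slope"] * esub["lam"].to_numpy()
            sse += float(((esub["value"].to_numpy() - pred) ** 2).sum())
        r2 = 1.0 - sse / sst if sst > 0 else np.nan
        df1, df2 = p_full - 1, n - p_full
        if sse == 0.0:
            f_stat, f_p = np.inf, 0.0
        else:
            f_stat = ((sst - sse) / df1) / (sse / df2)
            f_p = float(stats.f.sf(f_stat, df1, df2))
        rows.append({"mutation": mut, "n": n, "n_environments": k,
                     "pooled_r2": r2, "f_stat": f_stat, "f_p": f_p})
    tests = pd.DataFrame(rows)
    if len(tests):
        rej, adj = benjamini_hochberg(tests["f_p"].to_numpy(), alpha)
        tests["f_p_bh"] = adj
        tests["significant"] = rej
    return tests


def compare_slopes_pairwise(fits: pd.DataFrame, alpha: float = 0.05):
    """Welch t-tests of slope equality for every environment pair of
    every mutation, BH-corrected across all pairs.

    Returns ``(pairs, per_mutation, summary)``.  The Welch-Satterthwaite
    degrees of freedom combine the per-fit residual degrees of freedom
    (n - 2).
    """
    pair_rows = []
    for mut, sub in fits.groupby("mutation", sort=True):
        sub = sub.sort_values("environment")
        if len(sub) < 2:
            continue
        recs = sub.to_dict("records")
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                r1, r2 = recs[i], recs[j]
                v1, v2 = r1["se_slope"] ** 2, r2["se_slope"] ** 2
                diff = r1["slope"] - r2["slope"]
                if v1 + v2 == 0.0:
                    t = 0.0 if diff == 0.0 else np.inf
                    dof = np.inf
                    p = 1.0 if diff == 0.0 else 0.0
                else:
                    t = diff / np.sqrt(v1 + v2)
                    dof = (v1 + v2) ** 2 / (
                        v1 ** 2 / (r1["n"] - 2) + v2 ** 2 / (r2["n"] - 2))
                    p = float(2 * stats.t.sf(abs(t), dof))
                pair_rows.append({"mutation": mut, "env1": r1["environment"],
                                  "env2": r2["environment"], "t": float(t),
                                  "df": float(dof), "p": p})
    if not pair_rows:
        raise ValueError("no mutation has fits in at least 2 environments")
    pairs = pd.DataFrame(pair_rows)
    rej, adj = benjamini_hochberg(pairs["p"].to_numpy(), alpha)
    pairs["p_bh"] = adj
    pairs["significant"] = rej

    per_mut = pairs.groupby("mutation", sort=True)["significant"].agg(
        n_pairs="size", n_significant="sum").reset_index()
    per_mut["frac_significant"] = per_mut["n_significant"] / per_mut["n_pairs"]
    per_mut["all_indistinguishable"] = per_mut["n_significant"] == 0

    summary = {
        "n_pairs": int(len(pairs)),
        "frac_pairs_indistinguishable": float(1.0 - pairs["significant"].mean()),
        "n_mutations": int(len(per_mut)),
        "frac_mutations_all_indistinguishable":
            float(per_mut["all_indistinguishable"].mean()),
    }
    return pairs, per_mut, summary


def fit_invariant_slope(lam, dlam, env) -> dict:
    """Parallel-lines fit for one mutation across environments.

    One common slope, one intercept per environment, solved by least
    squares; also fits the full model (per-environment slopes and
    intercepts) and reports both models' pooled variance explained.
    The shared-slope model is nested in the full model, so
    ``r2_shared <= r2_full`` always.
    """
    x = np.asarray(lam, dtype=float)
    y = np.asarray(dlam, dtype=float)
    env = np.asarray(env)
    env_ids = sorted(pd.unique(env))
    counts = {e: int((env == e).sum()) for e in env_ids}
    usable = [e for e in env_ids if counts[e] >= MIN_STRAINS]
    if len(usable) < 2:
        raise ValueError("invariant-slope fit needs >=2 environments with "
                         f">= {MIN_STRAINS} strains each")
    keep = np.isin(env, usable)
    x, y, env = x[keep], y[keep], env[keep]
    n, k = len(x), len(usable)

    dummies = np.column_stack([(env == e).astype(float) for e in usable])
    X_shared = np.column_stack([dummies, x])
    beta, _, _, _ = np.linalg.lstsq(X_shared, y, rcond=None)
    resid_shared = y - X_shared @ beta
    sse_shared = float(resid_shared @ resid_shared)

    X_full = np.column_stack([dummies, dummies * x[:, None]])
    beta_full, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
    resid_full = y - X_full @ beta_full
    sse_full = float(resid_full @ resid_full)

    sst = float(((y - y.mean()) ** 2).sum())
    r2_shared = 1.0 - sse_shared / sst if sst > 0 else np.nan
    r2_full = 1.0 - sse_full / sst if sst > 0 else np.nan

    dof = n - (k + 1)
    sigma2 = sse_shared / dof if dof > 0 else 0.0
    xtx_inv = np.linalg.pinv(X_shared.T @ X_shared)
    se_slope = float(np.sqrt(max(sigma2 * xtx_inv[k, k], 0.0)))

    return {"slope": float(beta[k]), "se_slope": se_slope,
            "intercepts": {e: float(b) for e, b in zip(usable, beta[:k])},
            "r2_shared": r2_shared, "r2_full": r2_full,
            "delta_r2": r2_full - r2_shared if sst > 0 else np.nan,
            "n": n, "n_environments": k}


def fit_invariant_all(effects: EffectTable, growth: GrowthRateTable):
    """Invariant-slope fit for every mutation with enough data.

    Returns ``(per_mutation, intercepts, summary)``; the summary's mean
    R^2 values quantify how much a per-environment slope buys over a
    single environment-independent slope per mutation.
    """
    merged = _merge(effects, growth)
    rows, int_rows, skipped = [], [], []
    for mut, sub in merged.groupby("mutation", sort=True):
        try:
            res = fit_invariant_slope(sub["lam"], sub["value"], sub["environment"])
        except ValueError:
            skipped.append(mut)
            continue
        intercepts = res.pop("intercepts")
        rows.append({"mutation": mut, **res})
        for e, a in intercepts.items():
            int_rows.append({"mutation": mut, "environment": e, "intercept": a})
    if not rows:
        raise ValueError("no mutation has enough data for the invariant-slope model")
    per_mut = pd.DataFrame(rows)
    summary = {
        "n_mutations": int(len(per_mut)),
        "n_skipped": len(skipped),
        "mean_r2_full": float(per_mut["r2_full"].mean()),
        "mean_r2_shared": float(per_mut["r2_shared"].mean()),
        "mean_delta_r2": float(per_mut["delta_r2"].mean()),
    }
    return per_mut, pd.DataFrame(int_rows), summary
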