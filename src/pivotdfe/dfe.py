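"""Distribution of fitness effects (DFE): empirical moments, model
predictions and cross-environment comparisons.

Under the generalized global-epistasis equation with independent slope,
pivot-noise and idiosyncratic terms, the first three moments of the DFE
in a strain with environment-adjusted growth rate x = lambda - pivot are

    mean(x)     = mu_b * x
    variance(x) = var_b * x^2 + var_eta + var_xi   (+ measurement variance)
    m3(x)       = gamma_b * x^3,   skewness = m3 / variance^{3/2}

where (mu_b, var_b, gamma_b) are the mean, variance and third central
moment of the per-mutation slope ensemble.  The mean crosses zero at the
pivot, the variance parabola bottoms out there, and skewness declines
monotonically through zero — so the DFE is a function of the adjusted,
not absolute, growth rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import EffectTable, GrowthRateTable
from .pivot import PivotEstimate

__all__ = [
    "SlopeDistributionSummary",
    "empirical_moments",
    "compute_dfe_moments",
    "predict_moments",
    "params_from_fits",
    "fit_moment_curves",
    "MomentCurveFit",
    "pivot_from_dfe_mean",
    "dfe_distance",
    "compare_matched_pairs",
    "MatchedPairResult",
]


@dataclass
class SlopeDistributionSummary:
    """Moments of the slope ensemble plus noise variances (h^-1 scale).

    ``var_meas`` is the per-entry measurement variance contributing to
    the observed DFE width; include it when comparing predictions with
    measured (rather than noise-free) effects.
    """

    mu_b: float
    var_b: float
    gamma_b: float = 0.0
    var_eta: float = 0.0
    var_xi: float = 0.0
    var_meas: float = 0.0

    def __post_init__(self) -> None:
        for name in ("var_b", "var_eta", "var_xi", "var_meas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")

    @property
    def noise_variance(self) -> float:
        return self.var_eta + self.var_xi + self.var_meas


def empirical_moments(values, n_boot: int = 1000,
                      rng: np.random.Generator | None = None) -> dict:
    """Sample mean, variance (divisor n), third central moment and
    moment-estimator skewness m3/m2^{3/2}, with nonparametric bootstrap
    SEs over mutations.

    The divisor-n moment estimators match the population moments the
    model predicts; no small-sample bias correction is applied.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        raise ValueError(f"need >= 2 observed effects, got {n}")
    mean = float(x.mean())
    d = x - mean
    m2 = float((d ** 2).mean())
    m3 = float((d ** 3).mean())
    skew = m3 / m2 ** 1.5 if m2 > 0 else 0.0

    rng = np.random.default_rng() if rng is None else rng
    idx = rng.integers(0, n, size=(n_boot, n))
    s = x[idx]
    mu_b = s.mean(axis=1)
    db = s - mu_b[:, None]
    m2_b = (db ** 2).mean(axis=1)
    m3_b = (db ** 3).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sk_b = np.where(m2_b > 0, m3_b / m2_b ** 1.5, 0.0)
    return {"n": n, "mean": mean, "var": m2, "m3": m3, "skew": float(skew),
            "se_mean": float(mu_b.std(ddof=1)), "se_var": float(m2_b.std(ddof=1)),
            "se_m3": float(m3_b.std(ddof=1)), "se_skew": float(sk_b.std(ddof=1))}


def _pivot_series(pivots) -> pd.Series:
    if isinstance(pivots, pd.Series):
        return pivots
    if isinstance(pivots, dict):
        return pd.Series(pivots)
    return pd.Series({p.environment: p.pivot for p in pivots})


def compute_dfe_moments(effects: EffectTable, growth: GrowthRateTable,
                        pivots, params: SlopeDistributionSummary | None = None,
                        min_mutations: int = 20, n_boot: int = 1000,
                        seed: int = 0) -> pd.DataFrame:
    """Empirical DFE moments per strain x environment.

    ``pivots`` maps environment to pivot growth rate (a Series, dict or
    list of :class:`~pivotdfe.pivot.PivotEstimate`); the adjusted growth
    rate is lambda_ge minus the environment's pivot.  Cells with fewer
    than ``min_mutations`` observed effects are flagged (``usable`` =
    False) and should be excluded from moment-curve fits.  When
    ``params`` is given, model-predicted moments are attached.
    """
    piv = _pivot_series(pivots)
    rates = growth.rates()
    rng = np.random.default_rng(seed)
    rows = []
    for (strain, env), sub in effects.observed().groupby(
            ["strain", "environment"], sort=True):
        if env not in piv.index:
            continue
        lam = float(rates.loc[(strain, env)])
        x = lam - float(piv.loc[env])
        vals = sub["value"].to_numpy()
        row = {"strain": strain, "environment": env, "lam": lam, "lam_star": x,
               "usable": len(vals) >= max(min_mutations, 2)}
        if len(vals) >= 2:
            row.update(empirical_moments(vals, n_boot=n_boot, rng=rng))
        else:
            row.update({"n": len(vals)})
        rows.append(row)
    out = pd.DataFrame(rows)
    if params is not None and len(out):
        mean_p, var_p, skew_p = predict_moments(out["lam_star"].to_numpy(), params)
        out["pred_mean"] = mean_p
        out["pred_var"] = var_p
        out["pred_skew"] = skew_p
    return out


def predict_moments(x, params: SlopeDistributionSummary):
    """Model-predicted DFE mean, variance and skewness at adjusted
    growth rate(s) ``x``.  Scalar in, scalars out."""
    xa = np.asarray(x, dtype=float)
    mean = params.mu_b * xa
    var = params.var_b * xa ** 2 + params.noise_variance
    m3 = params.gamma_b * xa ** 3
    if np.any((var == 0) & (m3 != 0)):
        raise ValueError("zero predicted variance with nonzero third moment")
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(var > 0, m3 / var ** 1.5, 0.0)
    if xa.ndim == 0:
        return float(mean), float(var), float(skew)
    return mean, var, skew


def params_from_fits(invariant_fits: pd.DataFrame, var_eta: float,
                     mean_resid_var: float,
                     include_measurement: bool = True) -> SlopeDistributionSummary:
    """Slope-ensemble parameters from fitted invariant slopes.

    The slope variance is debiased by the mean squared slope SE; the
    per-fit residual variance (idiosyncratic epistasis plus measurement
    error) supplies the remaining variance floor, reported under
    ``var_xi``/``var_meas`` jointly.
    """
    b = invariant_fits["slope"].to_numpy()
    se2 = invariant_fits["se_slope"].to_numpy() ** 2
    var_b = max(float(np.var(b, ddof=1) - se2.mean()), 0.0)
    d = b - b.mean()
    gamma_b = float((d ** 3).mean())
    return SlopeDistributionSummary(
        mu_b=float(b.mean()), var_b=var_b, gamma_b=gamma_b,
        var_eta=float(var_eta),
        var_xi=float(mean_resid_var) if include_measurement else 0.0,
        var_meas=0.0)


@dataclass
class MomentCurveFit:
    """Theory-constrained and descriptive fits of moments vs lambda*."""

    mu_b: float          # slope of mean vs x (through origin)
    var_b: float         # quadratic coefficient of variance vs x^2
    gamma_b: float       # cubic coefficient of m3 vs x^3 (through origin)
    var_floor: float     # variance intercept: var_eta + var_xi (+ meas)
    poly_mean: np.ndarray = field(default_factory=lambda: np.zeros(2))
    poly_var: np.ndarray = field(default_factory=lambda: np.zeros(3))
    poly_m3: np.ndarray = field(default_factory=lambda: np.zeros(4))
    n_points: int = 0


def _wls_through_origin(x, y, w) -> float:
    return float((w * x * y).sum() / (w * x * x).sum())


def fit_moment_curves(moments: pd.DataFrame, min_points: int = 5) -> MomentCurveFit:
    """Estimate slope-ensemble parameters from empirical moments.

    Weighted least squares with bootstrap-SE weights: the mean is fit as
    mu_b*x through the origin, the variance as var_b*x^2 + floor, and
    the third central moment as gamma_b*x^3 through the origin.  The
    same data also get unconstrained polynomial fits of degree 1/2/3 as
    descriptive curves.
    """
    sub = moments[moments.get("usable", True) & moments["mean"].notna()]
    if len(sub) < min_points:
        raise ValueError(f"need >= {min_points} usable (strain, environment) "
                         f"points, got {len(sub)}")
    x = sub["lam_star"].to_numpy()

    def weights(se_col):
        se = sub[se_col].to_numpy()
        if np.any(se <= 0):
            return np.ones_like(se)
        return 1.0 / se ** 2

    w_mean = weights("se_mean")
    w_var = weights("se_var")
    w_m3 = weights("se_m3")
    y_mean = sub["mean"].to_numpy()
    y_var = sub["var"].to_numpy()
    y_m3 = sub["m3"].to_numpy()

    mu_b = _wls_through_origin(x, y_mean, w_mean)
    X = np.column_stack([np.ones_like(x), x ** 2])
    W = np.sqrt(w_var)
    coef, _, _, _ = np.linalg.lstsq(X * W[:, None], y_var * W, rcond=None)
    var_floor, var_b = float(coef[0]), float(coef[1])
    gamma_b = _wls_through_origin(x ** 3, y_m3, w_m3)

    poly_mean = np.polyfit(x, y_mean, 1, w=np.sqrt(w_mean))
    poly_var = np.polyfit(x, y_var, 2, w=np.sqrt(w_var))
    poly_m3 = np.polyfit(x, y_m3, 3, w=np.sqrt(w_m3))
    return MomentCurveFit(mu_b=mu_b, var_b=var_b, gamma_b=gamma_b,
                          var_floor=var_floor, poly_mean=poly_mean,
                          poly_var=poly_var, poly_m3=poly_m3,
                          n_points=int(len(sub)))


def pivot_from_dfe_mean(means, lams) -> dict:
    """Pivot growth rate of one environment as the zero crossing of the
    DFE mean vs background growth rate line.

    Fits an ordinary least-squares line of per-strain DFE means on
    growth rates and returns its root; the estimate is flagged as
    extrapolated when the root lies outside the observed growth-rate
    range (e.g. when all means share a sign).
    """
    y = np.asarray(means, dtype=float)
    x = np.asarray(lams, dtype=float)
    if len(x) < 3:
        raise ValueError("pivot from DFE mean needs >= 3 strains")
    if np.ptp(y) == 0.0:
        raise ValueError("DFE mean does not depend on growth rate; no zero crossing")
    fit = stats.linregress(x, y)
    if fit.slope == 0.0:
        raise ValueError("DFE mean does not depend on growth rate; no zero crossing")
    root = -fit.intercept / fit.slope
    return {"pivot": float(root), "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "extrapolated": bool(root < x.min() or root > x.max()),
            "n": len(x)}


def dfe_distance(sample1, sample2) -> float:
    """Two-sample Kolmogorov-Smirnov statistic between two DFEs."""
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError("DFE samples must be non-empty")
    return float(stats.ks_2samp(s1, s2).statistic)


@dataclass
class MatchedPairResult:
    """KS distances for matched strain pairs across environments."""

    pairs: pd.DataFrame
    distances: dict
    p_adjusted_vs_absolute: float
    p_adjusted_vs_same_strain: float


def compare_matched_pairs(effects: EffectTable, growth: GrowthRateTable,
                          pivots, tol: float = 0.01,
                          min_mutations: int = 20) -> MatchedPairResult:
    """Compare DFE similarity under three cross-environment pairings.

    For every pair of environments, strains are paired (i) by nearest
    adjusted growth rate, (ii) by nearest absolute growth rate (both
    nearest-neighbor within ``tol`` h^-1, unmatched strains dropped) and
    (iii) by identity (same strain, two environments).  Each pair's DFE
    dissimilarity is the two-sample KS statistic; one-sided rank-sum
    tests ask whether adjusted-matched pairs are more similar than the
    other two pairings.
    """
    piv = _pivot_series(pivots)
    rates = growth.rates()
    cells: dict[tuple[str, str], dict] = {}
    for (strain, env), sub in effects.observed().groupby(
            ["strain", "environment"], sort=True):
        if env not in piv.index or len(sub) < min_mutations:
            continue
        lam = float(rates.loc[(strain, env)])
        cells[(strain, env)] = {"lam": lam, "lam_star": lam - float(piv.loc[env]),
                                "values": sub["value"].to_numpy()}
    envs = sorted({e for _, e in cells})
    if len(envs) < 2:
        raise ValueError("matched-pair comparison needs >= 2 environments")

    rows = []
    for i in range(len(envs)):
        for j in range(i + 1, len(envs)):
            e1, e2 = envs[i], envs[j]
            c1 = {g: c for (g, e), c in cells.items() if e == e1}
            c2 = {g: c for (g, e), c in cells.items() if e == e2}
            if not c1 or not c2:
                continue
            for key, kind in (("lam_star", "adjusted"), ("lam", "absolute")):
                g2_ids = list(c2)
                vals2 = np.array([c2[g][key] for g in g2_ids])
                for g1, cell1 in c1.items():
                    k = int(np.argmin(np.abs(vals2 - cell1[key])))
                    if abs(vals2[k] - cell1[key]) > tol:
                        continue
                    g2 = g2_ids[k]
                    rows.append({
                        "kind": kind, "env1": e1, "env2": e2,
                        "strain1": g1, "strain2": g2,
                        "distance": dfe_distance(cell1["values"], c2[g2]["values"])})
            for g in set(c1) & set(c2):
                rows.append({"kind": "same_strain", "env1": e1, "env2": e2,
                             "strain1": g, "strain2": g,
                             "distance": dfe_distance(c1[g]["values"],
                                                      c2[g]["values"])})
    pairs = pd.DataFrame(rows)
    dists = {kind: pairs.loc[pairs["kind"] == kind, "distance"].to_numpy()
             for kind in ("adjusted", "absolute", "same_strain")}
    if len(dists["adjusted"]) == 0 or len(dists["absolute"]) == 0:
        raise ValueError(f"no strain pairs matched within tolerance {tol} h^-1")
    p_abs = float(stats.mannwhitneyu(dists["adjusted"], dists["absolute"],
                                     alternative="less").pvalue)
    p_same = float(stats.mannwhitneyu(dists["adjusted"], dists["same_strain"],
                                      alternative="less").pvalue) \
        if len(dists["same_strain"]) else np.nan
    return MatchedPairResult(pairs=pairs, distances=dists,
                             p_adjusted_vs_absolute=p_abs,
                             p_adjusted_vs_same_strain=p_same)
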