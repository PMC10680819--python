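"""End-to-end analysis pipeline: sign calls, epistasis fits, pivots, DFE.

Each stage is a pure function of its inputs plus configuration and seed;
``run_pipeline`` chains them (classify -> fit -> pivot -> dfe), writes
the result tables as CSV and a machine-readable JSON summary of the
headline statistics, and logs row counts per stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dfe as dfe_mod
from . import gefit, pivot as pivot_mod, signcalls
from .tables import EffectTable, GrowthRateTable

__all__ = ["PipelineResult", "PipelineError", "run_pipeline"]

log = logging.getLogger("pivotdfe")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    sign_calls: pd.DataFrame
    sign_context: pd.DataFrame
    sign_mutation: pd.DataFrame
    sign_regressions: pd.DataFrame
    strain_reshuffle: float
    fits: gefit.EpistasisFitResult
    slope_pairs: pd.DataFrame
    invariant_fits: pd.DataFrame
    pivots: pd.DataFrame
    pivot_noise: pd.DataFrame
    eta_residuals: pd.DataFrame
    pivot_comparisons: pd.DataFrame | str
    dfe_moments: pd.DataFrame
    moment_fit: dfe_mod.MomentCurveFit | None
    dfe_pairs: dfe_mod.MatchedPairResult | None
    dfe_mean_pivots: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_pipeline(effects: EffectTable, growth: GrowthRateTable, *,
                 alpha: float = 0.05, ci_level: float = 0.99, seed: int = 0,
                 min_mutations: int = 20, n_boot: int = 1000,
                 match_tol: float = 0.01, pivot_only_significant: bool = False,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run all stages on an effect table and growth-rate table.

    With ``out_dir`` the stage tables are written as CSV files alongside
    a ``summary.json``.  The pipeline is deterministic given its inputs
    and ``seed`` (which drives only the DFE bootstrap).
    """
    summary: dict = {"alpha": alpha, "ci_level": ci_level, "seed": seed}

    # -- stage 1: sign classification ---------------------------------
    stage = "classify"
    try:
        calls = signcalls.classify_table(effects, level=ci_level)
        context, mutation = signcalls.sign_summary(calls)
        regressions = signcalls.regress_sign_proportions(context, growth)
        n_envs = growth.data["environment"].nunique()
        if n_envs >= 2:
            strain_reshuffle, _ = signcalls.rank_reshuffle(
                growth.data, item_col="strain")
        else:
            strain_reshuffle = float("nan")
        log.info("classify: %d calls, %d contexts", len(calls), len(context))
    except Exception as exc:  # pragma: no cover - error path
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    summary["n_sign_calls"] = len(calls)
    summary["frac_sign_switching_mutations"] = float(
        mutation["sign_switching"].mean())
    summary["strain_rank_reshuffle_fraction"] = strain_reshuffle

    # -- stage 2: global-epistasis fits -------------------------------
    stage = "fit"
    try:
        fits = gefit.fit_all(effects, growth, alpha=alpha)
        slope_pairs = pd.DataFrame()
        pair_summary = {}
        if n_envs >= 2:
            slope_pairs, _, pair_summary = gefit.compare_slopes_pairwise(
                fits.fits, alpha=alpha)
        invariant_fits, _, inv_summary = gefit.fit_invariant_all(effects, growth) \
            if n_envs >= 2 else (pd.DataFrame(), pd.DataFrame(), {})
        log.info("fit: %d fits, %d skipped", len(fits.fits), len(fits.skipped))
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    summary["epistasis"] = fits.summary
    summary["slope_pairs"] = pair_summary
    summary["invariant_slope"] = inv_summary

    # -- stage 3: pivot growth rates ----------------------------------
    stage = "pivot"
    try:
        estimates = pivot_mod.estimate_pivots(
            fits.fits, only_significant=pivot_only_significant)
        pivots_df = pd.DataFrame([
            {"environment": e.environment, "pivot": e.pivot, "se": e.se,
             "n": e.n, "diagnostic_intercept": e.diagnostic_intercept,
             "diagnostic_intercept_p": e.diagnostic_intercept_p}
            for e in estimates])
        noise_df, pooled_noise = pivot_mod.pivot_noise_summary(estimates)
        eta_residuals = pd.concat([
            e.residuals.rename("eta").reset_index().assign(environment=e.environment)
            for e in estimates], ignore_index=True)
        if len(estimates) >= 2:
            comparisons: pd.DataFrame | str = pivot_mod.compare_pivots(
                estimates, alpha=alpha)
        else:
            comparisons = "not applicable"
        log.info("pivot: %d environments", len(estimates))
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    summary["pivots"] = {e.environment: e.pivot for e in estimates}
    summary["pivot_noise_pooled"] = pooled_noise

    # -- stage 4: DFE moments and comparisons -------------------------
    stage = "dfe"
    try:
        mean_resid_var = float((fits.fits["resid_sd"] ** 2).mean())
        params = None
        if len(invariant_fits):
            params = dfe_mod.params_from_fits(
                invariant_fits, var_eta=pooled_noise["sd"] ** 2,
                mean_resid_var=mean_resid_var)
        moments = dfe_mod.compute_dfe_moments(
            effects, growth, estimates, params=params,
            min_mutations=min_mutations, n_boot=n_boot, seed=seed)
        moment_fit = None
        usable = moments[moments["usable"]] if len(moments) else moments
        if len(usable) >= 5:
            moment_fit = dfe_mod.fit_moment_curves(moments)
        dfe_pairs = None
        if len(estimates) >= 2:
            try:
                dfe_pairs = dfe_mod.compare_matched_pairs(
                    effects, growth, estimates, tol=match_tol,
                    min_mutations=min_mutations)
            except ValueError:
                dfe_pairs = None
        mean_pivot_rows = []
        for env, sub in usable.groupby("environment", sort=True):
            if len(sub) < 3:
                continue
            try:
                res = dfe_mod.pivot_from_dfe_mean(sub["mean"], sub["lam"])
            except ValueError:
                continue
            mean_pivot_rows.append({"environment": env, **res})
        dfe_mean_pivots = pd.DataFrame(mean_pivot_rows)
        log.info("dfe: %d moment cells", len(moments))
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    if moment_fit is not None:
        summary["moment_fit"] = {
            "mu_b": moment_fit.mu_b, "var_b": moment_fit.var_b,
            "gamma_b": moment_fit.gamma_b, "var_floor": moment_fit.var_floor,
            "n_points": moment_fit.n_points}
    if dfe_pairs is not None:
        summary["dfe_matched_pairs"] = {
            "p_adjusted_vs_absolute": dfe_pairs.p_adjusted_vs_absolute,
            "p_adjusted_vs_same_strain": dfe_pairs.p_adjusted_vs_same_strain,
            "n_adjusted": len(dfe_pairs.distances["adjusted"]),
            "n_absolute": len(dfe_pairs.distances["absolute"]),
            "n_same_strain": len(dfe_pairs.distances["same_strain"])}
    summary["pivot_comparisons"] = (
        "not applicable" if isinstance(comparisons, str)
        else {"n_pairs": len(comparisons),
              "frac_significant": float(comparisons["significant"].mean())})

    result = PipelineResult(
        sign_calls=calls, sign_context=context, sign_mutation=mutation,
        sign_regressions=regressions, strain_reshuffle=strain_reshuffle,
        fits=fits, slope_pairs=slope_pairs, invariant_fits=invariant_fits,
        pivots=pivots_df, pivot_noise=noise_df, eta_residuals=eta_residuals,
        pivot_comparisons=comparisons,
        dfe_moments=moments, moment_fit=moment_fit, dfe_pairs=dfe_pairs,
        dfe_mean_pivots=dfe_mean_pivots, summary=_jsonable(summary))

    if out_dir is not None:
        _write_results(result, Path(out_dir))
    return result


def _write_results(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.sign_calls.to_csv(out_dir / "sign_calls.csv", index=False)
    result.sign_context.to_csv(out_dir / "sign_summary.csv", index=False)
    result.sign_regressions.to_csv(out_dir / "sign_regressions.csv", index=False)
    result.fits.fits.to_csv(out_dir / "epistasis_fits.csv", index=False)
    if len(result.slope_pairs):
        result.slope_pairs.to_csv(out_dir / "slope_pair_tests.csv", index=False)
    if len(result.invariant_fits):
        result.invariant_fits.to_csv(out_dir / "invariant_slope_fits.csv",
                                     index=False)
    result.pivots.to_csv(out_dir / "pivots.csv", index=False)
    result.eta_residuals.to_csv(out_dir / "pivot_noise.csv", index=False)
    result.pivot_noise.to_csv(out_dir / "pivot_noise_summary.csv", index=False)
    result.dfe_moments.to_csv(out_dir / "dfe_moments.csv", index=False)
    if result.dfe_pairs is not None:
        result.dfe_pairs.pairs.to_csv(out_dir / "dfe_distances.csv", index=False)
    (out_dir / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True))
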