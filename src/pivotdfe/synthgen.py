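"""Synthetic mutation-effect datasets with known ground truth.

The generative model is the generalized global-epistasis equation: the
effect of mutation ``m`` in strain ``g`` and environment ``e`` is

    dlambda_mge = b_m * (lambda_ge - pivot_e) + eta_me + xi_mge

with a per-mutation slope ``b_m``, an environment-specific pivot growth
rate, Gaussian pivot noise ``eta_me`` (per mutation x environment) and
Gaussian idiosyncratic epistasis ``xi_mge`` (per mutation x strain x
environment).  Measured effects add Gaussian measurement error and are
reported relative to the mean measured effect of a designated neutral
reference set within each strain x environment, emulating the
neutral-reference normalization of barcoded competition assays.  The
reference-mean subtraction inflates the reported standard error by
sqrt(1 + 1/n_reference).

Read counts and barcode frequencies are not modeled; Gaussian error on
the effect scale stands in for the whole measurement chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigError, GeneratorConfig
from .tables import EffectTable, GrowthRateTable

__all__ = ["GroundTruth", "generate_dataset", "apply_missingness"]


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would not.

    Attributes
    ----------
    slopes
        True slope ``b_m`` per mutation (reference mutations: exactly 0),
        indexed by mutation id.
    pivots
        True pivot growth rate per environment, indexed by environment id.
    eta
        Tidy frame (mutation, environment, eta) of realized pivot noise.
    effects
        Tidy frame (mutation, strain, environment) with the noise-free
        ``true_effect``, the realized ``xi`` and the raw measurement-noise
        draw ``meas_noise`` (before reference-mean subtraction) for every
        analyzed mutation.
    growth
        Tidy frame (strain, environment, true_rate) of noise-free
        background growth rates.
    reference_mutations
        Ids of the neutral-reference mutations.
    reference_effects
        Reference mutations' measured effects after the reference-mean
        subtraction (their mean is exactly 0 in every strain x
        environment by construction).
    """

    slopes: pd.Series
    pivots: pd.Series
    eta: pd.DataFrame
    effects: pd.DataFrame
    growth: pd.DataFrame
    reference_mutations: list[str]
    reference_effects: pd.DataFrame
    config: GeneratorConfig

    def true_effect_lookup(self) -> pd.Series:
        return self.effects.set_index(["mutation", "strain", "environment"])["true_effect"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "slopes": {str(k): float(v) for k, v in self.slopes.items()},
            "pivots": {str(k): float(v) for k, v in self.pivots.items()},
            "eta": self.eta.to_dict(orient="list"),
            "effects": self.effects.to_dict(orient="list"),
            "growth": self.growth.to_dict(orient="list"),
            "reference_mutations": list(self.reference_mutations),
            "reference_effects": self.reference_effects.to_dict(orient="list"),
            "config": self.config.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            slopes=pd.Series(payload["slopes"], name="slope").rename_axis("mutation"),
            pivots=pd.Series(payload["pivots"], name="pivot").rename_axis("environment"),
            eta=pd.DataFrame(payload["eta"]),
            effects=pd.DataFrame(payload["effects"]),
            growth=pd.DataFrame(payload["growth"]),
            reference_mutations=list(payload["reference_mutations"]),
            reference_effects=pd.DataFrame(payload["reference_effects"]),
            config=GeneratorConfig.from_dict(payload["config"]),
        )


def _draw_slopes(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_analyzed
    if config.slope_distribution == "normal":
        return config.mu_b_true + config.sigma_b_true * rng.standard_normal(n)
    # truncated normal, upper bound in original units
    upper = 0.0 if config.slope_upper is None else config.slope_upper
    if config.sigma_b_true == 0:
        if config.mu_b_true >= upper:
            raise ConfigError(
                "slope_upper must exceed mu_b_true when sigma_b_true is 0"
            )
        return np.full(n, config.mu_b_true)
    b = (upper - config.mu_b_true) / config.sigma_b_true
    return stats.truncnorm.rvs(-np.inf, b, loc=config.mu_b_true,
                               scale=config.sigma_b_true, size=n, random_state=rng)


def generate_dataset(
    config: GeneratorConfig | None = None,
) -> tuple[GrowthRateTable, EffectTable, GroundTruth]:
    """Generate one synthetic dataset; deterministic given ``config.seed``.

    Returns the measured background growth rates, the measured
    (reference-normalized) effects of the analyzed mutations, and the
    ground truth.  All random draws flow from a single seeded stream.
    """
    config = GeneratorConfig() if config is None else config
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_ref, n_mut = config.n_reference, config.n_analyzed
    mutations = [f"mut{i + 1:03d}" for i in range(n_mut)]
    references = [f"ref{i + 1:02d}" for i in range(n_ref)]
    strains = [f"strain{i + 1:02d}" for i in range(config.n_strains)]
    environments = [f"env{j + 1}" for j in range(config.n_environments)]
    pivots = config.resolved_pivots()
    intervals = config.resolved_intervals()

    # true background growth rates: uniform on an environment-specific interval
    lam_true = np.column_stack([
        rng.uniform(lo, hi, size=config.n_strains) for lo, hi in intervals
    ])  # (strain, environment)

    slopes = _draw_slopes(config, rng)                             # (mut,)
    eta = config.sigma_eta * rng.standard_normal((n_mut, len(environments)))
    xi = config.sigma_xi * rng.standard_normal((n_mut, config.n_strains,
                                                len(environments)))
    # noise-free effects, (mut, strain, env)
    lam_centered = lam_true[None, :, :] - pivots[None, None, :]
    true_eff = slopes[:, None, None] * lam_centered + eta[:, None, :] + xi

    eps_mut = config.sigma_meas * rng.standard_normal(true_eff.shape)
    eps_ref = config.sigma_meas * rng.standard_normal(
        (n_ref, config.n_strains, len(environments)))
    lam_noise = config.sigma_meas * rng.standard_normal(lam_true.shape)

    # neutral-reference normalization: subtract the reference-set mean
    # measured effect within each strain x environment
    ref_mean = eps_ref.mean(axis=0)                                # (strain, env)
    measured = true_eff + eps_mut - ref_mean[None, :, :]
    ref_adjusted = eps_ref - ref_mean[None, :, :]
    se_eff = config.sigma_meas * np.sqrt(1.0 + 1.0 / n_ref)

    midx = pd.MultiIndex.from_product(
        [mutations, strains, environments],
        names=["mutation", "strain", "environment"])
    effects = pd.DataFrame({
        "mutation": midx.get_level_values(0),
        "strain": midx.get_level_values(1),
        "environment": midx.get_level_values(2),
        "value": measured.ravel(),
        "se": se_eff,
    })
    effect_table = EffectTable(effects)
    if config.missing_fraction > 0:
        effect_table = apply_missingness(
            effect_table, config.missing_fraction,
            seed=int(rng.integers(2 ** 31)))

    gidx = pd.MultiIndex.from_product([strains, environments],
                                      names=["strain", "environment"])
    growth_table = GrowthRateTable(pd.DataFrame({
        "strain": gidx.get_level_values(0),
        "environment": gidx.get_level_values(1),
        "value": (lam_true + lam_noise).ravel(),
        "se": config.sigma_meas,
    }))

    ridx = pd.MultiIndex.from_product(
        [references, strains, environments],
        names=["mutation", "strain", "environment"])
    truth = GroundTruth(
        slopes=pd.Series(
            np.concatenate([slopes, np.zeros(n_ref)]),
            index=pd.Index(mutations + references, name="mutation"),
            name="slope"),
        pivots=pd.Series(pivots, index=pd.Index(environments, name="environment"),
                         name="pivot"),
        eta=pd.DataFrame({
            "mutation": np.repeat(mutations, len(environments)),
            "environment": np.tile(environments, n_mut),
            "eta": eta.ravel(),
        }),
        effects=pd.DataFrame({
            "mutation": midx.get_level_values(0),
            "strain": midx.get_level_values(1),
            "environment": midx.get_level_values(2),
            "true_effect": true_eff.ravel(),
            "xi": xi.ravel(),
            "meas_noise": eps_mut.ravel(),
        }),
        growth=pd.DataFrame({
            "strain": gidx.get_level_values(0),
            "environment": gidx.get_level_values(1),
            "true_rate": lam_true.ravel(),
        }),
        reference_mutations=references,
        reference_effects=pd.DataFrame({
            "mutation": ridx.get_level_values(0),
            "strain": ridx.get_level_values(1),
            "environment": ridx.get_level_values(2),
            "value": ref_adjusted.ravel(),
        }),
        config=config,
    )
    return growth_table, effect_table, truth


def apply_missingness(table: EffectTable, fraction: float, seed: int) -> EffectTable:
    """Set each effect entry to missing independently with probability
    ``fraction`` (missing completely at random); reproducible under
    ``seed``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError(f"missing_fraction must lie in [0, 1], got {fraction!r}")
    data = table.data.copy()
    if fraction > 0:
        rng = np.random.default_rng(seed)
        drop = rng.random(len(data)) < fraction
        data.loc[drop, "value"] = np.nan
    return EffectTable(data)
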