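"""Generator and pipeline configuration.

The synthetic-data generator is parameterized by :class:`GeneratorConfig`.
Its defaults describe a barcoded insertion-mutation assay: ~99 mutations
(5 of them a putatively neutral reference), 42 background strains, 6
environments, per-mutation global-epistasis slopes around -0.5, pivot
growth rates spread over 0.25-0.45 h^-1, pivot noise of 1.7e-2 h^-1,
idiosyncratic epistasis of 1.0e-2 h^-1 and measurement error of 7e-3 h^-1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = ["ConfigError", "GeneratorConfig"]

_SLOPE_FAMILIES = ("normal", "truncnorm")


class ConfigError(ValueError):
    """A configuration field is invalid; the message names the field."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic mutation-effect dataset.

    All rates are in units of h^-1.  ``n_mutations_total - n_reference``
    mutations are "analyzed"; the reference set defines the zero point of
    the measured effects (neutral-reference normalization).

    Parameters
    ----------
    slope_distribution
        Parametric family of the true per-mutation slopes ``b_m``:
        ``"normal"`` (mean ``mu_b_true``, SD ``sigma_b_true``) or
        ``"truncnorm"`` (same, truncated above at ``slope_upper``).
    pivot_rates
        True pivot growth rate per environment.  ``None`` means
        ``n_environments`` values evenly spread over [0.25, 0.45].
    strain_rate_intervals
        Per-environment ``(low, high)`` interval of the uniform
        distribution of true background growth rates.  ``None`` means
        ``(pivot_e - 0.15, pivot_e + 0.10)`` so that strains straddle the
        pivot and rank orders reshuffle across environments.
    """

    n_mutations_total: int = 99
    n_reference: int = 5
    n_strains: int = 42
    n_environments: int = 6
    slope_distribution: str = "normal"
    mu_b_true: float = -0.5
    sigma_b_true: float = 0.3
    slope_upper: float | None = None
    pivot_rates: Sequence[float] | None = None
    sigma_eta: float = 1.7e-2
    sigma_xi: float = 1.0e-2
    sigma_meas: float = 7e-3
    strain_rate_intervals: Sequence[Sequence[float]] | None = None
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        for name in ("n_mutations_total", "n_reference", "n_strains", "n_environments"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        if self.n_reference >= self.n_mutations_total:
            raise ConfigError(
                "n_reference must be smaller than n_mutations_total "
                f"({self.n_reference} >= {self.n_mutations_total})"
            )
        if self.slope_distribution not in _SLOPE_FAMILIES:
            raise ConfigError(
                f"slope_distribution must be one of {_SLOPE_FAMILIES}, "
                f"got {self.slope_distribution!r}"
            )
        for name in ("sigma_b_true", "sigma_eta", "sigma_xi", "sigma_meas"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ConfigError(
                f"missing_fraction must lie in [0, 1], got {self.missing_fraction!r}"
            )
        if self.pivot_rates is not None and len(self.pivot_rates) != self.n_environments:
            raise ConfigError(
                f"pivot_rates must have n_environments={self.n_environments} entries, "
                f"got {len(self.pivot_rates)}"
            )
        if self.strain_rate_intervals is not None:
            if len(self.strain_rate_intervals) != self.n_environments:
                raise ConfigError(
                    "strain_rate_intervals must have n_environments="
                    f"{self.n_environments} entries, got {len(self.strain_rate_intervals)}"
                )
            for lohi in self.strain_rate_intervals:
                if len(lohi) != 2 or not lohi[0] < lohi[1]:
                    raise ConfigError(
                        f"strain_rate_intervals entries must be (low, high) with low < high, got {lohi!r}"
                    )
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")

    # -- derived quantities -------------------------------------------

    @property
    def n_analyzed(self) -> int:
        return self.n_mutations_total - self.n_reference

    def resolved_pivots(self) -> np.ndarray:
        if self.pivot_rates is not None:
            return np.asarray(self.pivot_rates, dtype=float)
        return np.linspace(0.25, 0.45, self.n_environments)

    def resolved_intervals(self) -> np.ndarray:
        if self.strain_rate_intervals is not None:
            return np.asarray(self.strain_rate_intervals, dtype=float)
        pivots = self.resolved_pivots()
        return np.column_stack([pivots - 0.15, pivots + 0.10])

    # -- (de)serialization --------------------------------------------

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if out["pivot_rates"] is not None:
            out["pivot_rates"] = [float(x) for x in out["pivot_rates"]]
        if out["strain_rate_intervals"] is not None:
            out["strain_rate_intervals"] = [
                [float(a), float(b)] for a, b in out["strain_rate_intervals"]
            ]
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        """Load a config from YAML or JSON (decided by file suffix)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"configuration file {path} does not contain a mapping")
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
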