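"""Tidy data tables for growth rates and mutation effects.

Both tables are long-format pandas DataFrames: one row per measurement,
growth rates keyed by (strain, environment) and mutation effects keyed by
(mutation, strain, environment).  Values and standard errors are in h^-1.
A missing effect measurement is a row whose ``value`` is NaN (written as
an empty CSV field); missingness is first-class, not silently dropped.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TableFormatError", "GrowthRateTable", "EffectTable"]

GROWTH_COLUMNS = ("strain", "environment", "value", "se")
EFFECT_COLUMNS = ("mutation", "strain", "environment", "value", "se")


class TableFormatError(ValueError):
    """A table violates its schema; the message names the offending rows."""


def _validate(df: pd.DataFrame, columns: tuple, key_cols: list[str], *,
              allow_missing: bool, source: str | None) -> pd.DataFrame:
    where = f" in {source}" if source else ""
    missing_cols = [c for c in columns if c not in df.columns]
    if missing_cols:
        raise TableFormatError(f"missing required columns {missing_cols}{where}")
    df = df.loc[:, list(columns)].copy()
    for c in key_cols:
        df[c] = df[c].astype(str)
    for c in ("value", "se"):
        df[c] = pd.to_numeric(df[c], errors="raise")

    dup = df.duplicated(subset=key_cols)
    if dup.any():
        # +2: CSV data starts on line 2 (header is line 1)
        rows = (df.index[dup] + 2).tolist()
        raise TableFormatError(f"duplicate {tuple(key_cols)} keys at rows {rows}{where}")

    bad_se = df["se"].notna() & (df["se"] < 0)
    if bad_se.any():
        rows = (df.index[bad_se] + 2).tolist()
        raise TableFormatError(f"negative standard errors at rows {rows}{where}")

    if not allow_missing and df["value"].isna().any():
        rows = (df.index[df["value"].isna()] + 2).tolist()
        raise TableFormatError(f"missing growth-rate values at rows {rows}{where}")
    return df.reset_index(drop=True)


@dataclass
class GrowthRateTable:
    """Background growth rates lambda_ge with standard errors."""

    data: pd.DataFrame
    _source: str | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.data = _validate(self.data, GROWTH_COLUMNS, ["strain", "environment"],
                              allow_missing=False, source=self._source)

    @property
    def strains(self) -> list[str]:
        return sorted(self.data["strain"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.data["environment"].unique())

    def rates(self) -> pd.Series:
        """Growth rate indexed by (strain, environment)."""
        return self.data.set_index(["strain", "environment"])["value"]

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "GrowthRateTable":
        return cls(pd.read_csv(path, dtype={"strain": str, "environment": str}),
                   _source=str(path))


@dataclass
class EffectTable:
    """Mutation growth-rate effects dlambda_mge with standard errors.

    Rows with NaN ``value`` are missing measurements and are excluded by
    :meth:`observed`.
    """

    data: pd.DataFrame
    _source: str | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.data = _validate(self.data, EFFECT_COLUMNS,
                              ["mutation", "strain", "environment"],
                              allow_missing=True, source=self._source)

    @property
    def mutations(self) -> list[str]:
        return sorted(self.data["mutation"].unique())

    @property
    def strains(self) -> list[str]:
        return sorted(self.data["strain"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.data["environment"].unique())

    @property
    def n_missing(self) -> int:
        return int(self.data["value"].isna().sum())

    def observed(self) -> pd.DataFrame:
        """The non-missing rows."""
        return self.data[self.data["value"].notna()].reset_index(drop=True)

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "EffectTable":
        return cls(pd.read_csv(path, dtype={"mutation": str, "strain": str,
                                            "environment": str}),
                   _source=str(path))
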