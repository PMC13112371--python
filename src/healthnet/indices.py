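"""Composite health-index construction.

A city-year indicator panel (hospital counts, practicing physicians,
hospital beds, per-capita health expenditure, GDP) is min-max standardized
with declared indicator directions, weighted by the entropy-weight method,
and collapsed into the per-city Urban Health Index

    UHI_i(t) = sum_j w_j * x'_ij(t),

the mass term of the inter-city gravity model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Default direction tags for the five city-level indicators. ``+1`` means
#: "more is better" (standardized as (x-min)/(max-min)); ``-1`` reverses.
DEFAULT_DIRECTIONS: dict[str, int] = {
    "hospitals": 1,
    "physicians": 1,
    "beds": 1,
    "health_expenditure_per_capita": -1,
    "gdp": 1,
}


class ConstantColumnWarning(UserWarning):
    """An indicator had no variation in the standardization scope."""


@dataclass
class IndicatorPanel:
    """City x year x indicator panel with direction tags.

    Parameters
    ----------
    values
        DataFrame indexed by a (city, year) MultiIndex, one column per
        indicator. Every city-year cell must be present and non-missing.
    directions
        Per-indicator direction tag, ``+1`` or ``-1``.
    membership
        Series mapping each city to its agglomeration.
    standardized
        True once the panel holds min-max standardized values in [0, 1].
    """

    values: pd.DataFrame
    directions: dict[str, int]
    membership: pd.Series
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.values.empty:
            raise ValueError("indicator panel is empty")
        if self.values.index.nlevels != 2:
            raise ValueError("panel must be indexed by (city, year)")
        self.values.index = self.values.index.set_names(["city", "year"])
        if self.values.isna().any().any():
            raise ValueError("panel contains missing city-year cells")
        missing = set(self.values.columns) - set(self.directions)
        if missing:
            raise ValueError(f"no direction declared for indicators {sorted(missing)}")
        bad = {j: d for j, d in self.directions.items()
               if j in self.values.columns and d not in (1, -1)}
        if bad:
            raise ValueError(f"directions must be +1 or -1, got {bad}")
        cities = self.values.index.get_level_values("city").unique()
        unmapped = set(cities) - set(self.membership.index)
        if unmapped:
            raise ValueError(f"cities without agglomeration membership: {sorted(unmapped)}")
        # reject ragged panels: every city must cover every year
        n_cells = len(self.values)
        if n_cells != len(cities) * self.values.index.get_level_values("year").nunique():
            raise ValueError("panel is ragged: not every city covers every year")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate city-year rows in panel")

    # -- convenience views ------------------------------------------------
    @property
    def cities(self) -> list[str]:
        return list(self.values.index.get_level_values("city").unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.values.index.get_level_values("year").unique())

    @property
    def indicators(self) -> list[str]:
        return list(self.values.columns)

    @property
    def agglomerations(self) -> list[str]:
        return list(pd.unique(self.membership))

    def cities_of(self, agglomeration: str) -> list[str]:
        return [c for c in self.cities if self.membership[c] == agglomeration]

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame with city, agglomeration and year as columns."""
        out = self.values.reset_index()
        out.insert(1, "agglomeration", out["city"].map(self.membership))
        return out


@dataclass(frozen=True)
class WeightVector:
    """Nonnegative per-indicator weights summing to one."""

    weights: pd.Series
    method: str

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(float)
        if (w < -1e-12).any():
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum():.12f}")


def _minmax(block: pd.DataFrame, directions: dict[str, int]) -> pd.DataFrame:
    lo, hi = block.min(axis=0), block.max(axis=0)
    span = hi - lo
    out = pd.DataFrame(index=block.index, columns=block.columns, dtype=float)
    for col in block.columns:
        if span[col] == 0:
            warnings.warn(
                f"indicator '{col}' is constant in its standardization scope; "
                "mapped to 0.5", ConstantColumnWarning, stacklevel=3)
            out[col] = 0.5
        elif directions[col] > 0:
            out[col] = (block[col] - lo[col]) / span[col]
        else:
            out[col] = (hi[col] - block[col]) / span[col]
    return out


def standardize_panel(panel: IndicatorPanel, scope: str = "pooled") -> IndicatorPanel:
    """Min-max standardize a panel to [0, 1] honouring indicator directions.

    ``scope="pooled"`` (default) takes each indicator's min/max over all
    city-years, preserving between-year dynamics; ``scope="per_year"``
    standardizes within each year across cities, making values comparable
    only within a year. Constant columns map to 0.5 with a warning.
    """
    if scope not in ("pooled", "per_year"):
        raise ValueError(f"unknown standardization scope {scope!r}")
    if scope == "pooled":
        std = _minmax(panel.values, panel.directions)
    else:
        parts = [
            _minmax(block, panel.directions)
            for _, block in panel.values.groupby(level="year", sort=True)
        ]
        std = pd.concat(parts).loc[panel.values.index]
    return replace(panel, values=std, standardized=True)


def entropy_weights(standardized: IndicatorPanel) -> WeightVector:
    """Entropy-weight method on a standardized panel.

    With rows i (city-years) and indicators j: shares
    p_ij = x'_ij / sum_i x'_ij, entropy e_j = -(1/ln n) sum_i p_ij ln p_ij
    (taking 0*ln 0 = 0), divergence d_j = 1 - e_j and weights
    w_j = d_j / sum d_j. Indicators with no information (constant or
    all-zero columns) get weight 0.
    """
    x = standardized.values.to_numpy(float)
    if not standardized.standardized:
        if ((x < -1e-12) | (x > 1 + 1e-12)).any():
            raise ValueError("entropy weights require a standardized panel in [0, 1]")
    n = x.shape[0]
    col_sums = x.sum(axis=0)
    e = np.ones(x.shape[1])
    ok = col_sums > 0
    if not ok.all():
        bad = [c for c, good in zip(standardized.indicators, ok) if not good]
        warnings.warn(
            f"all-zero standardized columns {bad}: entropy set to 1 (weight 0)",
            ConstantColumnWarning, stacklevel=2)
    p = np.zeros_like(x)
    p[:, ok] = x[:, ok] / col_sums[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    e[ok] = -plogp[:, ok].sum(axis=0) / np.log(n)
    d = 1.0 - e
    d = np.clip(d, 0.0, None)  # guard tiny negative round-off
    if d.sum() <= 0:
        raise ValueError("no indicator carries information; entropy weights undefined")
    w = pd.Series(d / d.sum(), index=standardized.indicators)
    return WeightVector(weights=w, method="entropy")


def uniform_weights(indicators: list[str]) -> WeightVector:
    """Equal weights — the fixed-weight fallback exposed in config."""
    n = len(indicators)
    return WeightVector(pd.Series(1.0 / n, index=list(indicators)), method="fixed")


def compute_uhi(standardized: IndicatorPanel, weights: WeightVector) -> pd.Series:
    """Urban Health Index UHI_i(t) = sum_j w_j x'_ij(t).

    Returns a Series named ``uhi`` indexed by (city, year); bounded in
    [0, 1] when the panel is min-max standardized.
    """
    if set(weights.weights.index) != set(standardized.indicators):
        raise ValueError(
            "weight vector does not cover exactly the panel's indicators: "
            f"{sorted(weights.weights.index)} vs {sorted(standardized.indicators)}")
    w = weights.weights.reindex(standardized.indicators)
    uhi = standardized.values.to_numpy(float) @ w.to_numpy(float)
    return pd.Series(uhi, index=standardized.values.index, name="uhi")


def uhi_wide(uhi: pd.Series) -> pd.DataFrame:
    """Pivot a (city, year)-indexed UHI series to a city x year table."""
    return uhi.unstack("year")
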