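"""Regional Health Collaborative Development Index (HCDI).

Indicator weights come from an Analytic Hierarchy Process (AHP) judgment
matrix via the geometric-mean method; per-city composites of the
standardized indicators are aggregated over each agglomeration's member
cities with coefficients alpha_i to yield the agglomeration-year HCDI.

The HCDI indicator set extends the five city-level indicators with three
relational ones: policy support intensity and the inverse mean distance /
travel time to the other member cities of the same agglomeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .indices import IndicatorPanel, WeightVector

#: Saaty's random consistency index, n = 1..10.
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
                6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

#: Relative importance scores behind the default judgment matrix:
#: policy support above the health-resource block, distance/time last.
DEFAULT_IMPORTANCE = {
    "hospitals": 3.0,
    "physicians": 3.0,
    "beds": 3.0,
    "health_expenditure_per_capita": 2.0,
    "gdp": 2.0,
    "policy_intensity": 4.0,
    "inv_mean_distance": 1.5,
    "inv_mean_travel_time": 1.5,
}


class ConsistencyWarning(UserWarning):
    """Judgment matrix failed the CR < 0.1 consistency screen."""


@dataclass(frozen=True)
class AHPResult:
    weights: WeightVector
    lambda_max: float
    consistency_index: float
    consistency_ratio: float


def validate_judgment_matrix(matrix: pd.DataFrame, tol: float = 1e-9) -> np.ndarray:
    a = matrix.to_numpy(float)
    n, m = a.shape
    if n != m:
        raise ValueError("judgment matrix must be square")
    if (a <= 0).any():
        raise ValueError("judgment matrix entries must be strictly positive")
    if np.abs(np.diag(a) - 1.0).max() > tol:
        raise ValueError("judgment matrix must have unit diagonal")
    if np.abs(a * a.T - 1.0).max() > 1e-6:
        raise ValueError("judgment matrix is not reciprocal (a_ij * a_ji != 1)")
    return a


def ratio_matrix(importance: Mapping[str, float]) -> pd.DataFrame:
    """Perfectly consistent judgment matrix a_ij = s_i / s_j from scores."""
    idx = list(importance)
    s = np.array([importance[k] for k in idx], float)
    return pd.DataFrame(np.outer(s, 1.0 / s), index=idx, columns=idx)


def default_judgment_matrix() -> pd.DataFrame:
    return ratio_matrix(DEFAULT_IMPORTANCE)


def ahp_weights(matrix: pd.DataFrame) -> AHPResult:
    """AHP weights by the geometric-mean (row products) method.

    w_i = (prod_j a_ij)^(1/n) normalized; lambda_max from the weighted
    column sums; CI = (lambda_max - n)/(n - 1); CR = CI / RI. CR >= 0.1
    raises a ConsistencyWarning, not an error.
    """
    a = validate_judgment_matrix(matrix)
    n = a.shape[0]
    gm = np.exp(np.log(a).mean(axis=1))
    w = gm / gm.sum()
    lambda_max = float(a.sum(axis=0) @ w)
    ci = (lambda_max - n) / (n - 1) if n > 1 else 0.0
    if n <= 2:
        cr = 0.0
    else:
        if n not in RANDOM_INDEX:
            raise ValueError(f"no random consistency index tabulated for n={n}")
        cr = ci / RANDOM_INDEX[n]
    if cr >= 0.1:
        warnings.warn(f"judgment matrix consistency ratio {cr:.3f} >= 0.1",
                      ConsistencyWarning, stacklevel=2)
    weights = WeightVector(pd.Series(w, index=list(matrix.index)), method="ahp")
    return AHPResult(weights=weights, lambda_max=lambda_max,
                     consistency_index=float(ci), consistency_ratio=float(max(cr, 0.0)))


def relational_indicators(
    distances: Mapping[str, pd.DataFrame],
    travel_times: Mapping[str, pd.DataFrame],
    policy_intensity: pd.DataFrame,
    membership: pd.Series,
    years: list[int],
) -> pd.DataFrame:
    """Relational indicator block, (city, year)-indexed.

    inv_mean_distance and inv_mean_travel_time are 1 / (mean distance or
    travel time to the other cities of the same agglomeration), constant
    over years; policy_intensity is the city-year table from the policy
    module.
    """
    rows = []
    for aggl, dmat in distances.items():
        tmat = travel_times[aggl]
        cities = [c for c in membership.index if membership[c] == aggl]
        for c in cities:
            others = [o for o in cities if o != c]
            inv_d = 1.0 / float(dmat.loc[c, others].mean())
            inv_t = 1.0 / float(tmat.loc[c, others].mean())
            for y in years:
                rows.append({
                    "city": c, "year": y,
                    "policy_intensity": float(policy_intensity.loc[c, y]),
                    "inv_mean_distance": inv_d,
                    "inv_mean_travel_time": inv_t,
                })
    return pd.DataFrame(rows).set_index(["city", "year"])


def build_hcdi_panel(
    panel: IndicatorPanel,
    distances: Mapping[str, pd.DataFrame],
    travel_times: Mapping[str, pd.DataFrame],
    policy_intensity: pd.DataFrame,
) -> IndicatorPanel:
    """Join the city panel with the three relational indicators."""
    rel = relational_indicators(distances, travel_times, policy_intensity,
                                panel.membership, panel.years)
    values = panel.values.join(rel.reindex(panel.values.index))
    directions = dict(panel.directions)
    directions.update({"policy_intensity": 1, "inv_mean_distance": 1,
                       "inv_mean_travel_time": 1})
    return IndicatorPanel(values=values, directions=directions,
                          membership=panel.membership, standardized=False)


def compute_hcdi(
    standardized: IndicatorPanel,
    ahp: AHPResult,
    city_coefficients: pd.Series | None = None,
) -> pd.Series:
    """Agglomeration-year HCDI.

    City composite c_i(t) = sum_j w_j^AHP x'_ij(t); HCDI_region(t) =
    sum_{i in region} alpha_i c_i(t). alpha defaults to uniform 1/n within
    each agglomeration and must sum to 1 per agglomeration.
    """
    w = ahp.weights.weights
    if set(w.index) != set(standardized.indicators):
        raise ValueError("AHP weights do not cover exactly the HCDI panel indicators")
    composites = pd.Series(
        standardized.values.to_numpy(float) @ w.reindex(standardized.indicators).to_numpy(float),
        index=standardized.values.index, name="composite")

    membership = standardized.membership
    if city_coefficients is None:
        counts = membership.value_counts()
        city_coefficients = pd.Series(
            [1.0 / counts[membership[c]] for c in membership.index],
            index=membership.index)
    else:
        missing = set(membership.index) - set(city_coefficients.index)
        if missing:
            raise ValueError(f"alpha coefficients missing for cities {sorted(missing)}")
        if (city_coefficients < 0).any():
            raise ValueError("alpha coefficients must be nonnegative")
        sums = city_coefficients.groupby(membership).sum()
        bad = sums[(sums - 1.0).abs() > 1e-9]
        if len(bad):
            raise ValueError(
                f"alpha coefficients must sum to 1 within each agglomeration; got {bad.to_dict()}")

    frame = composites.reset_index()
    frame["agglomeration"] = frame["city"].map(membership)
    frame["alpha"] = frame["city"].map(city_coefficients)
    frame["weighted"] = frame["alpha"] * frame["composite"]
    hcdi = frame.groupby(["agglomeration", "year"])["weighted"].sum()
    hcdi.name = "hcdi"
    return hcdi
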