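"""Model validation: leave-one-agglomeration-out cross-validation.

Each fold excludes one agglomeration, fits the free gravity constants
(c, gamma, theta; T held at its 2 h default) to the reference gravity of
the remaining agglomerations by log-space least squares, predicts the
excluded agglomeration's gravity, and reports RMSE and R^2 on min-max
normalized values. Log-space residuals are used because gravity spans
orders of magnitude and the reference noise model is multiplicative.

The fit is deterministic: for each theta on a fixed grid the remaining
parameters (ln c, gamma) have a closed-form least-squares solution, and a
bounded scalar refinement polishes theta around the grid optimum.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .gravity import GravityParams, GravityTensor, compute_gravity
from .indices import compute_uhi, entropy_weights, standardize_panel
from .synthetic import SyntheticStudyArea

GAMMA_BOUNDS = (1.0, 2.5)
THETA_BOUNDS = (0.0, 0.9)


@dataclass
class FoldResult:
    held_out: str
    params: GravityParams
    rmse: float
    r2: float

    def to_dict(self) -> dict:
        return {"held_out": self.held_out, "params": asdict(self.params),
                "rmse": self.rmse, "r2": self.r2}


@dataclass
class ValidationReport:
    folds: list[FoldResult]
    seed: int
    n_cities: int
    sensitivity: pd.DataFrame | None = None

    @property
    def worst_rmse(self) -> float:
        return max(f.rmse for f in self.folds)

    @property
    def worst_r2(self) -> float:
        return min(f.r2 for f in self.folds)

    def to_dict(self) -> dict:
        out = {
            "seed": self.seed,
            "n_cities": self.n_cities,
            "folds": [f.to_dict() for f in self.folds],
            "worst_rmse": self.worst_rmse,
            "worst_r2": self.worst_r2,
        }
        if self.sensitivity is not None:
            out["sensitivity"] = self.sensitivity.to_dict(orient="records")
            out["sensitivity_max_pct"] = self.sensitivity.attrs.get("max_pct")
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def summary(self) -> str:
        lines = [f"LOOCV over {len(self.folds)} agglomerations "
                 f"({self.n_cities} cities, seed {self.seed})"]
        for f in self.folds:
            lines.append(
                f"  held out {f.held_out}: rmse={f.rmse:.4f} r2={f.r2:.4f} "
                f"(c={f.params.c:.3f}, gamma={f.params.gamma:.3f}, "
                f"theta={f.params.theta:.3f})")
        lines.append(f"  worst fold: rmse={self.worst_rmse:.4f} r2={self.worst_r2:.4f}")
        return "\n".join(lines)


def _pair_arrays(uhi: pd.Series, tensor: GravityTensor,
                 distances: pd.DataFrame, travel_times: pd.DataFrame):
    """Stack per-pair-year observations: ln Gref, ln(UiUj), ln d, dt, min/max."""
    cities = tensor.cities
    wide = uhi.unstack("year").loc[cities].sort_index(axis=1)
    u = wide.to_numpy(float)
    d = distances.loc[cities, cities].to_numpy(float)
    dt = travel_times.loc[cities, cities].to_numpy(float)
    iu, ju = np.triu_indices(len(cities), k=1)
    ln_ref, ln_mass, ln_d, dts, ratios = [], [], [], [], []
    for k in range(len(tensor.years)):
        ref = tensor.values[k][iu, ju]
        if (ref <= 0).any():
            raise ValueError("reference gravity must be strictly positive off-diagonal")
        ui, uj = u[iu, k], u[ju, k]
        ln_ref.append(np.log(ref))
        ln_mass.append(np.log(ui * uj))
        ln_d.append(np.log(d[iu, ju]))
        dts.append(dt[iu, ju])
        ratios.append(np.minimum(ui, uj) / np.maximum(ui, uj))
    return tuple(np.concatenate(a) for a in (ln_ref, ln_mass, ln_d, dts, ratios))


def fit_gravity_params(
    uhi: pd.Series,
    reference: Mapping[str, GravityTensor],
    distances: Mapping[str, pd.DataFrame],
    travel_times: Mapping[str, pd.DataFrame],
    train: Sequence[str],
    T: float = 2.0,
    theta_grid: int = 46,
) -> GravityParams:
    """Fit (c, gamma, theta) to reference gravity by log-space least squares.

    gamma is constrained to [1.0, 2.5] and theta to [0, 0.9]; T is held
    fixed. For each theta the residual is linear in (ln c, gamma), so the
    profile objective is minimized on a fixed grid then refined with a
    bounded scalar search — deterministic by construction.
    """
    if not train:
        raise ValueError("training set is empty")
    parts = [_pair_arrays(uhi, reference[a], distances[a], travel_times[a])
             for a in train]
    ln_ref, ln_mass, ln_d, dts, ratio = (
        np.concatenate([p[i] for p in parts]) for i in range(5))
    ld_var = ln_d.var()

    def profile_sse(theta: float) -> tuple[float, float, float]:
        # z = ln c - gamma * ln d  (everything else moved to the left side)
        z = ln_ref - ln_mass + dts / T - np.log1p(-theta * ratio)
        if ld_var > 0:
            gamma = -np.cov(z, ln_d, bias=True)[0, 1] / ld_var
        else:
            gamma = GravityParams().gamma
        gamma = float(np.clip(gamma, *GAMMA_BOUNDS))
        a = float(np.mean(z + gamma * ln_d))
        resid = z - (a - gamma * ln_d)
        return float(resid @ resid), gamma, a

    grid = np.linspace(*THETA_BOUNDS, theta_grid)
    sse = np.array([profile_sse(t)[0] for t in grid])
    k = int(np.argmin(sse))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(lambda t: profile_sse(t)[0], bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-10})
    theta = float(res.x) if res.fun <= sse[k] else float(grid[k])
    _, gamma, a = profile_sse(theta)
    return GravityParams(c=float(np.exp(a)), gamma=gamma, T=T, theta=theta)


def normalized_rmse_r2(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    """RMSE and R^2 after min-max normalizing both arrays by the reference range."""
    lo, hi = ref.min(), ref.max()
    span = hi - lo
    if span == 0:
        raise ValueError("reference gravity has zero range; normalization undefined")
    p = (pred - lo) / span
    r = (ref - lo) / span
    resid = p - r
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = float(1.0 - np.sum(resid ** 2) / ss_tot)
    return rmse, r2


def loocv(study: SyntheticStudyArea, T: float = 2.0) -> ValidationReport:
    """Leave-one-agglomeration-out cross-validation of the gravity model."""
    aggls = [a.name for a in study.spec.agglomerations]
    if len(aggls) < 2:
        raise ValueError("LOOCV requires at least 2 agglomerations")
    std = standardize_panel(study.panel, scope="pooled")
    uhi = compute_uhi(std, entropy_weights(std))
    membership = study.panel.membership

    folds = []
    for held in aggls:
        train = [a for a in aggls if a != held]
        fitted = fit_gravity_params(uhi, study.reference_gravity,
                                    study.distances, study.travel_times,
                                    train, T=T)
        cities = [c for c in membership.index if membership[c] == held]
        sub = uhi.loc[uhi.index.get_level_values("city").isin(cities)]
        pred = compute_gravity(sub, study.distances[held],
                               study.travel_times[held], fitted)
        ref = study.reference_gravity[held]
        # align city order before comparing pair values
        order = [pred.cities.index(c) for c in ref.cities]
        pred_vals = pred.values[:, order][:, :, order]
        iu = np.triu_indices(len(ref.cities), k=1)
        p = np.concatenate([pred_vals[k][iu] for k in range(len(ref.years))])
        r = ref.pair_values()
        rmse, r2 = normalized_rmse_r2(p, r)
        folds.append(FoldResult(held_out=held, params=fitted, rmse=rmse, r2=r2))
    return ValidationReport(folds=folds, seed=study.spec.seed,
                            n_cities=study.spec.n_cities_total)
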