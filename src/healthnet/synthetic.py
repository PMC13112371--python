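"""Synthetic study areas with planted statistical structure.

The study design this package targets — four urban agglomerations of
13/26/9/16 cities observed 2005-2023 — comes from statistical yearbooks
that are not machine-readable, so every downstream stage is exercised on
synthetic study areas that emulate the features the analysis assumes:

* rising indicator trajectories 2005-2019 with a multiplicative shock dip
  on the health-resource indicators at the shock year (2020);
* core cities with elevated indicator levels;
* compact lognormal intra-agglomeration distances (median 50 km, log-sd
  0.35) with travel time = distance / speed + small uniform noise;
* a policy pulse (elevated document counts) in 2015-2016;
* a noisy "reference" gravity tensor — the ground-truth gravity equation
  times multiplicative lognormal noise — giving the cross-validation
  stage a recoverable signal in place of unpublished patient-flow data.

:func:`plant_structure` additionally plants one of the four network
archetypes. City trajectories follow a lognormal factor construction
``value = base_j * size_i * multiplier_i * exp(rho*g(t) + xi*b_i(t))``
where ``g`` is a shared trend-shaped pattern and the ``b_i`` are
idiosyncratic patterns constructed sample-orthogonal to ``g`` and to each
other. The amplitudes are chosen analytically so that node-strength
correlations land on the intended side of the default edge threshold
(hub-periphery ~0.69-0.82, periphery-periphery ~0.48-0.68), which makes
archetype recovery by the network classifier near-deterministic on
noise-free data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import policy as policy_mod
from .gravity import GravityParams, GravityTensor, compute_gravity_study
from .indices import (DEFAULT_DIRECTIONS, IndicatorPanel, compute_uhi,
                      entropy_weights, standardize_panel)

#: Indicative indicator scales (arbitrary but realistic orders of magnitude).
INDICATOR_BASES = {
    "hospitals": 120.0,
    "physicians": 3.0e4,
    "beds": 5.0e4,
    "health_expenditure_per_capita": 2500.0,
    "gdp": 6000.0,
}
#: Indicators hit by the shock-year dip.
HEALTH_RESOURCE_INDICATORS = ("hospitals", "physicians", "beds")

ARCHETYPES = ("unipolar", "polycentric", "core_periphery", "dual_core_segmented")

# Planted-pattern amplitudes: relative sd of the shared trend component
# (rho) and of each city's idiosyncratic component (xi). For the star-like
# archetypes the hub edge dominates every periphery city's strength series
# (hub multiplier x close hub geography), so the strength deviation of
# periphery i is ~ c_i*(rho*g + xi_i*b_i) + q*rho*g and, with
# sample-orthogonal patterns, r(hub, i) ~ 1/sqrt(1+u_i^2) and
# r(i, j) ~ r(hub, i)*r(hub, j) for u_i = c_i*xi_i/(rho*(c_i+q)).
#
# A single xi cannot keep ALL periphery pairs below the edge threshold
# while keeping all hub edges above it (r_pp is the product of the two hub
# correlations), so the periphery is split into two strata: "upper" cities
# (elevated level, large wiggles) whose every non-hub correlation sits
# safely below tau — they are the only cities that could spuriously pass
# the above-median-UHI hub test — and "lower" cities (depressed level,
# small wiggles) forming a moderately connected mat that lifts the C_D
# percentile cut above any accidental upper-city edges. The polycentric
# fabric instead uses one moderate xi so that most (not all) periphery
# pairs stay connected.
# Amplitudes are kept small: the correlation geometry is invariant to the
# overall pattern scale, but the min-max floor makes low-level cities'
# UHI a convex function of the planted log-pattern, and that distortion
# (which leaks covariance across city pairs) grows with amplitude.
#
# Per-archetype (xi_upper, xi_lower) wiggle amplitudes. In the star-like
# archetypes the upper stratum are near-loners (large wiggles) and the
# lower stratum a moderately connected mat; the polycentric fabric flips
# this — the elevated stratum is the dense, tightly co-moving mat whose
# members all qualify as comparable hubs, while depressed loners keep the
# graph incomplete so the degree percentile stays below the mat. The
# core-periphery amplitudes are larger because its two adjacent cores
# double the shared-factor loading in every strength series.
_RHO = 0.08
_XI = {"unipolar": (0.16, 0.105),
       "core_periphery": (0.24, 0.16),
       "dual_core_segmented": (0.16, 0.07),
       "polycentric": (0.08, 0.17)}
_UPPER_LEVEL = 1.15
_LOWER_LEVEL = 0.85
_HUB_MULT = {"unipolar": 3.0, "polycentric": 2.0,
             "core_periphery": 2.5, "dual_core_segmented": 2.5}
_PERIPHERY_SIZE_SD = 0.05
# Planted geography (distance scale factors): hubs sit centrally among
# their periphery; in the segmented archetype the two camps are far apart.
_HUB_PERIPHERY_DISTANCE = 0.5
_PERIPHERY_PERIPHERY_DISTANCE = 2.0
_DUAL_CORE_CROSS_DISTANCE = 3.0   # spatial segmentation between the two camps
_CORE_PERIPHERY_CORE_DISTANCE = 0.4  # the two cores are adjacent


class SpecValidationError(ValueError):
    """Invalid study-area specification; ``field`` names the offender."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class AgglomerationSpec:
    name: str
    n_cities: int
    n_core_cities: int


DEFAULT_AGGLOMERATIONS = (
    AgglomerationSpec("BTH", 13, 1),
    AgglomerationSpec("YRD", 26, 3),
    AgglomerationSpec("PRD", 9, 2),
    AgglomerationSpec("CY", 16, 2),
)


@dataclass(frozen=True)
class StudyAreaSpec:
    """Parameters of a synthetic study area (defaults mirror the study design)."""

    agglomerations: tuple[AgglomerationSpec, ...] = DEFAULT_AGGLOMERATIONS
    years: tuple[int, int] = (2005, 2023)   # inclusive
    seed: int = 0
    distance_median_km: float = 50.0
    distance_log_sd: float = 0.35
    travel_speed_kmh: float = 150.0
    travel_time_noise_h: float = 0.1
    shock_year: int | None = 2020
    policy_pulse_years: frozenset[int] = frozenset({2015, 2016})
    noise_sd: float = 0.03              # lognormal sd of the reference gravity
    core_multiplier: float = 2.5        # indicator elevation of core cities
    shock_factor: float = 0.9           # dip on health-resource indicators
    trend_growth: float = 0.04          # annual indicator growth in expectation
    city_size_sd: float = 0.3           # lognormal sd of city size effects
    city_wiggle_sd: float = 0.05        # city-year idiosyncratic variation
    indicator_noise_sd: float = 0.05    # per-cell measurement noise

    def validate(self) -> None:
        if not self.agglomerations:
            raise SpecValidationError("agglomerations", "at least one agglomeration required")
        names = [a.name for a in self.agglomerations]
        if len(set(names)) != len(names):
            raise SpecValidationError("agglomerations", "agglomeration names must be unique")
        for a in self.agglomerations:
            if a.n_cities < 1:
                raise SpecValidationError("agglomerations", f"{a.name}: n_cities must be >= 1")
            if not 1 <= a.n_core_cities <= a.n_cities:
                raise SpecValidationError(
                    "agglomerations",
                    f"{a.name}: n_core_cities must be in [1, n_cities]")
        lo, hi = self.years
        if hi - lo + 1 < 3:
            raise SpecValidationError("years", "study period must span at least 3 years")
        for name in ("distance_median_km", "distance_log_sd", "travel_speed_kmh",
                     "core_multiplier", "shock_factor"):
            if getattr(self, name) <= 0:
                raise SpecValidationError(name, "must be > 0")
        for name in ("travel_time_noise_h", "noise_sd", "city_size_sd",
                     "city_wiggle_sd", "indicator_noise_sd"):
            if getattr(self, name) < 0:
                raise SpecValidationError(name, "must be >= 0")
        # a shock_year outside the study period simply has no effect

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def n_cities_total(self) -> int:
        return sum(a.n_cities for a in self.agglomerations)


@dataclass
class SyntheticStudyArea:
    """A generated study area: panel, geography, policies, truth, reference."""

    spec: StudyAreaSpec
    panel: IndicatorPanel
    distances: dict[str, pd.DataFrame]
    travel_times: dict[str, pd.DataFrame]
    policies: policy_mod.PolicyCorpus
    truth: dict
    reference_gravity: dict[str, GravityTensor]


# --------------------------------------------------------------------------
# building blocks

def _city_names(aggl: AgglomerationSpec) -> list[str]:
    return [f"{aggl.name}-{i + 1:02d}" for i in range(aggl.n_cities)]


def _trend_path(spec: StudyAreaSpec, with_shock: bool) -> np.ndarray:
    years = np.array(spec.year_list)
    path = (1.0 + spec.trend_growth) ** (years - years[0])
    if with_shock and spec.shock_year is not None:
        path = np.where(years >= spec.shock_year, path * spec.shock_factor, path)
    return path


def _distance_matrix(n: int, spec: StudyAreaSpec, rng: np.random.Generator) -> np.ndarray:
    d = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    d[iu] = np.exp(rng.normal(np.log(spec.distance_median_km),
                              spec.distance_log_sd, size=len(iu[0])))
    return d + d.T


def _travel_times(d: np.ndarray, spec: StudyAreaSpec, rng: np.random.Generator) -> np.ndarray:
    n = d.shape[0]
    t = d / spec.travel_speed_kmh
    iu = np.triu_indices(n, k=1)
    noise = rng.uniform(0.0, spec.travel_time_noise_h, size=len(iu[0])) \
        if spec.travel_time_noise_h > 0 else 0.0
    upper = np.zeros_like(d)
    upper[iu] = noise
    t = t + upper + upper.T
    np.fill_diagonal(t, 0.0)
    return t


def _policies(spec: StudyAreaSpec, cities_by_aggl: dict[str, list[str]],
              rng: np.random.Generator) -> policy_mod.PolicyCorpus:
    docs: list[policy_mod.PolicyDocument] = []
    levels = np.array(["national", "provincial", "municipal"])
    level_p = np.array([0.15, 0.35, 0.50])
    specificities = np.array(["detailed", "general"])
    spec_p = np.array([0.4, 0.6])
    for aggl, cities in cities_by_aggl.items():
        for year in spec.year_list:
            lam = 6.0 if year in spec.policy_pulse_years else 1.5
            for _ in range(int(rng.poisson(lam))):
                k = int(rng.integers(1, min(5, len(cities)) + 1))
                scope = rng.choice(cities, size=k, replace=False)
                docs.append(policy_mod.PolicyDocument(
                    year=year,
                    level=str(rng.choice(levels, p=level_p)),
                    specificity=str(rng.choice(specificities, p=spec_p)),
                    scope=frozenset(str(c) for c in scope)))
    return policy_mod.PolicyCorpus(docs)


def _reference_gravity(spec: StudyAreaSpec, panel: IndicatorPanel,
                       distances: dict[str, pd.DataFrame],
                       travel_times: dict[str, pd.DataFrame],
                       params: GravityParams,
                       rng: np.random.Generator) -> dict[str, GravityTensor]:
    std = standardize_panel(panel, scope="pooled")
    uhi = compute_uhi(std, entropy_weights(std))
    truth = compute_gravity_study(uhi, panel.membership, distances, travel_times, params)
    noisy: dict[str, GravityTensor] = {}
    for aggl, tensor in truth.items():
        vals = tensor.values.copy()
        n = len(tensor.cities)
        iu = np.triu_indices(n, k=1)
        for k in range(len(tensor.years)):
            eps = np.zeros((n, n))
            if spec.noise_sd > 0:
                eps[iu] = rng.normal(0.0, spec.noise_sd, size=len(iu[0]))
                eps = eps + eps.T
            vals[k] = vals[k] * np.exp(eps)
            np.fill_diagonal(vals[k], 0.0)
        noisy[aggl] = GravityTensor(tensor.cities, tensor.years, vals,
                                    tensor.distance_normalization)
    return noisy


def _assemble(spec: StudyAreaSpec, log_levels: dict[str, float],
              cities_by_aggl: dict[str, list[str]],
              pattern_by_city: dict[str, np.ndarray],
              rng: np.random.Generator,
              noise: bool) -> IndicatorPanel:
    """Build the panel from per-city level factors and temporal patterns."""
    years = spec.year_list
    rows, index = [], []
    for aggl, cities in cities_by_aggl.items():
        for c in cities:
            level = log_levels[c]
            pat = pattern_by_city[c]  # (T,) multiplicative pattern
            for k, y in enumerate(years):
                cell = {}
                for j, base in INDICATOR_BASES.items():
                    v = base * np.exp(level) * pat[k]
                    if noise and spec.indicator_noise_sd > 0:
                        v *= np.exp(rng.normal(0.0, spec.indicator_noise_sd))
                    cell[j] = v
                rows.append(cell)
                index.append((c, y))
    values = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["city", "year"]))
    membership = pd.Series({c: aggl for aggl, cs in cities_by_aggl.items() for c in cs})
    return IndicatorPanel(values=values, directions=dict(DEFAULT_DIRECTIONS),
                          membership=membership)


# --------------------------------------------------------------------------
# generators

def generate_study_area(spec: StudyAreaSpec = StudyAreaSpec(),
                        params: GravityParams = GravityParams()) -> SyntheticStudyArea:
    """Generate the default synthetic study area.

    Indicator trajectories rise in expectation through 2019 and dip at the
    shock year on health-resource indicators; core cities carry a
    ``core_multiplier`` level elevation; identical seeds give identical
    output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    years = spec.year_list
    n_years = len(years)
    resource_path = _trend_path(spec, with_shock=True)
    other_path = _trend_path(spec, with_shock=False)

    cities_by_aggl = {a.name: _city_names(a) for a in spec.agglomerations}
    cores = {a.name: cities_by_aggl[a.name][:a.n_core_cities]
             for a in spec.agglomerations}

    rows, index = [], []
    for a in spec.agglomerations:
        for c in cities_by_aggl[a.name]:
            size = rng.normal(0.0, spec.city_size_sd)
            mult = spec.core_multiplier if c in cores[a.name] else 1.0
            wiggle = rng.normal(0.0, spec.city_wiggle_sd, size=n_years)
            for k, y in enumerate(years):
                cell = {}
                for j, base in INDICATOR_BASES.items():
                    path = resource_path if j in HEALTH_RESOURCE_INDICATORS else other_path
                    noise = rng.normal(0.0, spec.indicator_noise_sd) \
                        if spec.indicator_noise_sd > 0 else 0.0
                    cell[j] = base * mult * path[k] * np.exp(size + wiggle[k] + noise)
                rows.append(cell)
                index.append((c, y))
    values = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["city", "year"]))
    membership = pd.Series({c: a.name for a in spec.agglomerations
                            for c in cities_by_aggl[a.name]})
    panel = IndicatorPanel(values=values, directions=dict(DEFAULT_DIRECTIONS),
                           membership=membership)

    distances, travel_times = {}, {}
    for a in spec.agglomerations:
        d = _distance_matrix(a.n_cities, spec, rng)
        names = cities_by_aggl[a.name]
        distances[a.name] = pd.DataFrame(d, index=names, columns=names)
        travel_times[a.name] = pd.DataFrame(_travel_times(d, spec, rng),
                                            index=names, columns=names)

    policies = _policies(spec, cities_by_aggl, rng)
    truth = {
        "labels": {a.name: None for a in spec.agglomerations},
        "cores": cores,
        "multipliers": {a.name: {c: (spec.core_multiplier if c in cores[a.name] else 1.0)
                                 for c in cities_by_aggl[a.name]}
                        for a in spec.agglomerations},
        "gravity_params": asdict(params),
    }
    reference = _reference_gravity(spec, panel, distances, travel_times, params, rng)
    return SyntheticStudyArea(spec=spec, panel=panel, distances=distances,
                              travel_times=travel_times, policies=policies,
                              truth=truth, reference_gravity=reference)


def _orthonormal_patterns(T: int, k: int, shape: np.ndarray,
                          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean unit-sample-sd patterns: the normalized ``shape`` plus k
    wiggle vectors sample-orthogonal to it (and to each other when the
    time dimension allows). Wiggles vanish at the final year so that
    final-year levels reflect the planted strata exactly.
    """
    from scipy.linalg import null_space

    g = shape - shape.mean()
    g = g / g.std()
    # subspace {v : v(T)=0, v ⟂ 1, v ⟂ g}
    constraints = np.vstack([np.ones(T), g, np.eye(T)[-1]])
    basis = null_space(constraints)  # (T, T-3)
    if k <= basis.shape[1]:
        z = basis @ rng.standard_normal((basis.shape[1], k))
        q, _ = np.linalg.qr(z)
        b = (q * np.sqrt(T)).T
    else:
        z = rng.standard_normal((k, T))
        z[:, -1] = 0.0
        z = z - z.mean(axis=1, keepdims=True)
        z = z - np.outer(z @ g, g) / (g @ g)  # remove the shared-trend component
        b = z / z.std(axis=1, keepdims=True)
    return g, b


def plant_structure(spec: StudyAreaSpec, archetype: str,
                    params: GravityParams = GravityParams()) -> SyntheticStudyArea:
    """Generate a study area with a planted network archetype.

    Every agglomeration in ``spec`` receives the same archetype; core
    counts must be compatible (1 for unipolar, >= 3 for polycentric, 2 for
    core_periphery and dual_core_segmented). Indicator trajectories are
    noise-free factor constructions, so the planted correlation geometry
    survives the standardize -> UHI -> gravity -> node-strength pipeline.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; expected one of {ARCHETYPES}")
    spec.validate()
    for a in spec.agglomerations:
        need = {"unipolar": (1, 1), "core_periphery": (2, 2),
                "dual_core_segmented": (2, 2), "polycentric": (3, None)}[archetype]
        lo, hi = need
        if a.n_core_cities < lo or (hi is not None and a.n_core_cities > hi):
            raise ValueError(
                f"archetype {archetype!r} requires "
                f"{'exactly ' + str(lo) if hi == lo else 'at least ' + str(lo)} core "
                f"cities; agglomeration {a.name} declares {a.n_core_cities}")
        min_cities = {"unipolar": 4, "polycentric": a.n_core_cities + 3,
                      "core_periphery": 5, "dual_core_segmented": 6}[archetype]
        if a.n_cities < min_cities:
            raise ValueError(
                f"archetype {archetype!r} needs >= {min_cities} cities; "
                f"{a.name} has {a.n_cities}")

    rng = np.random.default_rng(spec.seed)
    years = spec.year_list
    T = len(years)
    shape = _trend_path(spec, with_shock=True)
    rho = _RHO
    hub_mult = _HUB_MULT[archetype]

    cities_by_aggl = {a.name: _city_names(a) for a in spec.agglomerations}
    cores = {a.name: cities_by_aggl[a.name][:a.n_core_cities]
             for a in spec.agglomerations}
    log_levels: dict[str, float] = {}
    patterns: dict[str, np.ndarray] = {}
    multipliers: dict[str, dict[str, float]] = {}
    hub_patterns: dict[str, dict[str, list[float]]] = {}
    camps: dict[str, dict[str, str]] = {}
    distances, travel_times = {}, {}

    for a in spec.agglomerations:
        names = cities_by_aggl[a.name]
        hubs = cores[a.name]
        periphery = names[a.n_core_cities:]
        n_extra = 1 if archetype == "dual_core_segmented" else 0
        g, b = _orthonormal_patterns(T, len(periphery) + n_extra, shape, rng)
        mult = {h: hub_mult for h in hubs}
        upper = set(periphery[0::2])
        xi_upper, xi_lower = _XI[archetype]
        if archetype != "dual_core_segmented":
            deltas = {h: rho * g for h in hubs}
            for i, c in enumerate(periphery):
                xi = xi_upper if c in upper else xi_lower
                deltas[c] = rho * g + xi * b[i]
                mult[c] = _UPPER_LEVEL if c in upper else _LOWER_LEVEL
        else:  # two camps with orthogonal rhythms
            g2 = b[-1]
            half = len(periphery) // 2
            camp_a = [hubs[0]] + periphery[:half]
            camp_b = [hubs[1]] + periphery[half:]
            camps[a.name] = {c: ("A" if c in camp_a else "B") for c in names}
            deltas = {hubs[0]: rho * g, hubs[1]: rho * g2}
            for i, c in enumerate(periphery):
                base_pat = g if c in camp_a else g2
                xi = xi_upper if c in upper else xi_lower
                deltas[c] = rho * base_pat + xi * b[i]
                # depressed periphery relative to the two dominant cores
                mult[c] = 0.8 * (_UPPER_LEVEL if c in upper else _LOWER_LEVEL)

        for c in names:
            log_levels[c] = 0.0 if c in hubs else rng.normal(0.0, _PERIPHERY_SIZE_SD)
            patterns[c] = np.exp(deltas[c])
        multipliers[a.name] = mult
        hub_patterns[a.name] = {h: list(map(float, deltas[h])) for h in hubs}

        d = _distance_matrix(a.n_cities, spec, rng)
        if archetype != "polycentric":
            # hub-centred geography: hubs close to their periphery, the
            # periphery mutually spread out
            is_hub = np.array([c in hubs for c in names])
            hub_edge = np.outer(is_hub, ~is_hub) | np.outer(~is_hub, is_hub)
            periph_edge = np.outer(~is_hub, ~is_hub)
            scale = np.where(hub_edge, _HUB_PERIPHERY_DISTANCE,
                             np.where(periph_edge, _PERIPHERY_PERIPHERY_DISTANCE, 1.0))
            if archetype == "core_periphery":
                scale[np.outer(is_hub, is_hub)] = _CORE_PERIPHERY_CORE_DISTANCE
            d = d * scale
            np.fill_diagonal(d, 0.0)
        if archetype == "dual_core_segmented":
            in_a = np.array([camps[a.name][c] == "A" for c in names])
            cross = np.outer(in_a, ~in_a) | np.outer(~in_a, in_a)
            d = np.where(cross, d * _DUAL_CORE_CROSS_DISTANCE, d)
        distances[a.name] = pd.DataFrame(d, index=names, columns=names)
        travel_times[a.name] = pd.DataFrame(_travel_times(d, spec, rng),
                                            index=names, columns=names)

    # apply planted multipliers on top of size effects
    log_levels = {c: log_levels[c] + np.log(multipliers[aggl][c])
                  for aggl, cs in cities_by_aggl.items() for c in cs}
    panel = _assemble(spec, log_levels, cities_by_aggl, patterns, rng, noise=False)
    policies = _policies(spec, cities_by_aggl, rng)
    truth = {
        "labels": {a.name: archetype for a in spec.agglomerations},
        "cores": cores,
        "multipliers": multipliers,
        "hub_patterns": hub_patterns,
        "camps": camps,
        "gravity_params": asdict(params),
    }
    reference = _reference_gravity(spec, panel, distances, travel_times, params, rng)
    return SyntheticStudyArea(spec=spec, panel=panel, distances=distances,
                              travel_times=travel_times, policies=policies,
                              truth=truth, reference_gravity=reference)


def archetype_spec(archetype: str, seed: int = 0, **overrides) -> StudyAreaSpec:
    """Canonical single-agglomeration spec for a planted archetype."""
    sizes = {"unipolar": ("BTH", 13, 1), "polycentric": ("YRD", 26, 3),
             "core_periphery": ("PRD", 9, 2), "dual_core_segmented": ("CY", 16, 2)}
    if archetype not in sizes:
        raise ValueError(f"unknown archetype {archetype!r}")
    name, n, k = sizes[archetype]
    return StudyAreaSpec(agglomerations=(AgglomerationSpec(name, n, k),),
                         seed=seed, **overrides)


# --------------------------------------------------------------------------
# writers / readers

def write_study_area(study: SyntheticStudyArea, outdir: str | Path) -> dict[str, Path]:
    """Serialize a study area to plain-text artifacts; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    panel_path = outdir / "panel.csv"
    study.panel.to_frame().to_csv(panel_path, index=False)
    paths["panel"] = panel_path

    for aggl, mat in study.distances.items():
        p = outdir / f"distances_{aggl}.csv"
        mat.to_csv(p)
        paths[f"distances_{aggl}"] = p
    for aggl, mat in study.travel_times.items():
        p = outdir / f"travel_times_{aggl}.csv"
        mat.to_csv(p)
        paths[f"travel_times_{aggl}"] = p

    pol_path = outdir / "policies.csv"
    study.policies.to_csv(pol_path)
    paths["policies"] = pol_path

    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(study.truth, indent=2, sort_keys=True))
    paths["truth"] = truth_path

    ref = pd.concat(
        [t.to_long_frame().assign(agglomeration=aggl)
         for aggl, t in study.reference_gravity.items()],
        ignore_index=True)
    ref_path = outdir / "reference_gravity.csv"
    ref.to_csv(ref_path, index=False)
    paths["reference_gravity"] = ref_path
    return paths


def read_panel(path: str | Path,
               directions: dict[str, int] | None = None) -> IndicatorPanel:
    """Load a tidy panel CSV (city, agglomeration, year, indicators...)."""
    frame = pd.read_csv(path)
    membership = frame.drop_duplicates("city").set_index("city")["agglomeration"]
    values = frame.drop(columns=["agglomeration"]).set_index(["city", "year"])
    return IndicatorPanel(values=values,
                          directions=dict(directions or DEFAULT_DIRECTIONS),
                          membership=membership)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
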