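"""Collaboration-network construction and structure classification.

Gravity time series are reduced to per-city node-strength series
S_i(t) = sum_j G_ij(t); pairwise Pearson correlation of those series over
years gives the collaboration matrix r, thresholded at tau into a binary
adjacency. Degree centrality C_D(i) = sum_j g_ij / (n-1) and Freeman
degree centralization summarize the topology, and a rule cascade on the
number of hubs, the centralization and the inter-hub correlation labels
the agglomeration as one of four archetypes: unipolar radiating,
polycentric networked, core-periphery, or dual-core segmented.

A literal pairwise mode (correlating G_ij(t) with G_ji(t)) is retained
for completeness; on a symmetric gravity tensor it is identically 1 and
carries no structure, which is why node strengths are the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gravity import GravityTensor

ARCHETYPES = ("unipolar", "polycentric", "core_periphery", "dual_core_segmented")


class ConstantSeriesWarning(UserWarning):
    """A node-strength series had zero variance; its correlations are undefined."""


@dataclass(frozen=True)
class ClassifierThresholds:
    """Config-exposed heuristics separating the four planted archetypes."""

    tau: float = 0.6                  # edge threshold on r
    tau_core: float = 0.5             # inter-hub coupling cut
    hub_percentile: float = 75.0      # C_D percentile defining hub candidates
    unipolar_centralization: float = 0.5
    polycentric_centralization: float = 0.35


@dataclass
class CollaborationNetwork:
    r: pd.DataFrame
    adjacency: pd.DataFrame
    degree_centrality: pd.Series
    centralization: float
    structure_label: str = "indeterminate"

    @property
    def cities(self) -> list[str]:
        return list(self.r.index)


def node_strength_series(tensor: GravityTensor) -> pd.DataFrame:
    """Per-city gravity strength S_i(t) = sum_{j != i} G_ij(t).

    Returns a city x year DataFrame. Requires >= 3 years, the minimum for
    a meaningful Pearson correlation downstream.
    """
    if len(tensor.years) < 3:
        raise ValueError("node-strength correlation requires at least 3 years")
    s = tensor.values.sum(axis=2).T  # (n_cities, n_years)
    return pd.DataFrame(s, index=tensor.cities, columns=tensor.years)


def correlation_matrix(source, mode: str = "node_strength") -> pd.DataFrame:
    """Pearson correlation matrix of gravity dynamics.

    mode="node_strength": ``source`` is a city x year strength DataFrame;
    r_ij = Pearson(S_i(.), S_j(.)). mode="literal_pairwise": ``source`` is
    a GravityTensor and r_ij correlates the series G_ij(t) with G_ji(t).
    Constant series yield NaN entries with a warning.
    """
    if mode == "node_strength":
        series: pd.DataFrame = source
        if series.shape[1] < 3:
            raise ValueError("correlation requires at least 3 time points")
        x = series.to_numpy(float)
        xc = x - x.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(xc, axis=1)
        flat = norms == 0
        if flat.any():
            warnings.warn(
                f"constant strength series for {list(series.index[flat])}; "
                "correlation entries recorded as missing",
                ConstantSeriesWarning, stacklevel=2)
        safe = np.where(flat, 1.0, norms)
        r = (xc / safe[:, None]) @ (xc / safe[:, None]).T
        r[flat, :] = np.nan
        r[:, flat] = np.nan
        np.clip(r, -1.0, 1.0, out=r)
        np.fill_diagonal(r, 1.0)
        return pd.DataFrame(r, index=series.index, columns=series.index)
    if mode == "literal_pairwise":
        tensor: GravityTensor = source
        if len(tensor.years) < 3:
            raise ValueError("correlation requires at least 3 time points")
        n = len(tensor.cities)
        r = np.full((n, n), np.nan)
        np.fill_diagonal(r, 1.0)
        for i in range(n):
            for j in range(i + 1, n):
                a = tensor.values[:, i, j]
                b = tensor.values[:, j, i]
                if a.std() == 0 or b.std() == 0:
                    continue
                r[i, j] = r[j, i] = float(np.corrcoef(a, b)[0, 1])
        return pd.DataFrame(r, index=tensor.cities, columns=tensor.cities)
    raise ValueError(f"unknown correlation mode {mode!r}")


def binarize(r: pd.DataFrame, tau: float) -> pd.DataFrame:
    """Adjacency g_ij = 1 iff r_ij >= tau and i != j (NaN entries: no edge)."""
    if not -1 < tau < 1:
        raise ValueError(f"tau must lie in (-1, 1), got {tau}")
    a = (r.to_numpy(float) >= tau).astype(int)
    a[np.isnan(r.to_numpy(float))] = 0
    np.fill_diagonal(a, 0)
    return pd.DataFrame(a, index=r.index, columns=r.columns)


def degree_centrality(adjacency: pd.DataFrame) -> pd.Series:
    """C_D(i) = sum_j g_ij / (n - 1)."""
    n = adjacency.shape[0]
    if n < 2:
        raise ValueError("degree centrality requires at least 2 nodes")
    return adjacency.sum(axis=1) / (n - 1)


def centralization(adjacency: pd.DataFrame) -> float:
    """Freeman degree centralization, normalized so a star equals 1."""
    n = adjacency.shape[0]
    if n < 2:
        raise ValueError("centralization requires at least 2 nodes")
    if n == 2:
        return 0.0
    cd = degree_centrality(adjacency)
    return float((cd.max() - cd).sum() / (n - 2))


def build_network(
    tensor: GravityTensor,
    tau: float = ClassifierThresholds.tau,
    mode: str = "node_strength",
) -> CollaborationNetwork:
    """Assemble r, adjacency and centrality summaries from a gravity tensor."""
    if mode == "node_strength":
        r = correlation_matrix(node_strength_series(tensor), mode="node_strength")
    else:
        r = correlation_matrix(tensor, mode=mode)
    adj = binarize(r, tau)
    return CollaborationNetwork(
        r=r, adjacency=adj,
        degree_centrality=degree_centrality(adj),
        centralization=centralization(adj))


def classify_structure(
    network: CollaborationNetwork,
    uhi_last_year: pd.Series,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> str:
    """Label the archetype of a collaboration network.

    Hubs are cities whose degree centrality lies strictly above the
    hub percentile AND whose UHI lies strictly above the region median.
    Cascade on the hub count k*, the Freeman centralization and the
    inter-hub correlation:

    - k* = 1 and centralization >= 0.5      -> "unipolar"
    - k* = 2 and r(hub1, hub2) >= tau_core  -> "core_periphery"
    - k* = 2 and r(hub1, hub2) <  tau_core  -> "dual_core_segmented"
    - k* >= 3 and centralization < 0.35     -> "polycentric"
    - otherwise                              -> "indeterminate"
    """
    cd = network.degree_centrality
    uhi = uhi_last_year.reindex(cd.index)
    if uhi.isna().any():
        raise ValueError("UHI values missing for some network cities")
    cut = np.percentile(cd.to_numpy(float), thresholds.hub_percentile)
    hubs = [c for c in cd.index
            if cd[c] > cut and uhi[c] > float(uhi.median())]
    k = len(hubs)
    cz = network.centralization
    if k == 1 and cz >= thresholds.unipolar_centralization:
        return "unipolar"
    if k == 2:
        r_hh = network.r.loc[hubs[0], hubs[1]]
        if np.isnan(r_hh):
            return "indeterminate"
        return "core_periphery" if r_hh >= thresholds.tau_core else "dual_core_segmented"
    if k >= 3 and cz < thresholds.polycentric_centralization:
        return "polycentric"
    return "indeterminate"
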