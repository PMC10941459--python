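"""Unsupervised clustering of single-chromosome conformations.

Each trace's vectorized pairwise-distance matrix is a point in
conformation space; communities in a shared-nearest-neighbor (SNN) graph
over these points, found by Leiden modularity optimization, define
conformation subpopulations (e.g., one-arm-folded, both-arms-folded,
extended).  For pooled cross-strain analyses the slightly shorter HI
chromosome is first size-adjusted onto the N2 power-law baseline so
cluster membership reflects folding, not genome length.  Association
between cluster membership and chromosome group is quantified with a
chi-square test, Cramer's V effect size, and standardized residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .conformation_stats import PowerLawFit
from .core import Trace
from .tracing import pairwise_distance_matrix

__all__ = [
    "ClusterResult",
    "ContingencyStats",
    "size_adjust",
    "conformation_features",
    "cluster_traces",
    "find_resolution_for_k",
    "contingency_stats",
]


@dataclass
class ClusterResult:
    """Cluster labels (1..k) with per-cluster mean distance matrices."""

    labels: np.ndarray
    resolution: float
    k: int
    cluster_means: dict  # cluster -> (R', R') mean matrix over used regions
    group_frequencies: pd.DataFrame | None = None
    used_region_ids: np.ndarray | None = None


@dataclass
class ContingencyStats:
    """Chi-square association between cluster and chromosome group.

    chi2 = sum (O - E)^2 / E;  V = sqrt(chi2 / (n * min(k-1, r-1)));
    standardized residual = (O - E) / sqrt(E).
    """

    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    dof: int
    pvalue: float
    cramers_v: float
    std_residuals: pd.DataFrame
    n: int


def size_adjust(
    distances: np.ndarray,
    fit_a: PowerLawFit,
    coords_a: np.ndarray,
    coords_b: np.ndarray,
) -> np.ndarray:
    """Rescale strain-B distances onto strain A's power-law baseline.

    For each region pair the measured distance is divided by the ratio of
    the distances strain A's power law predicts at B's vs A's genomic
    separations, ``(g_B / g_A) ** s`` — removing the spatial footprint of
    B's shorter chromosome before pooled clustering.  Pairs with zero
    separation in either coordinate system are masked (NaN).
    """
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    g_a = np.abs(coords_a[None, :] - coords_a[:, None])
    g_b = np.abs(coords_b[None, :] - coords_b[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (g_b / g_a) ** fit_a.s
        adjusted = distances / ratio
    off = ~np.eye(distances.shape[0], dtype=bool)
    adjusted[off & ((g_a == 0) | (g_b == 0))] = np.nan
    return adjusted


def conformation_features(
    traces: list[Trace],
    excluded_regions=frozenset({17}),
    adjust: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix: vectorized upper-triangle distances per trace.

    ``excluded_regions`` removes low-yield regions from the feature space.
    ``adjust`` may map a strain name to ``(fit_a, coords_a, coords_b)``
    size-adjustment arguments applied to that strain's traces.  Missing
    entries are imputed by the population mean of each pair.  Returns the
    (n_traces, n_pairs) feature matrix and the region ids used.
    """
    region_ids = traces[0].region_ids
    keep = np.array([r not in excluded_regions for r in region_ids])
    used = region_ids[keep]
    rows = []
    iu = np.triu_indices(used.size, k=1)
    for t in traces:
        d = pairwise_distance_matrix(t)[np.ix_(keep, keep)]
        if adjust and t.strain in adjust:
            fit_a, ca, cb = adjust[t.strain]
            d = size_adjust(d, fit_a, np.asarray(ca)[keep], np.asarray(cb)[keep])
        rows.append(d[iu])
    X = np.asarray(rows)
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    return X, used


def _snn_graph(X: np.ndarray, n_neighbors: int) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = X.shape[0]
    nn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, n)).fit(X)
    _, idx = nn.kneighbors(X)
    neighbor_sets = [set(row[1:]) | {i} for i, row in enumerate(idx)]
    pairs = set()
    for i in range(n):
        for j in idx[i][1:]:
            j = int(j)
            if j != i:
                pairs.add((min(i, j), max(i, j)))
    edges, weights = [], []
    for i, j in sorted(pairs):
        inter = len(neighbor_sets[i] & neighbor_sets[j])
        union = len(neighbor_sets[i] | neighbor_sets[j])
        w = inter / union
        if w > 0:
            edges.append((i, j))
            weights.append(w)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_traces(
    traces: list[Trace],
    resolution: float = 0.7,
    excluded_regions=frozenset({17}),
    n_neighbors: int = 20,
    seed: int = 0,
    adjust: dict | None = None,
) -> ClusterResult:
    """Cluster traces by conformation via SNN graph + Leiden communities.

    The resolution parameter controls cluster granularity (larger ->
    more clusters).  Deterministic for a fixed seed.  Returns labels
    1..k, each cluster's mean distance matrix over the used regions, and
    per-group cluster frequencies when traces carry strain labels.
    """
    if len(traces) <= n_neighbors:
        raise ValueError(
            f"need more traces ({len(traces)}) than neighbors ({n_neighbors})"
        )
    X, used = conformation_features(traces, excluded_regions, adjust)
    graph = _snn_graph(X, n_neighbors)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership) + 1
    k = int(labels.max())

    keep = np.array([r not in excluded_regions for r in traces[0].region_ids])
    means = {}
    for c in range(1, k + 1):
        members = [t for t, l in zip(traces, labels) if l == c]
        acc = np.zeros((used.size, used.size))
        cnt = np.zeros_like(acc)
        for t in members:
            d = pairwise_distance_matrix(t)[np.ix_(keep, keep)]
            obs = ~np.isnan(d)
            acc[obs] += d[obs]
            cnt[obs] += 1
        with np.errstate(invalid="ignore"):
            means[c] = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)

    strains = np.array([t.strain for t in traces])
    freq = None
    if np.unique(strains).size > 1:
        tab = pd.crosstab(pd.Series(strains, name="group"),
                          pd.Series(labels, name="cluster"))
        freq = tab.div(tab.sum(axis=1), axis=0)
    return ClusterResult(labels, resolution, k, means, freq, used)


def find_resolution_for_k(
    traces: list[Trace],
    target_k: int = 5,
    resolutions=None,
    **kwargs,
) -> float:
    """Smallest scanned resolution giving exactly ``target_k`` clusters.

    Scans an ascending grid (default 0.1..2.0 in steps of 0.1) and returns
    the first resolution whose Leiden partition has ``target_k``
    communities; raises if none does.
    """
    if resolutions is None:
        resolutions = np.round(np.arange(0.1, 2.01, 0.1), 2)
    for r in resolutions:
        result = cluster_traces(traces, resolution=float(r), **kwargs)
        if result.k == target_k:
            return float(r)
    raise ValueError(f"no scanned resolution produced {target_k} clusters")


def contingency_stats(labels, groups) -> ContingencyStats:
    """Chi-square independence test of cluster membership vs group.

    Expected counts are the independence product E = outer(row sums,
    column sums) / n; the statistic, Cramer's V and standardized residuals
    follow the standard contingency-table formulas.  Raises if any
    expected cell is zero (the statistic is undefined there).
    """
    observed = pd.crosstab(
        pd.Series(np.asarray(groups), name="group"),
        pd.Series(np.asarray(labels), name="cluster"),
    )
    if observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValueError("need >= 2 groups and >= 2 clusters")
    O = observed.to_numpy(dtype=float)
    n = O.sum()
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / n
    if np.any(E == 0):
        raise ValueError("expected cell count of zero")
    chi2 = float(((O - E) ** 2 / E).sum())
    r, k = O.shape  # r groups x k clusters
    dof = (r - 1) * (k - 1)
    pvalue = float(stats.chi2.sf(chi2, dof))
    v = float(np.sqrt(chi2 / (n * min(k - 1, r - 1))))
    resid = (O - E) / np.sqrt(E)
    as_df = lambda arr: pd.DataFrame(arr, index=observed.index,
                                     columns=observed.columns)
    return ContingencyStats(
        observed=observed,
        expected=as_df(E),
        chi2=chi2,
        dof=dof,
        pvalue=pvalue,
        cramers_v=v,
        std_residuals=as_df(resid),
        n=int(n),
    )
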