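"""Graph metrics with degree-preserving null-model normalization.

Nine per-region metrics are computed on binary within-region subnetworks:

====== =====================================================================
SA     surface area: summed triangle areas of the region (mm^2)
FL     mean fiber length: mean trajectory length of intra-region streamlines
S      connectivity strength: summed area-normalized intra-region weights
d      edge density 2E / (N (N-1))
L      characteristic path length, averaged over *connected* ordered pairs
C      mean Watts-Strogatz clustering coefficient (degree < 2 contributes 0)
Eglob  global efficiency: mean 1/d_ij over all ordered pairs (0 if unreachable)
Eloc   mean over nodes of the global efficiency of the neighborhood subgraph
sigma  small-worldness (C / <C_null>) / (L / <L_null>)
====== =====================================================================

Because sparse binary graphs make the topological metrics sensitive to
density, L, C, Eglob and Eloc are reported normalized by their mean over
degree-preserving (Maslov-Sneppen double-edge-swap) rewired null networks;
d is invariant under rewiring and is reported raw.

The low-resolution (region-level) network is weighted; nodal strength,
nodal efficiency (path cost 1/w) and Onnela geometric-mean weighted
clustering are used there.

The inner loops (all-pairs BFS, triangle counting, neighborhood efficiency,
edge rewiring) are numba-compiled: a within-region graph of a few hundred
nodes with ~100 nulls costs milliseconds, which is what makes whole-cohort
normalized metric tables affordable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "METRIC_NAMES",
    "LOWRES_METRIC_NAMES",
    "MetricSettings",
    "MetricTable",
    "binary_global_metrics",
    "weighted_nodal_metrics",
    "rewire_degree_preserving",
    "null_normalize",
    "mean_fiber_length",
    "build_metric_table",
    "build_lowres_nodal_table",
    "metrics_from_edges",
    "null_normalized_from_edges",
    "edges_to_csr",
]

METRIC_NAMES = ["SA", "FL", "S", "d", "L", "C", "Eglob", "Eloc", "sigma"]
LOWRES_METRIC_NAMES = ["S_i", "E_i", "C_i"]

GLOBAL_HIGH = "GLOBAL_HIGH"
GLOBAL_LOW = "GLOBAL_LOW"


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=False)
def _bfs_path_stats(indptr, indices, n):
    """All-pairs BFS: (sum of distances, #connected ordered pairs, sum 1/d)."""
    dist = np.empty(n, np.int64)
    queue = np.empty(n, np.int64)
    sum_d = 0.0
    n_pairs = 0
    sum_inv = 0.0
    for s in range(n):
        for t in range(n):
            dist[t] = -1
        dist[s] = 0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for kk in range(indptr[u], indptr[u + 1]):
                v = indices[kk]
                if dist[v] < 0:
                    dist[v] = du + 1
                    queue[tail] = v
                    tail += 1
        for t in range(n):
            if t != s and dist[t] > 0:
                sum_d += dist[t]
                n_pairs += 1
                sum_inv += 1.0 / dist[t]
    return sum_d, n_pairs, sum_inv


@njit(cache=False)
def _contains(indices, lo, hi, x):
    """Binary search for x in the sorted slice indices[lo:hi]."""
    while lo < hi:
        mid = (lo + hi) // 2
        v = indices[mid]
        if v == x:
            return True
        elif v < x:
            lo = mid + 1
        else:
            hi = mid
    return False


@njit(cache=False)
def _clustering_mean(indptr, indices, n):
    """Mean Watts-Strogatz local clustering; degree < 2 contributes 0."""
    total = 0.0
    for u in range(n):
        k = indptr[u + 1] - indptr[u]
        if k < 2:
            continue
        t = 0
        for a in range(indptr[u], indptr[u + 1]):
            v = indices[a]
            for b in range(a + 1, indptr[u + 1]):
                w = indices[b]
                if _contains(indices, indptr[v], indptr[v + 1], w):
                    t += 1
        total += 2.0 * t / (k * (k - 1.0))
    return total / n if n > 0 else np.nan


@njit(cache=False)
def _local_efficiency(indptr, indices, n):
    """Mean over nodes of the neighborhood subgraph's global efficiency."""
    maxdeg = 0
    for u in range(n):
        k = indptr[u + 1] - indptr[u]
        if k > maxdeg:
            maxdeg = k
    nbr = np.empty(maxdeg, np.int64)
    sub_indptr = np.empty(maxdeg + 1, np.int64)
    sub_indices = np.empty(maxdeg * maxdeg, np.int64)
    dist = np.empty(maxdeg, np.int64)
    queue = np.empty(maxdeg, np.int64)
    total = 0.0
    for u in range(n):
        k = indptr[u + 1] - indptr[u]
        if k < 2:
            continue
        for a in range(k):
            nbr[a] = indices[indptr[u] + a]
        # induced subgraph on the (sorted) neighbor list
        pos = 0
        sub_indptr[0] = 0
        for a in range(k):
            v = nbr[a]
            for b in range(k):
                if b != a and _contains(indices, indptr[v], indptr[v + 1], nbr[b]):
                    sub_indices[pos] = b
                    pos += 1
            sub_indptr[a + 1] = pos
        # BFS within the subgraph
        sum_inv = 0.0
        for s in range(k):
            for t in range(k):
                dist[t] = -1
            dist[s] = 0
            queue[0] = s
            head, tail = 0, 1
            while head < tail:
                x = queue[head]
                head += 1
                dx = dist[x]
                for kk in range(sub_indptr[x], sub_indptr[x + 1]):
                    y = sub_indices[kk]
                    if dist[y] < 0:
                        dist[y] = dx + 1
                        queue[tail] = y
                        tail += 1
            for t in range(k):
                if t != s and dist[t] > 0:
                    sum_inv += 1.0 / dist[t]
        total += sum_inv / (k * (k - 1.0))
    return total / n if n > 0 else np.nan


@njit(cache=False)
def _metrics_csr(indptr, indices, n):
    """(d, L, C, Eglob, Eloc); L is NaN when no pair is connected."""
    e2 = indices.shape[0]                    # 2E
    d = e2 / (n * (n - 1.0)) if n > 1 else np.nan
    sum_d, n_pairs, sum_inv = _bfs_path_stats(indptr, indices, n)
    L = sum_d / n_pairs if n_pairs > 0 else np.nan
    eg = sum_inv / (n * (n - 1.0)) if n > 1 else np.nan
    c = _clustering_mean(indptr, indices, n)
    el = _local_efficiency(indptr, indices, n)
    return d, L, c, eg, el


@njit(cache=False)
def _csr_from_edges_nb(edges, n):
    """Symmetric CSR with row-sorted indices (counting sort + insertion)."""
    E = edges.shape[0]
    deg = np.zeros(n, np.int64)
    for e in range(E):
        deg[edges[e, 0]] += 1
        deg[edges[e, 1]] += 1
    indptr = np.zeros(n + 1, np.int64)
    for i in range(n):
        indptr[i + 1] = indptr[i] + deg[i]
    indices = np.empty(2 * E, np.int64)
    fill = indptr[:-1].copy()
    for e in range(E):
        u, v = edges[e, 0], edges[e, 1]
        indices[fill[u]] = v
        fill[u] += 1
        indices[fill[v]] = u
        fill[v] += 1
    for i in range(n):                      # small rows: insertion sort
        lo, hi = indptr[i], indptr[i + 1]
        for a in range(lo + 1, hi):
            key = indices[a]
            b = a - 1
            while b >= lo and indices[b] > key:
                indices[b + 1] = indices[b]
                b -= 1
            indices[b + 1] = key
    return indptr, indices


@njit(cache=False)
def _null_metric_means(edges, n, n_nulls, swaps_per_edge, seed):
    """Mean (L, C, Eglob, Eloc) over rewired nulls, with NaN-aware counts.

    Runs the entire rewire-and-measure loop compiled; null t uses RNG seed
    ``seed + t``.
    """
    sums = np.zeros(4)
    counts = np.zeros(4, np.int64)
    E = edges.shape[0]
    work = np.empty_like(edges)
    for t in range(n_nulls):
        for e in range(E):
            work[e, 0] = edges[e, 0]
            work[e, 1] = edges[e, 1]
        target = swaps_per_edge * E
        _rewire_edges(work, n, target, 20 * target + 100, seed + t)
        indptr, indices = _csr_from_edges_nb(work, n)
        _, L, c, eg, el = _metrics_csr(indptr, indices, n)
        vals = (L, c, eg, el)
        for k in range(4):
            if not np.isnan(vals[k]):
                sums[k] += vals[k]
                counts[k] += 1
    out = np.empty(4)
    for k in range(4):
        out[k] = sums[k] / counts[k] if counts[k] > 0 else np.nan
    return out


@njit(cache=False)
def _rewire_edges(edges, n, nswap_target, max_tries, seed):
    """In-place Maslov-Sneppen double-edge swaps; returns swaps performed.

    Edge membership is tracked in a dense boolean adjacency matrix, which
    bounds applicability to graphs of ~20k nodes; within-region subnetworks
    (hundreds of nodes) are far below that.
    """
    np.random.seed(seed)
    E = edges.shape[0]
    adj = np.zeros((n, n), dtype=np.bool_)
    for e in range(E):
        adj[edges[e, 0], edges[e, 1]] = True
        adj[edges[e, 1], edges[e, 0]] = True
    swaps = 0
    tries = 0
    while swaps < nswap_target and tries < max_tries:
        tries += 1
        e1 = np.random.randint(0, E)
        e2 = np.random.randint(0, E)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, dd = edges[e2, 0], edges[e2, 1]
        if np.random.randint(0, 2) == 1:
            c, dd = dd, c
        # proposed new edges: (a, dd) and (c, b)
        if a == dd or c == b:
            continue
        if adj[a, dd] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, dd] = adj[dd, c] = False
        adj[a, dd] = adj[dd, a] = True
        adj[c, b] = adj[b, c] = True
        edges[e1, 0], edges[e1, 1] = a, dd
        edges[e2, 0], edges[e2, 1] = c, b
        swaps += 1
    return swaps


# ---------------------------------------------------------------------------
# Edge-array plumbing
# ---------------------------------------------------------------------------

def edges_to_csr(edges: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric CSR (indptr, sorted indices) from an (E, 2) edge array."""
    if len(edges) == 0:
        return np.zeros(n + 1, dtype=np.int64), np.empty(0, dtype=np.int64)
    u = np.concatenate([edges[:, 0], edges[:, 1]])
    v = np.concatenate([edges[:, 1], edges[:, 0]])
    order = np.lexsort((v, u))
    u, v = u[order], v[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(u, minlength=n), out=indptr[1:])
    return indptr, v.astype(np.int64)


def _validate_edges(edges: np.ndarray) -> np.ndarray:
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if len(edges) and np.any(edges[:, 0] == edges[:, 1]):
        raise ValueError("self-loops are not allowed")
    canon = np.sort(edges, axis=1)
    if len(canon) != len(np.unique(canon, axis=0)):
        raise ValueError("multi-edges are not allowed")
    return canon


def _adjacency_to_edges(adjacency) -> tuple[np.ndarray, int]:
    import scipy.sparse as sp

    if sp.issparse(adjacency):
        a = adjacency.toarray()
    else:
        a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    iu, ju = np.where(np.triu(a, k=1) != 0)
    return np.column_stack([iu, ju]).astype(np.int64), a.shape[0]


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def metrics_from_edges(edges: np.ndarray, n: int) -> dict[str, float]:
    indptr, indices = edges_to_csr(np.asarray(edges, dtype=np.int64), n)
    d, L, c, eg, el = _metrics_csr(indptr, indices, n)
    return {"d": d, "L": L, "C": c, "Eglob": eg, "Eloc": el}


def binary_global_metrics(adjacency) -> dict[str, float]:
    """d, L, C, Eglob, Eloc of a binary symmetric zero-diagonal matrix.

    L averages shortest-path lengths over connected ordered pairs only and
    is NaN (flagged missing) when no pair is connected; Eglob counts
    disconnected pairs as zero efficiency.
    """
    edges, n = _adjacency_to_edges(adjacency)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    return metrics_from_edges(edges, n)


def rewire_degree_preserving(adjacency, swaps_per_edge: int = 10,
                             seed: int = 0) -> np.ndarray:
    """Maslov-Sneppen randomization; returns a dense binary adjacency.

    Every node keeps its exact degree; no self-loops or multi-edges are
    created.  Graphs with no feasible swap (e.g. complete graphs) come back
    unchanged with a warning.
    """
    edges, n = _adjacency_to_edges(adjacency)
    out = rewire_edge_array(edges, n, swaps_per_edge, seed)
    a = np.zeros((n, n), dtype=np.int8)
    if len(out):
        a[out[:, 0], out[:, 1]] = 1
        a[out[:, 1], out[:, 0]] = 1
    return a


def rewire_edge_array(edges: np.ndarray, n: int, swaps_per_edge: int = 10,
                      seed: int = 0, warn: bool = True) -> np.ndarray:
    """Edge-array form of :func:`rewire_degree_preserving`."""
    edges = _validate_edges(edges)
    E = len(edges)
    if E < 2:
        if warn:
            warnings.warn("graph has no feasible swap; returned unchanged")
        return edges.copy()
    out = edges.copy()
    target = swaps_per_edge * E
    swaps = _rewire_edges(out, n, target, 20 * target + 100, seed % (2 ** 31))
    if swaps == 0 and warn:
        warnings.warn("graph has no feasible swap; returned unchanged")
    return out


def null_normalized_from_edges(edges: np.ndarray, n: int, n_nulls: int,
                               seed: int, swaps_per_edge: int = 10,
                               ) -> dict[str, float]:
    """Raw metrics plus null-normalized L, C, Eglob, Eloc and sigma.

    Normalized metric = observed / mean over ``n_nulls`` degree-preserving
    rewired networks; sigma = (C/<C_null>) / (L/<L_null>).  A zero or
    undefined null mean flags the normalized value as missing (NaN).
    """
    if n_nulls < 2:
        raise ValueError("n_nulls must be >= 2")
    edges = _validate_edges(np.asarray(edges, dtype=np.int64))
    obs = metrics_from_edges(edges, n)
    base = int(np.int64(seed) % (2 ** 31 - n_nulls - 1))
    means = _null_metric_means(edges, n, n_nulls, swaps_per_edge, base)
    out = dict(obs)
    for k, mu in zip(("L", "C", "Eglob", "Eloc"), means):
        out[k + "_norm"] = obs[k] / mu if (mu and not np.isnan(mu)) else np.nan
    c_ratio = out["C_norm"]
    l_ratio = out["L_norm"]
    out["sigma"] = c_ratio / l_ratio if (l_ratio and not np.isnan(l_ratio)
                                         and not np.isnan(c_ratio)) else np.nan
    return out


def null_normalize(adjacency, metrics=("L", "C", "Eglob", "Eloc"),
                   n_nulls: int = 100, seed: int = 0,
                   swaps_per_edge: int = 10) -> dict[str, float]:
    """Adjacency-matrix form of :func:`null_normalized_from_edges`."""
    edges, n = _adjacency_to_edges(adjacency)
    full = null_normalized_from_edges(edges, n, n_nulls, seed, swaps_per_edge)
    out = {m: full[m + "_norm"] for m in metrics}
    out["sigma"] = full["sigma"]
    return out


def mean_fiber_length(lengths) -> float:
    """Arithmetic mean trajectory length; empty input is flagged missing."""
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        return np.nan
    if np.any(lengths < 0):
        raise ValueError("negative fiber length")
    return float(lengths.mean())


# ---------------------------------------------------------------------------
# Weighted (low-resolution) nodal metrics
# ---------------------------------------------------------------------------

def weighted_nodal_metrics(weights) -> pd.DataFrame:
    """Nodal strength, efficiency and Onnela weighted clustering.

    ``weights`` is a symmetric non-negative matrix with zero diagonal,
    scaled to [0, 1].  Path costs for nodal efficiency are 1/w on shortest
    weighted paths; clustering uses the geometric-mean (Onnela) formula with
    weights pre-scaled by the matrix maximum.
    """
    from scipy.sparse.csgraph import dijkstra

    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be square")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not np.allclose(w, w.T):
        raise ValueError("weights must be symmetric")
    n = w.shape[0]
    strength = w.sum(axis=1)

    cost = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    dist = dijkstra(cost, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    efficiency = inv.sum(axis=1) / (n - 1) if n > 1 else np.zeros(n)

    wmax = w.max()
    what = w / wmax if wmax > 0 else w
    cube = np.cbrt(what)
    num = np.diagonal(cube @ cube @ cube)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1.0)
    clustering = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)

    return pd.DataFrame({"S_i": strength, "E_i": efficiency,
                         "C_i": clustering})


def rewire_weighted(weights: np.ndarray, swaps_per_edge: int = 10,
                    seed: int = 0) -> np.ndarray:
    """Weighted null: rewire the binary topology, re-assign weights by rank.

    The topology is randomized by double-edge swaps; the original weights
    are then placed on the new edges so that the largest weights land on the
    edges whose endpoints have the largest original strength product, which
    approximately preserves the strength distribution.
    """
    w = np.asarray(weights, dtype=float)
    edges, n = _adjacency_to_edges((w > 0).astype(np.int8))
    vals = w[edges[:, 0], edges[:, 1]]
    new_edges = rewire_edge_array(edges, n, swaps_per_edge, seed, warn=False)
    strength = w.sum(axis=1)
    score = strength[new_edges[:, 0]] * strength[new_edges[:, 1]]
    order = np.argsort(-score, kind="stable")
    sorted_vals = np.sort(vals)[::-1]
    out = np.zeros_like(w)
    for rank, e in enumerate(order):
        i, j = new_edges[e]
        out[i, j] = out[j, i] = sorted_vals[rank]
    return out


# ---------------------------------------------------------------------------
# Cohort metric table
# ---------------------------------------------------------------------------

@dataclass
class MetricSettings:
    """Analysis settings for metric-table construction.

    ``n_nulls`` rewired networks normalize each within-region graph (the
    source protocol used 1,000; the desk-scale default is 100).
    ``n_nulls_global`` applies to the whole-brain high-resolution graph and
    defaults to 0 (raw metrics) because all-pairs BFS over thousands of
    nodes times the null count dominates runtime without informing the
    within-region analysis.
    """

    max_dist: float = 2.0
    length_bounds: tuple[float, float] = (10.0, 300.0)
    n_nulls: int = 100
    n_nulls_lowres: int = 50
    n_nulls_global: int = 0
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.length_bounds = tuple(self.length_bounds)
        low, high = self.length_bounds
        if self.max_dist <= 0 or low <= 0 or high <= low:
            raise ValueError("invalid metric settings")


@dataclass
class MetricTable:
    """Long-format subjects x regions x metrics table.

    ``data`` columns: subject, region (string label; ``GLOBAL_HIGH`` /
    ``GLOBAL_LOW`` for the whole-brain rows), metric, value (NaN = missing).
    ``node_counts`` maps region label -> node count (size screening).
    """

    data: pd.DataFrame
    node_counts: dict[str, int] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def wide(self) -> pd.DataFrame:
        return self.data.pivot_table(index="subject",
                                     columns=["region", "metric"],
                                     values="value", dropna=False)

    def subset(self, regions=None, metrics=None) -> "MetricTable":
        d = self.data
        if regions is not None:
            d = d[d.region.isin(regions)]
        if metrics is not None:
            d = d[d.metric.isin(metrics)]
        return MetricTable(d.reset_index(drop=True), self.node_counts,
                           self.provenance)


def _region_rows(conn, region: int, label: str, settings: MetricSettings,
                 region_seed: int) -> dict[str, float]:
    from .connectome import extract_region_subnetwork

    nodes = conn.region_nodes(region)
    sa = float(conn.node_area[nodes].sum())
    fl = mean_fiber_length(conn.intra_region_lengths.get(int(region),
                                                         np.empty(0)))
    sub = extract_region_subnetwork(conn, region)
    w = conn.weights[np.ix_(nodes, nodes)]
    strength = float(w.sum() / 2.0)
    edges = sub.edge_array()
    row = {"SA": sa, "FL": fl, "S": strength, "d": np.nan, "L": np.nan,
           "C": np.nan, "Eglob": np.nan, "Eloc": np.nan, "sigma": np.nan}
    if len(edges) >= 2 and sub.n_nodes >= 2:
        full = null_normalized_from_edges(
            edges, sub.n_nodes, settings.n_nulls, region_seed,
            settings.swaps_per_edge)
        row.update({"d": full["d"], "L": full["L_norm"], "C": full["C_norm"],
                    "Eglob": full["Eglob_norm"], "Eloc": full["Eloc_norm"],
                    "sigma": full["sigma"]})
    return row


def build_metric_table(cohort_subjects, settings: MetricSettings | None = None,
                       regions=None, include_global: bool = True,
                       lateralized: bool = True) -> MetricTable:
    """Per subject x region metric table for a generated/loaded cohort.

    Parameters
    ----------
    cohort_subjects : list of (SubjectRecord, SurfaceMesh, StreamlineSet)
    settings : metric settings shared by every subject (rejected otherwise)
    regions : optional iterable of *raw* region ids to restrict to
    include_global : add whole-brain high-res and low-res rows
    lateralized : relabel regions as ipsi/contra using each subject's
        assigned side (the seeded pseudo-side for controls)
    """
    from .connectome import (build_highres_connectome, build_lowres_connectome,
                             lateralize_region_labels)

    settings = settings or MetricSettings()
    rows = []
    node_counts: dict[str, int] = {}
    ss = np.random.SeedSequence(settings.seed)
    subj_seeds = ss.spawn(len(cohort_subjects))
    for (rec, mesh, streamlines), sseq in zip(cohort_subjects, subj_seeds):
        conn = build_highres_connectome(streamlines, mesh, settings.max_dist,
                                        settings.length_bounds)
        region_ids = conn.region_ids if regions is None else \
            np.asarray(sorted(regions))
        n_pairs = (len(conn.region_ids) + 1) // 2
        if lateralized:
            labels = lateralize_region_labels(region_ids, rec.assigned_side,
                                              n_pairs)
        else:
            labels = [f"region_{g:02d}" for g in region_ids]
        seeds = sseq.generate_state(len(region_ids) + 1) % (2 ** 31)
        for g, label, rseed in zip(region_ids, labels, seeds):
            row = _region_rows(conn, int(g), label, settings, int(rseed))
            node_counts[label] = int((conn.node_region == g).sum())
            for metric, value in row.items():
                rows.append((rec.id, label, metric, value))
        if include_global:
            # whole-brain high-resolution row (raw topology by default)
            all_lengths = np.concatenate(
                [v for v in conn.intra_region_lengths.values()]
            ) if conn.intra_region_lengths else np.empty(0)
            edges_coo = conn.counts.nonzero()
            mask = edges_coo[0] < edges_coo[1]
            edges = np.column_stack([edges_coo[0][mask],
                                     edges_coo[1][mask]]).astype(np.int64)
            grow = {"SA": float(conn.node_area.sum()),
                    "FL": mean_fiber_length(all_lengths),
                    "S": float(conn.weights.sum() / 2.0)}
            if len(edges) >= 2:
                if settings.n_nulls_global >= 2:
                    full = null_normalized_from_edges(
                        edges, conn.n_nodes, settings.n_nulls_global,
                        int(seeds[-1]), settings.swaps_per_edge)
                    grow.update({"d": full["d"], "L": full["L_norm"],
                                 "C": full["C_norm"],
                                 "Eglob": full["Eglob_norm"],
                                 "Eloc": full["Eloc_norm"],
                                 "sigma": full["sigma"]})
                else:
                    m = metrics_from_edges(edges, conn.n_nodes)
                    grow.update(m)
                    grow["sigma"] = np.nan
            for metric in METRIC_NAMES:
                rows.append((rec.id, GLOBAL_HIGH, metric,
                             grow.get(metric, np.nan)))
            low = build_lowres_connectome(conn)
            if low.n_regions > 1:
                nodal = weighted_nodal_metrics(low.weights)
                binary_density = float((low.counts > 0).sum()
                                       / (low.n_regions * (low.n_regions - 1)))
                lrow = {"S": float(nodal.S_i.mean()),
                        "Eglob": float(nodal.E_i.mean()),
                        "C": float(nodal.C_i.mean()), "d": binary_density}
                for metric in METRIC_NAMES:
                    rows.append((rec.id, GLOBAL_LOW, metric,
                                 lrow.get(metric, np.nan)))
    data = pd.DataFrame(rows, columns=["subject", "region", "metric", "value"])
    prov = {"settings": settings, "lateralized": lateralized}
    return MetricTable(data, node_counts, prov)


def build_lowres_nodal_table(cohort_subjects,
                             settings: MetricSettings | None = None,
                             lateralized: bool = True) -> MetricTable:
    """Per subject x region low-resolution nodal metrics (S_i, E_i, C_i)."""
    from .connectome import (build_highres_connectome, build_lowres_connectome,
                             lateralize_region_labels)

    settings = settings or MetricSettings()
    rows = []
    node_counts: dict[str, int] = {}
    for rec, mesh, streamlines in cohort_subjects:
        conn = build_highres_connectome(streamlines, mesh, settings.max_dist,
                                        settings.length_bounds)
        low = build_lowres_connectome(conn)
        if low.n_regions < 2:
            continue
        nodal = weighted_nodal_metrics(low.weights)
        n_pairs = (low.n_regions + 1) // 2
        if lateralized:
            labels = lateralize_region_labels(low.region_ids,
                                              rec.assigned_side, n_pairs)
        else:
            labels = [f"region_{g:02d}" for g in low.region_ids]
        for t, label in enumerate(labels):
            node_counts[label] = 1
            for metric in LOWRES_METRIC_NAMES:
                rows.append((rec.id, label, metric, float(nodal[metric][t])))
    data = pd.DataFrame(rows, columns=["subject", "region", "metric", "value"])
    return MetricTable(data, node_counts, {"settings": settings,
                                           "lateralized": lateralized})
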