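"""High- and low-resolution connectome construction.

A labeled surface mesh plus a streamline set become:

* a **high-resolution connectome**: sparse symmetric streamline-count matrix
  over triangle centers, with weights normalized by the mean endpoint
  triangle area;
* a **low-resolution connectome**: region-by-region counts mapped through a
  per-subject logistic function into weights in [0, 1);
* binary **within-region subnetworks**: the induced subgraph of one region's
  nodes, containing no inter-region edges.

Streamline endpoints are assigned to the nearest triangle center (Euclidean
distance, ties to the lowest index) within a configurable tolerance that
stands in for the gray-matter termination mask; streamlines outside the
trajectory-length window (default 10-300 mm, strict) are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .synthetic import StreamlineSet, SurfaceMesh

__all__ = [
    "HighResConnectome",
    "LowResConnectome",
    "RegionSubnetwork",
    "assign_endpoint_to_node",
    "filter_streamlines",
    "build_highres_connectome",
    "build_lowres_connectome",
    "extract_region_subnetwork",
    "lateralize_connectome",
    "lateralize_region_labels",
    "UNASSIGNED",
]

UNASSIGNED = -1

DEFAULT_MAX_DIST = 2.0          # mm; endpoint-to-center assignment tolerance
DEFAULT_LENGTH_BOUNDS = (10.0, 300.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class HighResConnectome:
    """Triangle-level structural network.

    ``counts`` and ``weights`` are sparse symmetric matrices with zero
    diagonal; ``weights[i, j] = counts[i, j] / ((area_i + area_j) / 2)``.
    ``intra_region_lengths`` maps region id -> trajectory lengths (mm) of
    retained streamlines whose two endpoints fall in that region (including
    streamlines whose endpoints map to the same triangle, which carry length
    information even though they add no edge).
    """

    counts: sp.csr_matrix
    weights: sp.csr_matrix
    node_region: np.ndarray
    node_center: np.ndarray
    node_area: np.ndarray
    node_hemisphere: np.ndarray
    intra_region_lengths: dict[int, np.ndarray]

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[0]

    @property
    def region_ids(self) -> np.ndarray:
        return np.unique(self.node_region)

    def region_nodes(self, region: int) -> np.ndarray:
        return np.where(self.node_region == region)[0]

    def n_streamlines_in_matrix(self) -> int:
        return int(sp.triu(self.counts, k=1).sum())


@dataclass
class LowResConnectome:
    """Region-level network: integer counts and logistic weights in [0, 1)."""

    counts: np.ndarray
    weights: np.ndarray
    region_ids: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.counts.shape[0]


@dataclass
class RegionSubnetwork:
    """Binary induced subgraph on one region's nodes (intra edges only)."""

    region: int
    node_ids: np.ndarray      # indices into the parent connectome
    adjacency: np.ndarray     # (n, n) binary symmetric, zero diagonal

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_array(self) -> np.ndarray:
        """(E, 2) upper-triangle edge list (local node indexing)."""
        iu, ju = np.where(np.triu(self.adjacency, k=1))
        return np.column_stack([iu, ju]).astype(np.int64)


# ---------------------------------------------------------------------------
# Endpoint assignment and filtering
# ---------------------------------------------------------------------------

def assign_endpoint_to_node(point: np.ndarray, mesh: SurfaceMesh,
                            max_dist: float = DEFAULT_MAX_DIST) -> int:
    """Nearest triangle center within ``max_dist``; ties to the lowest index.

    Returns ``UNASSIGNED`` (-1) when no center is close enough.
    """
    if mesh.n_triangles == 0:
        raise ValueError("empty mesh")
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    point = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(point)):
        raise ValueError("endpoint coordinates must be finite")
    d = np.linalg.norm(mesh.triangle_center - point, axis=1)
    best = int(np.argmin(d))          # argmin takes the lowest index on ties
    return best if d[best] <= max_dist else UNASSIGNED


def _assign_many(points: np.ndarray, centers: np.ndarray,
                 max_dist: float) -> np.ndarray:
    """Vectorized nearest-center assignment with the same tie rule."""
    tree = cKDTree(centers)
    dist, idx = tree.query(points, k=2 if len(centers) > 1 else 1)
    if len(centers) > 1:
        # kd-tree tie-breaking is unspecified; enforce lowest-index on ties
        tied = np.isclose(dist[:, 0], dist[:, 1], rtol=0, atol=1e-12)
        out = idx[:, 0].copy()
        out[tied] = np.minimum(idx[tied, 0], idx[tied, 1])
        dist = dist[:, 0]
    else:
        out = np.atleast_1d(idx).copy()
        dist = np.atleast_1d(dist)
    out[dist > max_dist] = UNASSIGNED
    return out.astype(np.int64)


def filter_streamlines(streamlines: StreamlineSet, mesh: SurfaceMesh,
                       max_dist: float = DEFAULT_MAX_DIST,
                       length_bounds: tuple[float, float] = DEFAULT_LENGTH_BOUNDS,
                       ) -> tuple[StreamlineSet, np.ndarray]:
    """Keep streamlines with both endpoints assigned and length in bounds.

    Length bounds are strict (``low < length < high``).  Returns the
    retained subset and the (n, 2) array of endpoint node pairs.
    """
    low, high = length_bounds
    if low <= 0 or high <= low:
        raise ValueError("length bounds must be positive with low < high")
    if streamlines.n == 0:
        return streamlines, np.empty((0, 2), dtype=np.int64)
    first, last = streamlines.endpoints
    centers = mesh.triangle_center
    a = _assign_many(first, centers, max_dist)
    b = _assign_many(last, centers, max_dist)
    lengths = streamlines.trajectory_length
    keep = (a != UNASSIGNED) & (b != UNASSIGNED) \
        & (lengths > low) & (lengths < high)
    idx = np.where(keep)[0]
    polys = [streamlines[i] for i in idx]
    retained = StreamlineSet.from_polylines(polys)
    pairs = np.column_stack([a[idx], b[idx]])
    return retained, pairs


# ---------------------------------------------------------------------------
# Connectome construction
# ---------------------------------------------------------------------------

def build_highres_connectome(streamlines: StreamlineSet, mesh: SurfaceMesh,
                             max_dist: float = DEFAULT_MAX_DIST,
                             length_bounds: tuple[float, float] = DEFAULT_LENGTH_BOUNDS,
                             ) -> HighResConnectome:
    """Streamline counts between nearest triangle centers, area-normalized.

    ``counts[i, j]`` is the number of retained streamlines with endpoint
    pair {i, j}, i != j.  Streamlines mapping both endpoints to one node are
    excluded from the matrix (no self-loops) but their lengths still count
    toward the region's fiber-length list.
    """
    retained, pairs = filter_streamlines(streamlines, mesh, max_dist,
                                         length_bounds)
    n = mesh.n_triangles
    area = mesh.triangle_area
    labels = mesh.region_label
    if len(pairs) == 0:
        warnings.warn("no streamlines retained; connectome is empty")
        empty = sp.csr_matrix((n, n))
        return HighResConnectome(
            counts=empty, weights=empty.copy(), node_region=labels.copy(),
            node_center=mesh.triangle_center, node_area=area,
            node_hemisphere=mesh.hemisphere.copy(), intra_region_lengths={})

    lengths = retained.trajectory_length
    i, j = pairs[:, 0], pairs[:, 1]
    distinct = i != j
    lo, hi = np.minimum(i, j)[distinct], np.maximum(i, j)[distinct]
    counts = sp.coo_matrix(
        (np.ones(distinct.sum()), (lo, hi)), shape=(n, n)).tocsr()
    counts.sum_duplicates()
    counts = counts + counts.T

    coo = sp.triu(counts, k=1).tocoo()
    w = coo.data / ((area[coo.row] + area[coo.col]) / 2.0)
    weights = sp.coo_matrix((w, (coo.row, coo.col)), shape=(n, n)).tocsr()
    weights = weights + weights.T

    intra = labels[i] == labels[j]
    intra_lengths: dict[int, np.ndarray] = {}
    for region in np.unique(labels[i][intra]):
        mask = intra & (labels[i] == region)
        intra_lengths[int(region)] = lengths[mask]

    return HighResConnectome(
        counts=counts, weights=weights, node_region=labels.copy(),
        node_center=mesh.triangle_center, node_area=area,
        node_hemisphere=mesh.hemisphere.copy(),
        intra_region_lengths=intra_lengths)


def logistic_weights(counts: np.ndarray) -> np.ndarray:
    """Per-subject logistic map of region-level counts to weights in [0, 1).

    ``w(c) = 1 / (1 + exp(-(log c - m) / s))`` for c > 0 with m, s the mean
    and SD of log counts over the nonzero entries of this matrix; w(0) = 0.
    Strictly increasing in c, bounded, and normalized per subject.
    """
    counts = np.asarray(counts, dtype=float)
    w = np.zeros_like(counts)
    nz = counts > 0
    if not nz.any():
        return w
    logs = np.log(counts[nz])
    m = logs.mean()
    s = logs.std()
    if s <= 0:
        s = 1.0
    w[nz] = 1.0 / (1.0 + np.exp(-(logs - m) / s))
    return w


def build_lowres_connectome(highres: HighResConnectome) -> LowResConnectome:
    """Aggregate high-res counts between regions; weights via logistic map."""
    regions = highres.region_ids
    r = len(regions)
    if r < 2:
        warnings.warn("single-region connectome; low-res matrix is 1x1 zero")
        return LowResConnectome(np.zeros((r, r)), np.zeros((r, r)), regions)
    index = {int(g): t for t, g in enumerate(regions)}
    coo = sp.triu(highres.counts, k=1).tocoo()
    ra = np.array([index[int(g)] for g in highres.node_region[coo.row]])
    rb = np.array([index[int(g)] for g in highres.node_region[coo.col]])
    counts = np.zeros((r, r))
    inter = ra != rb
    np.add.at(counts, (ra[inter], rb[inter]), coo.data[inter])
    np.add.at(counts, (rb[inter], ra[inter]), coo.data[inter])
    return LowResConnectome(counts, logistic_weights(counts), regions)


def extract_region_subnetwork(highres: HighResConnectome,
                              region: int) -> RegionSubnetwork:
    """Binary induced subgraph on one region's nodes (counts > 0 edges)."""
    nodes = highres.region_nodes(region)
    if len(nodes) == 0:
        raise KeyError(f"unknown region {region}")
    sub = highres.counts[np.ix_(nodes, nodes)].toarray()
    adj = (sub > 0).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return RegionSubnetwork(region=int(region), node_ids=nodes, adjacency=adj)


# ---------------------------------------------------------------------------
# Lateralization (ipsi/contra relabeling)
# ---------------------------------------------------------------------------

def lateralize_region_labels(region_ids: np.ndarray, side: str,
                             n_pairs: int) -> list[str]:
    """Map paired region ids to ipsi/contra labels.

    Regions 0..n_pairs-1 are left-hemisphere, n_pairs..2*n_pairs-1 their
    right homologues.  For ``side='L'`` the left hemisphere is ipsilateral;
    for ``side='R'`` labels are swapped first (applying the swap twice
    restores the original labeling).
    """
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    out = []
    for g in np.asarray(region_ids, dtype=int):
        if g < n_pairs:
            hemi, pair = "L", g
        else:
            hemi, pair = "R", g - n_pairs
        ipsi = (hemi == side)
        out.append(f"{'ipsi' if ipsi else 'contra'}_{pair:02d}")
    return out


def lateralize_connectome(highres: HighResConnectome, side: str,
                          n_pairs: int) -> HighResConnectome:
    """Swap left/right region ids for right-sided subjects.

    The edge set is untouched; only node_region / node_hemisphere labels
    change, and applying the transform twice is the identity.
    """
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R' (patients require a side)")
    if side == "L":
        return highres
    region = highres.node_region.copy()
    left = region < n_pairs
    region[left] += n_pairs
    region[~left] -= n_pairs
    hemi = np.where(highres.node_hemisphere == "L", "R", "L")
    lengths = {}
    for g, v in highres.intra_region_lengths.items():
        g = int(g)
        lengths[g + n_pairs if g < n_pairs else g - n_pairs] = v
    return replace(highres, node_region=region, node_hemisphere=hemi,
                   intra_region_lengths=lengths)
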