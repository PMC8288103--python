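"""Synthetic cohort generator.

Produces labeled spherical cortical meshes, streamline sets and full
control/patient cohorts with *planted*, recorded within-region connectivity
effects, so that every downstream stage (connectome construction, graph
metrics, confound control, group statistics, outcome prediction) can be
exercised and validated without access to patient MRI.

The generative model, briefly:

* The node substrate is a closed triangulated sphere scaled so that the mean
  triangle area matches a chosen resolution (3.5 mm^2 emulates a ~50k-node
  cortical mesh; 12.6 mm^2 a ~12.5k one).  Triangles are partitioned into
  contiguous regions by farthest-point clustering of triangle centers,
  mirrored across the x=0 plane so every left region has a right homologue.
* Healthy within-region connectivity is a noisy geometric graph on triangle
  centers: centers closer than a radius ``r`` are connected, edges are
  thinned and a few random long-range edges added.  Geometric graphs are
  locally clustered, which is the healthy phenotype the disease model
  degrades.
* The disease model rewires a fraction ("rate") of each affected region's
  shortest intra-region edges into long-range ones, preserving the edge
  count: fewer short connections, more long connections, lower clustering.
  The rate grows linearly with disease duration, and patients with a bad
  surgical outcome additionally receive effects in a contralateral region
  set.  Everything planted is recorded in :class:`EffectGroundTruth`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

__all__ = [
    "SurfaceMesh",
    "StreamlineSet",
    "SubjectRecord",
    "EffectGroundTruth",
    "CohortConfig",
    "generate_region_mesh",
    "generate_streamlines",
    "streamlines_from_edges",
    "plant_within_region_effect",
    "rewire_short_to_long",
    "generate_cohort",
    "RESOLUTION_AREAS_MM2",
]

# Mean triangle area (mm^2) emulating the three mesh densities studied:
# ~50,000 / ~25,000 / ~12,500 triangles for a full cortex.
RESOLUTION_AREAS_MM2 = {"50k": 3.5, "25k": 6.3, "12k": 12.6}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Labeled triangle mesh: the node substrate of the high-res network.

    Attributes
    ----------
    vertices : (V, 3) float array, mm
    triangles : (F, 3) int array of vertex indices
    region_label : (F,) int array, region id per triangle
    hemisphere : (F,) array of 'L'/'R' per triangle
    """

    vertices: np.ndarray
    triangles: np.ndarray
    region_label: np.ndarray
    hemisphere: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.region_label = np.asarray(self.region_label, dtype=np.int64)
        self.hemisphere = np.asarray(self.hemisphere)
        if len(self.region_label) != len(self.triangles):
            raise ValueError("one region label per triangle required")

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def triangle_center(self) -> np.ndarray:
        """(F, 3) centroid of each triangle, mm."""
        return self.vertices[self.triangles].mean(axis=1)

    @property
    def triangle_area(self) -> np.ndarray:
        """(F,) area of each triangle, mm^2."""
        p = self.vertices[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    @property
    def region_ids(self) -> np.ndarray:
        return np.unique(self.region_label)

    def region_hemisphere(self, region: int) -> str:
        """Majority hemisphere of a region's triangles."""
        tags = self.hemisphere[self.region_label == region]
        if len(tags) == 0:
            raise KeyError(f"unknown region {region}")
        vals, counts = np.unique(tags, return_counts=True)
        return str(vals[np.argmax(counts)])

    def scaled(self, factor: float) -> "SurfaceMesh":
        """Uniformly scaled copy (areas scale with factor**2)."""
        return replace(self, vertices=self.vertices * float(factor))

    def triangle_adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """Pairs of triangles sharing an edge, as two index arrays."""
        f = np.arange(self.n_triangles)
        edges = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]],
             self.triangles[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        faces = np.concatenate([f, f, f])
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        edges, faces = edges[order], faces[order]
        same = np.all(edges[:-1] == edges[1:], axis=1)
        return faces[:-1][same], faces[1:][same]


@dataclass
class StreamlineSet:
    """Polylines in mm coordinates, stored flat for vectorized work.

    ``points`` stacks the points of all streamlines; streamline ``i`` owns
    rows ``offsets[i]:offsets[i+1]``.
    """

    points: np.ndarray
    offsets: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.offsets = np.asarray(self.offsets, dtype=np.int64)

    @classmethod
    def from_polylines(cls, polylines: list[np.ndarray]) -> "StreamlineSet":
        if not polylines:
            return cls(np.empty((0, 3)), np.zeros(1, dtype=np.int64))
        pts = np.concatenate([np.asarray(p, dtype=float) for p in polylines])
        offs = np.zeros(len(polylines) + 1, dtype=np.int64)
        np.cumsum([len(p) for p in polylines], out=offs[1:])
        return cls(pts, offs)

    @property
    def n(self) -> int:
        return len(self.offsets) - 1

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i: int) -> np.ndarray:
        return self.points[self.offsets[i]:self.offsets[i + 1]]

    @property
    def trajectory_length(self) -> np.ndarray:
        """(n,) sum of consecutive-point Euclidean distances, mm."""
        if self.n == 0:
            return np.empty(0)
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        # zero out the phantom segments that bridge consecutive streamlines
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        starts, ends = self.offsets[:-1], self.offsets[1:] - 1
        return cum[ends] - cum[starts]

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """First and last point of every streamline, two (n, 3) arrays."""
        return self.points[self.offsets[:-1]], self.points[self.offsets[1:] - 1]


@dataclass
class SubjectRecord:
    """One cohort row.

    ``assigned_side`` drives ipsi/contra relabeling: it equals the surgery
    side for patients and a seeded, recorded pseudo-side for controls (the
    source data does not state how control hemispheres were paired for
    flipping, so the assignment is made explicit here).
    """

    id: str
    group: str                    # 'control' | 'patient'
    age: float
    sex: str                      # 'M' | 'F'
    side: str = "none"            # surgery side: 'L' | 'R' | 'none'
    duration: float | None = None  # years since first seizure
    outcome: int | None = None     # ILAE class 1-5
    assigned_side: str = "L"

    def __post_init__(self) -> None:
        if self.group == "patient":
            if self.side not in ("L", "R"):
                raise ValueError(f"patient {self.id} requires a surgery side")
            if self.duration is None or self.duration < 0:
                raise ValueError(f"patient {self.id} requires duration >= 0")
            if self.outcome not in (1, 2, 3, 4, 5):
                raise ValueError(f"patient {self.id} requires ILAE outcome 1-5")
        elif self.group == "control":
            if self.side != "none" or self.duration is not None or self.outcome is not None:
                raise ValueError(f"control {self.id} must not carry patient fields")
        else:
            raise ValueError(f"unknown group {self.group!r}")

    @property
    def good_outcome(self) -> bool | None:
        if self.outcome is None:
            return None
        return self.outcome <= 2


@dataclass
class EffectGroundTruth:
    """Record of everything the generator planted.

    ``affected_regions`` maps subject id -> {region id: rewiring rate}.
    Controls map to an empty dict.
    """

    affected_regions: dict[str, dict[int, float]]
    duration_regions: dict[str, list[int]]   # subject -> duration-related region ids
    outcome_regions: dict[str, list[int]]    # subject -> outcome-related region ids
    duration_slope: float
    baseline_rate: float
    flip_side: dict[str, str]                # subject -> assigned side

    def rate(self, subject: str, region: int) -> float:
        return self.affected_regions.get(subject, {}).get(region, 0.0)


# ---------------------------------------------------------------------------
# Mesh generation
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int, rng: np.random.Generator, jitter: float) -> np.ndarray:
    """Near-uniform points on the unit sphere with a little seeded jitter."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / phi
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    if jitter > 0:
        pts = pts + rng.normal(scale=jitter / np.sqrt(n), size=pts.shape)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def _farthest_point_seeds(points: np.ndarray, k: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Indices of k seeds chosen by farthest-point traversal."""
    n = len(points)
    seeds = np.empty(k, dtype=np.int64)
    seeds[0] = rng.integers(n)
    d = np.linalg.norm(points - points[seeds[0]], axis=1)
    for j in range(1, k):
        seeds[j] = int(np.argmax(d))
        d = np.minimum(d, np.linalg.norm(points - points[seeds[j]], axis=1))
    return seeds


def _repair_region_connectivity(labels: np.ndarray, adj_a: np.ndarray,
                                adj_b: np.ndarray,
                                hemisphere: np.ndarray) -> np.ndarray:
    """Reassign minority connected components so each region is edge-connected.

    Components are found by BFS over the triangle-adjacency graph restricted
    to each region; all but the largest component of a region are merged into
    the same-hemisphere neighbouring region they touch the most.
    """
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    n = len(labels)
    labels = labels.copy()
    for _ in range(20):
        changed = False
        same = labels[adj_a] == labels[adj_b]
        g = sp.coo_matrix(
            (np.ones(same.sum()), (adj_a[same], adj_b[same])), shape=(n, n)
        )
        _, comp = connected_components(g + g.T, directed=False)
        for region in np.unique(labels):
            mask = labels == region
            comps, counts = np.unique(comp[mask], return_counts=True)
            if len(comps) <= 1:
                continue
            keep = comps[np.argmax(counts)]
            for c in comps:
                if c == keep:
                    continue
                tri = np.where(mask & (comp == c))[0]
                tri_set = set(tri.tolist())
                # neighbouring regions of this stray component, same hemisphere
                votes: dict[int, int] = {}
                for a, b in zip(adj_a, adj_b):
                    for u, v in ((a, b), (b, a)):
                        if u in tri_set and labels[v] != region \
                                and hemisphere[v] == hemisphere[tri[0]]:
                            votes[labels[v]] = votes.get(labels[v], 0) + 1
                if votes:
                    target = max(votes, key=lambda r: votes[r])
                    labels[tri] = target
                    changed = True
        if not changed:
            break
    return labels


def generate_region_mesh(n_regions: int, n_triangles: int, seed: int,
                         mean_triangle_area: float = 3.5) -> SurfaceMesh:
    """Closed sphere mesh partitioned into contiguous labeled regions.

    Parameters
    ----------
    n_regions : number of regions; even values are split symmetrically into
        left/right hemispheres with mirrored homologues (left region ``j``
        pairs with right region ``j + n_regions//2``).
    n_triangles : target triangle count (achieved within 10%).
    seed : RNG seed (same seed -> identical mesh).
    mean_triangle_area : mm^2 per triangle; 3.5 emulates the ~50k-node
        density, 12.6 the ~12.5k one.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if n_triangles < 4 * n_regions:
        raise ValueError(
            f"impossible partition: need n_triangles >= 4*n_regions "
            f"({n_triangles} < {4 * n_regions})"
        )
    rng = np.random.default_rng(seed)
    # a convex hull of n points in general position has exactly 2n-4 facets
    n_points = n_triangles // 2 + 2
    pts = _fibonacci_sphere(n_points, rng, jitter=0.5)
    hull = ConvexHull(pts)
    triangles = hull.simplices.astype(np.int64)
    vertices = pts
    mesh = SurfaceMesh(vertices, triangles,
                       np.zeros(len(triangles), dtype=np.int64),
                       np.full(len(triangles), "L"))
    # scale so the mean triangle area matches the requested resolution
    total = mesh.triangle_area.sum()
    scale = np.sqrt(mean_triangle_area * len(triangles) / total)
    vertices = vertices * scale

    centers = vertices[triangles].mean(axis=1)
    hemisphere = np.where(centers[:, 0] < 0, "L", "R")

    if n_regions == 1:
        labels = np.zeros(len(triangles), dtype=np.int64)
        hemisphere = np.full(len(triangles), "L")
    elif n_regions % 2 == 0:
        k = n_regions // 2
        left = np.where(hemisphere == "L")[0]
        right = np.where(hemisphere == "R")[0]
        if len(left) < k or len(right) < k:
            raise ValueError("too few triangles per hemisphere for n_regions")
        seeds_l = centers[left[_farthest_point_seeds(centers[left], k, rng)]]
        seeds_r = seeds_l * np.array([-1.0, 1.0, 1.0])  # mirrored homologues
        labels = np.empty(len(triangles), dtype=np.int64)
        labels[left] = np.argmin(
            np.linalg.norm(centers[left][:, None] - seeds_l[None], axis=2), axis=1)
        labels[right] = k + np.argmin(
            np.linalg.norm(centers[right][:, None] - seeds_r[None], axis=2), axis=1)
    else:
        seeds = centers[_farthest_point_seeds(centers, n_regions, rng)]
        labels = np.argmin(
            np.linalg.norm(centers[:, None] - seeds[None], axis=2), axis=1
        ).astype(np.int64)
        hemisphere = np.where(seeds[labels, 0] < 0, "L", "R")

    mesh = SurfaceMesh(vertices, triangles, labels, hemisphere)
    if n_regions > 1:
        adj_a, adj_b = mesh.triangle_adjacency()
        labels = _repair_region_connectivity(labels, adj_a, adj_b, hemisphere)
        mesh = SurfaceMesh(vertices, triangles, labels, hemisphere)
    if len(np.unique(labels)) != n_regions:
        raise ValueError("region partition collapsed; use more triangles")
    return mesh


# ---------------------------------------------------------------------------
# Streamline generation
# ---------------------------------------------------------------------------

def _arc_polyline(a: np.ndarray, b: np.ndarray, length: float) -> np.ndarray:
    """Three-point polyline from a to b with exact trajectory length.

    The midpoint is displaced perpendicular to the chord so that
    |a-m| + |m-b| equals ``length`` exactly (requires length >= chord).
    """
    chord = float(np.linalg.norm(b - a))
    mid = 0.5 * (a + b)
    if length <= chord * (1 + 1e-12):
        return np.vstack([a, mid, b])
    h = np.sqrt((length / 2.0) ** 2 - (chord / 2.0) ** 2)
    # outward (radial) direction, made orthogonal to the chord
    u = mid.copy()
    d = b - a
    nd = np.linalg.norm(d)
    if nd > 0:
        u = u - (u @ d) / (nd * nd) * d
    if np.linalg.norm(u) < 1e-9:          # chord passes through the origin
        u = np.cross(d, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(u) < 1e-9:
            u = np.cross(d, np.array([0.0, 1.0, 0.0]))
    u = u / np.linalg.norm(u)
    return np.vstack([a, mid + h * u, b])


def streamlines_from_edges(mesh: SurfaceMesh, edges: np.ndarray,
                           length_bounds: tuple[float, float],
                           rng: np.random.Generator) -> StreamlineSet:
    """Materialize one curved streamline per (triangle_i, triangle_j) edge.

    Trajectory length is an affine, monotone function of the inter-center
    chord, ``low + margin + chord * (1 + bulge)``, clipped into the bounds —
    so rewiring short edges into long ones raises mean fiber length, while
    every generated length respects the tract-length filter.
    """
    low, high = length_bounds
    if len(edges) == 0:
        return StreamlineSet.from_polylines([])
    centers = mesh.triangle_center
    a = centers[edges[:, 0]]
    b = centers[edges[:, 1]]
    chord = np.linalg.norm(b - a, axis=1)
    bulge = rng.uniform(0.05, 0.35, size=len(edges))
    length = np.clip(low + 0.5 + chord * (1.0 + bulge), low + 0.25, high - 0.25)
    length = np.maximum(length, chord * (1 + 1e-9))
    # vectorized 3-point arcs: midpoint displaced perpendicular to the chord
    mid = 0.5 * (a + b)
    h = np.sqrt(np.maximum(0.0, (length / 2.0) ** 2 - (chord / 2.0) ** 2))
    d = b - a
    nd2 = np.maximum((d * d).sum(axis=1), 1e-30)
    u = mid - ((mid * d).sum(axis=1) / nd2)[:, None] * d
    nu = np.linalg.norm(u, axis=1)
    bad = nu < 1e-9                      # chord passes through the origin
    if bad.any():
        alt = np.cross(d[bad], np.array([0.0, 0.0, 1.0]))
        alt2 = np.cross(d[bad], np.array([0.0, 1.0, 0.0]))
        use2 = np.linalg.norm(alt, axis=1) < 1e-9
        alt[use2] = alt2[use2]
        u[bad] = alt
        nu = np.linalg.norm(u, axis=1)
    u = u / nu[:, None]
    pts = np.stack([a, mid + h[:, None] * u, b], axis=1).reshape(-1, 3)
    offs = np.arange(len(edges) + 1, dtype=np.int64) * 3
    return StreamlineSet(pts, offs)


def generate_streamlines(mesh: SurfaceMesh, n: int, intra_fraction: float,
                         length_bounds: tuple[float, float],
                         seed: int) -> StreamlineSet:
    """Random streamlines with endpoints at triangle centers.

    A fraction ``intra_fraction`` (in expectation; exact count by rounding)
    connects two triangles of the same region, the rest two different
    regions.  All trajectory lengths lie strictly inside ``length_bounds``.
    """
    if not 0.0 <= intra_fraction <= 1.0:
        raise ValueError("intra_fraction must be in [0, 1]")
    low, high = length_bounds
    if low <= 0 or high <= low:
        raise ValueError("length bounds must be positive with low < high")
    if n == 0:
        return StreamlineSet.from_polylines([])
    rng = np.random.default_rng(seed)
    labels = mesh.region_label
    n_tri = mesh.n_triangles
    n_intra = int(round(n * intra_fraction))
    pairs = np.empty((n, 2), dtype=np.int64)
    multi_region = len(np.unique(labels)) > 1
    for i in range(n):
        a = rng.integers(n_tri)
        same = labels == labels[a]
        if i < n_intra or not multi_region:
            pool = np.where(same)[0]
            pool = pool[pool != a]
            if len(pool) == 0:
                pool = np.array([a])
        else:
            pool = np.where(~same)[0]
        pairs[i] = (a, pool[rng.integers(len(pool))])
    return streamlines_from_edges(mesh, pairs, length_bounds, rng)


# ---------------------------------------------------------------------------
# Planted within-region effect
# ---------------------------------------------------------------------------

def rewire_short_to_long(edges: np.ndarray, centers: np.ndarray,
                         region_nodes: np.ndarray, rate: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Replace a fraction of the shortest intra-region edges by long ones.

    ``edges`` is an (E, 2) array over node ids; only edges with both ends in
    ``region_nodes`` are touched.  The number of intra-region edges is
    conserved; the removed edges are the shortest by inter-center distance
    and the added ones connect currently unconnected far-apart pairs (above
    the 75th percentile of the region's pairwise distances, relaxed if too
    few candidates exist).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    region_set = np.zeros(centers.shape[0], dtype=bool)
    region_set[region_nodes] = True
    intra_mask = region_set[edges[:, 0]] & region_set[edges[:, 1]]
    intra_idx = np.where(intra_mask)[0]
    n_intra = len(intra_idx)
    if n_intra < 2:
        warnings.warn("region has < 2 intra-region edges; returned unchanged")
        return edges.copy()
    m = int(round(rate * n_intra))
    if m == 0:
        return edges.copy()

    dist = np.linalg.norm(centers[edges[intra_idx, 0]]
                          - centers[edges[intra_idx, 1]], axis=1)
    remove = intra_idx[np.argsort(dist, kind="stable")[:m]]

    nodes = np.asarray(region_nodes)
    sub = centers[nodes]
    pd = np.linalg.norm(sub[:, None] - sub[None], axis=2)
    iu, ju = np.triu_indices(len(nodes), k=1)
    pair_d = pd[iu, ju]

    existing = set()
    for u, v in edges[intra_mask]:
        existing.add((min(u, v), max(u, v)))
    for q in (75.0, 50.0, 0.0):
        thresh = np.percentile(pair_d, q)
        cand = [(nodes[i], nodes[j]) for i, j, d0 in zip(iu, ju, pair_d)
                if d0 >= thresh
                and (min(nodes[i], nodes[j]), max(nodes[i], nodes[j])) not in existing]
        if len(cand) >= m:
            break
    if len(cand) < m:
        m = len(cand)
        remove = remove[:m]
    pick = rng.choice(len(cand), size=m, replace=False)
    new_edges = np.array([cand[i] for i in pick], dtype=np.int64).reshape(m, 2)
    out = edges.copy()
    out[remove] = new_edges
    return out


def plant_within_region_effect(connectome, region: int, rate: float, seed: int):
    """Apply the short-to-long rewiring effect to a built connectome.

    Returns a new ``HighResConnectome`` with the same intra-region edge
    count; inter-region edges are untouched.  The region's retained-length
    list is updated consistently: the lengths of the removed (shortest)
    edges are dropped and lengths for the new edges are synthesized from
    their inter-center chords using the region's observed length/chord
    ratio.  A rate of 0 returns an identical copy.
    """
    from .connectome import HighResConnectome  # local import to avoid a cycle
    import scipy.sparse as sp

    if region not in connectome.node_region:
        raise KeyError(f"unknown region {region}")
    counts = sp.triu(connectome.counts, k=1).tocoo()
    edges = np.column_stack([counts.row, counts.col]).astype(np.int64)
    vals = counts.data
    region_nodes = np.where(connectome.node_region == region)[0]
    rng = np.random.default_rng(seed)

    region_set = np.zeros(connectome.n_nodes, dtype=bool)
    region_set[region_nodes] = True
    intra_mask = region_set[edges[:, 0]] & region_set[edges[:, 1]]
    if intra_mask.sum() < 2:
        warnings.warn("region has < 2 intra-region edges; returned unchanged")
        return connectome

    centers = connectome.node_center
    old_intra = edges[intra_mask]
    new_edges = rewire_short_to_long(edges, centers, region_nodes, rate, rng)
    new_intra = new_edges[intra_mask]

    changed = np.any(old_intra != new_intra, axis=1)
    lengths = np.sort(np.asarray(
        connectome.intra_region_lengths.get(region, np.empty(0)), dtype=float))
    if changed.any() and len(lengths) >= changed.sum():
        old_chord = np.linalg.norm(centers[old_intra[:, 0]]
                                   - centers[old_intra[:, 1]], axis=1)
        new_chord = np.linalg.norm(centers[new_intra[changed, 0]]
                                   - centers[new_intra[changed, 1]], axis=1)
        ratio = (lengths.mean() / old_chord.mean()) if old_chord.mean() > 0 else 1.0
        lengths = np.concatenate(
            [lengths[changed.sum():], new_chord * ratio])

    n = connectome.n_nodes
    new_counts = sp.coo_matrix(
        (vals, (new_edges[:, 0], new_edges[:, 1])), shape=(n, n)).tocsr()
    new_counts = new_counts + new_counts.T
    area = connectome.node_area
    coo = sp.triu(new_counts, k=1).tocoo()
    w = coo.data / ((area[coo.row] + area[coo.col]) / 2.0)
    weights = sp.coo_matrix((w, (coo.row, coo.col)), shape=(n, n)).tocsr()
    weights = weights + weights.T

    new_lengths = dict(connectome.intra_region_lengths)
    new_lengths[region] = np.asarray(lengths, dtype=float)
    return HighResConnectome(
        counts=new_counts, weights=weights,
        node_region=connectome.node_region, node_center=connectome.node_center,
        node_area=connectome.node_area, node_hemisphere=connectome.node_hemisphere,
        intra_region_lengths=new_lengths,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Demographic marginals reproduce the study table exactly (36 controls,
    33 patients: 19 left / 14 right surgery, 21 good / 12 bad outcome, sex
    counts fixed, ages and durations drawn from the published mean/SD).
    The effect model plants, per patient, a rewiring rate
    ``baseline_rate + slope_multiplier[r] * duration_slope * duration`` in
    each duration-related (ipsilateral) region ``r``, and a fixed
    ``outcome_rate`` in a contralateral region set for bad-outcome patients.
    """

    # group structure (study Table 1)
    n_controls: int = 36
    control_sex_mf: tuple[int, int] = (17, 19)
    left_sex_mf: tuple[int, int] = (7, 12)
    right_sex_mf: tuple[int, int] = (8, 6)
    left_outcome_good_bad: tuple[int, int] = (12, 7)
    right_outcome_good_bad: tuple[int, int] = (9, 5)
    control_age: tuple[float, float] = (39.06, 12.32)
    patient_age: tuple[float, float] = (38.79, 12.79)
    duration_mean_sd: tuple[float, float] = (23.45, 15.03)
    min_duration: float = 1.0

    # mesh / resolution
    n_regions: int = 16
    triangles_per_region: int = 120
    resolution: str = "12k"               # key of RESOLUTION_AREAS_MM2
    sa_scale_sd: float = 0.03             # per-subject global surface scale SD

    # connectivity model
    geometric_radius_factor: float = 1.8  # r = factor * sqrt(mean area)
    radius_jitter_sd: float = 0.04        # per-subject fractional radius jitter
    edge_keep_prob: float = 0.88
    random_edge_frac: float = 0.06        # mean long-range edge burden
    random_edge_frac_sd: float = 0.05     # between-subject burden variability
    intra_fraction: float = 0.7
    length_bounds: tuple[float, float] = (10.0, 300.0)

    # planted effect model
    baseline_rate: float = 0.005
    duration_slope: float = 0.005         # rate increase per year past onset
    n_duration_regions: int = 6           # ipsilateral regions
    onset_years_range: tuple[float, float] = (0.0, 25.0)
    # regions are recruited progressively: region j becomes affected once
    # duration exceeds its onset (onsets spread evenly over the range), and
    # its rate then grows linearly with the years since onset
    n_outcome_regions: int = 4            # contralateral regions, bad outcome
    outcome_rate: float = 0.10
    rate_noise_sd: float = 0.025

    _TUPLE_FIELDS = ("control_sex_mf", "left_sex_mf", "right_sex_mf",
                     "left_outcome_good_bad", "right_outcome_good_bad",
                     "control_age", "patient_age", "duration_mean_sd",
                     "length_bounds", "onset_years_range")

    def __post_init__(self) -> None:
        for name in self._TUPLE_FIELDS:
            setattr(self, name, tuple(getattr(self, name)))
        if self.n_controls < 0 or min(self.left_outcome_good_bad) < 0 \
                or min(self.right_outcome_good_bad) < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_regions % 2 != 0:
            raise ValueError("n_regions must be even (hemisphere pairing)")
        if self.resolution not in RESOLUTION_AREAS_MM2:
            raise ValueError(f"resolution must be one of {list(RESOLUTION_AREAS_MM2)}")
        k = self.n_regions // 2
        if self.n_duration_regions > k or self.n_outcome_regions > k:
            raise ValueError("effect region sets exceed regions per hemisphere")

    @property
    def n_left(self) -> int:
        return sum(self.left_outcome_good_bad)

    @property
    def n_right(self) -> int:
        return sum(self.right_outcome_good_bad)

    @property
    def n_patients(self) -> int:
        return self.n_left + self.n_right

    @property
    def mean_triangle_area(self) -> float:
        return RESOLUTION_AREAS_MM2[self.resolution]


def _truncated_normal(rng, mean, sd, n, low):
    out = rng.normal(mean, sd, size=n)
    bad = out < low
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=bad.sum())
        bad = out < low
    return out


def _interleave_sexes(n_m: int, n_f: int, rng) -> list[str]:
    sexes = ["M"] * n_m + ["F"] * n_f
    rng.shuffle(sexes)
    return sexes


def _geometric_edges(centers: np.ndarray, labels: np.ndarray, region: int,
                     radius: float) -> np.ndarray:
    nodes = np.where(labels == region)[0]
    sub = centers[nodes]
    tree = cKDTree(sub)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64)
    return np.column_stack([nodes[pairs[:, 0]], nodes[pairs[:, 1]]]).astype(np.int64)


def _subject_edges(mesh: SurfaceMesh, cfg: CohortConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Noisy geometric intra-region edges plus random inter-region edges."""
    centers = mesh.triangle_center
    labels = mesh.region_label
    jitter = rng.normal(1.0, cfg.radius_jitter_sd) if cfg.radius_jitter_sd > 0 else 1.0
    radius = cfg.geometric_radius_factor * np.sqrt(cfg.mean_triangle_area) \
        * max(0.5, jitter)

    intra = []
    for region in mesh.region_ids:
        e = _geometric_edges(centers, labels, region, radius)
        if len(e):
            keep = rng.random(len(e)) < cfg.edge_keep_prob
            e = e[keep]
            # sprinkle a few random long-range intra edges
            nodes = np.where(labels == region)[0]
            # per-region long-range edge burden: the healthy variability
            # floor that planted disease effects must exceed
            edge_frac = float(np.clip(rng.normal(cfg.random_edge_frac,
                                                 cfg.random_edge_frac_sd),
                              0.0, 4.0 * cfg.random_edge_frac))
            n_extra = rng.poisson(edge_frac * len(e))
            if n_extra > 0 and len(nodes) > 2:
                extra = rng.choice(nodes, size=(n_extra, 2))
                extra = extra[extra[:, 0] != extra[:, 1]]
                e = np.vstack([e, np.sort(extra, axis=1)])
        intra.append(e)
    intra_edges = np.vstack([e for e in intra if len(e)]) if intra else \
        np.empty((0, 2), dtype=np.int64)
    # deduplicate
    intra_edges = np.unique(np.sort(intra_edges, axis=1), axis=0)

    f = cfg.intra_fraction
    n_inter = int(round(len(intra_edges) * (1.0 - f) / f)) if f > 0 else 0
    n_tri = mesh.n_triangles
    inter_parts = []
    remaining = n_inter
    while remaining > 0:
        cand = rng.integers(n_tri, size=(2 * remaining + 8, 2))
        cand = cand[labels[cand[:, 0]] != labels[cand[:, 1]]][:remaining]
        inter_parts.append(np.sort(cand, axis=1))
        remaining -= len(cand)
    inter_edges = np.vstack(inter_parts).astype(np.int64) if inter_parts \
        else np.empty((0, 2), dtype=np.int64)
    return np.vstack([intra_edges, inter_edges])


def generate_cohort(config: CohortConfig | None = None, seed: int = 0):
    """Generate the full synthetic cohort.

    Returns ``(subjects, ground_truth)`` where ``subjects`` is a list of
    ``(SubjectRecord, SurfaceMesh, StreamlineSet)`` and ``ground_truth``
    records every planted effect.  Same seed gives a bit-identical cohort.
    """
    cfg = config or CohortConfig()
    root = np.random.SeedSequence(seed)
    mesh_ss, demo_ss, subj_ss = root.spawn(3)
    mesh_seed = int(mesh_ss.generate_state(1)[0] % (2 ** 31))
    base_mesh = generate_region_mesh(
        cfg.n_regions, cfg.n_regions * cfg.triangles_per_region,
        seed=mesh_seed, mean_triangle_area=cfg.mean_triangle_area)
    k = cfg.n_regions // 2

    demo_rng = np.random.default_rng(demo_ss)
    records: list[SubjectRecord] = []
    # controls: pseudo-sides alternate L/R in seeded shuffled order
    sexes = _interleave_sexes(*cfg.control_sex_mf, demo_rng)
    ages = _truncated_normal(demo_rng, *cfg.control_age, cfg.n_controls, 0.0)
    pseudo = ["L", "R"] * (cfg.n_controls // 2 + 1)
    demo_rng.shuffle(pseudo)
    for i in range(cfg.n_controls):
        records.append(SubjectRecord(
            id=f"C{i + 1:02d}", group="control", age=float(ages[i]),
            sex=sexes[i], assigned_side=pseudo[i]))
    # patients
    for side, sex_mf, (n_good, n_bad) in (
            ("L", cfg.left_sex_mf, cfg.left_outcome_good_bad),
            ("R", cfg.right_sex_mf, cfg.right_outcome_good_bad)):
        n_side = n_good + n_bad
        sexes = _interleave_sexes(*sex_mf, demo_rng)
        ages = _truncated_normal(demo_rng, *cfg.patient_age, n_side, 0.0)
        durations = _truncated_normal(demo_rng, *cfg.duration_mean_sd,
                                      n_side, cfg.min_duration)
        # outcomes stratified over the sorted durations so short/long
        # duration groups carry matched outcome proportions (the study
        # reports matched outcome and side distributions at the 20-year
        # split, which the group comparisons rely on)
        outcomes = np.empty(n_side, dtype=int)
        order = np.argsort(durations)
        bad_slots = np.round(np.linspace(0, n_side - 1, n_bad)).astype(int) \
            if n_bad else np.empty(0, dtype=int)
        mask = np.zeros(n_side, dtype=bool)
        mask[bad_slots] = True
        outcomes[order] = np.where(mask, 4, 1)
        for i in range(n_side):
            records.append(SubjectRecord(
                id=f"P{side}{i + 1:02d}", group="patient", age=float(ages[i]),
                sex=sexes[i], side=side, duration=float(durations[i]),
                outcome=outcomes[i], assigned_side=side))

    # effect-region templates in within-hemisphere coordinates
    onsets = np.linspace(*cfg.onset_years_range, cfg.n_duration_regions) \
        if cfg.n_duration_regions else np.empty(0)
    dur_template = list(range(cfg.n_duration_regions))
    out_template = list(range(cfg.n_outcome_regions))

    affected: dict[str, dict[int, float]] = {}
    dur_regions: dict[str, list[int]] = {}
    out_regions: dict[str, list[int]] = {}
    flip: dict[str, str] = {}

    subjects = []
    child_seeds = subj_ss.spawn(len(records))
    for rec, ss in zip(records, child_seeds):
        rng = np.random.default_rng(ss)
        flip[rec.id] = rec.assigned_side
        scale = max(0.5, rng.normal(1.0, cfg.sa_scale_sd))
        mesh = base_mesh.scaled(scale)
        edges = _subject_edges(mesh, cfg, rng)
        affected[rec.id] = {}
        ipsi_offset = 0 if rec.assigned_side == "L" else k
        contra_offset = k - ipsi_offset
        dur_regions[rec.id] = [r + ipsi_offset for r in dur_template]
        out_regions[rec.id] = [r + contra_offset for r in out_template]
        if rec.group == "patient":
            centers = mesh.triangle_center
            for j, r_local in enumerate(dur_template):
                region = r_local + ipsi_offset
                years_past_onset = max(0.0, rec.duration - float(onsets[j]))
                rate = 0.0
                if years_past_onset > 0:
                    rate = cfg.baseline_rate \
                        + cfg.duration_slope * years_past_onset \
                        + rng.normal(0.0, cfg.rate_noise_sd)
                rate = float(np.clip(rate, 0.0, 1.0))
                if rate > 0:
                    nodes = np.where(mesh.region_label == region)[0]
                    edges = rewire_short_to_long(edges, centers, nodes, rate, rng)
                affected[rec.id][region] = rate
            if not rec.good_outcome:
                for r_local in out_template:
                    region = r_local + contra_offset
                    rate = float(np.clip(
                        cfg.outcome_rate + rng.normal(0.0, cfg.rate_noise_sd),
                        0.0, 1.0))
                    if rate > 0:
                        nodes = np.where(mesh.region_label == region)[0]
                        edges = rewire_short_to_long(edges, centers, nodes,
                                                     rate, rng)
                    affected[rec.id][region] = rate
        streamlines = streamlines_from_edges(mesh, edges, cfg.length_bounds, rng)
        subjects.append((rec, mesh, streamlines))

    truth = EffectGroundTruth(
        affected_regions=affected, duration_regions=dur_regions,
        outcome_regions=out_regions, duration_slope=cfg.duration_slope,
        baseline_rate=cfg.baseline_rate, flip_side=flip)
    return subjects, truth


def cohort_dataframe(records):
    """Cohort table as a pandas DataFrame (one row per subject)."""
    import pandas as pd

    rows = []
    for rec in records:
        rec = rec[0] if isinstance(rec, tuple) else rec
        rows.append({
            "id": rec.id, "group": rec.group, "age": rec.age, "sex": rec.sex,
            "side": rec.side, "duration": rec.duration, "outcome": rec.outcome,
            "assigned_side": rec.assigned_side,
        })
    return pd.DataFrame(rows)
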