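"""Random isotropic fiber-network generation with circular cell voids.

Networks are built in a square domain (arbitrary units, AU) by uniformly
scattering nodes and greedily connecting them with straight fiber elements so
that the resulting graph approaches a target mean connectivity with
near-uniform fiber orientations and homogeneous local density.  Cells are
represented as circular voids carved out of the network; the nodes on a void's
perimeter form the set on which contractile displacements are later imposed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "GenerationConfig",
    "CellVoid",
    "NetworkGeometry",
    "generate_network",
    "carve_cell_voids",
    "orientation_uniformity_pvalue",
    "local_density_cv",
]


@dataclass
class GenerationConfig:
    """Parameters controlling network generation.

    The defaults reproduce the reference architecture: mean connectivity 8,
    cell diameter 0.08 AU and a 4:1 cell-diameter to mean-fiber-length ratio
    (mean fiber length 0.02 AU) inside a [-halfwidth, halfwidth]^2 domain.
    """

    target_connectivity: float = 8.0
    cell_diameter: float = 0.08
    mean_fiber_length: float | None = None  # default: cell_diameter / 4
    domain_halfwidth: float = 2.0
    candidate_neighbors: int = 14
    min_fiber_angle_deg: float = 15.0
    length_weight: float = 1.0
    lloyd_iterations: int = 1
    lloyd_damping: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_fiber_length is None:
            self.mean_fiber_length = self.cell_diameter / 4.0
        if self.target_connectivity < 3:
            raise ValueError("target_connectivity must be >= 3")
        if not self.mean_fiber_length < self.domain_halfwidth:
            raise ValueError("mean_fiber_length must be smaller than the domain halfwidth")


@dataclass
class CellVoid:
    center: np.ndarray  # (2,) AU
    radius: float  # AU


@dataclass
class NetworkGeometry:
    """Nodes, fiber elements and cell voids of a simulated fibrous domain."""

    node_positions: np.ndarray  # (N, 2) AU
    fibers: np.ndarray  # (M, 2) int node indices
    rest_lengths: np.ndarray  # (M,) AU
    domain_halfwidth: float
    cell_diameter: float
    rim_node_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    cell_voids: list[CellVoid] = field(default_factory=list)
    void_boundary_nodes: list[np.ndarray] = field(default_factory=list)
    fiber_thickness: float = 0.2  # metadata only; mechanics uses unit cross-section

    @property
    def n_nodes(self) -> int:
        return int(self.node_positions.shape[0])

    @property
    def n_fibers(self) -> int:
        return int(self.fibers.shape[0])

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.fibers.ravel(), 1)
        return deg

    def mean_connectivity(self) -> float:
        return float(self.degrees().mean())

    @property
    def pair_distance_diameters(self) -> float | None:
        """Center-to-center distance of the first two voids, in cell diameters."""
        if len(self.cell_voids) < 2:
            return None
        d = np.linalg.norm(self.cell_voids[0].center - self.cell_voids[1].center)
        return float(d / self.cell_diameter)

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        obj = {
            "nodes": self.node_positions.tolist(),
            "fibers": [
                [int(i), int(j), float(l)]
                for (i, j), l in zip(self.fibers, self.rest_lengths)
            ],
            "domain_halfwidth": self.domain_halfwidth,
            "cell_diameter": self.cell_diameter,
            "fiber_thickness": self.fiber_thickness,
            "rim_node_ids": self.rim_node_ids.tolist(),
            "voids": [
                {
                    "center": v.center.tolist(),
                    "radius": v.radius,
                    "boundary_nodes": b.tolist(),
                }
                for v, b in zip(self.cell_voids, self.void_boundary_nodes)
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "NetworkGeometry":
        with open(path) as fh:
            obj = json.load(fh)
        fib = np.asarray([[f[0], f[1]] for f in obj["fibers"]], dtype=int)
        rest = np.asarray([f[2] for f in obj["fibers"]], dtype=float)
        return cls(
            node_positions=np.asarray(obj["nodes"], dtype=float),
            fibers=fib,
            rest_lengths=rest,
            domain_halfwidth=obj["domain_halfwidth"],
            cell_diameter=obj["cell_diameter"],
            fiber_thickness=obj.get("fiber_thickness", 0.2),
            rim_node_ids=np.asarray(obj["rim_node_ids"], dtype=int),
            cell_voids=[
                CellVoid(np.asarray(v["center"], dtype=float), v["radius"])
                for v in obj["voids"]
            ],
            void_boundary_nodes=[
                np.asarray(v["boundary_nodes"], dtype=int) for v in obj["voids"]
            ],
        )


class ConnectivityError(RuntimeError):
    """Raised when generation cannot reach the target mean connectivity."""

    def __init__(self, achieved: float, target: float):
        self.achieved = achieved
        self.target = target
        super().__init__(
            f"could not reach target mean connectivity {target:g}; achieved {achieved:.2f}"
        )


def _node_density(mean_fiber_length: float, target_connectivity: float) -> float:
    # Mean distance to the k-th nearest neighbor of a planar Poisson process of
    # intensity rho is Gamma(k + 1/2) / Gamma(k) / sqrt(pi * rho).  Matching the
    # average over the first `target_connectivity` neighbors to the desired mean
    # fiber length fixes the node density.
    k = max(int(round(target_connectivity)), 1)
    from scipy.special import gammaln

    coeffs = np.exp(gammaln(np.arange(1, k + 1) + 0.5) - gammaln(np.arange(1, k + 1)))
    c = coeffs.mean()
    return (c / mean_fiber_length) ** 2 / np.pi


def _lloyd_relax(
    pos: np.ndarray, h: float, iterations: int, damping: float = 0.5
) -> np.ndarray:
    """Damped centroidal-Voronoi relaxation toward homogeneous node density.

    Each iteration moves every node a fraction ``damping`` of the way to the
    centroid of its Voronoi cell, evening out local node spacing (and hence
    local fiber density).  The damping keeps positions disordered enough for
    the fiber orientation distribution to stay isotropic; undamped relaxation
    develops local hexagonal order with strongly preferred directions.
    Boundary cells are closed by reflecting the points across the four walls.
    """
    from scipy.spatial import Voronoi

    n = pos.shape[0]
    for _ in range(iterations):
        refl = [
            pos,
            np.column_stack([2 * h - pos[:, 0], pos[:, 1]]),
            np.column_stack([-2 * h - pos[:, 0], pos[:, 1]]),
            np.column_stack([pos[:, 0], 2 * h - pos[:, 1]]),
            np.column_stack([pos[:, 0], -2 * h - pos[:, 1]]),
        ]
        vor = Voronoi(np.concatenate(refl, axis=0))
        new = pos.copy()
        for i in range(n):
            verts = vor.vertices[vor.regions[vor.point_region[i]]]
            if verts.shape[0] < 3:
                continue
            x, y = verts[:, 0], verts[:, 1]
            cross = x * np.roll(y, -1) - np.roll(x, -1) * y
            area = 0.5 * cross.sum()
            if abs(area) < 1e-300:
                continue
            cx = np.sum((x + np.roll(x, -1)) * cross) / (6.0 * area)
            cy = np.sum((y + np.roll(y, -1)) * cross) / (6.0 * area)
            new[i] = (cx, cy)
        pos = np.clip(pos + damping * (new - pos), -h, h)
    return pos


def generate_network(config: GenerationConfig) -> NetworkGeometry:
    """Generate a random, isotropic, homogeneous fiber network.

    Nodes are scattered uniformly and connected by a greedy candidate-edge
    insertion: nearest-neighbor candidate edges are admitted in order of a
    length-based cost, subject to degree caps and a minimum inter-fiber angle
    at both endpoints; relaxation passes then top the mean connectivity up to
    the target.  The procedure is fully deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    h = config.domain_halfwidth
    L = config.mean_fiber_length
    rho = _node_density(L, config.target_connectivity)
    # stratified scatter: one uniform point per grid cell.  Compared to a pure
    # Poisson scatter this suppresses fiber-count fluctuations at the scale of
    # a quantification window, giving the homogeneous density the architecture
    # calls for while keeping positions (and fiber orientations) isotropic.
    nx = max(int(round(np.sqrt(rho) * 2.0 * h)), 2)
    n_nodes = nx * nx
    cell_w = 2.0 * h / nx
    gx, gy = np.meshgrid(np.arange(nx), np.arange(nx), indexing="ij")
    base = np.stack([gx.ravel(), gy.ravel()], axis=1) * cell_w - h
    pos = base + rng.uniform(0.0, cell_w, size=(n_nodes, 2))
    pos = _lloyd_relax(pos, h, config.lloyd_iterations, config.lloyd_damping)

    tree = cKDTree(pos)
    k = min(config.candidate_neighbors + 1, n_nodes)
    dist, idx = tree.query(pos, k=k)
    # candidate edges (i < j), deduplicated
    src = np.repeat(np.arange(n_nodes), k - 1)
    dst = idx[:, 1:].ravel()
    dd = dist[:, 1:].ravel()
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    key = lo.astype(np.int64) * n_nodes + hi
    _, uniq = np.unique(key, return_index=True)
    lo, hi, dd = lo[uniq], hi[uniq], dd[uniq]
    cost = config.length_weight * (dd / L - 1.0) ** 2
    order = np.argsort(cost, kind="stable")
    lo, hi, dd = lo[order], hi[order], dd[order]

    target = config.target_connectivity
    cap = int(round(target))
    deg = np.zeros(n_nodes, dtype=int)
    # incident unit vectors per node, for the angle constraint
    incident: list[list[np.ndarray]] = [[] for _ in range(n_nodes)]
    cos_max = np.cos(np.deg2rad(config.min_fiber_angle_deg))
    edges: list[tuple[int, int]] = []
    used = np.zeros(lo.shape[0], dtype=bool)

    def angle_ok(a: int, u: np.ndarray) -> bool:
        for v in incident[a]:
            if abs(float(u @ v)) > cos_max:
                return False
        return True

    # pass 1: degree caps + angle separation
    for e in range(lo.shape[0]):
        a, b = int(lo[e]), int(hi[e])
        if deg[a] >= cap or deg[b] >= cap:
            continue
        u = pos[b] - pos[a]
        u /= np.linalg.norm(u)
        if not (angle_ok(a, u) and angle_ok(b, u)):
            continue
        edges.append((a, b))
        incident[a].append(u)
        incident[b].append(u)
        deg[a] += 1
        deg[b] += 1
        used[e] = True

    # pass 2: fill remaining degree ignoring the angle constraint
    if deg.mean() < target - 0.1:
        for e in range(lo.shape[0]):
            if used[e]:
                continue
            a, b = int(lo[e]), int(hi[e])
            if deg[a] >= cap or deg[b] >= cap:
                continue
            edges.append((a, b))
            deg[a] += 1
            deg[b] += 1
            used[e] = True
            if deg.mean() >= target:
                break

    # pass 3: allow slight over-filling of one endpoint to lift the mean
    if deg.mean() < target - 0.4:
        for e in range(lo.shape[0]):
            if used[e]:
                continue
            a, b = int(lo[e]), int(hi[e])
            if min(deg[a], deg[b]) >= cap or max(deg[a], deg[b]) >= cap + 2:
                continue
            edges.append((a, b))
            deg[a] += 1
            deg[b] += 1
            used[e] = True
            if deg.mean() >= target:
                break

    fibers = np.asarray(edges, dtype=int)
    # drop isolated nodes (no incident fiber) and reindex
    connected = np.zeros(n_nodes, dtype=bool)
    connected[fibers.ravel()] = True
    if not np.all(connected):
        remap = np.cumsum(connected) - 1
        pos = pos[connected]
        fibers = remap[fibers]
        deg = deg[connected]
        n_nodes = pos.shape[0]

    mean_deg = float(deg.mean())
    if abs(mean_deg - target) > 0.5:
        raise ConnectivityError(mean_deg, target)

    rest = np.linalg.norm(pos[fibers[:, 0]] - pos[fibers[:, 1]], axis=1)
    rim_band = 1.5 * L
    rim = np.flatnonzero(np.max(np.abs(pos), axis=1) > h - rim_band)
    return NetworkGeometry(
        node_positions=pos,
        fibers=fibers,
        rest_lengths=rest,
        domain_halfwidth=h,
        cell_diameter=config.cell_diameter,
        rim_node_ids=rim,
    )


def _segment_point_distance(p0: np.ndarray, p1: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorized distance of segments p0->p1 to point c."""
    d = p1 - p0
    t = np.einsum("ij,ij->i", c - p0, d) / np.maximum(np.einsum("ij,ij->i", d, d), 1e-300)
    t = np.clip(t, 0.0, 1.0)
    proj = p0 + t[:, None] * d
    return np.linalg.norm(proj - c, axis=1)


def _truncate_at_circle(pos, fibers, rest, center, radius):
    """Truncate all fibers at a circle, removing the interior portions.

    New nodes are appended at circle intersections; a fiber passing straight
    through the disc is split into its two exterior segments.  Rest lengths
    are shared proportionally to the kept fraction of the segment.
    """
    c = np.asarray(center, dtype=float)
    tol = 1e-12
    p0 = pos[fibers[:, 0]]
    p1 = pos[fibers[:, 1]]
    in0 = np.linalg.norm(p0 - c, axis=1) < radius * (1.0 - 1e-9)
    in1 = np.linalg.norm(p1 - c, axis=1) < radius * (1.0 - 1e-9)
    crosses = _segment_point_distance(p0, p1, c[None, :]) < radius * (1.0 - 1e-9)

    keep_fibers = []  # (node_i or new pos, node_j or new pos, rest_length)
    new_pos = []

    def circle_roots(a, b):
        # parameters t of |a + t (b - a) - c| = radius along the segment
        d = b - a
        f = a - c
        A = d @ d
        B = 2.0 * (f @ d)
        C = f @ f - radius**2
        disc = B * B - 4.0 * A * C
        if disc <= 0.0 or A < tol:
            return None
        s = np.sqrt(disc)
        return (-B - s) / (2.0 * A), (-B + s) / (2.0 * A)

    def add_node(p):
        new_pos.append(p)
        return pos.shape[0] + len(new_pos) - 1

    keep_mask = ~(in0 | in1 | crosses)
    out_f, out_r = [fibers[keep_mask]], [rest[keep_mask]]
    for e in np.flatnonzero(~keep_mask):
        a, b = p0[e], p1[e]
        i, j = int(fibers[e, 0]), int(fibers[e, 1])
        if in0[e] and in1[e]:
            continue  # fully interior
        roots = circle_roots(a, b)
        if roots is None:
            continue
        t1, t2 = roots
        seg = b - a
        seg_len = np.linalg.norm(seg)
        if in0[e] != in1[e]:
            # one endpoint inside: keep the exterior part
            t = t2 if in0[e] else t1
            t = float(np.clip(t, 0.0, 1.0))
            p_cut = a + t * seg
            if in0[e]:
                frac = 1.0 - t
                pair = (add_node(p_cut), j)
            else:
                frac = t
                pair = (i, add_node(p_cut))
            if frac * seg_len > tol:
                out_f.append(np.array([pair]))
                out_r.append(np.array([rest[e] * frac]))
        else:
            # both endpoints outside, chord through the disc: two segments
            t1 = float(np.clip(t1, 0.0, 1.0))
            t2 = float(np.clip(t2, 0.0, 1.0))
            if t2 - t1 < tol:
                out_f.append(np.array([[i, j]]))
                out_r.append(np.array([rest[e]]))
                continue
            n1 = add_node(a + t1 * seg)
            n2 = add_node(a + t2 * seg)
            if t1 * seg_len > tol:
                out_f.append(np.array([[i, n1]]))
                out_r.append(np.array([rest[e] * t1]))
            if (1.0 - t2) * seg_len > tol:
                out_f.append(np.array([[n2, j]]))
                out_r.append(np.array([rest[e] * (1.0 - t2)]))

    if new_pos:
        pos = np.concatenate([pos, np.asarray(new_pos)], axis=0)
    fibers = np.concatenate(out_f, axis=0).astype(int)
    rest = np.concatenate(out_r)
    return pos, fibers, rest


def carve_cell_voids(
    geom: NetworkGeometry,
    centers: np.ndarray,
    diameter: float | None = None,
    boundary_annulus: float = 0.1,
) -> NetworkGeometry:
    """Carve circular cell voids into a network.

    Fibers crossing a void disc are truncated at the perimeter: the interior
    portion is removed and new nodes are created at the circle intersections,
    so the fiber material density is conserved right up to the cell boundary.
    Fibers fully inside a void are removed and interior nodes lose all their
    fibers (they are ignored downstream).  Truncated fibers keep a
    length-proportional share of their rest length, leaving the carved network
    stress-free at onset.  Nodes within the perimeter annulus (width
    ``boundary_annulus`` of the radius) are registered as that cell's boundary
    nodes.  Carving is idempotent.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if diameter is None:
        diameter = geom.cell_diameter
    radius = diameter / 2.0
    h = geom.domain_halfwidth

    for c in centers:
        if np.max(np.abs(c)) > h - (radius + diameter):
            raise ValueError(
                f"void center {c} too close to the domain rim; "
                f"need >= one diameter of margin"
            )
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.linalg.norm(centers[i] - centers[j]) < diameter:
                raise ValueError("cell voids overlap")

    pos = geom.node_positions.copy()
    fibers = geom.fibers.copy()
    rest = geom.rest_lengths.copy()
    for c in centers:
        pos, fibers, rest = _truncate_at_circle(pos, fibers, rest, c, radius)

    deg = np.zeros(pos.shape[0], dtype=int)
    np.add.at(deg, fibers.ravel(), 1)
    boundary_sets = []
    voids = []
    for c in centers:
        r = np.linalg.norm(pos - c, axis=1)
        bset = np.flatnonzero(
            (r >= radius * (1.0 - 1e-9)) & (r <= radius * (1.0 + boundary_annulus))
        )
        # only nodes that still carry fibers act as the cell boundary
        bset = bset[deg[bset] > 0]
        if bset.size == 0:
            raise ValueError(f"no boundary nodes captured for void at {c}")
        boundary_sets.append(bset)
        voids.append(CellVoid(center=np.asarray(c, float), radius=radius))

    return NetworkGeometry(
        node_positions=pos,
        fibers=fibers,
        rest_lengths=rest,
        domain_halfwidth=h,
        cell_diameter=diameter,
        rim_node_ids=geom.rim_node_ids,
        cell_voids=list(geom.cell_voids) + voids,
        void_boundary_nodes=list(geom.void_boundary_nodes) + boundary_sets,
        fiber_thickness=geom.fiber_thickness,
    )


# -- architecture statistics ------------------------------------------------


def orientation_uniformity_pvalue(geom: NetworkGeometry, n_bins: int = 12) -> float:
    """Chi-square p-value of fiber orientations against a uniform distribution."""
    d = geom.node_positions[geom.fibers[:, 1]] - geom.node_positions[geom.fibers[:, 0]]
    theta = np.mod(np.arctan2(d[:, 1], d[:, 0]), np.pi)
    counts, _ = np.histogram(theta, bins=n_bins, range=(0.0, np.pi))
    return float(stats.chisquare(counts).pvalue)


def local_density_cv(geom: NetworkGeometry, n_tiles: int = 10) -> float:
    """Coefficient of variation of total fiber length over an n x n tiling."""
    mid = 0.5 * (
        geom.node_positions[geom.fibers[:, 0]] + geom.node_positions[geom.fibers[:, 1]]
    )
    lengths = np.linalg.norm(
        geom.node_positions[geom.fibers[:, 1]] - geom.node_positions[geom.fibers[:, 0]],
        axis=1,
    )
    h = geom.domain_halfwidth
    ix = np.clip(((mid[:, 0] + h) / (2 * h) * n_tiles).astype(int), 0, n_tiles - 1)
    iy = np.clip(((mid[:, 1] + h) / (2 * h) * n_tiles).astype(int), 0, n_tiles - 1)
    tiles = np.zeros((n_tiles, n_tiles))
    np.add.at(tiles, (ix, iy), lengths)
    return float(tiles.std() / tiles.mean())
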