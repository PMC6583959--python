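"""Pseudo-2D angular pore networks.

The spatial backbone of every simulation is a lattice of nodes joined by
pores.  Each pore is a straight channel whose cross-section is either an
isosceles triangle (defined by the inscribed-circle radius ``r`` and the
apex angle ``gamma``) or a rectangle (width ``W`` x height ``H``).  Angular
cross-sections matter because they retain water in their corners under
suction, allowing liquid and gas to occupy the same pore — the property the
hydrology module builds on.

Networks are pseudo-2D: nodes carry planar coordinates and every pore has a
scalar ``depth`` (out-of-plane extrusion) used only for volume and
biomass-density bookkeeping.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PoreGeometry",
    "PoreNetwork",
    "triangle_total_area",
    "triangle_corner_angles",
    "build_lattice",
    "build_aggregate_domain",
    "sample_pore_geometries",
    "rescale_length_for_porosity",
]

#: Default out-of-plane pore depth (m).  Matches the surface-colony
#: comparison convention (70 um pore height); override per scenario.
DEFAULT_DEPTH = 70e-6

#: Default apex angle (degrees) for triangular soil pores.  Soil pore space
#: is dominated by slit-like wedges between grain contacts; a very acute
#: apex gives the strong corner retention such pores show (a pore of
#: inscribed radius r then drains only once the meniscus radius sigma/|Psi|
#: falls close to r, rather than at ~1.6 r as for an equilateral section).
DEFAULT_GAMMA = 5.0


def triangle_corner_angles(gamma: float) -> tuple[float, float, float]:
    """Corner angles (degrees) of an isosceles triangle with apex ``gamma``."""
    if not 0.0 < gamma < 180.0:
        raise ValueError(f"apex angle gamma must be in (0, 180) deg, got {gamma}")
    base = (180.0 - gamma) / 2.0
    return (gamma, base, base)


def triangle_total_area(r: float, gamma: float) -> float:
    """Total cross-sectional area of an isosceles triangle with inscribed
    circle radius ``r`` and apex angle ``gamma`` (degrees).

    For any triangle, A = r * s with s the semiperimeter, and each side
    subtends s_i = r * cot(alpha_i / 2); hence A = r^2 * sum_i cot(alpha_i/2).
    """
    if r <= 0:
        raise ValueError(f"inscribed radius r must be positive, got {r}")
    angles = triangle_corner_angles(gamma)
    return r * r * sum(1.0 / math.tan(math.radians(a) / 2.0) for a in angles)


@dataclass
class PoreGeometry:
    """Cross-sectional geometry of a single pore.

    ``shape`` is ``"isosceles_triangle"`` (fields ``r``, ``gamma``) or
    ``"rectangle"`` (fields ``width``, ``height``).  ``length`` is the pore
    length along its axis; ``depth`` the pseudo-3D extrusion used for
    volume bookkeeping.
    """

    shape: str
    length: float
    r: float | None = None
    gamma: float | None = None
    width: float | None = None
    height: float | None = None
    depth: float = DEFAULT_DEPTH

    def __post_init__(self) -> None:
        if self.shape not in ("isosceles_triangle", "rectangle"):
            raise ValueError(f"unknown pore shape {self.shape!r}")
        if self.length <= 0:
            raise ValueError(f"pore length must be positive, got {self.length}")
        if self.shape == "isosceles_triangle":
            if self.r is None or self.gamma is None:
                raise ValueError("triangular pores need r and gamma")
            if self.r <= 0:
                raise ValueError(f"inscribed radius must be positive, got {self.r}")
            triangle_corner_angles(self.gamma)  # validates range
        else:
            if self.width is None or self.height is None:
                raise ValueError("rectangular pores need width and height")
            if self.width <= 0 or self.height <= 0:
                raise ValueError("rectangle width/height must be positive")

    @property
    def corner_angles(self) -> tuple[float, ...]:
        if self.shape == "isosceles_triangle":
            return triangle_corner_angles(self.gamma)
        return (90.0, 90.0, 90.0, 90.0)

    @property
    def total_area(self) -> float:
        """Cross-sectional area A_t (m^2)."""
        if self.shape == "isosceles_triangle":
            return triangle_total_area(self.r, self.gamma)
        return self.width * self.height


@dataclass
class PoreNetwork:
    """Graph of nodes and angular pores.

    Pores are undirected edges stored once with canonical (min, max)
    endpoint ordering; indexing is 0-based throughout.
    """

    node_coordinates: np.ndarray  # (N, 2), metres
    pores: np.ndarray  # (M, 2) int, canonical order
    geometries: list[PoreGeometry]
    boundary_sets: dict[str, np.ndarray] = field(default_factory=dict)
    domain_volume: float | None = None  # m^3, frozen at construction

    def __post_init__(self) -> None:
        self.node_coordinates = np.asarray(self.node_coordinates, dtype=float)
        self.pores = np.asarray(self.pores, dtype=np.int64)
        if self.pores.ndim != 2 or self.pores.shape[1] != 2:
            raise ValueError("pores must be an (M, 2) array of node indices")
        lo = np.minimum(self.pores[:, 0], self.pores[:, 1])
        hi = np.maximum(self.pores[:, 0], self.pores[:, 1])
        self.pores = np.column_stack([lo, hi])
        self.boundary_sets = {
            k: np.asarray(sorted(set(np.asarray(v, dtype=np.int64).tolist())), dtype=np.int64)
            for k, v in self.boundary_sets.items()
        }
        self._incidence_cache: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
        if self.domain_volume is None:
            self.domain_volume = self._hull_volume()

    # -- basic properties -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_coordinates)

    @property
    def n_pores(self) -> int:
        return len(self.pores)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([g.length for g in self.geometries])

    @property
    def total_areas(self) -> np.ndarray:
        return np.array([g.total_area for g in self.geometries])

    @property
    def depths(self) -> np.ndarray:
        return np.array([g.depth for g in self.geometries])

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.pores[:, 0], 1)
        np.add.at(deg, self.pores[:, 1], 1)
        return deg

    def incidence(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """CSR-style incidence: (ptr, pore_idx, other_node).

        For node ``n``, pores ``pore_idx[ptr[n]:ptr[n+1]]`` are incident and
        ``other_node[...]`` holds the far endpoint of each.
        """
        if self._incidence_cache is None:
            ends = np.concatenate([self.pores[:, 0], self.pores[:, 1]])
            pidx = np.tile(np.arange(self.n_pores), 2)
            other = np.concatenate([self.pores[:, 1], self.pores[:, 0]])
            order = np.argsort(ends, kind="stable")
            ptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
            np.add.at(ptr, ends + 1, 1)
            ptr = np.cumsum(ptr)
            self._incidence_cache = (ptr, pidx[order], other[order])
        return self._incidence_cache

    def euclidean_lengths(self) -> np.ndarray:
        d = self.node_coordinates[self.pores[:, 0]] - self.node_coordinates[self.pores[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.pores))
        return g

    def pore_volumes(self) -> np.ndarray:
        """Per-pore volume A_t * L (m^3)."""
        return self.total_areas * self.lengths

    def porosity(self) -> float:
        return float(self.pore_volumes().sum() / self.domain_volume)

    def _hull_volume(self) -> float:
        xy = self.node_coordinates
        span = xy.max(axis=0) - xy.min(axis=0)
        plan = float(span[0] * span[1]) if self.n_nodes > 1 else 0.0
        if plan == 0.0:  # degenerate chain: fall back to a line "area"
            plan = float(max(span.max(), 1.0) ** 2)
        return plan * float(np.mean(self.depths)) if self.n_pores else plan

    # -- validation -------------------------------------------------------

    def validate(self, length_rtol: float = 1e-6) -> None:
        """Check structural invariants; raise ValueError on violation."""
        if not nx.is_connected(self.graph()):
            raise ValueError("pore network is not connected")
        eu = self.euclidean_lengths()
        if not np.allclose(eu, self.lengths, rtol=length_rtol):
            worst = int(np.argmax(np.abs(eu - self.lengths)))
            raise ValueError(
                f"pore {worst} length {self.lengths[worst]:g} does not match "
                f"endpoint distance {eu[worst]:g}"
            )
        for name, nodes in self.boundary_sets.items():
            if len(nodes) and (nodes.min() < 0 or nodes.max() >= self.n_nodes):
                raise ValueError(f"boundary set {name!r} references missing nodes")

    # -- persistence ------------------------------------------------------

    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        tags = np.array([""] * self.n_nodes, dtype=object)
        for name, nodes in self.boundary_sets.items():
            for n in nodes:
                tags[n] = f"{tags[n]}{'+' if tags[n] else ''}{name}"
        node_df = pd.DataFrame(
            {
                "id": np.arange(self.n_nodes),
                "x": self.node_coordinates[:, 0],
                "y": self.node_coordinates[:, 1],
                "boundary_tag": tags,
            }
        )
        rows = []
        for (a, b), g in zip(self.pores, self.geometries):
            rows.append(
                {
                    "node_a": a,
                    "node_b": b,
                    "shape": g.shape,
                    "r_or_W": g.r if g.shape == "isosceles_triangle" else g.width,
                    "gamma_or_H": g.gamma if g.shape == "isosceles_triangle" else g.height,
                    "L": g.length,
                    "depth": g.depth,
                }
            )
        return node_df, pd.DataFrame(rows)

    def write(self, node_file: str, edge_file: str) -> None:
        node_df, edge_df = self.to_tables()
        node_df.to_csv(node_file, sep="\t", index=False)
        edge_df.to_csv(edge_file, sep="\t", index=False)

    @classmethod
    def read(cls, node_file: str, edge_file: str) -> "PoreNetwork":
        node_df = pd.read_csv(node_file, sep="\t")
        edge_df = pd.read_csv(edge_file, sep="\t")
        coords = node_df[["x", "y"]].to_numpy()
        boundary: dict[str, list[int]] = {}
        for nid, tag in zip(node_df["id"], node_df["boundary_tag"].fillna("")):
            for name in str(tag).split("+"):
                if name:
                    boundary.setdefault(name, []).append(int(nid))
        geoms = []
        for row in edge_df.itertuples():
            if row.shape == "isosceles_triangle":
                geoms.append(
                    PoreGeometry(
                        "isosceles_triangle", length=row.L, r=row.r_or_W,
                        gamma=row.gamma_or_H, depth=row.depth,
                    )
                )
            else:
                geoms.append(
                    PoreGeometry(
                        "rectangle", length=row.L, width=row.r_or_W,
                        height=row.gamma_or_H, depth=row.depth,
                    )
                )
        return cls(
            node_coordinates=coords,
            pores=edge_df[["node_a", "node_b"]].to_numpy(),
            geometries=geoms,
            boundary_sets={k: np.array(v) for k, v in boundary.items()},
        )


# -- lattice builders -----------------------------------------------------


def _default_geometry(pore_length: float, depth: float) -> PoreGeometry:
    return PoreGeometry(
        "isosceles_triangle", length=pore_length, r=5e-6, gamma=DEFAULT_GAMMA,
        depth=depth,
    )


def build_lattice(
    topology: str,
    nx_nodes: int,
    ny_nodes: int,
    pore_length: float,
    geometry: PoreGeometry | None = None,
    depth: float = DEFAULT_DEPTH,
) -> PoreNetwork:
    """Build a regular lattice network.

    ``"square"`` gives interior coordination number 4 (chessboard);
    ``"hexagonal"`` gives interior coordination number 6 (honeycomb packing,
    i.e. a triangular lattice of nodes in pointy-top axial layout with rows
    offset by half a spacing).  The perimeter nodes are collected in the
    ``"edge"`` boundary set.
    """
    if nx_nodes < 2 or ny_nodes < 2:
        raise ValueError(
            f"lattice needs nx, ny >= 2, got nx={nx_nodes}, ny={ny_nodes}"
        )
    if pore_length <= 0:
        raise ValueError(f"pore_length must be positive, got {pore_length}")
    template = geometry or _default_geometry(pore_length, depth)

    def idx(i: int, j: int) -> int:
        return j * nx_nodes + i

    coords = np.zeros((nx_nodes * ny_nodes, 2))
    edges: list[tuple[int, int]] = []
    if topology == "square":
        for j in range(ny_nodes):
            for i in range(nx_nodes):
                coords[idx(i, j)] = (i * pore_length, j * pore_length)
                if i + 1 < nx_nodes:
                    edges.append((idx(i, j), idx(i + 1, j)))
                if j + 1 < ny_nodes:
                    edges.append((idx(i, j), idx(i, j + 1)))
    elif topology == "hexagonal":
        dy = pore_length * math.sqrt(3.0) / 2.0
        for j in range(ny_nodes):
            off = 0.5 * pore_length if j % 2 else 0.0
            for i in range(nx_nodes):
                coords[idx(i, j)] = (i * pore_length + off, j * dy)
                if i + 1 < nx_nodes:
                    edges.append((idx(i, j), idx(i + 1, j)))
                if j + 1 < ny_nodes:
                    # two down-links whose horizontal partner depends on row parity
                    edges.append((idx(i, j), idx(i, j + 1)))
                    k = i + 1 if j % 2 else i - 1
                    if 0 <= k < nx_nodes:
                        edges.append((idx(i, j), idx(k, j + 1)))
    else:
        raise ValueError(f"unknown topology {topology!r} (use 'square' or 'hexagonal')")

    perimeter = [
        idx(i, j)
        for j in range(ny_nodes)
        for i in range(nx_nodes)
        if i in (0, nx_nodes - 1) or j in (0, ny_nodes - 1)
    ]
    geoms = [dataclasses.replace(template, length=pore_length) for _ in edges]
    return PoreNetwork(
        node_coordinates=coords,
        pores=np.array(edges),
        geometries=geoms,
        boundary_sets={"edge": np.array(perimeter)},
    )


def build_chain(n_nodes: int, pore_length: float,
                geometry: PoreGeometry | None = None) -> PoreNetwork:
    """1-D chain of ``n_nodes`` nodes; ends collected in the ``"edge"`` set."""
    if n_nodes < 2:
        raise ValueError("chain needs at least 2 nodes")
    coords = np.column_stack([np.arange(n_nodes) * pore_length, np.zeros(n_nodes)])
    edges = np.column_stack([np.arange(n_nodes - 1), np.arange(1, n_nodes)])
    template = geometry or _default_geometry(pore_length, DEFAULT_DEPTH)
    geoms = [dataclasses.replace(template, length=pore_length) for _ in range(n_nodes - 1)]
    return PoreNetwork(
        node_coordinates=coords,
        pores=edges,
        geometries=geoms,
        boundary_sets={"edge": np.array([0, n_nodes - 1])},
    )


def build_aggregate_domain(
    diameter: float,
    topology: str,
    pore_length: float,
    geometry: PoreGeometry | None = None,
    depth: float = DEFAULT_DEPTH,
) -> PoreNetwork:
    """Disc-shaped network representing a soil-aggregate cross-section.

    A lattice is clipped to a disc of the given diameter (a pore survives
    iff both endpoints lie inside); the rim nodes form the ``"periphery"``
    set and the node(s) nearest the centroid the ``"center"`` set.
    """
    if diameter <= 2 * pore_length:
        raise ValueError(
            f"diameter must exceed 2*pore_length, got diameter={diameter}, "
            f"pore_length={pore_length}"
        )
    n_across = int(math.ceil(diameter / pore_length)) + 3
    lat = build_lattice(topology, n_across, n_across, pore_length, geometry, depth)
    center = lat.node_coordinates.mean(axis=0)
    radius = diameter / 2.0
    dist = np.hypot(*(lat.node_coordinates - center).T)
    keep = dist <= radius + 1e-12
    keep_idx = np.flatnonzero(keep)
    remap = -np.ones(lat.n_nodes, dtype=np.int64)
    remap[keep_idx] = np.arange(len(keep_idx))
    pore_keep = keep[lat.pores[:, 0]] & keep[lat.pores[:, 1]]
    pores = remap[lat.pores[pore_keep]]
    geoms = [g for g, k in zip(lat.geometries, pore_keep) if k]
    coords = lat.node_coordinates[keep_idx]

    # drop nodes isolated by the clip, then require connectivity
    deg = np.zeros(len(coords), dtype=np.int64)
    np.add.at(deg, pores[:, 0], 1)
    np.add.at(deg, pores[:, 1], 1)
    live = deg > 0
    live_idx = np.flatnonzero(live)
    remap2 = -np.ones(len(coords), dtype=np.int64)
    remap2[live_idx] = np.arange(len(live_idx))
    coords = coords[live_idx]
    pores = remap2[pores]

    interior_degree = 4 if topology == "square" else 6
    deg = deg[live_idx]
    periphery = np.flatnonzero(deg < interior_degree)
    cdist = np.hypot(*(coords - center).T)
    order = np.argsort(cdist, kind="stable")
    central = [int(order[0])]
    for n in order[1:]:
        if cdist[n] <= cdist[order[0]] + 1e-12:
            central.append(int(n))
    central = [n for n in central if n not in set(periphery.tolist())]
    if not central:
        raise ValueError("domain too small: central node coincides with periphery")

    net = PoreNetwork(
        node_coordinates=coords,
        pores=pores,
        geometries=geoms,
        boundary_sets={"periphery": periphery, "center": np.array(central)},
        domain_volume=math.pi * radius**2 * depth,
    )
    if not nx.is_connected(net.graph()):
        raise ValueError("clipping produced a disconnected network")
    return net


def sample_pore_geometries(
    network: PoreNetwork,
    mean: float,
    sd: float,
    gamma: float = DEFAULT_GAMMA,
    seed: int | None = None,
    quantity: str = "radius",
) -> PoreNetwork:
    """Assign lognormally distributed triangular cross-sections to all pores.

    ``mean`` and ``sd`` are the *arithmetic* mean and standard deviation of
    the sampled quantity — the inscribed-circle ``"radius"`` or
    ``"diameter"`` (halved before assignment).  Deterministic under a fixed
    seed.  Returns a new network sharing coordinates and topology.
    """
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be positive and sd non-negative")
    if quantity not in ("radius", "diameter"):
        raise ValueError(f"quantity must be 'radius' or 'diameter', got {quantity!r}")
    rng = np.random.default_rng(seed)
    if sd == 0:
        draws = np.full(network.n_pores, mean)
    else:
        s2 = math.log(1.0 + (sd / mean) ** 2)
        mu = math.log(mean) - s2 / 2.0
        draws = rng.lognormal(mean=mu, sigma=math.sqrt(s2), size=network.n_pores)
    radii = draws / 2.0 if quantity == "diameter" else draws
    geoms = [
        PoreGeometry(
            "isosceles_triangle", length=g.length, r=float(r), gamma=gamma,
            depth=g.depth,
        )
        for g, r in zip(network.geometries, radii)
    ]
    return PoreNetwork(
        node_coordinates=network.node_coordinates.copy(),
        pores=network.pores.copy(),
        geometries=geoms,
        boundary_sets={k: v.copy() for k, v in network.boundary_sets.items()},
        domain_volume=network.domain_volume,
    )


def rescale_length_for_porosity(
    network: PoreNetwork, target_porosity: float, rtol: float = 0.01
) -> PoreNetwork:
    """Uniformly rescale pore lengths (and coordinates) so that total pore
    volume over the frozen domain volume hits ``target_porosity``.

    Porosity is linear in the common length factor, so the exact factor is
    current/target; the operation is idempotent.
    """
    if not 0.0 < target_porosity < 1.0:
        raise ValueError(f"target porosity must be in (0, 1), got {target_porosity}")
    current = network.porosity()
    if current <= 0:
        raise ValueError("network has zero pore volume; porosity unattainable")
    k = target_porosity / current
    geoms = [dataclasses.replace(g, length=g.length * k) for g in network.geometries]
    out = PoreNetwork(
        node_coordinates=network.node_coordinates * k,
        pores=network.pores.copy(),
        geometries=geoms,
        boundary_sets={k_: v.copy() for k_, v in network.boundary_sets.items()},
        domain_volume=network.domain_volume,
    )
    achieved = out.porosity()
    if abs(achieved - target_porosity) > rtol * target_porosity:
        raise ValueError(
            f"porosity {target_porosity} unattainable: achieved {achieved:g} "
            f"(bounds depend on fixed domain volume {network.domain_volume:g} m^3)"
        )
    return out
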