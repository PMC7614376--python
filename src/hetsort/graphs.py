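"""Graph families: Watts–Strogatz rings and the islet-like hcp-sphere lattice.

Two undirected, connected graph families are supported:

* **WS** — Watts–Strogatz small-world rings (N nodes, even mean degree D,
  rewiring probability beta).  Nodes are ring-ordered; 2-D unit-circle
  coordinates are attached for plotting and raster ordering only.
* **betaC** — an islet-of-Langerhans-like lattice: 1,018 nodes on a
  hexagonal close-packed (hcp) lattice clipped to a sphere, every pair
  at nearest-neighbour distance connected, so interior nodes have the
  hcp coordination number 12 and boundary nodes fewer.

The hcp sphere is centred on a tetrahedral hole of the lattice (which
breaks distance-shell degeneracies that a lattice-point centre would
create) and the clipping radius is frozen as ``BC_RADIUS_SQ``; both are
regression-tested.  Nodes of the betaC graph are sorted by radial
distance from the sphere centre, matching the raster ordering used for
its dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Graph",
    "make_ws_graph",
    "make_bc_lattice",
    "local_edge_fraction",
    "radial_distance",
    "read_graph",
    "write_graph",
    "BC_N",
    "BC_RADIUS_SQ",
    "BC_CENTER",
    "COORDINATION",
]

#: hcp coordination number (reference degree J of interior lattice nodes).
COORDINATION = 12

#: Frozen betaC sphere: node count, squared clipping radius (in units of
#: the lattice spacing) and sphere centre relative to the hcp cell.
BC_N = 1018
BC_RADIUS_SQ = 92.0 / 3.0
BC_CENTER = (0.5, math.sqrt(3.0) / 6.0, math.sqrt(6.0) / 6.0)


@dataclass
class Graph:
    """Undirected graph with optional 3-D embedding.

    ``adjacency`` holds one sorted integer array of neighbour indices
    per node.  ``family`` is ``"WS"`` or ``"betaC"``; family-specific
    generation parameters live in ``family_params``.
    """

    N: int
    adjacency: list[np.ndarray]
    coords: Optional[np.ndarray] = None
    family: str = "custom"
    family_params: dict = field(default_factory=dict)
    J: int = COORDINATION

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self.adjacency])

    @property
    def n_edges(self) -> int:
        return int(self.degrees.sum()) // 2

    def edges(self) -> np.ndarray:
        """(m, 2) array of undirected edges with i < j."""
        out = []
        for i, nbrs in enumerate(self.adjacency):
            for j in nbrs:
                if i < j:
                    out.append((i, j))
        return np.array(out, dtype=int).reshape(-1, 2)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.N))
        g.add_edges_from(map(tuple, self.edges()))
        return g

    def laplacian(self):
        """Sparse combinatorial Laplacian L = D - A (CSR)."""
        import scipy.sparse as sp

        e = self.edges()
        data = np.ones(len(e))
        a = sp.coo_matrix(
            (np.r_[data, data], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(self.N, self.N),
        ).tocsr()
        return sp.diags(self.degrees.astype(float)) - a

    def validate(self) -> None:
        """Check symmetry, no self-loops/duplicates, connectivity."""
        for i, nbrs in enumerate(self.adjacency):
            if len(set(nbrs.tolist())) != len(nbrs):
                raise ValueError(f"duplicate neighbours at node {i}")
            if i in nbrs:
                raise ValueError(f"self-loop at node {i}")
            for j in nbrs:
                if i not in self.adjacency[j]:
                    raise ValueError(f"asymmetric adjacency: {i}->{j}")
        if not nx.is_connected(self.to_networkx()):
            raise ValueError("graph is not connected")


def _adjacency_from_nx(g: nx.Graph, N: int) -> list[np.ndarray]:
    return [np.array(sorted(g.neighbors(i)), dtype=int) for i in range(N)]


def make_ws_graph(N: int, D: int, beta: float, seed: int) -> Graph:
    """Watts–Strogatz ring: N nodes, D/2 nearest neighbours per side,
    each edge rewired with probability beta.

    Regenerates with an incremented seed until the graph is connected;
    the number of retries is recorded in ``family_params["retries"]``.
    Unit-circle coordinates (z = 0) are attached for plotting only.
    """
    if D % 2 != 0 or D <= 0:
        raise ValueError(f"mean degree D must be a positive even integer, got {D}")
    if D >= N:
        raise ValueError(f"need D < N, got D={D}, N={N}")
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")

    retries = 0
    while True:
        g = nx.watts_strogatz_graph(N, D, beta, seed=seed + retries)
        if nx.is_connected(g):
            break
        retries += 1
        if retries > 100:  # pragma: no cover
            raise RuntimeError("failed to generate a connected WS graph")

    theta = 2.0 * np.pi * np.arange(N) / N
    coords = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(N)])
    return Graph(
        N=N,
        adjacency=_adjacency_from_nx(g, N),
        coords=coords,
        family="WS",
        family_params={"D": D, "beta": beta, "seed": seed, "retries": retries},
    )


def _hcp_points(extent: int) -> np.ndarray:
    """hcp lattice points (ABAB stacking, unit nearest-neighbour spacing)."""
    rng = range(-extent, extent + 1)
    pts = []
    s3, s6 = math.sqrt(3.0), math.sqrt(6.0)
    for k in rng:
        for j in rng:
            for i in rng:
                pts.append(
                    (
                        i + ((j + k) % 2) * 0.5,
                        s3 / 2.0 * (j + (k % 2) / 3.0),
                        s6 / 3.0 * k,
                    )
                )
    return np.asarray(pts)


#: Desk-scale lattice size: the smallest achievable count >= 342 for the
#: frozen sphere centre (radius shells are discrete, so not every count
#: is realisable).
BC_N_DESK = 347


def make_bc_lattice(spacing: float = 1.0, n_nodes: int = BC_N) -> Graph:
    """Islet-like lattice: hcp nodes inside a sphere, coordination 12.

    The ``n_nodes`` lattice points nearest the frozen tetrahedral-hole
    centre are retained (for the default 1,018 this reproduces the
    frozen radius ``sqrt(BC_RADIUS_SQ)``) and every pair at
    nearest-neighbour distance (= ``spacing``) is connected.  Nodes are
    ordered by radial distance from the sphere centre.  Deterministic:
    no RNG is involved.  Raises when ``n_nodes`` falls inside a
    degenerate distance shell (no sphere radius realises that count).
    """
    pts = _hcp_points(9)
    if n_nodes >= len(pts):
        raise ValueError(f"n_nodes={n_nodes} exceeds generated lattice block")
    center = np.asarray(BC_CENTER)
    r2 = np.sum((pts - center) ** 2, axis=1)
    order_all = np.argsort(r2, kind="stable")
    r2_sorted = r2[order_all]
    if r2_sorted[n_nodes] - r2_sorted[n_nodes - 1] < 1e-9:
        achieved = int(np.searchsorted(r2_sorted, r2_sorted[n_nodes - 1] + 1e-9))
        raise ValueError(
            f"no sphere radius yields exactly {n_nodes} nodes (distance-shell "
            f"tie; nearest achievable count above is {achieved})"
        )
    sel = order_all[:n_nodes]
    coords = (pts[sel] - center) * spacing

    tree = cKDTree(coords)
    pairs = tree.query_pairs(spacing * (1.0 + 1e-9))
    adjacency = [[] for _ in range(n_nodes)]
    for a, b in pairs:
        adjacency[a].append(b)
        adjacency[b].append(a)
    radius_sq = 0.5 * (r2_sorted[n_nodes - 1] + r2_sorted[n_nodes])
    graph = Graph(
        N=n_nodes,
        adjacency=[np.array(sorted(a), dtype=int) for a in adjacency],
        coords=coords,
        family="betaC",
        family_params={"spacing": spacing, "radius_sq": radius_sq * spacing**2},
    )
    if graph.degrees.max() != COORDINATION:  # pragma: no cover
        raise RuntimeError("betaC lattice max degree != 12")
    return graph


def local_edge_fraction(graph: Graph) -> float:
    """Fraction of WS edges joining nodes within ring distance D/2.

    With rewiring probability beta, roughly a fraction 1 - beta of edges
    remain "local" in this sense (plus a small contribution from rewired
    edges that happen to land nearby).
    """
    if graph.family != "WS":
        raise ValueError(f"local_edge_fraction requires a WS graph, got {graph.family!r}")
    D = graph.family_params["D"]
    e = graph.edges()
    d = np.abs(e[:, 0] - e[:, 1])
    ring_dist = np.minimum(d, graph.N - d)
    return float(np.mean(ring_dist <= D // 2))


def radial_distance(graph: Graph) -> np.ndarray:
    """Per-node distance from the centroid of the embedded coordinates."""
    if graph.coords is None:
        raise ValueError("graph has no coordinates")
    c = graph.coords - graph.coords.mean(axis=0)
    return np.sqrt(np.sum(c**2, axis=1))


# --------------------------------------------------------------------------
# Text serialisation: edge list + node table
# --------------------------------------------------------------------------
# <stem>.edges : two integer columns, one undirected edge per line, i < j
# <stem>.nodes : id [label] [x y z]; header comment records family metadata


def write_graph(graph: Graph, path: str | Path, labels: Optional[np.ndarray] = None) -> None:
    """Write edge-list + node-table text files at ``path`` (stem).

    ``labels`` (optional, per-node integer population labels) are stored
    in the node table.
    """
    stem = Path(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    import json

    meta = {"family": graph.family, "family_params": graph.family_params, "J": graph.J}
    with open(stem.with_suffix(".edges"), "w") as fh:
        fh.write(f"# hetsort edge list, N={graph.N}\n")
        fh.write("# " + json.dumps(meta) + "\n")
        for i, j in graph.edges():
            fh.write(f"{i} {j}\n")
    with open(stem.with_suffix(".nodes"), "w") as fh:
        has_xyz = graph.coords is not None
        cols = ["id", "label"] + (["x", "y", "z"] if has_xyz else [])
        fh.write("# " + " ".join(cols) + "\n")
        for i in range(graph.N):
            lab = int(labels[i]) if labels is not None else 0
            row = f"{i} {lab}"
            if has_xyz:
                x, y, z = (float(v) for v in graph.coords[i])
                row += f" {x!r} {y!r} {z!r}"
            fh.write(row + "\n")


def read_graph(path: str | Path) -> tuple[Graph, Optional[np.ndarray]]:
    """Read a graph written by :func:`write_graph`.

    Returns ``(graph, labels)``; ``labels`` is None when the node table
    carries no labels (all zero).  Malformed input (non-integer ids,
    self-loops, duplicate edges, id mismatches) raises ``ValueError``
    with the offending line number.
    """
    import json

    stem = Path(path)
    meta = {"family": "custom", "family_params": {}, "J": COORDINATION}
    edges = []
    with open(stem.with_suffix(".edges")) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# {"):
                    meta = json.loads(line[2:])
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{stem}.edges line {ln}: expected two columns")
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError:
                raise ValueError(f"{stem}.edges line {ln}: non-integer node id") from None
            if i == j:
                raise ValueError(f"{stem}.edges line {ln}: self-loop {i}")
            if i > j:
                i, j = j, i
            edges.append((i, j))
    if len(set(edges)) != len(edges):
        raise ValueError(f"{stem}.edges: duplicate edges present")

    ids, labels, coords = [], [], []
    with open(stem.with_suffix(".nodes")) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                ids.append(int(parts[0]))
                labels.append(int(parts[1]) if len(parts) > 1 else 0)
            except ValueError:
                raise ValueError(f"{stem}.nodes line {ln}: malformed row") from None
            if len(parts) >= 5:
                coords.append([float(v) for v in parts[2:5]])

    N = len(ids)
    if sorted(ids) != list(range(N)):
        raise ValueError(f"{stem}.nodes: ids must be 0..{N - 1} without gaps")
    for i, j in edges:
        if j >= N:
            raise ValueError(f"{stem}.edges: node id {j} missing from node table")

    adjacency = [[] for _ in range(N)]
    for i, j in edges:
        adjacency[i].append(j)
        adjacency[j].append(i)
    order = np.argsort(ids)
    lab = np.array(labels, dtype=int)[order]
    graph = Graph(
        N=N,
        adjacency=[np.array(sorted(a), dtype=int) for a in adjacency],
        coords=np.array(coords)[order] if coords else None,
        family=meta.get("family", "custom"),
        family_params=meta.get("family_params", {}),
        J=meta.get("J", COORDINATION),
    )
    return graph, (lab if lab.any() else None)
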