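"""First-neighbor graphs and box-clipped Voronoi tessellations.

Cell centers are tessellated into Voronoi polygons clipped to the
simulation box; the topological charge ``Z`` of a cell is its number of
sides, equivalently its number of Voronoi neighbors.  Clipping uses the
mirror construction: reflecting every center across each box side makes
all real regions finite and bounded exactly by the box, so the clipped
polygons tile the box without any explicit polygon intersection step.

Only *interior* cells -- those whose polygon is untouched by the box
boundary, so their neighbor shell is complete -- carry a trustworthy Z
and enter defect statistics downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.spatial import Delaunay, QhullError, Voronoi

from .scenarios import SQRT3_HALF

__all__ = ["NeighborGraph", "Tessellation", "first_neighbors", "voronoi_cells", "crop"]

logger = logging.getLogger(__name__)

#: Voronoi facets shorter than this (mm) do not count as cell sides;
#: guards against cocircular near-degeneracies.
MIN_FACET_LEN = 1e-9

#: distance (mm) within which a polygon vertex counts as touching the box
BOUNDARY_TOL = 1e-7


@dataclass
class NeighborGraph:
    """Undirected first-neighbor (Delaunay) edge set with edge lengths."""

    n: int
    edges: np.ndarray      # (m, 2) int, each row sorted, no duplicates
    lengths: np.ndarray    # (m,) Euclidean length in mm

    @cached_property
    def _adj(self) -> list[np.ndarray]:
        lists: list[list[int]] = [[] for _ in range(self.n)]
        for a, b in self.edges:
            lists[a].append(b)
            lists[b].append(a)
        return [np.asarray(v, dtype=int) for v in lists]

    def neighbors(self, i: int) -> np.ndarray:
        return self._adj[i]

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def edge_set(self) -> set[frozenset]:
        return {frozenset((int(a), int(b))) for a, b in self.edges}

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        for (a, b), r in zip(self.edges, self.lengths):
            g.add_edge(int(a), int(b), length=float(r))
        return g


def first_neighbors(positions: np.ndarray) -> NeighborGraph:
    """Delaunay first-neighbor graph of a point set.

    Raises ``ValueError`` on degenerate (collinear or too-small) input.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 3:
        raise ValueError("need at least 3 points for a triangulation")
    try:
        tri = Delaunay(positions)
    except QhullError as exc:
        raise ValueError(f"degenerate point set: {exc}") from exc
    if tri.simplices.size == 0:
        raise ValueError("degenerate (collinear) point set")
    edges = set()
    for simplex in tri.simplices:
        for k in range(3):
            a, b = int(simplex[k]), int(simplex[(k + 1) % 3])
            edges.add((a, b) if a < b else (b, a))
    earr = np.asarray(sorted(edges), dtype=int)
    lengths = np.hypot(*(positions[earr[:, 0]] - positions[earr[:, 1]]).T)
    return NeighborGraph(len(positions), earr, lengths)


def _polygon_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _order_ccw(verts: np.ndarray) -> np.ndarray:
    c = verts.mean(axis=0)
    ang = np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0])
    return verts[np.argsort(ang)]


@dataclass
class Tessellation:
    """Box-clipped Voronoi cells of a center set.

    Attributes
    ----------
    points : (n, 2) array of centers in mm.
    polygons : list of (k, 2) arrays, CCW-ordered clipped cell vertices.
    Z : int array; number of positive-length Voronoi facets to other
        centers.  Equals the cell's side count (and its Delaunay degree)
        for interior cells.
    area : cell polygon areas in mm^2.
    interior : bool array; True where the polygon is untouched by the
        box boundary, i.e. the neighbor shell is complete.
    adjacency : (m, 2) int array of center pairs sharing a facet longer
        than ``MIN_FACET_LEN``.
    crop_rows : height of the analysis window in lattice rows.
    """

    points: np.ndarray
    polygons: list
    Z: np.ndarray
    area: np.ndarray
    interior: np.ndarray
    adjacency: np.ndarray
    box: tuple
    d: float
    crop_rows: int

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def d_tilde(self) -> float:
        return SQRT3_HALF * self.d

    @cached_property
    def neighbor_lists(self) -> list[np.ndarray]:
        lists: list[list[int]] = [[] for _ in range(self.n)]
        for a, b in self.adjacency:
            lists[a].append(b)
            lists[b].append(a)
        return [np.asarray(v, dtype=int) for v in lists]

    def adjacency_graph(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from((int(a), int(b)) for a, b in self.adjacency)
        return g

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "cell_id": np.arange(self.n),
            "x_mm": self.points[:, 0],
            "y_mm": self.points[:, 1],
            "Z": self.Z,
            "area_mm2": self.area,
            "interior": self.interior,
        })


def voronoi_cells(positions: np.ndarray, box, d: float = 5.4) -> Tessellation:
    """Clipped Voronoi tessellation of ``positions`` inside ``box``.

    ``box`` is ``(lo, hi)`` with 2-vectors in mm and must contain all
    points.  ``d`` is the reference lattice constant used to convert the
    box height into lattice rows.
    """
    positions = np.asarray(positions, dtype=float)
    lo = np.asarray(box[0], dtype=float)
    hi = np.asarray(box[1], dtype=float)
    n = len(positions)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.any(positions < lo - 1e-9) or np.any(positions > hi + 1e-9):
        raise ValueError("box must contain all points")

    # mirror across each box side: real regions become finite and
    # exactly clipped at the box boundary
    mirrors = []
    for axis, bound in ((0, lo[0]), (0, hi[0]), (1, lo[1]), (1, hi[1])):
        m = positions.copy()
        m[:, axis] = 2.0 * bound - m[:, axis]
        mirrors.append(m)
    aug = np.vstack([positions] + mirrors)
    try:
        vor = Voronoi(aug)
    except QhullError as exc:
        raise ValueError(f"degenerate point set: {exc}") from exc

    polygons = []
    area = np.empty(n)
    interior = np.zeros(n, dtype=bool)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise ValueError(f"unbounded region for point {i} despite mirroring")
        verts = _order_ccw(vor.vertices[region])
        polygons.append(verts)
        area[i] = _polygon_area(verts)
        interior[i] = (
            np.all(verts[:, 0] > lo[0] + BOUNDARY_TOL)
            and np.all(verts[:, 0] < hi[0] - BOUNDARY_TOL)
            and np.all(verts[:, 1] > lo[1] + BOUNDARY_TOL)
            and np.all(verts[:, 1] < hi[1] - BOUNDARY_TOL)
        )

    Z = np.zeros(n, dtype=int)
    adjacency = []
    for (a, b), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if a >= n or b >= n:
            continue  # facet with a mirror image: a box-edge side
        if -1 in rv:
            continue
        flen = float(np.hypot(*(vor.vertices[rv[0]] - vor.vertices[rv[1]])))
        if flen <= MIN_FACET_LEN:
            continue
        Z[a] += 1
        Z[b] += 1
        adjacency.append((min(a, b), max(a, b)))
    adjacency = (np.asarray(sorted(adjacency), dtype=int)
                 if adjacency else np.empty((0, 2), dtype=int))

    crop_rows = int(round((hi[1] - lo[1]) / (SQRT3_HALF * d)))
    return Tessellation(positions, polygons, Z, area, interior, adjacency,
                        (lo, hi), d, crop_rows)


def crop(tess: Tessellation, window) -> Tessellation:
    """Subset of cells whose centers fall inside ``window``.

    ``window`` is ``(lo, hi)``; the returned tessellation records the
    window height in lattice rows (``round(height / d_tilde)``).  Cell
    polygons are kept as-is (the window selects centers, it does not
    re-clip), and adjacency is restricted to the retained cells.
    """
    wlo = np.asarray(window[0], dtype=float)
    whi = np.asarray(window[1], dtype=float)
    keep = np.flatnonzero(
        (tess.points[:, 0] >= wlo[0]) & (tess.points[:, 0] <= whi[0])
        & (tess.points[:, 1] >= wlo[1]) & (tess.points[:, 1] <= whi[1])
    )
    rows = int(round((whi[1] - wlo[1]) / tess.d_tilde))
    if len(keep) == 0:
        logger.warning("crop window selects no cells")
        return Tessellation(tess.points[:0], [], np.empty(0, dtype=int),
                            np.empty(0), np.empty(0, dtype=bool),
                            np.empty((0, 2), dtype=int), (wlo, whi), tess.d, 0)
    remap = -np.ones(tess.n, dtype=int)
    remap[keep] = np.arange(len(keep))
    adj = [(remap[a], remap[b]) for a, b in tess.adjacency
           if remap[a] >= 0 and remap[b] >= 0]
    adj = np.asarray(sorted(adj), dtype=int) if adj else np.empty((0, 2), dtype=int)
    return Tessellation(
        tess.points[keep], [tess.polygons[i] for i in keep], tess.Z[keep],
        tess.area[keep], tess.interior[keep], adj, (wlo, whi), tess.d, rows,
    )
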