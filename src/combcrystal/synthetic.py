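"""Ground-truth synthetic lattices for testing the analysis stages.

Provides perfect triangular lattices, jittered lattices, and lattices
with dislocations seeded at chosen lattice indices.  A dislocation is
created by the half-row termination construction: the sites of one row
beyond a chosen column are removed, the flanking material closes the
vacancy line (a vertical merge plus a +/- d/4 horizontal shear that
restores triangular registry, making the Burgers vector a proper
lattice vector), and a short low-temperature annealing stage
regularizes the core.  The result is exactly one 5-cell adjacent to one
7-cell per termination.  A finite termination span produces a
dislocation dipole: one 5-7 duplet at each end.

Every fixture can be paired with a machine-derived ground-truth
inventory (defect counts, chain partition, chain spacings) computed by
independent flood-fill/shortest-path oracles, so analysis tests compare
against derived, not hand-asserted, values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .annealer import AnnealConfig, PairPotentialParams, anneal
from .scenarios import SQRT3_HALF, ParticleSystem, make_hex_panel
from .tessellation import Tessellation, voronoi_cells

__all__ = [
    "FixtureSpec",
    "perfect_lattice",
    "jitter",
    "seed_dislocation",
    "analysis_box",
    "build_fixture",
    "fixture_ground_truth",
]

#: box padding for analyzing a bare lattice, in units of d (below d/2 so
#: the ragged lattice fringe is clipped away rather than miscounted)
ANALYSIS_PAD_FRAC = 0.25


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic lattice fixture.

    ``dislocations`` lists half-row terminations as ``(row, col)`` for a
    single dislocation (terminating to the right edge) or
    ``(row, col_start, col_end)`` for a dipole with duplets near both
    span ends.  ``jitter_amplitude`` must stay below ``0.3 * d`` so the
    perturbation does not change the lattice topology uncontrollably.
    """

    kind: str = "perfect"
    rows: int = 12
    cols: int = 12
    d: float = 5.4
    jitter_amplitude: float = 0.0
    dislocations: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"perfect", "jittered", "dislocation_pair",
                             "dislocation_row"}:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.jitter_amplitude < 0 or self.jitter_amplitude >= 0.3 * self.d:
            if self.jitter_amplitude != 0.0:
                raise ValueError("jitter_amplitude must be in [0, 0.3*d)")


def perfect_lattice(rows: int, cols: int, d: float = 5.4) -> np.ndarray:
    """Triangular lattice with spacing ``d`` (rows x cols sites)."""
    if rows < 3 or cols < 3:
        raise ValueError("fixture lattices need rows, cols >= 3")
    return make_hex_panel((0.0, 0.0), rows, cols, d)


def jitter(lattice: np.ndarray, amplitude: float, seed: int = 0) -> np.ndarray:
    """Displace each site uniformly within a disc of radius ``amplitude``."""
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if amplitude == 0:
        return np.asarray(lattice, dtype=float).copy()
    rng = np.random.default_rng(seed)
    n = len(lattice)
    r = amplitude * np.sqrt(rng.random(n))
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    return np.asarray(lattice, dtype=float) + np.column_stack(
        [r * np.cos(theta), r * np.sin(theta)])


def _lattice_indices(points: np.ndarray, d: float):
    dt = SQRT3_HALF * d
    rows = np.round(points[:, 1] / dt).astype(int)
    cols = np.round(points[:, 0] / d - 0.5 * (rows % 2)).astype(int)
    return rows, cols


def _relax(points: np.ndarray, d: float, sweeps: int, seed: int) -> np.ndarray:
    """One low-temperature annealing stage; the outer site ring stays fixed."""
    dt = SQRT3_HALF * d
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    inner = ((points[:, 0] > lo[0] + 0.6 * d) & (points[:, 0] < hi[0] - 0.6 * d)
             & (points[:, 1] > lo[1] + 0.6 * dt) & (points[:, 1] < hi[1] - 0.6 * dt))
    system = ParticleSystem(points, ~inner, (lo - 0.1 * d, hi + 0.1 * d))
    cfg = AnnealConfig(T0=0.01, n_stages=1, sweeps_per_stage=sweeps,
                       step_sigma=0.03 * d, relocate_prob=0.0, seed=seed)
    relaxed, _ = anneal(system, PairPotentialParams(d=d), cfg)
    return relaxed.positions


def seed_dislocation(lattice: np.ndarray, at, d: float = 5.4,
                     relax_sweeps: int = 30, relax_seed: int = 12345) -> np.ndarray:
    """Terminate a half-row at lattice index ``at``, producing a 5-7 duplet.

    ``at`` is ``(row, col)``: sites of ``row`` with column >= ``col`` are
    removed and the flanks merge toward the vacancy line.  A third
    element gives ``(row, col_start, col_end)``: only that span is
    removed, producing a dislocation dipole.  The index must be interior
    (at least two rows/columns from every lattice edge).
    """
    pts = np.asarray(lattice, dtype=float)
    rows_idx, cols_idx = _lattice_indices(pts, d)
    n_rows = rows_idx.max() + 1
    n_cols = cols_idx.max() + 1
    if len(at) == 2:
        row, col_start = at
        col_end = None
    else:
        row, col_start, col_end = at
    if not (2 <= row <= n_rows - 3):
        raise ValueError(f"dislocation row {row} too close to the lattice edge")
    if not (2 <= col_start <= n_cols - 3):
        raise ValueError(f"dislocation column {col_start} too close to the edge")
    if col_end is not None and not (col_start + 2 <= col_end <= n_cols - 3):
        raise ValueError("dipole span must be >= 2 columns and interior")

    dt = SQRT3_HALF * d
    y_r = row * dt
    x_start = (col_start + 0.5 * (row % 2)) * d
    x_end = math.inf if col_end is None else (col_end + 0.5 * (row % 2)) * d

    removed = (rows_idx == row) & (cols_idx >= col_start)
    if col_end is not None:
        removed &= cols_idx < col_end
    pts = pts[~removed]

    x, y = pts[:, 0], pts[:, 1]
    ramp = np.clip((x - x_start + d) / (2.0 * d), 0.0, 1.0)
    if col_end is not None:
        ramp *= np.clip((x_end - x + d) / (2.0 * d), 0.0, 1.0)
    above = y > y_r + 1e-9
    below = y < y_r - 1e-9
    h_top = (n_rows - 1) * dt - y_r
    h_bot = y_r
    lam_top = (h_top - dt / 2.0) / h_top
    lam_bot = (h_bot - dt / 2.0) / h_bot
    new_x = x.copy()
    new_y = y.copy()
    new_y[above] = y_r + (y[above] - y_r) * (1.0 - (1.0 - lam_top) * ramp[above])
    new_y[below] = y_r + (y[below] - y_r) * (1.0 - (1.0 - lam_bot) * ramp[below])
    new_x[above] = x[above] + 0.25 * d * ramp[above]
    new_x[below] = x[below] - 0.25 * d * ramp[below]
    out = np.column_stack([new_x, new_y])
    if relax_sweeps > 0:
        out = _relax(out, d, relax_sweeps, relax_seed)
    return out


def analysis_box(points: np.ndarray, d: float = 5.4):
    """Analysis box for a bare lattice: bounds padded by ``0.25 * d``."""
    pad = ANALYSIS_PAD_FRAC * d
    pts = np.asarray(points, dtype=float)
    return (pts.min(axis=0) - pad, pts.max(axis=0) + pad)


def build_fixture(spec: FixtureSpec, edge_margin: float = 2.0):
    """Construct a fixture with its tessellation and ground truth.

    The defect inventory is taken on a window cropped ``edge_margin * d``
    in from the lattice bounds, so free-edge relaxation artifacts of the
    dislocation construction stay out of the statistics.  Returns
    ``(points, tess, truth)`` with ``truth`` the inventory from
    :func:`fixture_ground_truth` on the cropped tessellation.
    """
    from .tessellation import crop

    pts = perfect_lattice(spec.rows, spec.cols, spec.d)
    for at in spec.dislocations:
        pts = seed_dislocation(pts, at, spec.d)
    if spec.jitter_amplitude > 0:
        pts = jitter(pts, spec.jitter_amplitude, spec.seed)
    tess = voronoi_cells(pts, analysis_box(pts, spec.d), d=spec.d)
    if edge_margin > 0:
        m = edge_margin * spec.d
        lo, hi = tess.box
        tess = crop(tess, (lo + m, hi - m))
    return pts, tess, fixture_ground_truth(tess)


def fixture_ground_truth(tess: Tessellation) -> dict:
    """Brute-force defect inventory of a tessellation.

    Uses an explicit flood fill over the adjacency matrix for the chain
    partition and networkx shortest paths for chain spacings --
    deliberately different machinery from the defect-statistics module,
    so the two can check each other.
    """
    import networkx as nx

    inside = np.flatnonzero(tess.interior)
    z = {int(i): int(tess.Z[i]) for i in inside}
    defects = sorted(i for i, zz in z.items() if zz != 6)
    adj = np.zeros((tess.n, tess.n), dtype=bool)
    for a, b in tess.adjacency:
        adj[a, b] = adj[b, a] = True
    # flood fill over the boolean adjacency matrix
    components = []
    unvisited = set(defects)
    while unvisited:
        comp = {unvisited.pop()}
        frontier = set(comp)
        while frontier:
            nxt = set()
            for a in frontier:
                for b in np.flatnonzero(adj[a]):
                    if int(b) in unvisited:
                        unvisited.discard(int(b))
                        nxt.add(int(b))
            comp |= nxt
            frontier = nxt
        components.append(sorted(comp))
    components.sort(key=lambda c: float(tess.points[c, 0].mean()))

    g = nx.Graph()
    g.add_nodes_from(range(tess.n))
    g.add_edges_from((int(a), int(b)) for a, b in tess.adjacency)
    spacings = []
    for c1, c2 in zip(components, components[1:]):
        best = min(
            nx.shortest_path_length(g, a, b) for a in c1 for b in c2
        )
        spacings.append(int(best))

    return {
        "n_interior": int(len(inside)),
        "n_defect": len(defects),
        "n_below6": sum(1 for i in defects if z[i] < 6),
        "n_above6": sum(1 for i in defects if z[i] > 6),
        "components": components,
        "chain_lengths": [len(c) for c in components],
        "spacings": spacings,
    }


def write_fixture(path_prefix: str, points: np.ndarray, truth: dict) -> None:
    """Write a fixture as a centers CSV plus a JSON ground-truth sidecar."""
    import pandas as pd

    df = pd.DataFrame({
        "x_mm": points[:, 0], "y_mm": points[:, 1],
        "fixed": np.zeros(len(points), dtype=int),
    })
    df.to_csv(f"{path_prefix}.csv", index=False, float_format="%.12g")
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(truth, fh, indent=1)
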