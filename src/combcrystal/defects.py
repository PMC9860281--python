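"""Topological-defect statistics of a tessellated comb.

A *defect* is an interior cell with topological charge Z != 6.  Defects
organize into *chains*: maximal connected components of non-hexagonal
cells under shared-Voronoi-edge adjacency.  This module computes the
readout used to compare model and comb: per-cell classification, chain
lengths, topological spacing between chains, linear defect density per
lattice row, chain orientation angles, and cell-area summaries by
charge class, together with replicate aggregation and an RMSE
comparison against external reference tables.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .tessellation import Tessellation

__all__ = [
    "BELOW6", "HEX", "ABOVE6", "EXCLUDED",
    "DefectChain", "SummaryStats",
    "classify", "find_chains", "defect_spacing", "defect_density",
    "chain_angle", "area_by_charge", "summarize", "compare_to_reference",
]

logger = logging.getLogger(__name__)

BELOW6 = "below6"
HEX = "hex"
ABOVE6 = "above6"
EXCLUDED = "excluded"

# The gap is a vertical strip: chains line up along y (the boundary
# direction), while orientation angles are measured from the horizontal.
ALONG_GAP = np.array([0.0, 1.0])
HORIZONTAL = np.array([1.0, 0.0])
GAP_AXIS = HORIZONTAL  # angle reference axis

_ANGLE_TOL = 1e-9


@dataclass
class DefectChain:
    """A maximal connected component of non-hexagonal interior cells."""

    members: np.ndarray          # cell ids, ordered along the chain axis
    centroid: np.ndarray         # mean member-center position, mm

    @property
    def length(self) -> int:
        return len(self.members)


@dataclass
class SummaryStats:
    """Replicate-aggregated defect statistics.

    Scalar statistics carry a cross-replicate mean and SD (SD is NaN
    with fewer than two contributing replicates).  The chain-angle
    statistics are pooled over every chain of every replicate, matching
    how an angle histogram is accumulated.
    """

    n_replicates: int = 0
    defect_density_mean: float = math.nan
    defect_density_sd: float = math.nan
    chain_length_mean: float = math.nan
    chain_length_sd: float = math.nan
    defect_spacing_mean: float = math.nan
    defect_spacing_sd: float = math.nan
    area_by_class: dict = field(default_factory=dict)
    alpha_mean: float = math.nan
    alpha_sd: float = math.nan
    n_alpha: int = 0

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "defect_density": {"mean": self.defect_density_mean,
                               "sd": self.defect_density_sd},
            "chain_length": {"mean": self.chain_length_mean,
                             "sd": self.chain_length_sd},
            "defect_spacing": {"mean": self.defect_spacing_mean,
                               "sd": self.defect_spacing_sd},
            "area_by_class": {k: {"mean": v[0], "sd": v[1]}
                              for k, v in self.area_by_class.items()},
            "alpha": {"mean": self.alpha_mean, "sd": self.alpha_sd,
                      "n": self.n_alpha},
        }


def classify(tess: Tessellation) -> np.ndarray:
    """Label each cell ``below6`` / ``hex`` / ``above6``; non-interior
    cells are labeled ``excluded``."""
    labels = np.full(tess.n, EXCLUDED, dtype=object)
    inside = tess.interior
    labels[inside & (tess.Z < 6)] = BELOW6
    labels[inside & (tess.Z == 6)] = HEX
    labels[inside & (tess.Z > 6)] = ABOVE6
    return labels


def find_chains(tess: Tessellation) -> list[DefectChain]:
    """Connected components of non-hexagonal interior cells.

    Adjacency is a shared positive-length Voronoi facet.  Returns an
    empty list for a defect-free tessellation.
    """
    labels = classify(tess)
    defect_ids = set(np.flatnonzero((labels == BELOW6) | (labels == ABOVE6)).tolist())
    nbr = tess.neighbor_lists
    chains = []
    seen: set[int] = set()
    for start in sorted(defect_ids):
        if start in seen:
            continue
        comp = []
        queue = deque([start])
        seen.add(start)
        while queue:
            a = queue.popleft()
            comp.append(a)
            for b in nbr[a]:
                b = int(b)
                if b in defect_ids and b not in seen:
                    seen.add(b)
                    queue.append(b)
        members = np.asarray(sorted(comp), dtype=int)
        centroid = tess.points[members].mean(axis=0)
        # order members along the chain's principal axis for readability
        centered = tess.points[members] - centroid
        if len(members) > 1:
            _, vecs = np.linalg.eigh(centered.T @ centered)
            members = members[np.argsort(centered @ vecs[:, -1])]
        chains.append(DefectChain(members, centroid))
    chains.sort(key=lambda c: float(c.centroid @ ALONG_GAP))
    return chains


def _min_graph_distance(tess: Tessellation, sources, targets) -> int | None:
    """Fewest adjacency-graph edges from any source cell to any target cell."""
    targets = set(int(t) for t in targets)
    nbr = tess.neighbor_lists
    dist = {int(s): 0 for s in sources}
    queue = deque(dist)
    while queue:
        a = queue.popleft()
        if a in targets:
            return dist[a]
        for b in nbr[a]:
            b = int(b)
            if b not in dist:
                dist[b] = dist[a] + 1
                queue.append(b)
    return None


def _dislocation_units(tess: Tessellation,
                       chains: list[DefectChain]) -> list[np.ndarray]:
    """Split chains into dislocation units: adjacent 5-7 duplets, plus
    any unmatched defect cells as singleton units.

    An isolated dislocation is a 5-7 duplet; a long grain-boundary chain
    of alternating 5- and 7-cells is a string of contiguous
    dislocations.  Matching each below-6 cell with an adjacent above-6
    cell inside its chain recovers those units.
    """
    units: list[np.ndarray] = []
    nbr = tess.neighbor_lists
    for chain in chains:
        below = [int(i) for i in chain.members if tess.Z[i] < 6]
        above = {int(i) for i in chain.members if tess.Z[i] > 6}
        used: set[int] = set()
        for b in below:
            partner = next((int(a) for a in nbr[b]
                            if int(a) in above and int(a) not in used), None)
            if partner is None:
                units.append(np.asarray([b]))
            else:
                used.add(partner)
                units.append(np.asarray([b, partner]))
        units.extend(np.asarray([a]) for a in sorted(above - used))
    return units


def defect_spacing(tess: Tessellation, chains: list[DefectChain],
                   axis=ALONG_GAP) -> float | None:
    """Mean topological distance between consecutive dislocations.

    Chains are decomposed into dislocation units (adjacent 5-7 duplets;
    see :func:`_dislocation_units`), the units are ordered by centroid
    projection on ``axis`` (the along-gap direction by default), and for
    each consecutive pair the spacing is the number of edges on the
    shortest path in the cell-adjacency graph between their closest
    members -- so contiguous dislocations inside one grain-boundary
    chain sit at spacing 1, and isolated dislocations contribute the
    hexagon hops between them plus one.  Undefined (None) with fewer
    than two units.
    """
    units = _dislocation_units(tess, chains)
    if len(units) < 2:
        return None
    ax = np.asarray(axis, dtype=float)
    units = sorted(units, key=lambda u: float(tess.points[u].mean(axis=0) @ ax))
    spacings = []
    for a, b in zip(units, units[1:]):
        s = _min_graph_distance(tess, a, b)
        if s is not None:
            spacings.append(s)
    return float(np.mean(spacings)) if spacings else None


def defect_density(tess: Tessellation) -> float:
    """Interior non-hexagonal cell count divided by the crop height in rows."""
    if tess.crop_rows < 1:
        raise ValueError("defect density requires a crop of at least one row")
    labels = classify(tess)
    n_defect = int(np.sum((labels == BELOW6) | (labels == ABOVE6)))
    return n_defect / tess.crop_rows


def chain_angle(chain: DefectChain, tess: Tessellation,
                axis=GAP_AXIS) -> float | None:
    """Orientation angle of a defect chain, folded into the open
    interval (0, 90) degrees.

    The chain axis is the total-least-squares line through the member
    cell centers (principal eigenvector of the scatter matrix); the
    angle is measured against the gap axis.  Chains of length 1 and
    exact 0/90-degree fits fall outside the open interval and are
    excluded (None).
    """
    if chain.length < 2:
        return None
    pts = tess.points[chain.members]
    centered = pts - pts.mean(axis=0)
    _, vecs = np.linalg.eigh(centered.T @ centered)
    direction = vecs[:, -1]
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.hypot(*ax)
    angle = math.degrees(math.atan2(
        direction[0] * ax[1] - direction[1] * ax[0],
        direction @ ax,
    )) % 180.0
    if angle > 90.0:
        angle = 180.0 - angle
    if angle < _ANGLE_TOL or angle > 90.0 - _ANGLE_TOL:
        logger.info("chain angle %.3f at interval boundary; excluded", angle)
        return None
    return float(angle)


def area_by_charge(tess: Tessellation) -> dict[str, float]:
    """Mean interior-cell area per charge class; empty classes omitted."""
    labels = classify(tess)
    out = {}
    for cls in (BELOW6, HEX, ABOVE6):
        mask = labels == cls
        if mask.any():
            out[cls] = float(tess.area[mask].mean())
    return out


def _nanmean_sd(values) -> tuple[float, float]:
    vals = [v for v in values if v is not None and not math.isnan(v)]
    if not vals:
        return math.nan, math.nan
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else math.nan
    return mean, sd


def summarize(replicates: list[Tessellation]) -> SummaryStats:
    """Aggregate defect statistics over replicate tessellations.

    Scalar statistics are computed per replicate and averaged, with the
    cross-replicate SD as the uncertainty; chain angles are pooled over
    all chains of all replicates.  Replicates where a statistic is
    undefined (no chains, or fewer than two) do not contribute to it.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    densities, lengths, spacings, alphas = [], [], [], []
    areas: dict[str, list[float]] = {}
    for tess in replicates:
        densities.append(defect_density(tess))
        chains = find_chains(tess)
        if chains:
            lengths.append(float(np.mean([c.length for c in chains])))
        spacing = defect_spacing(tess, chains)
        if spacing is not None:
            spacings.append(spacing)
        for c in chains:
            a = chain_angle(c, tess)
            if a is not None:
                alphas.append(a)
        for cls, val in area_by_charge(tess).items():
            areas.setdefault(cls, []).append(val)
    stats = SummaryStats(n_replicates=len(replicates))
    stats.defect_density_mean, stats.defect_density_sd = _nanmean_sd(densities)
    stats.chain_length_mean, stats.chain_length_sd = _nanmean_sd(lengths)
    stats.defect_spacing_mean, stats.defect_spacing_sd = _nanmean_sd(spacings)
    stats.area_by_class = {cls: _nanmean_sd(v) for cls, v in areas.items()}
    if alphas:
        stats.alpha_mean = float(np.mean(alphas))
        stats.alpha_sd = float(np.std(alphas, ddof=1)) if len(alphas) > 1 else math.nan
        stats.n_alpha = len(alphas)
    if len(replicates) == 1:
        logger.info("single replicate: cross-replicate SDs are undefined")
    return stats


def compare_to_reference(model, reference) -> dict[str, float]:
    """RMSE between model and reference statistic tables.

    Both inputs are DataFrames with scenario-parameter columns (any of
    ``A``, ``L_over_d``, ``h_over_dtilde``), a ``statistic`` column and
    a ``mean`` column, one row per (scenario, statistic).  Returns the
    RMSE over parameter points for each statistic present in both.
    Raises ``ValueError`` if the parameter grids do not match.
    """
    import pandas as pd

    keys = [c for c in ("A", "L_over_d", "h_over_dtilde", "statistic")
            if c in model.columns and c in reference.columns]
    if "statistic" not in keys:
        raise ValueError("both tables need a 'statistic' column")
    m = model.set_index(keys)["mean"]
    r = reference.set_index(keys)["mean"]
    missing = m.index.difference(r.index)
    extra = r.index.difference(m.index)
    if len(missing) or len(extra):
        raise ValueError(
            "parameter grids do not match; "
            f"missing from reference: {list(missing)}; "
            f"missing from model: {list(extra)}"
        )
    joined = pd.DataFrame({"model": m, "reference": r}).reset_index()
    out = {}
    for stat, grp in joined.groupby("statistic"):
        diff = grp["model"].to_numpy() - grp["reference"].to_numpy()
        out[str(stat)] = float(np.sqrt(np.mean(diff ** 2)))
    return out
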