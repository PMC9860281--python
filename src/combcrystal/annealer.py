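"""Metropolis simulated annealing of cell centers under a Lennard-Jones
pair potential restricted to Delaunay first neighbors.

The energy of a configuration is the sum over Delaunay edges of

    U(r) = (sigma/r)**12 - (sigma/r)**6,

with ``sigma = d / 2**(1/6)`` so that the pair minimum sits exactly at
the equilibrium cell spacing ``d``.  The well-depth prefactor is fixed
to 1: it rescales all energies uniformly and cannot change which
configurations are minima.  Long-range pairs are excluded -- only edges
of the current Delaunay triangulation interact, and the triangulation
is updated as centers move so that lattice topology and geometry evolve
together.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .scenarios import ParticleSystem

__all__ = [
    "PairPotentialParams",
    "AnnealConfig",
    "EnergyTrace",
    "pair_potential",
    "local_energy",
    "metropolis_accept",
    "propose_move",
    "total_energy",
    "anneal",
]

logger = logging.getLogger(__name__)

SIXTH_ROOT_OF_2 = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class PairPotentialParams:
    """Lennard-Jones parameters; ``sigma`` is derived from ``d``."""

    d: float = 5.4

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError(f"d must be positive, got {self.d}")

    @property
    def sigma(self) -> float:
        """Zero-crossing distance, ``d / 2**(1/6)``."""
        return self.d / SIXTH_ROOT_OF_2


@dataclass(frozen=True)
class AnnealConfig:
    """Cooling schedule and proposal parameters.

    The temperature at stage ``k`` is ``T0 * gamma**k``.  Each stage
    performs ``sweeps_per_stage`` passes over the moving centers in
    randomized order.  Proposals are isotropic Gaussian displacements of
    scale ``step_sigma`` (clamped to the box); with probability
    ``relocate_prob`` a proposal instead draws a uniform position in the
    system's free region, which lets vacancy/interstitial pairs
    annihilate instead of freezing in.  Relocations switch off once the
    temperature drops below ``relocate_T_freeze``: at low temperature
    they can only inject metastable configurations that local moves can
    no longer heal (see the methods note).
    """

    T0: float = 0.5
    gamma: float = 0.9
    sweeps_per_stage: int = 50
    n_stages: int = 40
    step_sigma: float = 0.54
    relocate_prob: float = 0.1
    relocate_T_freeze: float = 0.05
    patch_radius_factor: float = 3.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise ValueError(f"T0 must be positive, got {self.T0}")
        if not (0.0 < self.gamma < 1.0):
            raise ValueError(f"gamma must be in (0, 1), got {self.gamma}")
        if self.step_sigma <= 0:
            raise ValueError(f"step_sigma must be positive, got {self.step_sigma}")
        if self.sweeps_per_stage < 1 or self.n_stages < 1:
            raise ValueError("sweeps_per_stage and n_stages must be >= 1")
        if not (0.0 <= self.relocate_prob < 1.0):
            raise ValueError("relocate_prob must be in [0, 1)")


@dataclass
class EnergyTrace:
    """Per-stage record of the annealing run."""

    temperature: np.ndarray
    total_energy: np.ndarray
    acceptance_rate: np.ndarray

    def __len__(self) -> int:
        return len(self.temperature)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "stage": np.arange(len(self)),
            "T": self.temperature,
            "total_energy": self.total_energy,
            "acceptance_rate": self.acceptance_rate,
        })


def pair_potential(r, params: PairPotentialParams):
    """Evaluate ``(sigma/r)**12 - (sigma/r)**6`` for ``r > 0`` (mm).

    Accepts scalars or arrays; the minimum value is -1/4 at ``r = d``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distances must be positive")
    s6 = (params.sigma / r) ** 6
    out = s6 * s6 - s6
    return float(out) if out.ndim == 0 else out


def local_energy(system: ParticleSystem, graph, i: int) -> float:
    """Sum of pair energies over the graph edges incident to particle ``i``."""
    nbrs = graph.neighbors(i)
    if len(nbrs) == 0:
        logger.warning("particle %d has no neighbors; local energy is 0", i)
        return 0.0
    params = PairPotentialParams(d=system.spec.d if system.spec else 5.4)
    r = np.hypot(*(system.positions[nbrs] - system.positions[i]).T)
    return float(np.sum(pair_potential(r, params)))


def metropolis_accept(delta_U: float, T: float, u: float) -> bool:
    """Accept iff ``u < min(1, exp(-delta_U / T))``; requires ``T > 0``."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if delta_U <= 0:
        return True
    return u < math.exp(-delta_U / T)


def propose_move(system: ParticleSystem, i: int, step_sigma: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Gaussian displacement of particle ``i``, clamped to the box."""
    if system.fixed_mask[i]:
        raise ValueError(f"particle {i} is fixed; only moving centers may be proposed")
    cand = system.positions[i] + rng.normal(0.0, step_sigma, size=2)
    lo, hi = system.box
    return np.clip(cand, lo, hi)


def total_energy(positions: np.ndarray, params: PairPotentialParams) -> float:
    """Total energy: sum of the pair potential over all Delaunay edges."""
    tri = Delaunay(positions)
    indptr, indices = tri.vertex_neighbor_vertices
    e = 0.0
    for a in range(len(positions)):
        nb = indices[indptr[a]: indptr[a + 1]]
        nb = nb[nb > a]
        if len(nb):
            r = np.hypot(*(positions[nb] - positions[a]).T)
            e += float(np.sum(pair_potential(r, params)))
    return e


def _adjacency_sets(positions: np.ndarray) -> list[set]:
    tri = Delaunay(positions)
    indptr, indices = tri.vertex_neighbor_vertices
    return [set(indices[indptr[k]: indptr[k + 1]].tolist())
            for k in range(len(positions))]


def anneal(system: ParticleSystem, pot: PairPotentialParams,
           cfg: AnnealConfig) -> tuple[ParticleSystem, EnergyTrace]:
    """Anneal the moving centers toward a minimum-energy configuration.

    At stage ``k`` the temperature is ``T0 * gamma**k``.  Every sweep
    visits the moving centers in a fresh random order.  For each
    proposal the new first-neighbor set of the displaced center is
    recomputed from a Delaunay triangulation of the local patch of
    points around the candidate position (the patch radius bounds the
    relevant circumcircles, so the incident edges match the full
    retriangulation); the energy change is

        dU = E_local(new position, new neighbors)
           - E_local(old position, old neighbors),

    and the move is accepted with the Metropolis probability
    ``min(1, exp(-dU/T))``.  Accepted moves update the neighbor graph in
    place; the full triangulation is refreshed at the start of every
    sweep.  Fixed centers never move.

    Returns the final system and the per-stage energy trace.
    """
    if system.n_moving < 1:
        raise ValueError("system has no moving particles")
    if system.n < 3:
        raise ValueError("at least 3 particles are required for triangulation")

    rng = np.random.default_rng(cfg.seed)
    out = system.copy()
    pos = out.positions
    lo, hi = out.box
    glo, ghi = out.free_region
    moving = out.moving_indices
    patch_r = cfg.patch_radius_factor * pot.d
    guard = 1e-6 * pot.d
    # relocation proposals target the uncovered (foundation-free) region:
    # uniform draws over the free region, rejected near fixed centers
    fixed_pos = pos[out.fixed_mask]
    fixed_tree = cKDTree(fixed_pos) if len(fixed_pos) else None
    excl = 0.5 * pot.d

    def draw_relocation():
        for _ in range(8):
            cand = rng.uniform(glo, ghi)
            if fixed_tree is None or \
                    fixed_tree.query(cand, k=1)[0] >= excl:
                return cand
        return None

    temps = np.empty(cfg.n_stages)
    energies = np.empty(cfg.n_stages)
    acc_rates = np.empty(cfg.n_stages)

    for k in range(cfg.n_stages):
        T = cfg.T0 * cfg.gamma ** k
        p_relocate = cfg.relocate_prob if T >= cfg.relocate_T_freeze else 0.0
        accepted = proposed = 0
        for _ in range(cfg.sweeps_per_stage):
            graph = _adjacency_sets(pos)
            tree = cKDTree(pos)
            for i in rng.permutation(moving):
                cand = None
                if p_relocate and rng.random() < p_relocate:
                    cand = draw_relocation()
                if cand is None:
                    cand = np.clip(pos[i] + rng.normal(0.0, cfg.step_sigma, 2),
                                   lo, hi)
                patch = np.asarray(tree.query_ball_point(cand, patch_r))
                others = patch[patch != i]
                if len(others) < 2:  # need 3 points total to triangulate
                    continue
                d_new = np.hypot(*(pos[others] - cand).T)
                if d_new.min() < guard:
                    continue  # coincident-point guard
                local = np.vstack([pos[others], cand])
                try:
                    ltri = Delaunay(local)
                except Exception:
                    continue
                lptr, lind = ltri.vertex_neighbor_vertices
                new_nb = others[lind[lptr[len(others)]: lptr[len(others) + 1]]]
                old_nb = np.fromiter(graph[i], dtype=int, count=len(graph[i]))
                e_old = 0.0
                if len(old_nb):
                    r_old = np.hypot(*(pos[old_nb] - pos[i]).T)
                    e_old = float(np.sum(pair_potential(r_old, pot)))
                r_new = np.hypot(*(pos[new_nb] - cand).T)
                e_new = float(np.sum(pair_potential(r_new, pot)))
                proposed += 1
                if metropolis_accept(e_new - e_old, T, rng.random()):
                    for j in graph[i]:
                        graph[j].discard(i)
                    graph[i] = set(new_nb.tolist())
                    for j in graph[i]:
                        graph[j].add(i)
                    pos[i] = cand
                    accepted += 1
        temps[k] = T
        energies[k] = total_energy(pos, pot)
        acc_rates[k] = accepted / proposed if proposed else 0.0
        logger.info("stage %d: T=%.4g U=%.4f acc=%.3f",
                    k, T, energies[k], acc_rates[k])

    trace = EnergyTrace(temps, energies, acc_rates)
    return out, trace
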