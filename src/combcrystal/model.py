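"""Model / Results facade over scenario construction, annealing and the
defect readout.

:class:`HoneycombModel` bundles a particle system (fixed foundation
centers plus free gap centers), the pair potential, and an annealing
schedule; :meth:`HoneycombModel.fit` runs the simulated annealing and
returns a :class:`HoneycombResults` carrying the final configuration,
the energy trace, the tessellation and the defect statistics, with a
``summary()`` table in the spirit of a statsmodels results object.
"""

from __future__ import annotations

from dataclasses import replace
from functools import cached_property

import numpy as np

from . import defects as dstats
from .annealer import AnnealConfig, EnergyTrace, PairPotentialParams, anneal
from .scenarios import FrustrationSpec, ParticleSystem, build_scenario
from .tessellation import Tessellation, voronoi_cells

__all__ = ["HoneycombModel", "HoneycombResults", "run_replicates"]


class HoneycombModel:
    """Annealed Lennard-Jones model of comb construction in a frustrated gap.

    Parameters
    ----------
    system : ParticleSystem
        Fixed and moving cell centers inside a box.
    potential : PairPotentialParams, optional
        Defaults to the equilibrium spacing of the system's scenario
        (5.4 mm if the system carries no scenario).
    config : AnnealConfig, optional
        Cooling schedule; see :class:`AnnealConfig` for defaults.
    """

    def __init__(self, system: ParticleSystem,
                 potential: PairPotentialParams | None = None,
                 config: AnnealConfig | None = None):
        self.system = system
        d = system.spec.d if system.spec is not None else 5.4
        self.potential = potential or PairPotentialParams(d=d)
        self.config = config or AnnealConfig()

    @classmethod
    def from_scenario(cls, spec: FrustrationSpec | None = None,
                      n_moving: int | None = None, seed: int = 0,
                      config: AnnealConfig | None = None,
                      **spec_kwargs) -> "HoneycombModel":
        """Build the model for a frustration scenario.

        Either pass a :class:`FrustrationSpec` or its fields as keyword
        arguments (``A=30, L=2, h=0, ...``).  ``seed`` controls both the
        gap seeding and, unless ``config`` overrides it, the annealer.
        """
        if spec is None:
            spec = FrustrationSpec(**spec_kwargs)
        elif spec_kwargs:
            spec = replace(spec, **spec_kwargs)
        system = build_scenario(spec, n_moving=n_moving, rng_seed=seed)
        if config is None:
            config = AnnealConfig(seed=seed)
        return cls(system, config=config)

    def fit(self, seed: int | None = None) -> "HoneycombResults":
        """Run the simulated annealing; returns the results object."""
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        final, trace = anneal(self.system, self.potential, cfg)
        return HoneycombResults(self, final, trace)


class HoneycombResults:
    """Final configuration and diagnostics of one annealing run."""

    def __init__(self, model: HoneycombModel, system: ParticleSystem,
                 trace: EnergyTrace):
        self.model = model
        self.system = system
        self.trace = trace

    @property
    def positions(self) -> np.ndarray:
        return self.system.positions

    @property
    def final_energy(self) -> float:
        return float(self.trace.total_energy[-1])

    @cached_property
    def tessellation(self) -> Tessellation:
        return voronoi_cells(self.system.positions, self.system.box,
                             d=self.model.potential.d)

    @cached_property
    def chains(self) -> list:
        return dstats.find_chains(self.tessellation)

    @cached_property
    def defect_summary(self) -> dstats.SummaryStats:
        return dstats.summarize([self.tessellation])

    def chain_angles(self) -> list[float]:
        """Orientation angles of all chains of length >= 2, degrees."""
        angles = [dstats.chain_angle(c, self.tessellation) for c in self.chains]
        return [a for a in angles if a is not None]

    def gap_neighbor_spacing(self) -> float:
        """Mean first-neighbor distance of the interior moving (gap)
        centers, from the tessellation's facet adjacency.

        Restricting to interior cells keeps box-boundary artifacts (long
        sliver edges along the clipped rim) out of the average.
        """
        tess = self.tessellation
        moving = set(self.system.moving_indices.tolist())
        pts = self.system.positions
        rs = []
        for i in np.flatnonzero(tess.interior):
            if i not in moving:
                continue
            nb = tess.neighbor_lists[i]
            rs.extend(np.hypot(*(pts[nb] - pts[i]).T).tolist())
        return float(np.mean(rs))

    def summary(self) -> str:
        """Human-readable run summary."""
        spec = self.system.spec
        s = self.defect_summary
        lines = ["Honeycomb annealing results",
                 "=" * 33]
        if spec is not None:
            lines.append(f"scenario            A={spec.A:g} deg, L={spec.L:g} d, "
                         f"h={spec.h:g} d~ (d={spec.d:g} mm)")
        lines += [
            f"particles           {self.system.n} "
            f"({self.system.n_moving} moving)",
            f"stages x sweeps     {len(self.trace)} x "
            f"{self.model.config.sweeps_per_stage}",
            f"final energy        {self.final_energy:.4f}",
            f"final acceptance    {self.trace.acceptance_rate[-1]:.3f}",
            f"interior cells      {int(self.tessellation.interior.sum())}",
            f"defect density      {s.defect_density_mean:.4f} cells/row",
            f"defect chains       {len(self.chains)}",
        ]
        if s.n_alpha:
            lines.append(f"chain angle (deg)   mean {s.alpha_mean:.2f}"
                         + (f", sd {s.alpha_sd:.2f}" if s.n_alpha > 1 else ""))
        return "\n".join(lines)

    def plot_tessellation(self, ax=None, **kwargs):
        from .plotting import plot_tessellation

        return plot_tessellation(self.tessellation, ax=ax,
                                 moving_mask=~self.system.fixed_mask, **kwargs)

    def plot_energy_trace(self, ax=None):
        from .plotting import plot_energy_trace

        return plot_energy_trace(self.trace, ax=ax)


def run_replicates(spec: FrustrationSpec, n_replicates: int, base_seed: int = 0,
                   config: AnnealConfig | None = None,
                   n_moving: int | None = None) -> list[HoneycombResults]:
    """Fit ``n_replicates`` independently seeded runs of one scenario.

    Replicate ``k`` uses seed ``base_seed + k`` for both gap seeding and
    annealing, so a run list is fully reproducible from ``base_seed``.
    """
    results = []
    for k in range(n_replicates):
        seed = base_seed + k
        cfg = replace(config, seed=seed) if config is not None else None
        model = HoneycombModel.from_scenario(spec, n_moving=n_moving,
                                             seed=seed, config=cfg)
        results.append(model.fit())
    return results
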