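# Methods

## The model

`combcrystal` models honeycomb construction in a geometrically
frustrated gap as energy minimization of a 2-D particle system.  Each
comb cell is represented by its center; the centers imprinted in the
two foundation panels are fixed, the centers in the gap are free.  The
configuration energy is the sum over first-neighbor pairs of a
Lennard-Jones interaction

    U(r) = (sigma/r)^12 - (sigma/r)^6,   sigma = d / 2^(1/6),

whose minimum (-1/4) sits at the equilibrium cell spacing `d = 5.4 mm`,
the center-to-center distance of unconstrained comb.  The well depth is
fixed to 1: it only rescales energies and temperatures and cannot move
any minimum.  First neighbors are the edges of the Delaunay
triangulation of the current positions, so there are no long-range
interactions, and the neighbor topology co-evolves with the geometry as
centers move.  Bees are implicit: the model describes where cell
centers end up, not how wax is deposited.

The energy is minimized by Metropolis simulated annealing: a proposed
displacement is accepted with probability `min(1, exp(-dU/T))`, and the
temperature is lowered over the run.  The final configuration is read
out as a Voronoi tessellation: the topological charge `Z` of a cell is
its number of sides (equivalently its Voronoi-neighbor count), defects
are cells with `Z != 6`, and chains, spacings, densities, orientation
angles and area summaries are computed from the tessellation exactly as
for a digitized comb photograph.

## Scenario geometry

A scenario is parameterized by the misalignment angle `A` (degrees),
the horizontal gap `L` (multiples of `d`, center-to-center between the
innermost fixed columns), and the vertical shift `h` (multiples of the
row spacing `d_tilde = (sqrt(3)/2) d ~ 4.676 mm`).  Panels hold 22 rows
by default, the largest common analysis-crop height.  The right panel
is realized the way a printed design sheet is: the lattice pattern is
shifted by `h*d_tilde`, rotated by `A` about the midpoint of the
panel's inner edge, and clipped to the fixed panel rectangle.  The gap
therefore remains a vertical strip of width `L*d` at every angle;
tilting or shifting instead removes pattern cells at the panel rim and
so enlarges the area the free cells must fill.

The interpretation of the row spacing deserves a note: the geometric
vertical distance between nearest-neighbor cells in adjacent rows of a
triangular lattice with spacing `d` is `(sqrt(3)/2) d`, and that is the
default.  With this choice the vertical-shift scenario produces the
expected sporadic short chains of defects; the alternative reading
`3d/2` (selectable via `FrustrationSpec(d_tilde=...)`) produces dense
system-spanning grain boundaries instead and is not used.

The number of free centers defaults to number conservation at lattice
density: the sites of the continued regular lattice inside the box,
minus the fixed centers.  For the frustration-free control this is
exactly the site count of the missing columns (22 for `L = 2d`, one
per row); for tilted or shifted panels it grows with the uncovered rim
area.  Underfilling the gap is not a neutral choice: it stretches every
gap cell and inverts the empirical ordering of cell areas by charge
class.  The count can be overridden per run (`n_moving`), e.g. to use
counts digitized from experiments.

## Annealing schedule and proposals

The cooling schedule is geometric, `T_k = T0 * gamma^k`, with defaults
`T0 = 0.5`, `gamma = 0.9`, 40 stages and 50 sweeps per stage; one sweep
visits every moving center once in random order.  These values are
conventional rather than derived: `T0` is of the order of a few bond
energies (the pair well is 1/4), and by the last stages
(`T ~ 8e-3`) uphill moves are effectively frozen, which shows up as
the energy plateau in the trace.

Proposals are isotropic Gaussian displacements of scale
`step_sigma = 0.1 d`, clamped to the box (walls are non-reflecting).
With probability `relocate_prob = 0.1` a proposal instead draws a
uniform position in the foundation-free region (uniform over the free
rectangle, rejected within `0.5 d` of a fixed center).  Relocations are
a symmetric proposal kernel, so Metropolis acceptance is unchanged;
they exist because pure local displacements cannot annihilate a
vacancy/interstitial pair across many rows within any practical
schedule -- without them the control scenario freezes with spurious
defects, which contradicts its defining property.  Relocations switch
off once `T` falls below `relocate_T_freeze = 0.05`: at low temperature
an accepted relocation can only drop into a deep local minimum, where
it tends to nucleate dislocation dipoles that subsequent local moves
cannot heal (annihilating them would require climb, not glide).  The
box-pad strips along the walls are excluded from the relocation region:
their shallow interstitial pockets are clamping traps, not buildable
cell sites.

Energy bookkeeping under a topology change: for a proposed move of
center `i`, `dU` is the local energy of `i` under the post-move
triangulation minus its local energy under the pre-move triangulation.
The post-move neighbor set is recomputed exactly from a Delaunay
triangulation of the patch of points within `3.2 d` of the candidate
position (the patch radius bounds the circumcircles relevant to edges
incident to `i`); the global neighbor graph is updated in place on
acceptance and fully refreshed at the start of every sweep.  Within a
sweep, an edge between two *other* centers can lag the exact Delaunay
graph until the refresh; this affects only which pairs interact for at
most one sweep and is treated as Monte Carlo noise.  Proposals landing
within `1e-6 d` of another center are rejected outright to keep the
potential finite and the triangulation well posed.

The run length is a fixed stage count rather than an adaptive stopping
rule, so replicates are exactly reproducible from their seeds; the
per-stage energy trace lets users confirm the plateau.

## Defect statistics

Only *interior* cells enter statistics: cells whose clipped Voronoi
polygon does not touch the box boundary, so their neighbor shell is
complete.  The box is padded `0.25 d` beyond the outermost fixed
centers -- deliberately less than `d/2`, so the ragged lattice fringe
is clipped away rather than miscounted as `Z = 5` cells.  Voronoi
facets shorter than 1e-9 mm do not count as sides.

* **Classification**: interior cells are labeled by charge class
  (`Z < 6`, `Z = 6`, `Z > 6`).
* **Chains**: connected components of non-hexagonal interior cells
  under shared-facet adjacency; the chain length is its cell count.
* **Spacing**: measured between *dislocations*, not whole chains: each
  chain is decomposed into 5-7 duplet units (every below-6 cell matched
  with an adjacent above-6 cell; leftovers are singletons), units are
  ordered along the gap direction (y -- the gap is a vertical strip, so
  defects stack vertically along the grain boundary), and each
  consecutive pair contributes the number of edges on the shortest
  cell-adjacency path between their closest members (breadth-first
  search).  Contiguous dislocations inside one long alternating 5-7
  chain therefore sit at spacing 1, which is what lets the statistic
  keep falling as misalignment grows and boundaries become continuous.
  Undefined with fewer than two units.
* **Density**: interior non-hexagonal cells divided by the crop height
  in lattice rows (`round(height / d_tilde)`).
* **Angle**: total-least-squares line through the member centers of a
  chain of length >= 2, folded into the open interval (0, 90) degrees
  against the horizontal gap axis; boundary fits (exactly 0 or 90) are
  excluded, as is any length-1 chain.
* **Replicates**: scalar statistics are averaged across replicates with
  the cross-replicate SD as uncertainty; chain angles are pooled over
  all chains of all replicates, as when accumulating an angle
  histogram.  A statistic undefined in a replicate (e.g. spacing with
  one chain) simply does not contribute.

`compare_to_reference` computes, per statistic, the RMSE between two
statistic tables over a common scenario grid -- the hook for comparing
against externally digitized comb data, which ships with no data of its
own.

## Synthetic fixtures

Analysis operations are validated against constructed lattices:
perfect triangular lattices, jittered lattices (uniform displacement in
a disc; below `0.3 d` the Voronoi topology is stable), and seeded
dislocations.  A dislocation is made by terminating a half-row:
removing the sites of one row beyond a chosen column, closing the
vacancy line vertically, and shearing the material above/below the cut
by `+/- d/4` so that the Burgers vector is a proper lattice vector (a
purely vertical merge leaves a same-parity stacking fault).  A short
low-temperature annealing stage regularizes the core, leaving exactly
one 5-cell adjacent to one 7-cell per termination; a finite termination
span yields a dipole with one duplet at each end.  Fixture inventories
(defect counts, chain partition, spacings) are computed at build time
by independent machinery -- an explicit flood fill over the adjacency
matrix and networkx shortest paths -- so tests compare the analysis
pipeline against derived, not hand-asserted, values.  Inventories are
taken on a window cropped `2 d` in from the lattice bounds, keeping
free-edge artifacts of the construction out of the counts.

What the fixtures do not emulate: real comb images have detection
noise, curved walls, damaged regions and size gradients (drone cells);
passing on fixtures validates the topological readout, not robustness
to imaging artifacts.  External center tables flow through the same
analysis path unchanged.

## Problem sizes and numerical choices

Default ensembles follow the study design: 22-row panels
(~250-310 centers, of which 22-40 move), 10 replicates for the control
and vertical-shift scenarios, and 5 replicates per misalignment angle
for the trend checks.  A single default-schedule run triangulates a
~40-point patch per proposal (~44,000 proposals) and completes in tens
of seconds on one core.  Degenerate inputs fail loudly: collinear
point sets, boxes that do not contain their points, and sub-3-point
systems raise errors rather than produce silent nonsense.

## Known limitations

* The annealing schedule and proposal scale are conventional choices;
  the quenched defect ensemble (and hence the chain-angle distribution)
  retains some dependence on them, as it does in any simulated
  annealing study.
* Defect statistics near the box boundary are excluded by construction;
  a chain partially outside the interior region is truncated.
* The model is athermal in interpretation: temperature is an
  optimization device, not a physical temperature of the colony.
* No weighted/Laguerre tessellations and no periodic boundaries; cell
  size heterogeneity beyond what the potential produces (e.g. drone
  cells) is out of scope.
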