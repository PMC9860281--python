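"""Frustrated-foundation scenario construction.

A scenario consists of two panels of fixed cell centers on a triangular
lattice (the imprinted foundation) separated by a gap, plus free ("moving")
centers seeded inside the gap.  Three parameters control the geometric
frustration between the panels:

* ``A`` -- misalignment angle of the right panel, in degrees,
* ``L`` -- horizontal gap between the innermost fixed columns, in units of
  the lattice constant ``d``,
* ``h`` -- vertical shift of the right panel, in units of the row spacing
  ``d_tilde = (sqrt(3)/2) * d``.

The control case (A=0, L=2, h=0) is frustration-free: the union of both
panels plus the ideal in-fill is a perfect triangular lattice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SQRT3_HALF",
    "FrustrationSpec",
    "ParticleSystem",
    "SeedingError",
    "make_hex_panel",
    "build_scenario",
    "estimate_gap_cell_count",
]

SQRT3_HALF = math.sqrt(3.0) / 2.0

#: default equilibrium spacing between comb cell centers (mm)
DEFAULT_D_MM = 5.4

#: box padding beyond the outermost fixed centers, in units of d.  Kept
#: below d/2 so that clipping removes the Voronoi cells of the ragged
#: lattice fringe (which otherwise read as spurious Z=5 boundary cells).
BOX_PAD_FRAC = 0.25


class SeedingError(RuntimeError):
    """Raised when moving centers cannot be placed under the minimum
    separation constraint within the retry budget."""


@dataclass(frozen=True)
class FrustrationSpec:
    """Parameters of one engineered frustration scenario.

    Parameters
    ----------
    A : float
        Misalignment angle of the right panel in degrees, in [0, 30].
    L : float
        Horizontal gap between the innermost fixed columns, measured
        center-to-center, in multiples of ``d``.
    h : float
        Vertical shift of the right panel in multiples of ``d_tilde``.
    d : float
        Lattice constant (equilibrium center spacing) in mm.
    rows : int
        Number of lattice rows per panel.
    cols : int
        Number of lattice columns per panel.
    d_tilde : float, optional
        Row spacing in mm.  Defaults to ``(sqrt(3)/2) * d``, the vertical
        distance between nearest-neighbor centers in adjacent rows; a
        different value may be supplied explicitly to explore alternative
        conventions.
    """

    A: float = 0.0
    L: float = 2.0
    h: float = 0.0
    d: float = DEFAULT_D_MM
    rows: int = 22
    cols: int = 6
    d_tilde: float | None = None
    box_width_mm: float | None = None
    box_height_mm: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.A <= 30.0):
            raise ValueError(f"A must be in [0, 30] degrees, got {self.A}")
        if self.L < 0:
            raise ValueError(f"L must be non-negative, got {self.L}")
        if self.h < 0:
            raise ValueError(f"h must be non-negative, got {self.h}")
        if self.d <= 0:
            raise ValueError(f"d must be positive, got {self.d}")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.d_tilde is None:
            object.__setattr__(self, "d_tilde", SQRT3_HALF * self.d)
        elif self.d_tilde <= 0:
            raise ValueError(f"d_tilde must be positive, got {self.d_tilde}")

    def with_(self, **kwargs) -> "FrustrationSpec":
        return replace(self, **kwargs)


@dataclass
class ParticleSystem:
    """Cell-center coordinates with fixed/moving flags inside a bounded box.

    ``fixed_mask`` marks imprinted foundation centers, which never move
    during an annealing run.  ``box`` is ``(lo, hi)`` with each an (x, y)
    array in mm; walls clamp rather than reflect.  ``free_region`` is the
    rectangle within which moving centers were seeded (used for the
    annealer's occasional relocation proposals); it defaults to the box.
    """

    positions: np.ndarray
    fixed_mask: np.ndarray
    box: tuple[np.ndarray, np.ndarray]
    free_region: tuple[np.ndarray, np.ndarray] | None = None
    spec: FrustrationSpec | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if self.fixed_mask.shape != (len(self.positions),):
            raise ValueError("fixed_mask length must match positions")
        lo, hi = (np.asarray(b, dtype=float) for b in self.box)
        self.box = (lo, hi)
        if np.any(self.positions < lo - 1e-9) or np.any(self.positions > hi + 1e-9):
            raise ValueError("all positions must lie inside the box")
        if self.free_region is None:
            self.free_region = self.box

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def moving_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.fixed_mask)

    @property
    def n_moving(self) -> int:
        return int((~self.fixed_mask).sum())

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            self.positions.copy(), self.fixed_mask.copy(),
            (self.box[0].copy(), self.box[1].copy()),
            (self.free_region[0].copy(), self.free_region[1].copy()),
            self.spec,
        )


def make_hex_panel(origin, rows: int, cols: int, d: float,
                   tilt_deg: float = 0.0, pivot=None) -> np.ndarray:
    """Centers of a ``rows x cols`` triangular-lattice panel.

    Nearest-neighbor spacing is ``d``; alternate rows are offset by
    ``d/2`` and rows are spaced ``(sqrt(3)/2) d`` apart.  The panel is
    rigidly rotated by ``tilt_deg`` about ``pivot`` (default: the panel
    origin).
    """
    if d <= 0:
        raise ValueError(f"d must be positive, got {d}")
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    r = np.arange(rows)
    c = np.arange(cols)
    cc, rr = np.meshgrid(c, r)
    x = (cc + 0.5 * (rr % 2)) * d
    y = rr * (SQRT3_HALF * d)
    pts = np.column_stack([x.ravel(), y.ravel()]) + np.asarray(origin, dtype=float)
    if tilt_deg:
        theta = math.radians(tilt_deg)
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        piv = np.asarray(pivot if pivot is not None else origin, dtype=float)
        pts = (pts - piv) @ rot.T + piv
    return pts


def _panel_geometry(spec: FrustrationSpec):
    """Fixed centers of both panels plus derived box and gap rectangles.

    The left panel is an untilted ``rows x cols`` lattice.  The right
    panel is a lattice shifted up by ``h * d_tilde`` and tilted by ``A``
    degrees about the midpoint of the panel's inner edge, then clipped
    to the panel rectangle -- mirroring printed foundations, where the
    pattern tilts inside a fixed panel region so the gap stays a
    vertical strip of width ``L * d`` for every angle.
    """
    d, dt = spec.d, spec.d_tilde
    left = make_hex_panel((0.0, 0.0), spec.rows, spec.cols, d)
    x_left_inner = (spec.cols - 1) * d
    x_right_inner = x_left_inner + spec.L * d
    panel_w = (spec.cols - 1) * d
    panel_h = (spec.rows - 1) * dt
    pivot = (x_right_inner, panel_h / 2.0 + spec.h * dt)
    # over-generate the tilted lattice, then clip to the panel rectangle;
    # even margins preserve row parity so A=0 reproduces an untilted panel
    margin = 2 * (spec.rows // 4 + 4)
    raw = make_hex_panel(
        (x_right_inner - margin * d, spec.h * dt - margin * dt),
        spec.rows + 2 * margin, spec.cols + 2 * margin, d,
        tilt_deg=spec.A, pivot=pivot,
    )
    eps = 1e-9
    pad = BOX_PAD_FRAC * d
    # the odd-row overhang of d/2 belongs to the panel, as on the left
    lo = np.array([-pad, -pad])
    hi = np.array([x_right_inner + panel_w + 0.5 * d + pad, panel_h + pad])
    # clip only the gap-facing edge at the panel line; on the outer and
    # top/bottom sides the pattern runs to the box boundary, so the
    # ragged tilted fringe sits on the clipped rim (excluded from
    # statistics) instead of leaving bare wedges inside the crop
    keep = ((raw[:, 0] >= x_right_inner - eps)
            & (raw[:, 0] <= hi[0] + eps)
            & (raw[:, 1] >= lo[1] - eps) & (raw[:, 1] <= hi[1] + eps))
    right = raw[keep]
    fixed = np.vstack([left, right])
    if spec.box_width_mm is not None:
        hi = np.array([lo[0] + spec.box_width_mm, hi[1]])
    if spec.box_height_mm is not None:
        hi = np.array([hi[0], lo[1] + spec.box_height_mm])
    # free (buildable) region: the gap strip plus the right panel area,
    # whose clipped rim leaves uncovered wedges under tilt or shift; the
    # 0.5*d exclusion around fixed centers carves out the covered part.
    # Wall pad strips are excluded: their shallow interstitial pockets
    # are clamping traps, not buildable cell sites.
    gap_lo = np.array([x_left_inner + 0.25 * d, lo[1]])
    gap_hi = np.array([x_right_inner + panel_w, hi[1]])
    return fixed, (lo, hi), (gap_lo, gap_hi), (x_left_inner, x_right_inner)


def estimate_gap_cell_count(spec: FrustrationSpec) -> int:
    """Number of unit Voronoi cells fitting the uncovered gap area.

    Each cell of a triangular lattice with spacing ``d`` claims the unit
    area ``(sqrt(3)/2) d**2``, so the uncovered area holds as many cells
    as the continuation of the regular lattice would place there.  The
    count is the number of sites of the continued (untilted) lattice
    inside the box minus the number of fixed foundation centers; for
    the frustration-free case this is exactly the site count of the
    missing columns (one per row at ``L = 2d``), and tilting or
    shifting the right panel -- which removes pattern cells at the
    clipped rim -- enlarges it by the corresponding uncovered area.
    """
    fixed, (lo, hi), _, _ = _panel_geometry(spec)
    n_cols = int(math.ceil((hi[0] - lo[0]) / spec.d)) + 2
    reference = make_hex_panel((0.0, 0.0), spec.rows, n_cols, spec.d)
    in_box = ((reference[:, 0] >= lo[0]) & (reference[:, 0] <= hi[0])
              & (reference[:, 1] >= lo[1]) & (reference[:, 1] <= hi[1]))
    return max(int(in_box.sum()) - len(fixed), 0)


def build_scenario(spec: FrustrationSpec, n_moving: int | None = None,
                   rng_seed: int = 0, max_tries: int = 200) -> ParticleSystem:
    """Construct the fixed panels and seed moving centers for a scenario.

    The left panel is untilted at the left box edge; the right panel is
    offset horizontally by ``L*d``, vertically by ``h*d_tilde``, and
    tilted by ``A`` degrees about the midpoint of its inner edge (the
    pattern tilts inside the panel rectangle).  Moving centers are
    seeded uniformly at random inside the uncovered gap region --
    realized as uniform draws over the box rejected within ``0.5*d`` of
    any existing center, which confines them to the un-imprinted area
    whatever its shape.

    Parameters
    ----------
    n_moving : int, optional
        Number of moving centers.  Defaults to the area-based estimate
        of :func:`estimate_gap_cell_count`.
    max_tries : int
        Rejection-sampling attempts allowed per center before a
        :class:`SeedingError` is raised.
    """
    fixed, box, gap, _ = _panel_geometry(spec)
    if n_moving is None:
        n_moving = estimate_gap_cell_count(spec)
    rng = np.random.default_rng(rng_seed)
    glo, ghi = gap
    placed: list[np.ndarray] = []
    existing = fixed
    min_sep = 0.5 * spec.d
    for _ in range(n_moving):
        for _attempt in range(max_tries):
            p = rng.uniform(glo, ghi)
            dmin = np.min(np.hypot(*(existing - p).T))
            if placed:
                dmin = min(dmin, np.min(np.hypot(*(np.asarray(placed) - p).T)))
            if dmin >= min_sep:
                placed.append(p)
                break
        else:
            raise SeedingError(
                f"could not place moving center {len(placed) + 1}/{n_moving} "
                f"at min separation {min_sep:.2f} mm after {max_tries} tries"
            )
    moving = np.asarray(placed).reshape(len(placed), 2)
    positions = np.vstack([fixed, moving]) if len(moving) else fixed.copy()
    fixed_mask = np.zeros(len(positions), dtype=bool)
    fixed_mask[: len(fixed)] = True
    return ParticleSystem(positions, fixed_mask, box, gap, spec)
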