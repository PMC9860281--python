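"""File formats: center tables, scenario configs, summaries, manifests.

Center coordinates travel as plain CSV with unit-suffixed headers
(``x_mm, y_mm, fixed``), so tables digitized from comb photographs can
flow into the analysis stages unchanged.  Summaries are JSON; run
manifests record everything needed to re-execute a run.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annealer import AnnealConfig, EnergyTrace
from .scenarios import FrustrationSpec, ParticleSystem

__all__ = [
    "read_centers", "write_centers", "read_config",
    "write_trace", "write_summary", "RunManifest",
]

CENTER_COLUMNS = ("x_mm", "y_mm", "fixed")


def write_centers(system: ParticleSystem, path) -> None:
    """Write a center table (columns ``x_mm, y_mm, fixed``)."""
    df = pd.DataFrame({
        "x_mm": system.positions[:, 0],
        "y_mm": system.positions[:, 1],
        "fixed": system.fixed_mask.astype(int),
    })
    df.to_csv(path, index=False, float_format="%.12g")


def read_centers(path, d: float = 5.4, pad: float | None = None) -> ParticleSystem:
    """Read a center table back into a :class:`ParticleSystem`.

    The box is the bounding box of the centers padded by ``pad`` mm
    (default ``0.25 * d``, the same convention the scenario builder
    uses).  Coordinates round-trip to within 1e-9 mm.  Malformed rows
    are reported with their line number.
    """
    df = pd.read_csv(path)
    missing = [c for c in CENTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; "
                         f"expected header x_mm,y_mm,fixed")
    coords = df[["x_mm", "y_mm"]].apply(pd.to_numeric, errors="coerce")
    bad = df.index[~np.isfinite(coords).all(axis=1)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]  # +2: header plus 1-based
        raise ValueError(f"{path}: non-finite coordinate at line(s) {lines}")
    positions = coords.to_numpy(dtype=float)
    fixed = df["fixed"].to_numpy().astype(bool)
    if pad is None:
        pad = 0.25 * d
    lo = positions.min(axis=0) - pad
    hi = positions.max(axis=0) + pad
    return ParticleSystem(positions, fixed, (lo, hi))


def read_config(path) -> tuple[FrustrationSpec, AnnealConfig, dict]:
    """Parse a YAML scenario config into spec, annealing config and extras.

    Recognized scenario keys: ``A_deg, L_over_d, h_over_dtilde, d_mm,
    rows, cols``; optional ``n_moving, seed, replicates``; optional
    ``annealing:`` section with :class:`AnnealConfig` fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "A_deg" not in raw:
        raise ValueError(f"{path}: missing required field 'A_deg'")
    spec_kwargs = {}
    for src, dst in (("A_deg", "A"), ("L_over_d", "L"), ("h_over_dtilde", "h"),
                     ("d_mm", "d"), ("rows", "rows"), ("cols", "cols")):
        if src in raw:
            spec_kwargs[dst] = raw[src]
    try:
        spec = FrustrationSpec(**spec_kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: invalid scenario field: {exc}") from exc
    ann_kwargs = dict(raw.get("annealing") or {})
    if "seed" in raw and "seed" not in ann_kwargs:
        ann_kwargs["seed"] = raw["seed"]
    try:
        cfg = AnnealConfig(**ann_kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: invalid annealing field: {exc}") from exc
    extras = {k: raw[k] for k in ("n_moving", "seed", "replicates") if k in raw}
    return spec, cfg, extras


def write_trace(trace: EnergyTrace, path) -> None:
    trace.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


def write_summary(summary: dict, path) -> None:
    """Write a summary dict as JSON (NaN becomes null)."""
    with open(path, "w") as fh:
        json.dump(_jsonify(summary), fh, indent=1, sort_keys=True)
        fh.write("\n")


@dataclass
class RunManifest:
    """Record of one scenario run sufficient to re-execute it."""

    scenario: dict
    annealing: dict
    replicate_seeds: list
    outputs: list
    software_version: str = ""
    timestamp: str = field(default_factory=lambda: time.strftime(
        "%Y-%m-%dT%H:%M:%S", time.gmtime()))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(_jsonify(asdict(self)), fh, indent=1, sort_keys=True)
            fh.write("\n")
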