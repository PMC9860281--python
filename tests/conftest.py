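import numpy as np
import pytest

import combcrystal as cc
from combcrystal.synthetic import analysis_box


@pytest.fixture(scope="session")
def perfect_tess():
    """Tessellation of a 12x12 perfect lattice."""
    pts = cc.perfect_lattice(12, 12, 5.4)
    return cc.voronoi_cells(pts, analysis_box(pts), d=5.4)


@pytest.fixture(scope="session")
def dislocation_fixture():
    """Single seeded 5-7 dislocation with its oracle-derived inventory."""
    spec = cc.FixtureSpec(kind="dislocation_pair", rows=15, cols=15,
                          dislocations=((7, 7),))
    return cc.build_fixture(spec)


@pytest.fixture(scope="session")
def dipole_fixture():
    """Two 5-7 duplets from a finite half-row termination, seven
    adjacency steps apart (the illustrated topological-distance case)."""
    spec = cc.FixtureSpec(kind="dislocation_row", rows=17, cols=23,
                          dislocations=((8, 5, 13),))
    return cc.build_fixture(spec)


@pytest.fixture(scope="session")
def tiny_result():
    """A quick annealed control run on a small scenario, for API tests."""
    spec = cc.FrustrationSpec(A=0, L=2, h=0, rows=8, cols=4)
    cfg = cc.AnnealConfig(n_stages=8, sweeps_per_stage=15, seed=3)
    model = cc.HoneycombModel.from_scenario(spec, seed=3, config=cfg)
    return model.fit()
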