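import math

import numpy as np
import pandas as pd
import pytest

import combcrystal as cc
from combcrystal import defects as ds
from combcrystal.scenarios import SQRT3_HALF
from combcrystal.synthetic import analysis_box
from combcrystal.tessellation import Tessellation

D = 5.4


def _points_only_tess(points) -> Tessellation:
    """Minimal tessellation stub for geometry-only operations."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    return Tessellation(pts, [None] * n, np.full(n, 6), np.ones(n),
                        np.ones(n, bool), np.empty((0, 2), int),
                        (pts.min(0) - 1, pts.max(0) + 1), D, 1)


class TestClassify:
    def test_perfect_lattice_all_hex(self, perfect_tess):
        labels = ds.classify(perfect_tess)
        inside = perfect_tess.interior
        assert np.all(labels[inside] == ds.HEX)
        assert np.all(labels[~inside] == ds.EXCLUDED)

    def test_seeded_dislocation_gives_one_five_and_one_seven(
            self, dislocation_fixture):
        _, tess, truth = dislocation_fixture
        labels = ds.classify(tess)
        assert int((labels == ds.BELOW6).sum()) == truth["n_below6"] == 1
        assert int((labels == ds.ABOVE6).sum()) == truth["n_above6"] == 1

    def test_labels_permutation_invariant(self, dislocation_fixture):
        pts, _, _ = dislocation_fixture
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pts))
        tess = cc.voronoi_cells(pts[perm], analysis_box(pts), d=D)
        labels = ds.classify(tess)
        ref = ds.classify(cc.voronoi_cells(pts, analysis_box(pts), d=D))
        assert sorted(labels.tolist()) == sorted(ref.tolist())


class TestChains:
    def test_single_dislocation_is_one_chain_of_two(self, dislocation_fixture):
        _, tess, truth = dislocation_fixture
        chains = ds.find_chains(tess)
        assert len(chains) == len(truth["components"]) == 1
        assert chains[0].length == 2

    def test_dipole_gives_two_chains(self, dipole_fixture):
        _, tess, truth = dipole_fixture
        chains = ds.find_chains(tess)
        assert len(chains) == len(truth["components"]) == 2

    def test_partition_matches_flood_fill_oracle(self, dipole_fixture):
        _, tess, truth = dipole_fixture
        chains = ds.find_chains(tess)
        got = sorted(sorted(c.members.tolist()) for c in chains)
        assert got == sorted(truth["components"])
        # partition property: each defect cell in exactly one chain
        members = [i for c in chains for i in c.members]
        assert len(members) == len(set(members)) == truth["n_defect"]

    def test_defect_free_tessellation_has_no_chains(self, perfect_tess):
        assert ds.find_chains(perfect_tess) == []


class TestDefectSpacing:
    def test_matches_bfs_oracle_on_dipole(self, dipole_fixture):
        _, tess, truth = dipole_fixture
        chains = ds.find_chains(tess)
        got = ds.defect_spacing(tess, chains)
        assert got == pytest.approx(np.mean(truth["spacings"]))

    def test_symmetric_in_chain_order(self, dipole_fixture):
        _, tess, truth = dipole_fixture
        chains = ds.find_chains(tess)
        assert ds.defect_spacing(tess, chains) == \
            ds.defect_spacing(tess, chains[::-1])

    def test_fewer_than_two_chains_is_undefined(self, dislocation_fixture):
        _, tess, _ = dislocation_fixture
        chains = ds.find_chains(tess)
        assert ds.defect_spacing(tess, chains) is None

    def test_seven_cell_separation_fixture(self, dipole_fixture):
        """The dipole fixture's duplets sit seven adjacency steps apart:
        the oracle and the implementation must both measure 7."""
        _, tess, truth = dipole_fixture
        assert truth["spacings"] == [7]
        chains = ds.find_chains(tess)
        assert ds.defect_spacing(tess, chains) == pytest.approx(7.0)


class TestDefectDensity:
    def test_arithmetic_of_definition(self, dislocation_fixture):
        _, tess, truth = dislocation_fixture
        assert ds.defect_density(tess) == pytest.approx(
            truth["n_defect"] / tess.crop_rows)

    def test_zero_rows_raises(self, perfect_tess):
        broken = cc.crop(perfect_tess, ((1e4, 1e4), (1e4 + 1, 1e4 + 1)))
        with pytest.raises(ValueError):
            ds.defect_density(broken)

    def test_four_defects_in_22_rows(self):
        # direct check of the definition on a stub
        pts = cc.perfect_lattice(4, 4, D)
        tess = cc.voronoi_cells(pts, analysis_box(pts), d=D)
        tess.crop_rows = 22
        tess.Z = tess.Z.copy()
        inside = np.flatnonzero(tess.interior)[:4]
        tess.Z[inside] = 5
        assert ds.defect_density(tess) == pytest.approx(4 / 22)


class TestChainAngle:
    def test_vertical_chain_is_boundary_excluded(self):
        tess = _points_only_tess([[0, 0], [0, 5], [20, 20]])
        chain = ds.DefectChain(np.array([0, 1]), np.array([0.0, 2.5]))
        assert ds.chain_angle(chain, tess) is None

    def test_diagonal_chain_is_45_degrees(self):
        tess = _points_only_tess([[0, 0], [3, 3], [20, 0.0]])
        chain = ds.DefectChain(np.array([0, 1]), np.array([1.5, 1.5]))
        assert ds.chain_angle(chain, tess) == pytest.approx(45.0)

    def test_obtuse_fit_folds_into_interval(self):
        # raw direction at 135 degrees folds to 45
        tess = _points_only_tess([[0, 0], [-3, 3], [20, 0.0]])
        chain = ds.DefectChain(np.array([0, 1]), np.array([-1.5, 1.5]))
        assert ds.chain_angle(chain, tess) == pytest.approx(45.0)

    def test_single_cell_chain_is_undefined(self):
        tess = _points_only_tess([[0, 0], [3, 3], [20, 0.0]])
        chain = ds.DefectChain(np.array([0]), np.array([0.0, 0.0]))
        assert ds.chain_angle(chain, tess) is None

    def test_total_least_squares_through_three_members(self):
        tess = _points_only_tess([[0, 0], [1, 1], [2, 2], [30, 0.0]])
        chain = ds.DefectChain(np.array([0, 1, 2]), np.array([1.0, 1.0]))
        assert ds.chain_angle(chain, tess) == pytest.approx(45.0)


class TestAreaByCharge:
    def test_perfect_lattice_hexagons_only(self, perfect_tess):
        out = ds.area_by_charge(perfect_tess)
        assert set(out) == {ds.HEX}
        assert out[ds.HEX] == pytest.approx(SQRT3_HALF * D**2, rel=1e-9)

    def test_class_means_are_member_averages(self, dipole_fixture):
        _, tess, _ = dipole_fixture
        labels = ds.classify(tess)
        out = ds.area_by_charge(tess)
        for cls in out:
            assert out[cls] == pytest.approx(tess.area[labels == cls].mean())


class TestSummarize:
    def test_identical_replicates_have_zero_sd(self, dislocation_fixture):
        _, tess, _ = dislocation_fixture
        stats = ds.summarize([tess, tess, tess])
        assert stats.n_replicates == 3
        assert stats.defect_density_sd == pytest.approx(0.0, abs=1e-12)
        assert stats.chain_length_sd == pytest.approx(0.0, abs=1e-12)

    def test_single_replicate_sd_is_flagged_nan(self, dislocation_fixture):
        _, tess, _ = dislocation_fixture
        stats = ds.summarize([tess])
        assert math.isnan(stats.defect_density_sd)

    def test_defect_free_replicates(self, perfect_tess):
        stats = ds.summarize([perfect_tess] * 3)
        assert stats.defect_density_mean == 0.0
        assert stats.n_alpha == 0
        assert math.isnan(stats.alpha_mean)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ds.summarize([])


class TestCompareToReference:
    def _table(self, values):
        rows = []
        for (A, stat), v in values.items():
            rows.append({"A": A, "statistic": stat, "mean": v})
        return pd.DataFrame(rows)

    def test_identical_tables_have_zero_rmse(self):
        t = self._table({(10, "density"): 1.0, (20, "density"): 2.0})
        out = ds.compare_to_reference(t, t.copy())
        assert out == {"density": 0.0}

    def test_constant_offset_gives_that_offset(self):
        m = self._table({(10, "density"): 1.0, (20, "density"): 2.0,
                         (30, "density"): 3.0})
        r = self._table({(10, "density"): 1.5, (20, "density"): 2.5,
                         (30, "density"): 3.5})
        assert ds.compare_to_reference(m, r)["density"] == pytest.approx(0.5)

    def test_three_point_toy_matches_direct_arithmetic(self):
        m = self._table({(10, "s"): 1.0, (20, "s"): 4.0, (30, "s"): 2.0})
        r = self._table({(10, "s"): 2.0, (20, "s"): 2.0, (30, "s"): 5.0})
        expect = math.sqrt((1 + 4 + 9) / 3)
        assert ds.compare_to_reference(m, r)["s"] == pytest.approx(expect)

    def test_mismatched_grids_raise(self):
        m = self._table({(10, "s"): 1.0, (20, "s"): 2.0})
        r = self._table({(10, "s"): 1.0, (30, "s"): 2.0})
        with pytest.raises(ValueError, match="do not match"):
            ds.compare_to_reference(m, r)
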