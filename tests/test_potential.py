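"""WRD statistic, potential diagrams, equipotential contours, merging."""

import numpy as np
import pytest

from protpot import composition as cp
from protpot import diffexpr as dx
from protpot import potential as pt
from protpot import thermo as th
from protpot import workbench as wb


def _plane_diagram(grid, fn, name="plane", n_up=10, n_down=10):
    xx, yy = np.meshgrid(grid.x, grid.y)
    return pt.PotentialDiagram(grid=grid, field=fn(xx, yy), name=name,
                               n_up=n_up, n_down=n_down)


SMALL_GRID = th.GridSpec(-72, -60, 13, -4, 2, 13)


class TestWrdStatistic:
    def test_hand_computed_toys(self):
        assert pt.wrd([2, 3], [1]) == pytest.approx(2.0)
        assert pt.wrd([3, 1], [2]) == pytest.approx(0.0)

    def test_identical_multisets_balance(self):
        assert pt.wrd([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(0.0)

    def test_bound_and_equality_at_separation(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n_up, n_down = rng.integers(1, 12, 2)
            up = rng.normal(size=n_up)
            down = rng.normal(size=n_down)
            val = pt.wrd(up, down)
            assert abs(val) <= n_up * n_down + 1e-9
            separated = up.min() > down.max() or down.min() > up.max()
            if separated:
                assert abs(val) == pytest.approx(n_up * n_down)
            else:
                assert abs(val) < n_up * n_down - 1e-9

    def test_antisymmetry(self):
        rng = np.random.default_rng(13)
        up, down = rng.normal(size=6), rng.normal(size=4)
        assert pt.wrd(up, down) == pytest.approx(-pt.wrd(down, up))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(14)
        up, down = rng.normal(size=7), rng.normal(size=5)
        base = pt.wrd(up, down)
        for f in (np.exp, lambda v: 3 * v - 10, np.arctan):
            assert pt.wrd(f(up), f(down)) == pytest.approx(base)

    def test_consistency_with_cles(self):
        """Dual route: WRD = n_up * n_down * (2 CLES/100 - 1)."""
        rng = np.random.default_rng(15)
        up, down = rng.normal(size=9), rng.normal(size=6)
        expected = 9 * 6 * (2 * dx.cles(up, down) / 100.0 - 1.0)
        assert pt.wrd(up, down) == pytest.approx(expected)

    def test_wrd_at_point_rejects_overlap(self):
        with pytest.raises(ValueError):
            pt.wrd_at_point({"A": 1.0, "B": 2.0}, ["A", "B"], ["B"])


@pytest.fixture(scope="module")
def experiment():
    spec = wb.SyntheticSpec(seed=3, n_up=5, n_down=5,
                            beta_up=wb.calibrate_beta(-0.04))
    dataset, records, _ = wb.generate_synthetic_experiment(spec)
    return dataset, cp.records_as_mapping(records)


class TestPotentialDiagram:
    def test_matches_scalar_wrd_oracle(self, experiment, thermo_table):
        dataset, proteome = experiment
        diag = pt.potential_diagram(dataset, proteome, grid=SMALL_GRID, table=thermo_table)
        for iy, y in enumerate(SMALL_GRID.y):
            for ix, x in enumerate(SMALL_GRID.x):
                conds = th.ThermoConditions(log_fO2=x, log_aH2O=y)
                affinities = {
                    pid: th.affinity_per_residue(rec, conds, table=thermo_table).a_star
                    for pid, rec in proteome.items()
                }
                oracle = pt.wrd_at_point(affinities, dataset.up_ids, dataset.down_ids)
                assert diag.field[iy, ix] == pytest.approx(oracle, abs=1e-9)

    def test_identical_groups_zero_field(self, thermo_table):
        comp = cp.AminoAcidComposition.from_sequence("MKVLAGGQE")
        proteome = {pid: cp.ProteinRecord(pid, comp) for pid in ("U1", "U2", "D1", "D2")}
        ds = dx.ExpressionDataset("same", ("U1", "U2"), ("D1", "D2"))
        diag = pt.potential_diagram(ds, proteome, grid=SMALL_GRID, table=thermo_table)
        assert np.allclose(diag.field, 0.0)

    def test_oxygen_demand_ordering_makes_field_monotone(self, thermo_table):
        """If every up protein has higher n̄_O2 than every down protein, WRD is
        non-decreasing along the log f_O2 axis at fixed log a_H2O."""
        oxidized = cp.AminoAcidComposition({"Gly": 50.0, "Asp": 30.0})   # high n_O2
        reduced = cp.AminoAcidComposition({"Leu": 50.0, "Ile": 30.0})    # low n_O2
        proteome = {}
        for i in range(3):
            proteome[f"U{i}"] = cp.ProteinRecord(f"U{i}", cp.AminoAcidComposition(
                {"Gly": 50.0 + i, "Asp": 30.0}))
            proteome[f"D{i}"] = cp.ProteinRecord(f"D{i}", cp.AminoAcidComposition(
                {"Leu": 50.0 + i, "Ile": 30.0}))
        ds = dx.ExpressionDataset("ordered", tuple(f"U{i}" for i in range(3)),
                                  tuple(f"D{i}" for i in range(3)))
        diag = pt.potential_diagram(ds, proteome, grid=SMALL_GRID, table=thermo_table)
        assert (np.diff(diag.field, axis=1) >= -1e-9).all()
        # sanity: the ordering premise itself
        assert (cp.project_onto_basis(cp.formula_from_composition(oxidized), cp.QEC,
                                      length=80).per_residue["O2"]
                > cp.project_onto_basis(cp.formula_from_composition(reduced), cp.QEC,
                                        length=80).per_residue["O2"])

    def test_bound_violation_rejected(self):
        with pytest.raises(ValueError, match="n_up"):
            pt.PotentialDiagram(grid=SMALL_GRID,
                                field=np.full((13, 13), 5.0), name="bad",
                                n_up=2, n_down=2)


class TestZeroContour:
    def test_vertical_analytic_contour(self):
        diag = _plane_diagram(SMALL_GRID, lambda x, y: x + 66.0)
        res = pt.zero_contour_positions(diag, axis="x")
        assert res.crossing
        assert res.position == pytest.approx(-66.0, abs=1e-9)

    def test_single_sign_field_no_crossing(self):
        diag = _plane_diagram(SMALL_GRID, lambda x, y: np.ones_like(x))
        res = pt.zero_contour_positions(diag)
        assert not res.crossing and np.isnan(res.position)

    def test_stepped_field_interpolates_midpoint(self):
        grid = th.GridSpec(-72, -60, 13, -4, 2, 5)  # unit x spacing
        x_cols = grid.x[np.newaxis, :]
        field = np.where(np.broadcast_to(x_cols, (5, 13)) <= -67.0, -2.0, 2.0)
        diag = pt.PotentialDiagram(grid=grid, field=field, name="step", n_up=2, n_down=2)
        res = pt.zero_contour_positions(diag, axis="x")
        assert res.position == pytest.approx(-66.5, abs=1e-9)

    def test_zero_plateau_reports_midpoint(self):
        diag = _plane_diagram(SMALL_GRID, lambda x, y: np.zeros_like(x))
        res = pt.zero_contour_positions(diag, axis="y")
        assert res.crossing
        assert res.position == pytest.approx(-1.0)  # midpoint of [-4, 2]


class TestMerging:
    def test_merge_single_is_identity(self):
        diag = _plane_diagram(SMALL_GRID, lambda x, y: x + 65.0)
        merged = pt.merge_diagrams([diag])
        assert np.allclose(merged.field, diag.field)
        assert merged.members == ("plane",)

    def test_merge_with_negation_cancels(self):
        d1 = _plane_diagram(SMALL_GRID, lambda x, y: x + 65.0)
        d2 = _plane_diagram(SMALL_GRID, lambda x, y: -(x + 65.0), name="neg")
        merged = pt.merge_diagrams([d1, d2])
        assert np.allclose(merged.field, 0.0)

    def test_member_position_quartiles(self):
        diagrams = [
            _plane_diagram(SMALL_GRID, lambda x, y, c=c: x - c, name=f"p{c}")
            for c in (-66.0, -67.0, -68.0)
        ]
        merged = pt.merge_diagrams(diagrams, axis="x")
        assert sorted(merged.positions) == pytest.approx([-68.0, -67.0, -66.0])
        assert merged.median == pytest.approx(-67.0)
        assert merged.q1 == pytest.approx(-67.5)
        assert merged.q3 == pytest.approx(-66.5)

    def test_grid_mismatch_rejected(self):
        d1 = _plane_diagram(SMALL_GRID, lambda x, y: x + 66.0)
        other = th.GridSpec(-72, -60, 9, -4, 2, 9)
        d2 = _plane_diagram(other, lambda x, y: x + 66.0)
        with pytest.raises(ValueError, match="grids"):
            pt.merge_diagrams([d1, d2])


class TestGrouping:
    def test_membership_equals_brute_force_filter(self, thermo_table):
        """Predicate-selected membership matches an independent filter, and the
        merged diagram covers exactly those members."""
        datasets, proteomes, results = {}, {}, {}
        for seed, target in ((1, +0.04), (2, +0.002), (3, +0.05), (4, -0.04)):
            spec = wb.SyntheticSpec(seed=seed, n_up=20, n_down=20,
                                    beta_up=wb.calibrate_beta(target),
                                    name=f"tilt{target:+.3f}")
            ds, recs, _ = wb.generate_synthetic_experiment(spec)
            datasets[ds.name] = ds
            proteomes[ds.name] = cp.records_as_mapping(recs)
            results[ds.name] = dx.compare_groups(ds, cp.compute_metrics(recs))
        pred = dx.diagram_group_predicate("Zc", sign=+1, exclude_other=False)
        merged, members = pt.group_and_summarize(
            results, datasets, proteomes, pred, grid=SMALL_GRID, table=thermo_table)
        brute = tuple(n for n, r in results.items() if r.delta["Zc"] > 0.01)
        assert members == brute
        assert merged.members == brute

    def test_empty_group_reported(self, thermo_table):
        merged, members = pt.group_and_summarize(
            {}, {}, {}, lambda r: True, grid=SMALL_GRID, table=thermo_table)
        assert merged is None and members == ()


class TestSerialization:
    def test_round_trip(self, tmp_path):
        diag = _plane_diagram(SMALL_GRID, lambda x, y: x + 66.0 + 0.1 * y)
        pt.write_diagram(diag, tmp_path / "d")
        back = pt.read_diagram(tmp_path / "d")
        assert back.grid == diag.grid
        assert np.allclose(back.field, diag.field)
        assert (back.name, back.n_up, back.n_down) == ("plane", 10, 10)

    def test_plot_writes_file(self, tmp_path):
        diag = _plane_diagram(SMALL_GRID, lambda x, y: x + 66.0)
        pt.plot_diagram(diag, tmp_path / "d.png")
        assert (tmp_path / "d.png").stat().st_size > 0
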