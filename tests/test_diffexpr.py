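"""Dataset loading rules and group-comparison statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from protpot import composition as cp
from protpot import diffexpr as dx


def _table(rows):
    return pd.DataFrame(rows, columns=["id", "direction"])


class TestLoadDataset:
    def test_opposite_directions_excluded(self):
        ds = dx.load_dataset(_table([("P1", "up"), ("P2", "down"),
                                     ("P3", "up"), ("P3", "down")]))
        assert ds.up_ids == ("P1",)
        assert ds.down_ids == ("P2",)
        assert ds.cleaning["opposite_direction_excluded"] == 1

    def test_id_updates_applied(self):
        ds = dx.load_dataset(_table([("Q9X000", "up"), ("P2", "down")]),
                             id_updates={"Q9X000": "P99999"})
        assert ds.up_ids == ("P99999",)
        assert ds.cleaning["ids_updated"] == 1

    def test_duplicates_collapsed(self):
        ds = dx.load_dataset(_table([("P1", "up"), ("P1", "up"), ("P2", "down")]))
        assert ds.up_ids == ("P1",)
        assert ds.cleaning["duplicates_collapsed"] == 1

    def test_log2_ratio_signs(self):
        df = pd.DataFrame({"id": ["A", "B"], "log2_ratio": [1.5, -0.7]})
        ds = dx.load_dataset(df)
        assert ds.up_ids == ("A",) and ds.down_ids == ("B",)

    def test_malformed_direction_names_row(self):
        with pytest.raises(ValueError, match="row 1"):
            dx.load_dataset(_table([("P1", "up"), ("P2", "sideways")]))

    def test_empty_group_after_cleaning_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            dx.load_dataset(_table([("P1", "up"), ("P1", "down")]))


class TestWilcoxon:
    def test_extreme_small_case_exact_third(self):
        assert dx.wilcoxon_p([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_samples_give_one(self):
        assert dx.wilcoxon_p([5, 5, 5], [5, 5]) == 1.0
        assert dx.wilcoxon_p([1.0, 2.0], [1.0, 2.0]) <= 1.0

    def _enumerate_exact(self, x, y):
        """Brute-force two-sided rank-sum p by enumerating group assignments."""
        pooled = np.concatenate([x, y])
        ranks = pooled.argsort().argsort() + 1.0
        n, nx = len(pooled), len(x)
        observed = ranks[:nx].sum()
        mean = nx * (n + 1) / 2
        stats = [sum(ranks[list(idx)]) for idx in combinations(range(n), nx)]
        extreme = sum(abs(s - mean) >= abs(observed - mean) - 1e-9 for s in stats)
        return extreme / len(stats)

    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.permutation(20)[: rng.integers(2, 6)].astype(float)
            y = np.setdiff1d(np.arange(20), x)[: rng.integers(2, 6)].astype(float) + 0.5
            assert dx.wilcoxon_p(x, y) == pytest.approx(self._enumerate_exact(x, y), abs=1e-12)

    def test_exact_and_asymptotic_agree_for_moderate_sizes(self):
        rng = np.random.default_rng(8)
        for n1, n2 in ((15, 18), (20, 25), (25, 25)):
            x = rng.normal(size=n1)
            y = rng.normal(0.3, size=n2)
            pooled = np.concatenate([x, y])
            p_exact = dx.wilcoxon_p(x, y)  # tie-free continuous -> exact path
            from scipy.stats import mannwhitneyu
            p_asym = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                  use_continuity=True).pvalue
            assert abs(p_exact - p_asym) < 0.01
            assert np.unique(pooled).size == pooled.size


class TestCles:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([0.1, 0.3], [0.0, 0.2], 75.0),  # 3 of 4 pairings positive
            ([7.0], [7.0], 50.0),            # single tied pair, half credit
            ([5, 6], [1, 2], 100.0),
            ([1, 2], [5, 6], 0.0),
        ],
    )
    def test_examples(self, x, y, expected):
        assert dx.cles(x, y) == pytest.approx(expected)

    @given(
        x=st.lists(st.integers(-50, 50), min_size=1, max_size=15),
        y=st.lists(st.integers(-50, 50), min_size=1, max_size=15),
    )
    def test_complementarity_and_bounds(self, x, y):
        a, b = dx.cles(x, y), dx.cles(y, x)
        assert a + b == pytest.approx(100.0)
        assert 0.0 <= a <= 100.0


class TestCompareGroups:
    @staticmethod
    def _metrics(values):
        return pd.DataFrame(
            {"Zc": [v[0] for v in values.values()], "nH2O": [v[1] for v in values.values()]},
            index=list(values),
        )

    def test_identical_compositions_null_result(self):
        vals = {"U1": (0.1, -0.7), "U2": (0.2, -0.8), "D1": (0.1, -0.7), "D2": (0.2, -0.8)}
        ds = dx.ExpressionDataset("toy", up_ids=("U1", "U2"), down_ids=("D1", "D2"))
        res = dx.compare_groups(ds, self._metrics(vals))
        for m in dx.METRICS:
            assert res.delta[m] == pytest.approx(0.0, abs=1e-15)
            assert res.cles_pct[m] == pytest.approx(50.0)
            assert res.p_value[m] == 1.0

    def test_two_vs_two_hand_computed(self):
        """Full hand calculation of the 2v2 comparison."""
        vals = {"U1": (0.10, -0.70), "U2": (0.30, -0.75),
                "D1": (0.00, -0.72), "D2": (0.20, -0.78)}
        ds = dx.ExpressionDataset("toy", up_ids=("U1", "U2"), down_ids=("D1", "D2"))
        res = dx.compare_groups(ds, self._metrics(vals))
        assert res.mean_up["Zc"] == pytest.approx(0.20)
        assert res.mean_down["Zc"] == pytest.approx(0.10)
        assert res.delta["Zc"] == pytest.approx(0.10)
        assert res.cles_pct["Zc"] == pytest.approx(75.0)  # pairs: 3 of 4 positive
        # ranks of up = {2, 4}: exact two-sided p from 6 assignments = 2*(2/6)
        assert res.p_value["Zc"] == pytest.approx(2 / 3)
        assert res.delta["nH2O"] == pytest.approx(0.025)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        vals = {f"P{i}": (float(rng.normal()), float(rng.normal())) for i in range(20)}
        tab = self._metrics(vals)
        up = tuple(f"P{i}" for i in range(10))
        down = tuple(f"P{i}" for i in range(10, 20))
        a = dx.compare_groups(dx.ExpressionDataset("d", up, down), tab)
        b = dx.compare_groups(dx.ExpressionDataset("d", up[::-1], down[::-1]),
                              tab.iloc[::-1])
        for m in dx.METRICS:
            assert a.delta[m] == pytest.approx(b.delta[m], abs=1e-12)
            assert a.p_value[m] == pytest.approx(b.p_value[m], abs=1e-12)
            assert a.cles_pct[m] == pytest.approx(b.cles_pct[m], abs=1e-12)

    def test_isoform_fallback_and_drop_counting(self):
        tab = self._metrics({"P1": (0.1, 0.0), "P2": (0.2, 0.0), "P3": (0.3, 0.0)})
        ds = dx.ExpressionDataset("d", up_ids=("P1-2", "MISSING"), down_ids=("P2", "P3"))
        res = dx.compare_groups(ds, tab)
        assert res.n2 == 1 and res.dropped_up == 1
        assert res.mean_up["Zc"] == pytest.approx(0.1)

    def test_fully_unresolvable_group_lists_ids(self):
        tab = self._metrics({"P1": (0.1, 0.0), "P2": (0.2, 0.0)})
        ds = dx.ExpressionDataset("d", up_ids=("X1", "X2"), down_ids=("P1", "P2"))
        with pytest.raises(ValueError, match="X1"):
            dx.compare_groups(ds, tab)


class TestClassification:
    @staticmethod
    def _result(delta_zc, p_zc, cles_zc, delta_w=0.0, p_w=0.5, cles_w=50.0):
        return dx.ComparisonResult(
            name="r", n1=10, n2=10,
            mean_down={"Zc": 0.0, "nH2O": 0.0},
            mean_up={"Zc": delta_zc, "nH2O": delta_w},
            delta={"Zc": delta_zc, "nH2O": delta_w},
            p_value={"Zc": p_zc, "nH2O": p_w},
            cles_pct={"Zc": cles_zc, "nH2O": cles_w},
        )

    def test_small_insignificant(self):
        flags = dx.classify_dataset(self._result(0.005, 0.2, 55.0))["Zc"]
        assert not flags["large"] and not flags["significant"] and not flags["strong_effect"]

    def test_large_significant_strong(self):
        flags = dx.classify_dataset(self._result(0.02, 0.01, 65.0))["Zc"]
        assert flags["large"] and flags["significant"] and flags["strong_effect"]

    def test_diagram_group_predicate(self):
        pred = dx.diagram_group_predicate("Zc", sign=+1)
        # qualifies: large positive delta Zc, other metric quiet
        assert pred(self._result(0.02, 0.01, 65.0, delta_w=0.005, p_w=0.30, cles_w=52.0))
        # disqualified by a significant water-demand difference
        assert not pred(self._result(0.02, 0.01, 65.0, delta_w=0.005, p_w=0.01, cles_w=52.0))
        # wrong sign
        assert not pred(self._result(-0.02, 0.01, 35.0))

    def test_asymmetric_cles_bounds_rejected(self):
        with pytest.raises(ValueError):
            dx.ClassificationThresholds(cles_low=45.0, cles_high=60.0)


class TestSummaries:
    def test_three_datasets_six_rows_and_determinism(self):
        rng = np.random.default_rng(6)
        ids = [f"P{i}" for i in range(30)]
        tab = pd.DataFrame({"Zc": rng.normal(size=30), "nH2O": rng.normal(size=30)}, index=ids)
        datasets = [
            dx.ExpressionDataset(f"ds{k}", tuple(ids[k * 5:k * 5 + 5]),
                                 tuple(ids[15 + k * 5:20 + k * 5]))
            for k in range(3)
        ]
        summary, errors = dx.summarize_datasets(datasets, tab)
        assert len(summary) == 6 and not errors
        again, _ = dx.summarize_datasets(datasets, tab)
        assert summary.to_csv() == again.to_csv()

    def test_per_dataset_failures_reported_not_fatal(self):
        tab = pd.DataFrame({"Zc": [0.1, 0.2, 0.0, 0.3], "nH2O": [0.0, 0.1, 0.2, 0.3]},
                           index=["P1", "P2", "P3", "P4"])
        good = dx.ExpressionDataset("good", ("P1", "P2"), ("P3", "P4"))
        bad = dx.ExpressionDataset("bad", ("X1",), ("P1",))
        summary, errors = dx.summarize_datasets([good, bad], tab)
        assert set(summary["dataset"]) == {"good"}
        assert "bad" in errors
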