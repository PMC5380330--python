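import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from mirdem import normalization
from mirdem.dem_screen import (
    ContrastResult,
    call_dems,
    compare_contrasts,
    flag_consistency_filter,
    fold_change,
    hierarchical_order,
    run_contrast,
    student_t_test,
    truncate_percent,
)
from mirdem.io_formats import ExpressionDataset
from mirdem.synthetic_data import DESpec, generate_expression_dataset


def make_dataset(present_a, present_b, values=None):
    n = len(present_a[0]) if isinstance(present_a[0], (list, tuple)) else 1
    present = np.array([list(pa) + list(pb) for pa, pb in zip(present_a, present_b)])
    n_probes = present.shape[0]
    if values is None:
        values = np.full(present.shape, 100.0)
    samples = [f"A_r{i}" for i in range(1, 4)] + [f"B_r{i}" for i in range(1, 4)]
    return ExpressionDataset(
        probe_ids=[f"p{i}" for i in range(n_probes)],
        sample_ids=samples,
        intensities=values,
        present=present,
        groups={s: s.split("_")[0] for s in samples},
    )


class TestFlagConsistency:
    def test_all_present_both_groups_passes(self):
        ds = make_dataset([[True, True, True]], [[True, True, True]])
        assert flag_consistency_filter(ds, "A", "B").tolist() == [True]

    def test_inconsistent_group_fails(self):
        ds = make_dataset([[True, True, False]], [[True, True, True]])
        assert flag_consistency_filter(ds, "A", "B").tolist() == [False]

    def test_all_absent_both_groups_fails(self):
        ds = make_dataset([[False, False, False]], [[False, False, False]])
        assert flag_consistency_filter(ds, "A", "B").tolist() == [False]

    def test_one_group_absent_other_present_passes(self):
        ds = make_dataset([[False, False, False]], [[True, True, True]])
        assert flag_consistency_filter(ds, "A", "B").tolist() == [True]

    def test_single_replicate_group_rejected(self):
        samples = ["A_r1", "B_r1", "B_r2"]
        ds = ExpressionDataset(
            probe_ids=["p0"],
            sample_ids=samples,
            intensities=np.full((1, 3), 1.0),
            present=np.full((1, 3), True),
            groups={"A_r1": "A", "B_r1": "B", "B_r2": "B"},
        )
        with pytest.raises(ValueError):
            flag_consistency_filter(ds, "A", "B")


class TestStudentT:
    def test_equal_means_t_zero_p_one(self):
        values = np.array([[1.0, 2.0, 3.0, 3.0, 2.0, 1.0]])
        t, p, deg = student_t_test(values, [0, 1, 2], [3, 4, 5])
        assert t[0] == 0.0 and p[0] == 1.0 and not deg[0]

    def test_hand_example(self):
        values = np.array([[10.0, 11.0, 12.0, 13.0, 14.0, 15.0]])
        t, p, deg = student_t_test(values, [0, 1, 2], [3, 4, 5])
        assert t[0] == pytest.approx(-3.6742346, rel=1e-6)
        # independent oracle: pooled-variance formula + t CDF
        expected_p = 2 * stats.t.sf(3.0 / math.sqrt(1.0 * (2 / 3)), df=4)
        assert p[0] == pytest.approx(expected_p, rel=1e-12)
        assert p[0] == pytest.approx(0.0213, abs=5e-4)

    def test_degenerate_zero_variance_unequal_means(self):
        values = np.array([[5.0, 5.0, 5.0, 7.0, 7.0, 7.0]])
        t, p, deg = student_t_test(values, [0, 1, 2], [3, 4, 5])
        assert deg[0] and p[0] == 0.0 and math.isinf(t[0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_pooled_ttest(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(8, 2, size=(40, 7))
        idx_a, idx_b = [0, 1, 2], [3, 4, 5, 6]
        t, p, deg = student_t_test(values, idx_a, idx_b)
        ref = stats.ttest_ind(values[:, idx_a], values[:, idx_b], axis=1, equal_var=True)
        np.testing.assert_allclose(t, ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(p, ref.pvalue, rtol=1e-10)
        assert not deg.any()


class TestFoldChange:
    def test_basic_ratio(self):
        values = np.array([[200.0, 200.0, 100.0, 100.0]])
        fc = fold_change(values, [0, 1], [2, 3])
        assert fc[0] == 2.0

    def test_equal_means_is_one(self):
        values = np.array([[100.0, 100.0, 100.0, 100.0]])
        assert fold_change(values, [0, 1], [2, 3])[0] == 1.0

    def test_zero_reference_mean_is_nan(self):
        values = np.array([[5.0, 5.0, 0.0, 0.0]])
        assert np.isnan(fold_change(values, [0, 1], [2, 3])[0])


def result_from_rows(rows):
    df = pd.DataFrame(rows, index=[f"p{i}" for i in range(len(rows))])
    return ContrastResult(test="A", reference="B", table=df)


class TestCallDems:
    def base_row(self, **kw):
        row = {"fc_linear": 1.0, "log2fc": 0.0, "t_stat": 0.0, "p_value": 1.0,
               "flag_ok": True, "degenerate": False}
        row.update(kw)
        return row

    def test_up_call(self):
        r = call_dems(result_from_rows([self.base_row(fc_linear=2.5, p_value=0.01)]))
        assert r.table["call"].tolist() == ["up"]

    def test_fc_exactly_two_not_called(self):
        r = call_dems(result_from_rows([self.base_row(fc_linear=2.0, p_value=0.001)]))
        assert r.table["call"].tolist() == ["none"]

    def test_high_p_not_called(self):
        r = call_dems(result_from_rows([self.base_row(fc_linear=3.0, p_value=0.2)]))
        assert r.table["call"].tolist() == ["none"]

    def test_flag_fail_not_called(self):
        r = call_dems(result_from_rows([self.base_row(fc_linear=3.0, p_value=0.001, flag_ok=False)]))
        assert r.table["call"].tolist() == ["none"]

    def test_down_call(self):
        r = call_dems(result_from_rows([self.base_row(fc_linear=0.3, p_value=0.01)]))
        assert r.table["call"].tolist() == ["down"]

    def test_calls_partition(self):
        rng = np.random.default_rng(0)
        rows = [
            self.base_row(fc_linear=float(fc), p_value=float(p), flag_ok=bool(f))
            for fc, p, f in zip(rng.uniform(0, 5, 200), rng.uniform(0, 1, 200),
                                rng.random(200) < 0.8)
        ]
        r = call_dems(result_from_rows(rows))
        assert set(r.table["call"]) <= {"up", "down", "none"}
        assert r.table["call"].notna().all()


class TestContrastSymmetry:
    def test_swapping_groups_inverts_fc_and_calls(self):
        spec = DESpec(n_probes=300, seed=3)
        ds, _ = generate_expression_dataset(spec)
        lin = normalization.quantile_normalize(ds.intensities)
        lg = normalization.log2_transform(lin, 1.0)
        ds2 = ds.with_intensities(lin)
        fwd = run_contrast(ds2, lg.log2_values, "CIK_IL2", "PBMC")
        rev = run_contrast(ds2, lg.log2_values, "PBMC", "CIK_IL2")
        np.testing.assert_allclose(
            fwd.table["fc_linear"], 1.0 / rev.table["fc_linear"], rtol=1e-10
        )
        np.testing.assert_allclose(fwd.table["p_value"], rev.table["p_value"], rtol=1e-10)
        assert fwd.up_probes == rev.down_probes
        assert fwd.down_probes == rev.up_probes


class TestTruncatePercent:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(130, 150, 86.66), (130, 140, 92.85), (103, 111, 92.79), (103, 109, 94.49)],
    )
    def test_printed_percentages(self, count, total, expected):
        assert truncate_percent(count, total) == expected

    @given(st.integers(0, 1000), st.integers(1, 1000))
    @settings(max_examples=200, deadline=None)
    def test_is_exact_floor(self, count, total):
        got = truncate_percent(count, total)
        exact = Fraction(100 * count, total)
        assert Fraction(int(got * 100 + 0.5), 100) <= exact
        assert exact - Fraction(int(got * 100 + 0.5), 100) < Fraction(1, 100)


class TestCompareContrasts:
    def make(self, up_a, down_a, up_b, down_b, universe):
        calls_a = {p: "up" if p in up_a else "down" if p in down_a else "none" for p in universe}
        calls_b = {p: "up" if p in up_b else "down" if p in down_b else "none" for p in universe}
        return (
            ContrastResult.from_calls("A", "ref", calls_a),
            ContrastResult.from_calls("B", "ref", calls_b),
        )

    def test_disjoint_sets_zero_percent(self):
        universe = [f"p{i}" for i in range(10)]
        a, b = self.make({"p0"}, {"p1"}, {"p2"}, {"p3"}, universe)
        cmp = compare_contrasts(a, b)
        assert cmp.pct_shared_up_a == cmp.pct_shared_up_b == 0.0
        assert cmp.pct_shared_down_a == cmp.pct_shared_down_b == 0.0

    def test_counts_equal_brute_force_set_ops(self):
        rng = np.random.default_rng(1)
        universe = [f"p{i}" for i in range(500)]
        calls = {}
        for tag in "ab":
            labels = rng.choice(["up", "down", "none"], size=500, p=[0.2, 0.2, 0.6])
            calls[tag] = dict(zip(universe, labels))
        a = ContrastResult.from_calls("A", "ref", calls["a"])
        b = ContrastResult.from_calls("B", "ref", calls["b"])
        cmp = compare_contrasts(a, b)
        up_a = {p for p, c in calls["a"].items() if c == "up"}
        up_b = {p for p, c in calls["b"].items() if c == "up"}
        down_a = {p for p, c in calls["a"].items() if c == "down"}
        down_b = {p for p, c in calls["b"].items() if c == "down"}
        assert cmp.shared_up == up_a & up_b
        assert cmp.shared_down == down_a & down_b
        assert cmp.specific_up_a == up_a - up_b
        assert cmp.specific_down_b == down_b - down_a
        assert cmp.shared_up <= up_a and cmp.shared_up <= up_b

    def test_different_universe_rejected(self):
        a = ContrastResult.from_calls("A", "ref", {"p1": "up"})
        b = ContrastResult.from_calls("B", "ref", {"p2": "up"})
        with pytest.raises(ValueError):
            compare_contrasts(a, b)


class TestHierarchicalOrder:
    def test_identical_profiles_merge_first_at_zero(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(5, 6))
        values[3] = values[1] * 2.0 + 1.0  # perfectly correlated with row 1
        ids = [f"p{i}" for i in range(5)]
        order, merges = hierarchical_order(values, ids)
        left, right, height, size = merges[0]
        assert {left, right} == {"p1", "p3"}
        assert height == pytest.approx(0.0, abs=1e-12)
        assert size == 2

    def test_matches_scipy_average_linkage_heights(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(8, 10))
        ids = [f"p{i}" for i in range(8)]
        _, merges = hierarchical_order(values, ids)
        d = 1.0 - np.corrcoef(values)
        np.fill_diagonal(d, 0.0)
        z = hierarchy.linkage(squareform(d, checks=False), method="average")
        np.testing.assert_allclose(
            sorted(m[2] for m in merges), sorted(z[:, 2]), rtol=1e-8, atol=1e-12
        )

    def test_row_permutation_gives_identical_leaf_order(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(7, 5))
        ids = [f"p{i}" for i in range(7)]
        order1, _ = hierarchical_order(values, ids)
        perm = rng.permutation(7)
        order2, _ = hierarchical_order(values[perm], [ids[i] for i in perm])
        assert order1 == order2

    def test_zero_variance_probe_at_distance_one(self):
        values = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        order, merges = hierarchical_order(values, ["flat", "a", "b"])
        # perfectly correlated pair merges first; flat joins last at height 1
        assert {merges[0][0], merges[0][1]} == {"a", "b"}
        assert merges[0][2] == pytest.approx(0.0, abs=1e-12)
        assert merges[-1][2] == pytest.approx(1.0, abs=1e-12)

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_order(np.ones((1, 3)), ["p0"])


class TestNullCalibration:
    def test_type_one_error_rate(self):
        spec = DESpec(n_probes=6000, de_fraction_up=0.0, de_fraction_down=0.0,
                      flag_dropout=0.0, seed=11)
        ds, truth = generate_expression_dataset(spec)
        assert (truth == "none").all().all()
        lg = normalization.log2_transform(
            normalization.quantile_normalize(ds.intensities), 1.0
        )
        _, p, _ = student_t_test(
            lg.log2_values, ds.sample_indices("CIK_IL2"), ds.sample_indices("PBMC")
        )
        assert abs((p < 0.05).mean() - 0.05) <= 0.02
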