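"""DSC metric and the statistical comparison suite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from csiseg.evaluation import (
    EPSILON,
    RECORD_COLUMNS,
    StatsConfig,
    age_group_compare,
    compare_models,
    dataset_compare,
    dsc,
    dunn_pairwise,
    mann_kendall,
    summarize,
    trend_with_age,
)

from conftest import random_mask


def _tau_pair_oracle(x: np.ndarray) -> float:
    """Brute-force tau-b: concordant/discordant pair counting with ties."""
    n = len(x)
    s = 0
    ties = 0
    for i in range(n):
        for j in range(i + 1, n):
            if x[j] > x[i]:
                s += 1
            elif x[j] < x[i]:
                s -= 1
            else:
                ties += 1
    n_pairs = n * (n - 1) / 2
    denom = np.sqrt((n_pairs - ties) * n_pairs)
    return s / denom if denom > 0 else 0.0


def _records(rows):
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


class TestDSC:
    def test_identical_masks_score_1(self, rng):
        A = random_mask(rng, (10, 10, 10))
        assert dsc(A, A) == 1.0

    def test_disjoint_masks_score_near_0(self):
        A = np.zeros((10, 10, 10), bool)
        B = np.zeros_like(A)
        A[:1], B[5:6] = True, True
        v = dsc(A, B)
        assert v == pytest.approx(EPSILON / (200 + EPSILON))

    def test_both_empty_scores_1(self):
        Z = np.zeros((4, 4, 4), bool)
        assert dsc(Z, Z) == 1.0

    def test_half_overlap_scores_half(self):
        A = np.zeros((1, 10, 20), bool)
        B = np.zeros_like(A)
        A[0, :5, :20] = True  # 100 voxels
        B[0, :5, 10:] = np.True_  # 100 voxels, overlap 50
        B[0, 5:, :10] = True
        assert dsc(A, B) == pytest.approx(0.5, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dsc(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(1, 8, 3))
        A = rng.uniform(size=shape) < 0.4
        B = rng.uniform(size=shape) < 0.4
        v = dsc(A, B)
        assert 0.0 <= v <= 1.0
        assert v == dsc(B, A)
        if v == 1.0:
            np.testing.assert_array_equal(A, B)


class TestMannKendall:
    def test_strictly_increasing_tau_1(self):
        tau, p, S, z = mann_kendall(np.arange(10, dtype=float))
        assert tau == 1.0 and p < 0.01

    def test_strictly_decreasing_tau_minus_1(self):
        tau, _, _, _ = mann_kendall(np.arange(10, 0, -1, dtype=float))
        assert tau == -1.0

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 20))
            x = rng.integers(0, 6, n).astype(float)  # ties likely
            tau, _, _, _ = mann_kendall(x)
            assert tau == pytest.approx(_tau_pair_oracle(x), abs=1e-12)

    def test_matches_scipy_kendalltau(self, rng):
        x = rng.normal(size=30)
        tau, _, _, _ = mann_kendall(x)
        ref = sps.kendalltau(np.arange(30), x).statistic
        assert tau == pytest.approx(ref, abs=1e-10)

    def test_antisymmetric_under_reversal(self, rng):
        x = rng.normal(size=15)
        t1, _, s1, _ = mann_kendall(x)
        t2, _, s2, _ = mann_kendall(x[::-1])
        assert t1 == pytest.approx(-t2, abs=1e-12)
        assert s1 == -s2

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mann_kendall([1.0, 2.0, 3.0])


class TestCompareModels:
    def _table(self, groups, organ="kidney_l"):
        rows = []
        for model, vals in groups.items():
            for i, v in enumerate(vals):
                rows.append((f"P{i}", organ, model, "validation", 10.0, v))
        return _records(rows)

    def test_identical_groups_not_significant_no_dunn(self):
        vals = list(np.linspace(0.7, 0.9, 10))
        df = self._table({"a": vals, "b": vals, "c": vals})
        res = compare_models(df)
        kw = [r for r in res if r.test.value == "kruskal_wallis"]
        assert len(kw) == 1 and not kw[0].significant
        assert kw[0].statistic == pytest.approx(0.0, abs=1e-9)
        assert not [r for r in res if r.test.value == "dunn"]

    def test_separated_groups_significant_with_dunn(self, rng):
        lo = rng.uniform(0.2, 0.4, 20)
        hi = rng.uniform(0.8, 0.9, 20)
        res = compare_models(self._table({"weak": lo, "strong": hi}))
        kw = [r for r in res if r.test.value == "kruskal_wallis"][0]
        assert kw.significant
        dunn = [r for r in res if r.test.value == "dunn"]
        assert len(dunn) == 1 and dunn[0].significant

    def test_holm_step_down_hand_computation(self, rng):
        """Two organs with raw p ~= (p1 < p2): Holm gives (2 p1, max(2 p1? ...))
        — verified against the closed-form step-down rule."""
        lo = rng.uniform(0.2, 0.4, 15)
        hi = rng.uniform(0.8, 0.9, 15)
        mid = np.concatenate([rng.uniform(0.4, 0.6, 8), rng.uniform(0.5, 0.7, 7)])
        df = pd.concat([
            self._table({"a": lo, "b": hi}, organ="o1"),
            self._table({"a": mid, "b": np.roll(mid, 3)}, organ="o2"),
        ])
        res = [r for r in compare_models(df) if r.test.value == "kruskal_wallis"]
        praw = np.array([r.p_raw for r in res])
        order = np.argsort(praw)
        expected = np.empty(2)
        expected[order[0]] = min(1.0, 2 * praw[order[0]])
        expected[order[1]] = min(1.0, max(expected[order[0]], praw[order[1]]))
        for r, e in zip(res, expected):
            assert r.p_adjusted == pytest.approx(e, rel=1e-9)

    def test_fewer_than_two_models_rejected(self):
        df = self._table({"only": np.linspace(0, 1, 5)})
        with pytest.raises(ValueError):
            compare_models(df)


class TestDunn:
    def test_identical_groups_z_zero(self):
        g = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([1.0, 2.0, 3.0])}
        (name_a, name_b, z, p) = dunn_pairwise(g)[0]
        assert z == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_ordering_of_separated_groups(self):
        g = {"low": np.array([1.0, 2, 3, 4]), "high": np.array([10.0, 11, 12, 13])}
        _, _, z, p = dunn_pairwise(g)[0]
        assert z < 0 and p < 0.05


class TestTrendWithAge:
    def _table(self, dscs, ages, model="m", organ="k"):
        rows = [(f"P{i}", organ, model, "validation", a, d)
                for i, (a, d) in enumerate(zip(ages, dscs))]
        return _records(rows)

    def test_increasing_trend_detected(self):
        ages = np.arange(4, 20, dtype=float)
        res = trend_with_age(self._table(np.linspace(0.5, 0.9, 16), ages))
        assert len(res) == 1
        assert res[0].statistic == 1.0 and res[0].significant

    def test_records_sorted_by_age_not_input_order(self, rng):
        ages = np.arange(4, 16, dtype=float)
        dscs = np.linspace(0.5, 0.9, 12)
        perm = rng.permutation(12)
        res = trend_with_age(self._table(dscs[perm], ages[perm]))
        assert res[0].statistic == 1.0  # perfectly increasing once sorted

    def test_fdr_applied_across_batch(self):
        ages = np.arange(4, 16, dtype=float)
        df = pd.concat([
            self._table(np.linspace(0.5, 0.9, 12), ages, organ="up"),
            self._table(np.full(12, 0.7), ages, organ="flat"),
        ])
        res = {r.organ: r for r in trend_with_age(df)}
        assert res["up"].significant and not res["flat"].significant
        assert res["up"].adjust_method == "fdr_bh"

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            trend_with_age(self._table([0.5, 0.6, 0.7], [4.0, 5.0, 6.0]))


class TestAgeGroupCompare:
    def test_identical_groups_maximal_p(self):
        vals = [0.5, 0.6, 0.7, 0.8]
        rows = ([(f"A{i}", "k", "m", "validation", 5.0, v) for i, v in enumerate(vals)]
                + [(f"B{i}", "k", "m", "validation", 15.0, v) for i, v in enumerate(vals)])
        res = age_group_compare(_records(rows), "m", "k")
        assert res.statistic == pytest.approx(len(vals) ** 2 / 2)
        assert not res.significant

    def test_fully_separated_groups(self, rng):
        young = [(f"A{i}", "k", "m", "v", 6.0, v)
                 for i, v in enumerate(rng.uniform(0.2, 0.4, 6))]
        old = [(f"B{i}", "k", "m", "v", 14.0, v)
               for i, v in enumerate(rng.uniform(0.6, 0.9, 21))]
        res = age_group_compare(_records(young + old), "m", "k")
        assert res.statistic in (0.0, 6 * 21)
        assert res.p_raw < 1e-4

    def test_age_exactly_10_joins_older_group(self):
        rows = ([("A", "k", "m", "v", 9.9, 0.5)]
                + [(f"B{i}", "k", "m", "v", 10.0, 0.8) for i in range(3)])
        res = age_group_compare(_records(rows), "m", "k")
        assert res.extra == {"n_young": 1, "n_old": 3}

    def test_empty_group_rejected(self):
        rows = [(f"B{i}", "k", "m", "v", 12.0, 0.8) for i in range(4)]
        with pytest.raises(ValueError):
            age_group_compare(_records(rows), "m", "k")


class TestDatasetCompare:
    def test_shifted_cohort_flagged_only_for_shifted_organ(self, rng):
        rows = []
        for organ, shift in (("stable", 0.0), ("shifted", 0.35)):
            for i in range(15):
                rows.append((f"V{i}", organ, "m", "validation", 10.0,
                             float(rng.uniform(0.5, 0.6))))
                rows.append((f"T{i}", organ, "m", "test", 10.0,
                             float(rng.uniform(0.5, 0.6) - shift)))
        res = {r.organ: r for r in dataset_compare(_records(rows))}
        assert res["shifted"].significant
        assert not res["stable"].significant

    def test_missing_cohort_rejected(self):
        rows = [(f"V{i}", "k", "m", "validation", 10.0, 0.5) for i in range(5)]
        with pytest.raises(ValueError):
            dataset_compare(_records(rows))


class TestSummarize:
    def test_single_record_mean_is_value_std_zero(self):
        df = _records([("P0", "k", "m", "validation", 10.0, 0.73)])
        tables = summarize(df)
        row = tables["dsc_summary"].iloc[0]
        assert row["mean"] == 0.73 and row["std"] == 0.0

    def test_random_table_matches_numpy(self, rng):
        rows = [(f"P{i}", "k", "m", "validation", 10.0, float(v))
                for i, v in enumerate(rng.uniform(0.3, 0.9, 12))]
        tables = summarize(_records(rows))
        vals = np.array([r[-1] for r in rows])
        row = tables["dsc_summary"].iloc[0]
        assert row["mean"] == pytest.approx(vals.mean())
        assert row["std"] == pytest.approx(vals.std(ddof=0))
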