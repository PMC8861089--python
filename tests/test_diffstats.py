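from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lipidfinger.diffstats import (
    anova_tukey,
    bh_adjust,
    classify_volcano,
    log2_fold_change,
    venn_overlap,
    welch_t,
)
from lipidfinger.errors import ValidationError


def bh_brute_force(p):
    """Literal step-up definition: p_adj(i) = min_{j>=i} (m/j) p_(j), capped."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            min(1.0, m / (j + 1) * p[order[j]]) for j in range(rank_pos, m)
        ]
        out[idx] = min(candidates)
    return out


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        # x=(1,2,3), y=(1.5,2.5,3.5): means 2, 2.5; variances 1, 1
        # t = -0.5/sqrt(2/3), df = (2/3)^2 / (2*(1/9)) = 4
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.5, 2.5, 3.5])
        assert t == pytest.approx(-0.6123724356957945, abs=1e-12)
        assert df == pytest.approx(4.0, abs=1e-12)
        assert p == pytest.approx(0.5733922538253555, abs=1e-12)

    def test_matches_scipy_on_random_data(self, rng):
        x, y = rng.normal(0, 1, (40, 6)), rng.normal(0.3, 1.6, (40, 7))
        t, df, p = welch_t(x, y, axis=1)
        ref = stats.ttest_ind(x, y, axis=1, equal_var=False)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-10)
        np.testing.assert_allclose(p, ref.pvalue, atol=1e-10)

    def test_null_pvalues_uniform(self, rng):
        x = rng.normal(0, 1, (10000, 6))
        y = rng.normal(0, 1, (10000, 6))
        _, _, p = welch_t(x, y, axis=1)
        d, _ = stats.kstest(p, "uniform")
        assert d < 0.02

    def test_zero_variance_unequal_means_p_zero(self, caplog):
        with caplog.at_level("WARNING", logger="lipidfinger"):
            t, df, p = welch_t([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0

    def test_too_small_group_rejected(self):
        with pytest.raises(ValidationError):
            welch_t([1.0], [1.0, 2.0])


class TestBhAdjust:
    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03] * 5), [0.03] * 5)

    def test_arithmetic_sequence_example(self):
        # brute-force step-up gives 0.04 for every entry
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_exhaustive_against_brute_force(self, rng):
        for n in range(1, 9):
            for _ in range(20):
                p = rng.uniform(0, 1, n)
                np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(0, 1, 200)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(0, 1, 50)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_properties_hold_for_arbitrary_pvectors(self, p):
        adj = bh_adjust(p)
        assert np.all((adj >= np.asarray(p) - 1e-15) & (adj <= 1.0))
        # order-preserving: smaller raw p never gets a larger adjusted p
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)
        np.testing.assert_allclose(adj, bh_brute_force(p), atol=1e-12)


class TestLog2FoldChange:
    def test_double_is_one(self):
        assert log2_fold_change([2.0, 2.0], [1.0, 1.0], eps=0.0) == pytest.approx(1.0)

    def test_default_floor_is_half_smallest_positive(self):
        # eps = 0.5 * 0.2; log2((1 + 0.1)/(0.2 + 0.1))
        lfc = log2_fold_change([1.0, 1.0], [0.2, 0.2])
        assert lfc == pytest.approx(np.log2(1.1 / 0.3))

    def test_equal_means_zero(self):
        assert log2_fold_change([1.0, 3.0], [2.0, 2.0]) == pytest.approx(0.0)

    def test_zero_mean_uses_floor(self):
        lfc = log2_fold_change([0.0, 0.0], [1.0, 1.0], eps=0.01)
        assert lfc == pytest.approx(np.log2(0.01 / 1.01))

    def test_both_zero_warns_and_returns_zero(self, caplog):
        with caplog.at_level("WARNING", logger="lipidfinger"):
            assert log2_fold_change([0.0, 0.0], [0.0, 0.0]) == 0.0


class TestClassifyVolcano:
    @pytest.mark.parametrize(
        "lfc,p_adj,expected",
        [
            (0.9, 0.003, True),   # strong marker regime
            (0.2, 0.001, False),  # below fold-change floor
            (0.5, 0.02, False),   # above adjusted-p threshold
        ],
    )
    def test_threshold_logic(self, lfc, p_adj, expected):
        table = pd.DataFrame({"log2fc": [lfc], "p_adj": [p_adj]})
        assert classify_volcano(table).significant[0] == expected


class TestVennOverlap:
    def test_identical_sets(self):
        res = venn_overlap({"a": {1, 2}, "b": {1, 2}})
        assert res.intersection_size == res.union_size == 2
        assert res.shared_fraction_percent == 100.0

    def test_disjoint_sets(self):
        res = venn_overlap({"a": {1}, "b": {2}})
        assert res.intersection_size == 0

    def test_three_conditions_against_brute_force(self, rng):
        universe = np.arange(120)
        sets = {
            "low": set(rng.choice(universe, 38, replace=False).tolist()),
            "mid": set(rng.choice(universe, 45, replace=False).tolist()),
            "high": set(rng.choice(universe, 39, replace=False).tolist()),
        }
        res = venn_overlap(sets)
        names = list(sets)
        for r in range(1, 4):
            for combo in combinations(names, r):
                # brute force: elements in exactly these conditions
                count = sum(
                    1
                    for x in set().union(*sets.values())
                    if all(x in sets[c] for c in combo)
                    and not any(x in sets[c] for c in names if c not in combo)
                )
                assert res.regions[combo] == count
        assert res.union_size == len(set().union(*sets.values()))

    def test_single_condition_rejected(self):
        with pytest.raises(ValidationError):
            venn_overlap({"a": {1}})


class TestAnovaTukey:
    def test_identical_groups_nothing_significant(self):
        groups = {g: [1.0, 2.0, 3.0, 4.0] for g in ("a", "b", "c")}
        f, p, pairs = anova_tukey(groups)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert not pairs.significant.any()

    def test_one_shifted_group_detected(self, rng):
        noise = rng.normal(0, 1e-3, (3, 4))
        groups = {
            "a": noise[0], "b": noise[1], "c": 5.0 + noise[2],
        }
        _, _, pairs = anova_tukey(groups)
        by_pair = {(r.group_a, r.group_b): r.significant for r in pairs.itertuples()}
        assert by_pair[("a", "c")] and by_pair[("b", "c")]
        assert not by_pair[("a", "b")]

    def test_matches_reference_implementations(self, rng):
        groups = {k: rng.normal(i * 0.5, 1.0, 8) for i, k in enumerate("abc")}
        f, p, pairs = anova_tukey(groups)
        ref_f, ref_p = stats.f_oneway(*groups.values())
        assert f == pytest.approx(ref_f, abs=1e-8)
        assert p == pytest.approx(ref_p, abs=1e-8)
        # Tukey adjusted p against statsmodels
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        sm = pairwise_tukeyhsd(values, labels)
        np.testing.assert_allclose(pairs.p_adj, sm.pvalues, atol=1e-6)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValidationError):
            anova_tukey({"a": [1.0, 2.0], "b": [1.0, 2.0]})
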