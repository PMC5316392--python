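"""Statistical layer: summaries, rank tests, chi-square, Cohen's kappa."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from glutmorph import (
    ConfigurationError,
    NormalizationError,
    chi_square_bonferroni,
    cohen_kappa,
    kruskal_wallis_dunn,
    summarize,
)
from glutmorph.stats import bin_by_quantiles, kappa_band


class TestSummarize:
    def test_control_vs_itself_is_100_percent(self, rng):
        vals = rng.normal(10, 2, 25)
        s = summarize(vals, vals, group="control")
        assert s.percent_of_control_median == 100.0

    def test_hand_enumerated_order_statistics(self):
        s = summarize([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert s.median == 3.0
        assert s.iqr == (2.0, 4.0)

    def test_ratio_of_medians(self):
        s = summarize([3, 3, 3], [2, 2, 2])
        assert s.percent_of_control_median == pytest.approx(150.0)

    def test_quartiles_bracket_median(self, rng):
        vals = rng.normal(0, 1, 40)
        s = summarize(vals, vals)
        assert s.iqr[0] <= s.median <= s.iqr[1]

    def test_zero_control_median_rejected(self):
        with pytest.raises(NormalizationError):
            summarize([1.0, 2.0], [0.0, 0.0])


def exact_kw_oracle(groups):
    """Enumerate every distinct assignment of the pooled values to the group
    sizes and count those with H >= observed."""
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], float) for g in names])
    sizes = [len(groups[g]) for g in names]
    ranks = sps.rankdata(pooled)
    n = pooled.size

    def h_of(parts):
        h = 0.0
        for part in parts:
            r = ranks[list(part)]
            h += r.sum() ** 2 / len(part)
        return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)

    observed = h_of(
        [list(range(sum(sizes[:i]), sum(sizes[: i + 1]))) for i in range(len(sizes))]
    )
    count = total = 0
    idx = list(range(n))

    def rec(remaining, sizes_left, acc):
        nonlocal count, total
        if not sizes_left:
            total += 1
            if h_of(acc) >= observed - 1e-12:
                count += 1
            return
        for chosen in itertools.combinations(remaining, sizes_left[0]):
            rest = [i for i in remaining if i not in set(chosen)]
            rec(rest, sizes_left[1:], acc + [list(chosen)])

    rec(idx, sizes, [])
    return observed, count / total


class TestKruskalWallisDunn:
    def test_identical_groups_give_h_zero_p_one(self):
        groups = {g: [5.0, 5.0, 5.0] for g in "abcd"}
        t = kruskal_wallis_dunn(groups)
        assert t.statistic == 0.0
        assert t.p_value == 1.0
        assert all(p.p_adjusted == 1.0 for p in t.post_hoc)

    def test_exact_permutation_matches_enumeration_oracle(self):
        groups = {"lo": [1.0, 2.0], "hi": [3.0, 4.0]}
        t = kruskal_wallis_dunn(groups)
        h_oracle, p_oracle = exact_kw_oracle(groups)
        assert t.statistic == pytest.approx(h_oracle)
        assert t.p_value == pytest.approx(p_oracle)
        assert "exact" in t.method

    def test_exact_three_group_case(self):
        groups = {"a": [3.0, 9.0], "b": [1.0, 6.0], "c": [4.0, 8.0, 2.0]}
        t = kruskal_wallis_dunn(groups)
        _, p_oracle = exact_kw_oracle(groups)
        assert t.p_value == pytest.approx(p_oracle)

    def test_asymptotic_matches_scipy(self, rng):
        groups = {g: rng.normal(mu, 1, 12) for g, mu in [("a", 0), ("b", 0.5), ("c", 1.0)]}
        t = kruskal_wallis_dunn(groups)
        h, p = sps.kruskal(*groups.values())
        assert t.statistic == pytest.approx(h)
        assert t.p_value == pytest.approx(p)

    def test_invariant_under_monotone_transforms(self, rng):
        groups = {g: rng.gamma(2, 1, 15) for g in "abc"}
        base = kruskal_wallis_dunn(groups)
        for f in (np.exp, lambda x: 3 * np.asarray(x) + 7, lambda x: np.asarray(x) ** 3):
            t = kruskal_wallis_dunn({g: f(v) for g, v in groups.items()})
            assert t.statistic == pytest.approx(base.statistic)

    def test_dunn_adjustment_bounds(self, rng):
        groups = {g: rng.normal(mu, 1, 10) for g, mu in [("a", 0), ("b", 1), ("c", 2), ("d", 0)]}
        t = kruskal_wallis_dunn(groups)
        assert len(t.post_hoc) == 6
        for p in t.post_hoc:
            assert p.p_raw <= p.p_adjusted <= 1.0
            assert p.p_adjusted == pytest.approx(min(1.0, p.p_raw * 6))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            kruskal_wallis_dunn({"a": [1, 2]})
        with pytest.raises(ConfigurationError):
            kruskal_wallis_dunn({"a": [1, 2], "b": [1]})


class TestChiSquare:
    def test_balanced_table_gives_zero(self):
        t = chi_square_bonferroni(np.array([[10, 10], [10, 10]]))
        assert t.statistic == 0.0
        assert t.p_value == 1.0

    def test_matches_hand_computed_expected_counts(self):
        """Macrosomia counts: 3/6 affected vs 5/25 affected."""
        observed = np.array([[3.0, 3.0], [5.0, 20.0]])
        row, col, n = observed.sum(1), observed.sum(0), observed.sum()
        expected = np.outer(row, col) / n
        stat_oracle = ((observed - expected) ** 2 / expected).sum()
        t = chi_square_bonferroni(observed.astype(int))
        assert t.statistic == pytest.approx(stat_oracle)

    def test_bonferroni_multiplies_by_comparison_count(self):
        table = {
            "a": [8, 2],
            "b": [2, 8],
            "c": [5, 5],
            "d": [7, 3],
        }
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        t = chi_square_bonferroni(table, comparisons=pairs)
        assert len(t.post_hoc) == 3
        for p in t.post_hoc:
            assert p.p_adjusted == pytest.approx(min(1.0, p.p_raw * 3))

    def test_all_zero_row_comparison_excluded(self):
        table = {"a": [0, 0], "b": [5, 5], "c": [4, 6]}
        with pytest.warns(UserWarning, match="excluded"):
            t = chi_square_bonferroni(table, comparisons=[("a", "b"), ("b", "c")])
        assert len(t.post_hoc) == 1
        assert t.post_hoc[0].pair == ("b", "c")

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            chi_square_bonferroni(np.array([[1.5, 2.0], [3.0, 4.0]]))


class TestCohenKappa:
    def test_perfect_agreement(self):
        k = cohen_kappa(["A", "B"] * 10, ["A", "B"] * 10)
        assert k.kappa == pytest.approx(1.0)
        assert k.band == "almost_perfect"

    def test_perfect_disagreement_hand_computed(self):
        """p_o = 0 and p_e = 0.5 give kappa = -1."""
        k = cohen_kappa(list("AABB"), list("BBAA"))
        assert k.kappa == pytest.approx(-1.0)

    def test_band_thresholds(self):
        assert kappa_band(0.7) == "substantial"
        assert kappa_band(0.85) == "almost_perfect"
        assert kappa_band(0.5) == "moderate"
        assert kappa_band(0.3) == "fair"
        assert kappa_band(0.1) == "poor"

    def test_symmetry_and_relabeling_invariance(self, rng):
        a = rng.integers(0, 3, 60)
        b = np.where(rng.random(60) < 0.7, a, rng.integers(0, 3, 60))
        k_ab = cohen_kappa(a, b)
        k_ba = cohen_kappa(b, a)
        assert k_ab.kappa == pytest.approx(k_ba.kappa)
        relabel = np.array([2, 0, 1])
        k_rel = cohen_kappa(relabel[a], relabel[b])
        assert k_rel.kappa == pytest.approx(k_ab.kappa)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(0, 3, 80)
        b = np.where(rng.random(80) < 0.6, a, rng.integers(0, 3, 80))
        assert cohen_kappa(a, b).kappa == pytest.approx(cohen_kappa_score(a, b))

    def test_both_raters_constant_flags(self):
        k = cohen_kappa(["A"] * 5, ["A"] * 5)
        assert k.flagged
        assert k.kappa == 1.0

    def test_tertile_binning_shares_edges(self, rng):
        a = rng.normal(0, 1, 90)
        b = a + rng.normal(0, 0.1, 90)
        ba, bb = bin_by_quantiles(a, b, n_bins=3)
        assert set(np.unique(ba)) <= {0, 1, 2}
        assert (ba == bb).mean() > 0.8
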