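"""Variance-routed group comparisons, Dunn post hoc, trends, slope CIs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from endoquant import (
    compact_letter_display,
    compare_groups,
    dunn_test,
    slope_ci,
    spearman_trend,
    variability_test,
)


def table(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "value": np.concatenate(list(groups.values())),
            "timepoint": np.repeat(list(groups.keys()), [len(v) for v in groups.values()]),
        }
    )


def brute_mean_ranks(arrays):
    """Independent rank computation: sort-based with manual tie averaging."""
    pooled = sorted((v, gi, i) for gi, a in enumerate(arrays) for i, v in enumerate(a))
    n = len(pooled)
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[j + 1][0] == pooled[i][0]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[k] = avg
        i = j + 1
    sums = [0.0] * len(arrays)
    for rk, (_, gi, _) in zip(ranks, pooled):
        sums[gi] += rk
    return [s / len(a) for s, a in zip(sums, arrays)]


class TestCompareGroups:
    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 2, 15)
        t = table({"a": base, "b": base + rng.normal(0, 1e-9, 15)})
        c = compare_groups(t)
        assert len(set(c.letters.values())) == 1

    def test_ten_sd_separation_gets_distinct_letters(self):
        rng = np.random.default_rng(1)
        t = table({"a": rng.normal(0, 1, 15), "b": rng.normal(10, 1, 15)})
        c = compare_groups(t)
        assert c.letters["a"] != c.letters["b"]
        assert c.p_value < 0.001

    def test_routing_flips_with_inflated_variance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 25)
        equal = table({"a": a, "b": rng.normal(0, 1, 25)})
        assert compare_groups(equal).test == "anova_tukey"
        inflated = table({"a": a, "b": rng.normal(0, 10, 25)})
        c = compare_groups(inflated)
        assert c.test == "kruskal_dunn_bh"
        # routing agrees with a direct Levene computation
        assert sps.levene(a, inflated[inflated.timepoint == "b"].value, center="mean").pvalue < 0.05

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(table({"a": np.array([1.0]), "b": np.array([1.0, 2.0])}))
        with pytest.raises(ValueError):
            compare_groups(table({"only": np.arange(5.0)}))

    def test_letters_consistent_with_pairwise_matrix(self):
        rng = np.random.default_rng(3)
        t = table(
            {
                "a": rng.normal(0, 1, 12),
                "b": rng.normal(0.5, 1, 12),
                "c": rng.normal(8, 1, 12),
                "d": rng.normal(8.2, 1, 12),
            }
        )
        c = compare_groups(t)
        for g1, g2 in itertools.combinations(c.groups, 2):
            share = set(c.letters[g1]) & set(c.letters[g2])
            p = c.pairwise_p.loc[g1, g2]
            if share:
                assert p >= c.alpha  # sharing a letter implies non-significance
            else:
                assert p < c.alpha


class TestDunn:
    def test_mean_ranks_match_brute_force(self):
        rng = np.random.default_rng(4)
        arrays = [rng.normal(i, 1, 10 + i) for i in range(3)]
        oracle = brute_mean_ranks(arrays)
        pooled = np.concatenate(arrays)
        ranks = sps.rankdata(pooled)
        got, start = [], 0
        for a in arrays:
            got.append(ranks[start : start + len(a)].mean())
            start += len(a)
        assert got == pytest.approx(oracle)

    def test_dunn_z_against_direct_formula(self):
        rng = np.random.default_rng(5)
        arrays = [rng.normal(0, 1, 8), rng.normal(2, 1, 12)]
        pw = dunn_test(arrays, ["a", "b"], p_adjust=None)
        mr = brute_mean_ranks(arrays)
        n = 20
        # no ties in continuous data: variance term is N(N+1)/12
        se = np.sqrt(n * (n + 1) / 12 * (1 / 8 + 1 / 12))
        z = (mr[0] - mr[1]) / se
        expected = 2 * sps.norm.sf(abs(z))
        assert pw.loc["a", "b"] == pytest.approx(expected)

    def test_bh_never_decreases_p(self):
        rng = np.random.default_rng(6)
        arrays = [rng.normal(m, 1, 10) for m in (0, 0.5, 1, 3)]
        raw = dunn_test(arrays, list("abcd"), p_adjust=None)
        adj = dunn_test(arrays, list("abcd"), p_adjust="bh")
        for i, j in itertools.combinations(range(4), 2):
            assert adj.iloc[i, j] >= raw.iloc[i, j] - 1e-15


class TestCompactLetterDisplay:
    def test_three_group_chain(self):
        # a != c significant; a-b and b-c not: letters a="a", b="ab", c="b"
        pw = pd.DataFrame(
            [[np.nan, 0.2, 0.01], [0.2, np.nan, 0.3], [0.01, 0.3, np.nan]],
            index=list("abc"),
            columns=list("abc"),
        )
        letters = compact_letter_display(pw)
        assert letters["a"] != letters["c"]
        assert set(letters["b"]) & set(letters["a"]) and set(letters["b"]) & set(letters["c"])

    def test_all_significant_all_distinct(self):
        pw = pd.DataFrame(0.001, index=list("abc"), columns=list("abc"))
        np.fill_diagonal(pw.values, np.nan)
        letters = compact_letter_display(pw)
        assert len({letters[g] for g in "abc"}) == 3


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman_trend([1, 2, 3, 4], [1, 2, 3, 4])[0] == pytest.approx(1.0)
        assert spearman_trend([4, 3, 2, 1], [1, 2, 3, 4])[0] == pytest.approx(-1.0)

    def test_matches_rank_based_oracle(self):
        rng = np.random.default_rng(7)
        t = np.repeat(np.arange(5), 8).astype(float)
        y = 0.5 * t + rng.normal(0, 1, 40)
        rho, _ = spearman_trend(y, t)
        # independent: Pearson correlation of the rank vectors
        oracle = np.corrcoef(sps.rankdata(t), sps.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            spearman_trend([1, 2], [1, 2])


class TestVariability:
    def test_equal_spread_is_null(self):
        rng = np.random.default_rng(8)
        t = table({"a": rng.normal(5, 2, 20), "b": rng.normal(50, 2, 20)})
        c = variability_test(t)
        # same spread despite different means: no split expected
        assert c.p_value > 0.05
        assert len(set(c.letters.values())) == 1

    def test_scaled_spread_detected(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 25)
        b = rng.normal(0, 5, 25)
        c = variability_test(table({"a": a, "b": b}))
        assert c.p_value < 0.05
        assert c.letters["a"] != c.letters["b"]

    def test_transform_is_mean_absolute_deviation(self):
        x = np.array([1.0, 3.0, 5.0, 7.0])
        devs = np.abs(x - x.mean())
        assert devs.mean() == pytest.approx(np.abs(x - x.mean()).mean())


class TestSlopeCI:
    def test_exact_line(self):
        slope, lo, hi, r2 = slope_ci([2, 4, 6, 8], [1, 2, 3, 4])
        assert slope == pytest.approx(2.0)
        assert hi - lo == pytest.approx(0.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_constant_response(self):
        slope, lo, hi, r2 = slope_ci([5, 5, 5, 5], [1, 2, 3, 4])
        assert slope == 0.0

    def test_halfwidth_is_1_96_times_stderr(self):
        rng = np.random.default_rng(10)
        x = np.linspace(0, 1, 50)
        y = 3 * x + rng.normal(0, 0.5, 50)
        slope, lo, hi, _ = slope_ci(y, x)
        se = sps.linregress(x, y).stderr
        assert hi - slope == pytest.approx(1.96 * se)

    def test_coverage_near_nominal(self):
        rng = np.random.default_rng(11)
        cover = 0
        n_rep = 400
        for _ in range(n_rep):
            x = np.linspace(0, 1, 200)
            y = 3 * x + rng.normal(0, 1, 200)
            _, lo, hi, _ = slope_ci(y, x)
            cover += lo <= 3 <= hi
        assert 0.92 <= cover / n_rep <= 0.98
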