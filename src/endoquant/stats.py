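"""Group-comparison statistics for morphometric tables.

The battery applied to each metric across timepoints:

* :func:`compare_groups` — Levene's test (classic, mean-centered) routes the
  comparison: equal variances (p >= 0.05) go to one-way ANOVA with Tukey HSD
  post-hoc grouping; unequal variances go to Kruskal-Wallis with Dunn's
  post-hoc test under Benjamini-Hochberg correction. Compact letter displays
  are derived from the adjusted pairwise matrix by insert-and-absorb.
* :func:`spearman_trend` — rank correlation of a metric against ordered time.
* :func:`variability_test` — compares spread across groups by replacing each
  value with its absolute deviation from the group mean, then running
  Kruskal-Wallis + Dunn/BH on the deviations.
* :func:`slope_ci` — OLS slope over time with a 95% CI of
  slope +/- 1.96 x SE(slope), plus r^2. (The CI multiplier applies to the
  standard error of the slope estimate; see docs/methods.md.)

Dunn's test is implemented here directly (rank sums with tie correction,
two-sided normal p-values) since no post-hoc library is declared as a
dependency; it is cross-checked against a brute-force rank computation in
the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05
LEVENE_ALPHA = 0.05


@dataclass
class GroupComparison:
    """Result of a routed multi-group comparison."""

    test: str  # "anova_tukey" or "kruskal_dunn_bh"
    levene_p: float
    statistic: float
    p_value: float
    groups: list[str]
    pairwise_p: pd.DataFrame  # adjusted p-values, symmetric, diag NaN
    letters: dict[str, str]
    alpha: float = ALPHA


def _as_groups(table: pd.DataFrame, value: str, group: str) -> tuple[list[str], list[np.ndarray]]:
    names = list(pd.unique(table[group]))
    arrays = [table.loc[table[group] == g, value].to_numpy(dtype=float) for g in names]
    return [str(g) for g in names], arrays


def compare_groups(
    table: pd.DataFrame,
    value: str = "value",
    group: str = "timepoint",
    alpha: float = ALPHA,
    levene_alpha: float = LEVENE_ALPHA,
) -> GroupComparison:
    """Variance-routed multi-group comparison with a compact letter display.

    Levene's test (mean-centered) decides the route: p >= ``levene_alpha``
    means variances are compatible and the parametric ANOVA + Tukey HSD path
    is taken; otherwise Kruskal-Wallis + Dunn with Benjamini-Hochberg
    adjustment. Groups sharing a letter are not significantly different at
    ``alpha`` in the adjusted pairwise matrix.
    """
    names, arrays = _as_groups(table, value, group)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g, a in zip(names, arrays):
        if len(a) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    levene_p = float(sps.levene(*arrays, center="mean").pvalue)
    if levene_p >= levene_alpha:
        stat, p = sps.f_oneway(*arrays)
        pw = _tukey_matrix(table, value, group, names, alpha)
        test = "anova_tukey"
    else:
        stat, p = sps.kruskal(*arrays)
        pw = dunn_test(arrays, names, p_adjust="bh")
        test = "kruskal_dunn_bh"
    letters = compact_letter_display(pw, alpha)
    return GroupComparison(
        test=test,
        levene_p=levene_p,
        statistic=float(stat),
        p_value=float(p),
        groups=names,
        pairwise_p=pw,
        letters=letters,
        alpha=alpha,
    )


def _tukey_matrix(
    table: pd.DataFrame, value: str, group: str, names: list[str], alpha: float
) -> pd.DataFrame:
    res = pairwise_tukeyhsd(
        table[value].to_numpy(dtype=float), table[group].astype(str).to_numpy(), alpha=alpha
    )
    pw = pd.DataFrame(np.nan, index=names, columns=names)
    # statsmodels orders pairs over its sorted group list
    sm_groups = list(res.groupsunique)
    k = 0
    for i in range(len(sm_groups)):
        for j in range(i + 1, len(sm_groups)):
            p = float(res.pvalues[k])
            pw.loc[sm_groups[i], sm_groups[j]] = p
            pw.loc[sm_groups[j], sm_groups[i]] = p
            k += 1
    return pw


def dunn_test(
    arrays: list[np.ndarray], names: list[str], p_adjust: str | None = "bh"
) -> pd.DataFrame:
    """Dunn's post-hoc test on ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with
    tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values,
    optionally Benjamini-Hochberg adjusted across all pairs.
    """
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + len(a)].mean())
        sizes.append(len(a))
        start += len(a)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(range(len(arrays)), 2))
    raw = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        raw.append(2.0 * sps.norm.sf(abs(z)))
    if p_adjust == "bh":
        adj = multipletests(raw, method="fdr_bh")[1]
    elif p_adjust is None:
        adj = np.asarray(raw)
    else:
        raise ValueError(f"unknown adjustment {p_adjust!r}")
    pw = pd.DataFrame(np.nan, index=names, columns=names)
    for (i, j), p in zip(pairs, adj):
        pw.iloc[i, j] = p
        pw.iloc[j, i] = p
    return pw


def compact_letter_display(pairwise_p: pd.DataFrame, alpha: float = ALPHA) -> dict[str, str]:
    """Insert-and-absorb compact letter display from an adjusted p matrix.

    Groups sharing a letter have adjusted p >= alpha; every significant pair
    is separated. Letters are assigned a, b, c, ... in group order.
    """
    groups = list(pairwise_p.index)
    letter_sets: list[set[str]] = [set(groups)]
    for i, gi in enumerate(groups):
        for gj in groups[i + 1 :]:
            p = pairwise_p.loc[gi, gj]
            if pd.isna(p) or p >= alpha:
                continue
            new_sets: list[set[str]] = []
            for s in letter_sets:
                if gi in s and gj in s:
                    new_sets.append(s - {gi})
                    new_sets.append(s - {gj})
                else:
                    new_sets.append(s)
            # absorb: drop sets contained in another
            letter_sets = [
                s
                for k, s in enumerate(new_sets)
                if s and not any(s < t or (s == t and k > m) for m, t in enumerate(new_sets))
            ]
    # order letters by the first group they contain
    letter_sets.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def spearman_trend(values, ordered_time) -> tuple[float, float]:
    """Spearman rank correlation of a metric against ordered time labels."""
    values = np.asarray(values, dtype=float)
    time = np.asarray(ordered_time, dtype=float)
    if len(values) < 3 or len(values) != len(time):
        raise ValueError("need >= 3 paired observations")
    rho, p = sps.spearmanr(time, values)
    return float(rho), float(p)


def variability_test(
    table: pd.DataFrame, value: str = "value", group: str = "timepoint", alpha: float = ALPHA
) -> GroupComparison:
    """Compare within-group spread across groups.

    Each value is replaced by its absolute deviation from its group mean
    (whose group average is the mean absolute deviation); the deviations are
    compared with Kruskal-Wallis + Dunn/BH.
    """
    names, arrays = _as_groups(table, value, group)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    devs = [np.abs(a - a.mean()) for a in arrays]
    stat, p = sps.kruskal(*devs)
    pw = dunn_test(devs, names, p_adjust="bh")
    letters = compact_letter_display(pw, alpha)
    levene_p = float(sps.levene(*arrays, center="mean").pvalue)
    return GroupComparison(
        test="kruskal_dunn_bh",
        levene_p=levene_p,
        statistic=float(stat),
        p_value=float(p),
        groups=names,
        pairwise_p=pw,
        letters=letters,
        alpha=alpha,
    )


def slope_ci(values, time) -> tuple[float, float, float, float]:
    """OLS slope of metric vs time with a 95% CI and r^2.

    CI = slope +/- 1.96 x SE(slope), where SE is the standard error of the
    slope estimate. Returns (slope, ci_low, ci_high, r2).
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    if len(values) < 3 or len(values) != len(time):
        raise ValueError("need >= 3 paired observations")
    res = sps.linregress(time, values)
    half = 1.96 * res.stderr
    return float(res.slope), float(res.slope - half), float(res.slope + half), float(res.rvalue**2)
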