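"""Potency-distribution statistics.

Global comparisons (non-covalent inhibitors vs each covalent warhead
subset) use one-way ANOVA with a Tukey-Kramer post-hoc test (the
studentized-range procedure generalized to unequal group sizes); local
comparisons of analogue-pair potency deltas use the paired t-test
(one-sample t on the deltas against zero).  Tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


def summarize_distribution(pPotencies) -> tuple[float, float, float, int]:
    """Median and quartiles (linear-interpolation convention) plus n."""
    arr = np.asarray(list(pPotencies), dtype=float)
    if arr.size == 0:
        raise ValueError("empty distribution")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3), int(arr.size)


def _check_groups(groups):
    if len(groups) < 2:
        raise ValueError("degenerate_group")
    arrs = [np.asarray(list(g), dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("degenerate_group")
    return arrs


def one_way_anova(groups) -> tuple[float, float]:
    """Between/within mean-square F ratio with (k-1, N-k) df p-value."""
    arrs = _check_groups(groups)
    if all(np.ptp(a) == 0 for a in arrs) and len({a[0] for a in arrs}) == 1:
        # all observations identical: no variance anywhere
        return 0.0, 1.0
    f, p = sps.f_oneway(*arrs)
    return float(f), float(p)


@dataclass(frozen=True)
class TukeyRow:
    group_i: str
    group_j: str
    mean_diff: float
    q_statistic: float
    adjusted_p: float
    significant: bool


def tukey_hsd(groups, alpha: float = 0.05, names=None) -> list[TukeyRow]:
    """Tukey-Kramer pairwise comparisons after one-way ANOVA.

    One row per unordered group pair; ``significant`` iff the
    studentized-range adjusted p-value is below ``alpha``.
    """
    arrs = _check_groups(groups)
    if names is None:
        names = [f"group{i}" for i in range(len(arrs))]
    res = sps.tukey_hsd(*arrs)
    n_total = sum(a.size for a in arrs)
    k = len(arrs)
    msw = sum(((a.size - 1) * np.var(a, ddof=1)) for a in arrs) / (n_total - k)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(np.mean(arrs[i]) - np.mean(arrs[j]))
            se = np.sqrt(msw / 2.0 * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
            q = abs(diff) / se if se > 0 else 0.0
            p = float(res.pvalue[i, j])
            rows.append(
                TukeyRow(
                    group_i=names[i],
                    group_j=names[j],
                    mean_diff=diff,
                    q_statistic=float(q),
                    adjusted_p=p,
                    significant=bool(p < alpha),
                )
            )
    return rows


@dataclass(frozen=True)
class GroupComparison:
    """ANOVA + Tukey summary of several potency distributions."""

    group_names: list
    group_sizes: list
    medians: list
    F_statistic: float
    p_value: float
    tukey: list


def compare_groups(groups, names=None, alpha: float = 0.05) -> GroupComparison:
    """Full battery: distribution summaries, one-way ANOVA, Tukey post hoc."""
    arrs = _check_groups(groups)
    if names is None:
        names = [f"group{i}" for i in range(len(arrs))]
    f, p = one_way_anova(arrs)
    return GroupComparison(
        group_names=list(names),
        group_sizes=[int(a.size) for a in arrs],
        medians=[summarize_distribution(a)[0] for a in arrs],
        F_statistic=f,
        p_value=p,
        tukey=tukey_hsd(arrs, alpha=alpha, names=names),
    )


@dataclass(frozen=True)
class PairTest:
    """Paired t-test of analogue-pair potency deltas for one warhead."""

    warhead: str
    n_pairs: int
    mean_delta: float
    t_statistic: float
    p_value: float


def paired_t_test(deltas, warhead: str = "") -> PairTest:
    """One-sample t on the deltas against zero, two-sided p."""
    arr = np.asarray(list(deltas), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 deltas")
    if np.ptp(arr) == 0:
        raise ValueError("zero_variance")
    t, p = sps.ttest_1samp(arr, 0.0)
    return PairTest(
        warhead=warhead,
        n_pairs=int(arr.size),
        mean_delta=float(np.mean(arr)),
        t_statistic=float(t),
        p_value=float(p),
    )
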