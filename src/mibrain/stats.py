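"""Per-threshold group comparisons: one-way ANOVA with homogeneity-gated
post-hoc pairwise tests.

At each proportional threshold a network metric (interhemispheric edge count,
mean clustering coefficient, ...) is compared across the four groups by a
classical fixed-effects one-way ANOVA. Pairwise post-hocs follow the SPSS
convention: if Levene's test (centre = mean, alpha = 0.05) does not reject
homogeneity of variances, unadjusted LSD t-tests on the pooled ANOVA error
term are used; otherwise Tamhane's T2 — Welch t statistics with Satterthwaite
degrees of freedom and a Sidak-type multiplicity adjustment over the pairwise
family. No correction is applied across thresholds by default (each threshold
row stands alone); a Bonferroni-across-thresholds option exists but is off.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

GROUP_ORDER = ("HC", "PSND", "PSMD", "PSD")


@dataclass
class GroupSample:
    """Per-subject values of one metric for one group."""

    group_label: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be a 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.group_label}: non-finite metric values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if self.n > 1 else float("nan")


def _check_samples(samples: Sequence[GroupSample]):
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for s in samples:
        if s.n < 2:
            raise ValueError(f"group {s.group_label!r} has fewer than 2 values")


def one_way_anova(samples: Sequence[GroupSample]) -> Dict[str, float]:
    """Classical fixed-effects one-way ANOVA from sums of squares.

    Returns F, the (between, within) degrees of freedom, and the p-value from
    the F distribution. Identical groups give F = 0, p = 1.
    """
    _check_samples(samples)
    all_values = np.concatenate([s.values for s in samples])
    grand_mean = all_values.mean()
    n_total = all_values.size
    k = len(samples)
    ss_between = sum(s.n * (s.mean - grand_mean) ** 2 for s in samples)
    ss_within = sum(float(((s.values - s.mean) ** 2).sum()) for s in samples)
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        # all groups internally constant: F is 0/0 -> define as 0 if means
        # agree, +inf otherwise
        f_stat = 0.0 if ss_between == 0 else float("inf")
    else:
        f_stat = ms_between / ms_within
    p = float(scipy.stats.f.sf(f_stat, df_between, df_within)) if np.isfinite(f_stat) else 0.0
    return {
        "F": float(f_stat),
        "df_between": df_between,
        "df_within": df_within,
        "p": p,
        "ss_between": float(ss_between),
        "ss_within": float(ss_within),
        "ms_within": float(ms_within),
    }


def levene_homogeneity(samples: Sequence[GroupSample]) -> float:
    """Levene's test for homogeneity of variances (centre = mean); returns p.

    Degenerate case: if the test statistic is undefined (e.g. all
    within-group deviations are zero, as happens with integer-valued metrics
    at sparse thresholds), there is no evidence of heterogeneity and p = 1.
    """
    _check_samples(samples)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        p = float(scipy.stats.levene(*(s.values for s in samples), center="mean").pvalue)
    return 1.0 if np.isnan(p) else p


def _find_pair(samples, pair):
    by_label = {s.group_label: s for s in samples}
    try:
        return by_label[pair[0]], by_label[pair[1]]
    except KeyError as exc:
        raise KeyError(
            f"unknown group {exc.args[0]!r}; groups present: {sorted(by_label)}"
        ) from None


def posthoc_lsd(samples: Sequence[GroupSample], pair: Tuple[str, str]) -> float:
    """Fisher's LSD pairwise p-value.

    A two-sided t-test on the pair's mean difference using the overall ANOVA's
    pooled within-group mean square and its df = N - k; no multiplicity
    adjustment. With exactly two groups this reduces to the pooled t-test.
    """
    _check_samples(samples)
    a, b = _find_pair(samples, pair)
    anova = one_way_anova(samples)
    mse, df = anova["ms_within"], anova["df_within"]
    se = np.sqrt(mse * (1.0 / a.n + 1.0 / b.n))
    if se == 0.0:
        return 1.0 if a.mean == b.mean else 0.0
    t = (a.mean - b.mean) / se
    return float(2.0 * scipy.stats.t.sf(abs(t), df))


def welch_t_p(a: GroupSample, b: GroupSample) -> float:
    """Two-sided Welch t-test p-value with Satterthwaite (non-integer) df."""
    va, vb = a.values.var(ddof=1) / a.n, b.values.var(ddof=1) / b.n
    se2 = va + vb
    if se2 == 0.0:
        return 1.0 if a.mean == b.mean else 0.0
    t = (a.mean - b.mean) / np.sqrt(se2)
    df = se2 ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    return float(2.0 * scipy.stats.t.sf(abs(t), df))


def posthoc_tamhane_t2(
    samples: Sequence[GroupSample], pair: Tuple[str, str], n_pairs: int = None
) -> float:
    """Tamhane's T2 pairwise p-value.

    A Welch t-test with Satterthwaite df, Sidak-adjusted over the family of
    ``n_pairs`` comparisons (default: all k(k-1)/2 pairs):
    p_adj = 1 - (1 - p_welch)^n_pairs, capped at 1. Robust to unequal group
    variances; always at least the unadjusted Welch p.
    """
    _check_samples(samples)
    a, b = _find_pair(samples, pair)
    if n_pairs is None:
        k = len(samples)
        n_pairs = k * (k - 1) // 2
    p = welch_t_p(a, b)
    return float(min(1.0, 1.0 - (1.0 - p) ** n_pairs))


@dataclass
class GroupComparisonTable:
    """Per-threshold group statistics in tidy tabular form.

    ``table`` has one row per threshold with group means/SDs, the ANOVA F, df
    and p, the Levene homogeneity p, the post-hoc method used (LSD or
    TamhaneT2), all pairwise post-hoc p-values, and boolean significance flags
    at the chosen alpha.
    """

    table: pd.DataFrame
    metric_name: str
    alpha: float
    group_order: tuple

    def significant_pairs(self, threshold: float) -> List[Tuple[str, str]]:
        row = self.table.loc[self.table["threshold"] == threshold]
        if row.empty:
            raise KeyError(f"no row for threshold {threshold}")
        row = row.iloc[0]
        out = []
        for a, b in itertools.combinations(self.group_order, 2):
            if row[f"p_{a}_vs_{b}"] < self.alpha:
                out.append((a, b))
        return out


def compare_groups(
    samples: Sequence[GroupSample], alpha: float = 0.05
) -> Dict:
    """One threshold's worth of statistics: ANOVA + gated post-hocs."""
    anova = one_way_anova(samples)
    levene_p = levene_homogeneity(samples)
    homogeneous = levene_p >= alpha
    method = "LSD" if homogeneous else "TamhaneT2"
    k = len(samples)
    n_pairs = k * (k - 1) // 2
    pair_p = {}
    for a, b in itertools.combinations([s.group_label for s in samples], 2):
        if homogeneous:
            pair_p[(a, b)] = posthoc_lsd(samples, (a, b))
        else:
            pair_p[(a, b)] = posthoc_tamhane_t2(samples, (a, b), n_pairs)
    return {
        "anova": anova,
        "levene_p": levene_p,
        "method": method,
        "pairwise_p": pair_p,
    }


def compare_across_thresholds(
    metric_table: pd.DataFrame,
    metric_name: str,
    alpha: float = 0.05,
    group_order: Sequence[str] = GROUP_ORDER,
    bonferroni_across_thresholds: bool = False,
) -> GroupComparisonTable:
    """Build the per-threshold comparison table for one network metric.

    ``metric_table`` is tidy long-format with columns ``subject``, ``group``,
    ``threshold``, ``metric``, ``value``. Every group in ``group_order`` must
    be present at every threshold. Each threshold is tested independently; by
    default no correction is applied across thresholds (each row's p-values
    are as a single-threshold analysis would report them), with an optional
    Bonferroni correction across the threshold grid.
    """
    sub = metric_table.loc[metric_table["metric"] == metric_name]
    if sub.empty:
        raise ValueError(f"metric {metric_name!r} not present in the table")
    thresholds = sorted(sub["threshold"].unique())
    group_order = tuple(group_order)
    rows = []
    for threshold in thresholds:
        at = sub.loc[sub["threshold"] == threshold]
        samples = []
        for group in group_order:
            values = at.loc[at["group"] == group, "value"].to_numpy()
            if values.size == 0:
                raise ValueError(f"group {group!r} missing at threshold {threshold}")
            samples.append(GroupSample(group, values))
        res = compare_groups(samples, alpha)
        row = {"threshold": threshold}
        for s in samples:
            row[f"mean_{s.group_label}"] = s.mean
            row[f"sd_{s.group_label}"] = s.sd
            row[f"n_{s.group_label}"] = s.n
        row.update(
            F=res["anova"]["F"],
            df_between=res["anova"]["df_between"],
            df_within=res["anova"]["df_within"],
            anova_p=res["anova"]["p"],
            levene_p=res["levene_p"],
            method=res["method"],
        )
        correction = len(thresholds) if bonferroni_across_thresholds else 1
        for (a, b), p in res["pairwise_p"].items():
            p_corr = min(1.0, p * correction)
            row[f"p_{a}_vs_{b}"] = p_corr
            row[f"sig_{a}_vs_{b}"] = p_corr < alpha
        rows.append(row)
    return GroupComparisonTable(
        table=pd.DataFrame(rows),
        metric_name=metric_name,
        alpha=alpha,
        group_order=group_order,
    )
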