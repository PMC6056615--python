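"""Group statistics: ANOVA identities, Levene gating, and post-hoc tests
against independent references."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from mibrain.stats import (
    GroupSample,
    compare_across_thresholds,
    compare_groups,
    levene_homogeneity,
    one_way_anova,
    posthoc_lsd,
    posthoc_tamhane_t2,
    welch_t_p,
)


def groups(*arrays, labels=("HC", "PSND", "PSMD", "PSD")):
    return [GroupSample(l, np.asarray(a, float)) for l, a in zip(labels, arrays)]


class TestOneWayAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        res = one_way_anova(groups([1, 2, 3], [1, 2, 3]))
        assert res["F"] == 0.0
        assert res["p"] == 1.0

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c = rng.standard_normal((3, 12))
            res = one_way_anova(groups(a, b, c))
            ref = scipy.stats.f_oneway(a, b, c)
            assert res["F"] == pytest.approx(ref.statistic, rel=1e-10)
            assert res["p"] == pytest.approx(ref.pvalue, rel=1e-8)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.standard_normal((2, 10))
            res = one_way_anova(groups(a, b))
            t = scipy.stats.ttest_ind(a, b, equal_var=True)
            assert res["F"] == pytest.approx(t.statistic**2, abs=1e-10)
            assert res["p"] == pytest.approx(t.pvalue, abs=1e-10)

    def test_sum_of_squares_decomposition(self):
        rng = np.random.default_rng(2)
        a, b, c, d = rng.standard_normal((4, 15)) + [[0], [1], [2], [3]]
        res = one_way_anova(groups(a, b, c, d))
        total = np.concatenate([a, b, c, d])
        ss_total = ((total - total.mean()) ** 2).sum()
        assert res["ss_between"] + res["ss_within"] == pytest.approx(ss_total, rel=1e-9)
        assert res["df_between"] == 3
        assert res["df_within"] == 56

    def test_type_one_error_calibrated(self):
        # under the global null the 5%-level rejection rate stays near 5%
        rng = np.random.default_rng(12345)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            samples = groups(*rng.standard_normal((4, 15)))
            if one_way_anova(samples)["p"] < 0.05:
                rejections += 1
        assert 0.035 <= rejections / n_rep <= 0.065

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="PSND"):
            one_way_anova(groups([1.0, 2.0], [3.0]))


class TestLevene:
    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal((2, 30))
        b *= 5
        p = levene_homogeneity(groups(a, b))
        ref = scipy.stats.levene(a, b, center="mean").pvalue
        assert p == pytest.approx(ref, rel=1e-12)

    def test_detects_gross_variance_ratio(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(200):
            a = rng.standard_normal(30)
            b = rng.standard_normal(30) * 5
            if levene_homogeneity(groups(a, b)) < 0.05:
                hits += 1
        assert hits / 200 > 0.95

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        ps = [
            levene_homogeneity(groups(*rng.standard_normal((2, 30))))
            for _ in range(500)
        ]
        ks = scipy.stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


def oracle_lsd_p(samples, pair):
    """From-scratch LSD: pooled MSE over ALL groups, t CDF from scipy."""
    k = len(samples)
    N = sum(s.n for s in samples)
    mse = sum(((s.values - s.values.mean()) ** 2).sum() for s in samples) / (N - k)
    by = {s.group_label: s for s in samples}
    a, b = by[pair[0]], by[pair[1]]
    t = (a.values.mean() - b.values.mean()) / np.sqrt(mse * (1 / a.n + 1 / b.n))
    return 2 * scipy.stats.t.sf(abs(t), N - k)


class TestPosthocLSD:
    def test_identical_groups_give_p_one(self):
        s = groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [0.0, 1.0, 5.0])
        assert posthoc_lsd(s, ("HC", "PSND")) == pytest.approx(1.0)

    def test_reduces_to_pooled_t_test_for_two_groups(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, b = rng.standard_normal((2, 9))
            s = groups(a, b)
            ref = scipy.stats.ttest_ind(a, b, equal_var=True).pvalue
            assert posthoc_lsd(s, ("HC", "PSND")) == pytest.approx(ref, abs=1e-10)

    def test_matches_from_scratch_oracle(self):
        s = groups([0.0, 0.0, 0.1, -0.1], [1.0, 1.1, 0.9, 1.0], [0.5, 0.4, 0.6, 0.5])
        for pair in itertools.combinations(("HC", "PSND", "PSMD"), 2):
            assert posthoc_lsd(s, pair) == pytest.approx(oracle_lsd_p(s, pair), abs=1e-12)

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            posthoc_lsd(groups([1.0, 2.0], [3.0, 4.0]), ("HC", "XX"))


class TestPosthocTamhane:
    def test_identical_pair_gives_one(self):
        s = groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 9.5, 10.0])
        assert posthoc_tamhane_t2(s, ("HC", "PSND")) == pytest.approx(1.0)

    def test_adjustment_dominates_welch_p(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.standard_normal(8)
            b = rng.standard_normal(12) * rng.uniform(0.5, 3)
            c = rng.standard_normal(10)
            s = groups(a, b, c)
            p_adj = posthoc_tamhane_t2(s, ("HC", "PSND"))
            by = {x.group_label: x for x in s}
            assert p_adj >= welch_t_p(by["HC"], by["PSND"]) - 1e-12

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(8)
        a = GroupSample("HC", rng.standard_normal(9))
        b = GroupSample("PSD", rng.standard_normal(14) * 3)
        ref = scipy.stats.ttest_ind(a.values, b.values, equal_var=False).pvalue
        assert welch_t_p(a, b) == pytest.approx(ref, rel=1e-10)

    def test_converges_to_lsd_under_equal_variance_large_n(self):
        rng = np.random.default_rng(9)
        a, b = rng.standard_normal((2, 200))
        s = groups(a, b)
        p_welch = welch_t_p(s[0], s[1])
        p_lsd = posthoc_lsd(s, ("HC", "PSND"))
        assert p_welch == pytest.approx(p_lsd, abs=0.01)


class TestGatedComparison:
    def test_gate_selects_lsd_when_homogeneous(self):
        rng = np.random.default_rng(10)
        s = groups(*(rng.standard_normal((4, 20)) + [[0], [1], [2], [3]]))
        res = compare_groups(s)
        assert res["levene_p"] >= 0.05
        assert res["method"] == "LSD"

    def test_gate_selects_tamhane_when_heteroskedastic(self):
        rng = np.random.default_rng(11)
        arrays = [rng.standard_normal(20) * sd for sd in (0.2, 1.0, 5.0, 25.0)]
        res = compare_groups(groups(*arrays))
        assert res["levene_p"] < 0.05
        assert res["method"] == "TamhaneT2"

    def test_all_six_pairs_reported(self):
        rng = np.random.default_rng(12)
        res = compare_groups(groups(*rng.standard_normal((4, 10))))
        assert len(res["pairwise_p"]) == 6


def make_metric_table(rng, n_thresholds=21, n_per_group=10, shift=None):
    rows = []
    thresholds = np.round(np.arange(0.10, 0.10 + 0.01 * n_thresholds, 0.01), 2)
    shift = shift or {}
    for g in ("HC", "PSND", "PSMD", "PSD"):
        for subj in range(n_per_group):
            base = rng.standard_normal(n_thresholds) + shift.get(g, 0.0)
            for t, v in zip(thresholds, base):
                rows.append(
                    {"subject": f"{g}_{subj}", "group": g, "threshold": t,
                     "metric": "interhemispheric_edges", "value": v}
                )
    return pd.DataFrame(rows)


class TestCompareAcrossThresholds:
    def test_default_grid_yields_21_rows(self):
        table = make_metric_table(np.random.default_rng(13))
        res = compare_across_thresholds(table, "interhemispheric_edges")
        assert len(res.table) == 21
        assert set(res.table["method"]).issubset({"LSD", "TamhaneT2"})

    def test_group_shift_detected(self):
        table = make_metric_table(np.random.default_rng(14), shift={"HC": 2.0})
        res = compare_across_thresholds(table, "interhemispheric_edges")
        assert (res.table["p_HC_vs_PSD"] < 0.05).mean() > 0.8

    def test_null_significance_rate_near_alpha(self):
        # pooled over replicates, the per-threshold ANOVA rejects ~5%
        rng = np.random.default_rng(15)
        flags = []
        for _ in range(25):
            table = make_metric_table(rng, n_thresholds=10)
            res = compare_across_thresholds(table, "interhemispheric_edges")
            flags.extend(res.table["anova_p"] < 0.05)
        rate = np.mean(flags)
        assert 0.02 <= rate <= 0.09

    def test_missing_group_raises(self):
        table = make_metric_table(np.random.default_rng(16))
        table = table[table["group"] != "PSD"]
        with pytest.raises(ValueError, match="PSD"):
            compare_across_thresholds(table, "interhemispheric_edges")

    def test_bonferroni_option_scales_p(self):
        table = make_metric_table(np.random.default_rng(17), n_thresholds=5)
        plain = compare_across_thresholds(table, "interhemispheric_edges")
        corr = compare_across_thresholds(
            table, "interhemispheric_edges", bonferroni_across_thresholds=True
        )
        for col in [c for c in plain.table.columns if c.startswith("p_")]:
            assert np.all(corr.table[col] >= plain.table[col] - 1e-12)

    def test_significant_pairs_helper(self):
        table = make_metric_table(np.random.default_rng(18), shift={"HC": 5.0})
        res = compare_across_thresholds(table, "interhemispheric_edges")
        pairs = res.significant_pairs(res.table["threshold"].iloc[0])
        assert ("HC", "PSD") in pairs
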