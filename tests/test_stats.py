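"""Co-occurrence arithmetic, abundance shares, and rank-based tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nearshore_overlap.stats import (CooccurrenceSummary, compact_letter_display,
                                     cooccurrence_rate, dunn_posthoc,
                                     kruskal_wallis, max_density,
                                     relative_abundance, round_half_up,
                                     wilcoxon_rank_sum)


def day_table(pairs, group_b="surfer"):
    """Survey-day table with `pairs` = list of (shark_count, group_b_count)."""
    rows = []
    for i, (s, g) in enumerate(pairs):
        rows.append({"beach": 0, "day": i, "shark": s, group_b: g,
                     "wader": 0, "swimmer": 0, "bodyboarder": 0, "SUP": 0,
                     "n_surveys": 1, "shark_distinct": s})
    return pd.DataFrame(rows)


class TestRounding:
    @pytest.mark.parametrize("x,dec,want", [
        (96.666, 0, 97.0), (78.378, 1, 78.4), (94.736, 1, 94.7),
        (72.97, 0, 73.0), (37.84, 0, 38.0), (33.78, 0, 34.0),
        (51.35, 0, 51.0), (87.84, 0, 88.0), (0.5, 0, 1.0),
    ])
    def test_half_up(self, x, dec, want):
        assert round_half_up(x, dec) == want


class TestCooccurrence:
    def test_aggregation_site_fraction(self):
        pairs = [(1, 1)] * 58 + [(0, 1), (1, 0)]
        summary = cooccurrence_rate(day_table(pairs), "shark", "surfer")
        assert summary.rate == pytest.approx(58 / 60)
        assert summary.percent(0) == 97.0

    def test_beach_specific_fraction(self):
        pairs = [(2, 3)] * 36 + [(0, 1), (0, 2)]
        summary = cooccurrence_rate(day_table(pairs), "shark", "surfer")
        assert summary.percent(1) == 94.7

    def test_no_sharks_zero_rate(self):
        summary = cooccurrence_rate(day_table([(0, 5)] * 10), "shark", "surfer")
        assert summary.rate == 0.0

    def test_mean_abundance_on_cooccurrence_days(self):
        pairs = [(2, 10), (4, 20), (0, 99)]
        summary = cooccurrence_rate(day_table(pairs), "shark", "surfer")
        assert summary.mean_abundance_a == pytest.approx(3.0)
        assert summary.mean_abundance_b == pytest.approx(15.0)

    def test_day_is_the_unit_duplication_invariant(self):
        # splitting a day's surveys in two must not change the rate
        t = day_table([(1, 1), (0, 1), (1, 0)])
        t2 = pd.concat([t, t.assign(n_surveys=1)], ignore_index=True)
        t2 = (t2.groupby(["beach", "day"], as_index=False)
              .agg({"shark": "max", "surfer": "max", "wader": "max",
                    "swimmer": "max", "bodyboarder": "max", "SUP": "max",
                    "n_surveys": "sum", "shark_distinct": "max"}))
        r1 = cooccurrence_rate(t, "shark", "surfer").rate
        r2 = cooccurrence_rate(t2, "shark", "surfer").rate
        assert r1 == r2

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError):
            cooccurrence_rate(day_table([(1, 1)]), "shark", "surfer", beaches=[99])


class TestRelativeAbundance:
    def test_one_survey_share(self):
        t = day_table([(0, 4)])
        t["wader"] = 6
        rel = relative_abundance(t, ["surfer", "wader"])
        share = dict(zip(rel["group"], rel["proportion"]))
        assert share["surfer"] == pytest.approx(0.4)
        assert share["wader"] == pytest.approx(0.6)

    def test_proportions_sum_to_one(self, demo_run):
        _, outdir, _ = demo_run
        rel = pd.read_csv(outdir / "stats_relative_abundance.csv")
        assert rel["proportion"].sum() == pytest.approx(1.0)

    def test_empty_surveys_dilute_means(self):
        t = day_table([(0, 4), (0, 0)])
        rel = relative_abundance(t, ["surfer"])
        assert rel["mean_per_survey"].iloc[0] == pytest.approx(2.0)

    def test_zero_surveys_rejected(self):
        t = day_table([(0, 4)])
        t["n_surveys"] = 0
        with pytest.raises(ValueError):
            relative_abundance(t, ["surfer"])


class TestMaxDensity:
    def test_ten_sharks_over_100ha(self):
        t = day_table([(3, 0)])
        t["shark_distinct"] = 10
        assert max_density(t, 100.0) == pytest.approx(0.100)

    def test_inverse_consistency_with_reported_density(self):
        # 15 individuals at 0.086 sharks/ha implies ~174.4 ha surveyed
        t = day_table([(15, 0)])
        t["shark_distinct"] = 15
        assert max_density(t, 15 / 0.086) == pytest.approx(0.086)

    def test_zero_sharks(self):
        t = day_table([(0, 0)])
        t["shark_distinct"] = 0
        assert max_density(t, 50.0) == 0.0


def exhaustive_ranksum_p(a, b):
    """Oracle: enumerate all assignments of pooled values to the two samples."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    mu = n1 * (len(pooled) + 1) / 2
    obs = abs(ranks[:n1].sum() - mu)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9:
            count += 1
    return count / total


class TestRankTests:
    def test_identical_constant_groups_degenerate(self):
        res = kruskal_wallis({"a": [5, 5, 5], "b": [5, 5, 5]})
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_wilcoxon_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 3), rng.normal(0.5, 1, 3)
        got = wilcoxon_rank_sum(a, b, method="exact")
        assert got.p_value == pytest.approx(exhaustive_ranksum_p(a, b))

    def test_exact_kruskal_two_groups_matches_wilcoxon(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 4), rng.normal(1, 1, 4)
        kw = kruskal_wallis({"a": a, "b": b}, method="exact")
        w = wilcoxon_rank_sum(a, b, method="exact")
        assert kw.p_value == pytest.approx(w.p_value)

    def test_asymptotic_kruskal_matches_scipy(self):
        rng = np.random.default_rng(4)
        groups = {g: rng.normal(i, 1, 30) for i, g in enumerate("abc")}
        res = kruskal_wallis(groups, method="asymptotic")
        H, p = sps.kruskal(*groups.values())
        assert res.statistic == pytest.approx(H)
        assert res.p_value == pytest.approx(p)

    def test_asymptotic_wilcoxon_matches_scipy_with_ties(self):
        rng = np.random.default_rng(5)
        a = np.round(rng.normal(0, 1, 40), 1)
        b = np.round(rng.normal(0.4, 1, 35), 1)
        got = wilcoxon_rank_sum(a, b, method="asymptotic")
        want = sps.mannwhitneyu(a, b, method="asymptotic", use_continuity=True)
        assert got.p_value == pytest.approx(want.pvalue, rel=1e-6)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1.0], [2.0, 3.0])


class TestDunn:
    def test_adjusted_never_below_raw(self, rng):
        groups = {g: rng.normal(i * 0.3, 1, 25) for i, g in enumerate("abcd")}
        for r in dunn_posthoc(groups):
            assert r.p_adjusted >= r.p_value
            assert r.p_adjusted <= 1.0

    def test_bonferroni_factor_is_all_pairs(self, rng):
        groups = {g: rng.normal(0, 1, 20) for g in "abcd"}
        m = 4 * 3 // 2
        for r in dunn_posthoc(groups):
            assert r.p_adjusted == pytest.approx(min(1.0, m * r.p_value))

    def test_well_separated_groups_all_letters_distinct(self):
        rng = np.random.default_rng(0)
        groups = {g: rng.normal(10 * i, 0.5, 30) for i, g in enumerate("abc")}
        pairs = dunn_posthoc(groups)
        letters = compact_letter_display(list(groups), pairs)
        assert len({letters[g] for g in groups}) == 3

    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(1)
        pool = rng.normal(0, 1, 90)
        groups = {"a": pool[:30], "b": pool[30:60], "c": pool[60:]}
        letters = compact_letter_display(list(groups), dunn_posthoc(groups))
        assert letters["a"] == letters["b"] == letters["c"]
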