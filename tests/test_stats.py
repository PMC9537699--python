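"""Cohort statistics: calibration, oracles and fixed small datasets."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ohcquant.stats import (
    _mw_exact_p,
    _mw_u_statistic,
    anova_tukey,
    count_cells_per_region,
    kruskal_dunn,
    mann_whitney,
    multiple_t_bky,
    normality_check,
    onset_analysis,
)
from ohcquant.synthetic import generate_cohort, onset_cohort_spec


def bky_stepup_oracle(p, q=0.05):
    """Step-by-step two-stage linear step-up procedure (independent oracle)."""
    p = np.asarray(p, float)
    m = len(p)
    q1 = q / (1 + q)

    def bh_reject(pvals, level):
        order = np.argsort(pvals)
        sp = pvals[order]
        ok = np.nonzero(sp <= level * np.arange(1, m + 1) / m)[0]
        r = ok[-1] + 1 if len(ok) else 0
        rej = np.zeros(m, bool)
        rej[order[:r]] = True
        return rej, r

    rej1, r1 = bh_reject(p, q1)
    if r1 == 0:
        return np.zeros(m, bool)
    if r1 == m:
        return np.ones(m, bool)
    m0 = m - r1
    rej2, _ = bh_reject(p, q1 * m / m0)
    return rej2


class TestNormality:
    def test_gaussian_samples_pass_at_expected_rate(self):
        # "pass" requires BOTH Shapiro-Wilk and Lilliefors p > 0.05, so under
        # the null the pass rate is bracketed by the Bonferroni bound
        # [1 - 2a, 1 - a] = [0.90, 0.95]; allow 3 SE of Monte-Carlo slack
        rng = np.random.default_rng(101)
        passed = sum(
            normality_check({"g": rng.normal(size=50)})["passed"].iloc[0]
            for _ in range(500)
        )
        assert 0.87 <= passed / 500 <= 0.97

    def test_exponential_samples_fail_with_high_power(self):
        rng = np.random.default_rng(102)
        failed = sum(
            not normality_check({"g": rng.exponential(size=100)})["passed"].iloc[0]
            for _ in range(500)
        )
        assert failed / 500 >= 0.90

    def test_constant_values_flagged_degenerate(self):
        out = normality_check({"g": [2.0] * 10})
        assert not out["passed"].iloc[0]
        assert "degenerate" in out["reason"].iloc[0]

    def test_small_sample_reported_na(self):
        out = normality_check({"g": [1.0, 2.0]})
        assert out["passed"].iloc[0] is None
        assert np.isnan(out["shapiro_p"].iloc[0])


class TestKruskalDunn:
    def test_hand_computed_h_on_fixed_dataset(self):
        # ranks 1..9 in three blocks: H = 12/(N(N+1)) Σ R²/n − 3(N+1) = 7.2
        res = kruskal_dunn({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        assert res.statistic == pytest.approx(7.2, abs=1e-12)
        assert (res.comparisons["p_adjusted"] >= res.comparisons["p_raw"] - 1e-15).all()

    def test_identical_constant_groups_degenerate(self):
        res = kruskal_dunn({"a": [5, 5], "b": [5, 5], "c": [5, 5]})
        assert res.statistic == 0.0
        assert res.pvalue == 1.0
        assert res.details["degenerate"]

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(103)
        rej = sum(
            kruskal_dunn({k: rng.normal(size=10) for k in "abc"}).pvalue < 0.05
            for _ in range(2000)
        )
        assert 0.035 <= rej / 2000 <= 0.065

    def test_p_within_monte_carlo_error_of_permutation_null(self):
        groups = {"a": [1.1, 3.4, 2.2, 5.1], "b": [2.0, 4.4, 6.2, 3.3],
                  "c": [7.9, 5.5, 8.1, 6.6]}
        res = kruskal_dunn(groups)
        pooled = np.concatenate(list(groups.values()))
        ranks = sps.rankdata(pooled)
        n, k = len(pooled), 3
        sizes = np.array([4, 4, 4])
        # vectorized permutation null for the H statistic
        nperm = 100_000
        rng = np.random.default_rng(104)
        keys = rng.random((nperm, n)).argsort(axis=1)
        permuted = ranks[keys]
        h_perm = np.zeros(nperm)
        start = 0
        for sz in sizes:
            rsum = permuted[:, start:start + sz].sum(axis=1)
            h_perm += rsum**2 / sz
            start += sz
        h_perm = 12 / (n * (n + 1)) * h_perm - 3 * (n + 1)
        p_perm = np.mean(h_perm >= res.statistic - 1e-12)
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / nperm)
        # chi-square approximation differs from the exact permutation null by
        # more than MC error at n=12; allow the known approximation slack too
        assert res.pvalue == pytest.approx(p_perm, abs=max(0.02, mc_err))

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn({"a": [1, 2], "b": [3, 4]})


class TestAnovaTukey:
    def test_two_identical_groups_give_f_near_zero(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0] * 2,
                           "g": ["a"] * 3 + ["b"] * 3})
        res = anova_tukey(df, "v", ["g"])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0, abs=1e-9)

    def test_one_way_f_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(105)
        df = pd.DataFrame({
            "v": np.concatenate([rng.normal(m, 1, 8) for m in (0, 0.5, 2.0)]),
            "g": np.repeat(list("abc"), 8),
        })
        res = anova_tukey(df, "v", ["g"])
        # explicit between/within decomposition
        grand = df["v"].mean()
        ssb = sum(len(s) * (s.mean() - grand) ** 2 for _, s in df.groupby("g")["v"])
        ssw = sum(((s - s.mean()) ** 2).sum() for _, s in df.groupby("g")["v"])
        f_oracle = (ssb / 2) / (ssw / (24 - 3))
        assert res.statistic == pytest.approx(f_oracle, rel=1e-10)
        assert res.pvalue == pytest.approx(sps.f.sf(f_oracle, 2, 21), rel=1e-10)

    def test_balanced_two_way_null_type_one_error(self):
        rng = np.random.default_rng(106)
        hits = {"geno": 0, "age": 0}
        reps = 500
        for _ in range(reps):
            df = pd.DataFrame({
                "v": rng.normal(size=20),
                "geno": np.tile(np.repeat(["wt", "ko"], 5), 2),
                "age": np.repeat(["P8", "P14"], 10),
            })
            res = anova_tukey(df, "v", ["geno", "age"])
            for eff in hits:
                if res.details["effects"][eff]["p"] < 0.05:
                    hits[eff] += 1
        for eff, n_hit in hits.items():
            assert 0.025 <= n_hit / reps <= 0.08, eff

    def test_tukey_adjusted_p_reported_per_pair(self):
        rng = np.random.default_rng(107)
        df = pd.DataFrame({
            "v": np.concatenate([rng.normal(m, 0.5, 10) for m in (0, 0, 3)]),
            "g": np.repeat(list("abc"), 10),
        })
        res = anova_tukey(df, "v", ["g"])
        comp = res.comparisons.set_index(["group_a", "group_b"])
        assert comp.loc[("a", "c"), "p_adjusted"] < 0.001
        assert comp.loc[("a", "b"), "p_adjusted"] > 0.05

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"v": [1.0, 2.0], "g": ["a", "a"]})
        with pytest.raises(ValueError, match="levels"):
            anova_tukey(df, "v", ["g"])


class TestMultipleTBky:
    @staticmethod
    def _table_from_p_targets(rng, shifts, n=10):
        rows = []
        for cond, shift in enumerate(shifts):
            for grp, mu in (("a", 0.0), ("b", shift)):
                for v in rng.normal(mu, 1.0, n):
                    rows.append({"cond": f"c{cond}", "group": grp, "v": v})
        return pd.DataFrame(rows)

    def test_discovery_set_matches_stepwise_oracle_on_fixed_vectors(self):
        from statsmodels.stats.multitest import multipletests
        for p in ([0.001, 0.2, 0.3, 0.9], [1e-8] * 4, [0.04, 0.045, 0.05, 0.9],
                  [0.9, 0.95, 0.99, 0.2], [0.01, 0.02, 0.03, 0.04]):
            reject, *_ = multipletests(p, alpha=0.05, method="fdr_tsbh")
            np.testing.assert_array_equal(reject, bky_stepup_oracle(p),
                                          err_msg=str(p))

    def test_tiny_equal_p_values_all_discovered(self):
        np.testing.assert_array_equal(bky_stepup_oracle([1e-8] * 4),
                                      [True] * 4)
        rng = np.random.default_rng(108)
        table = self._table_from_p_targets(rng, [5.0, 5.0, 5.0, 5.0])
        out = multiple_t_bky(table, "v", "cond", "group")
        assert out["discovery"].all()

    def test_mixed_vector_discovery_via_pipeline(self):
        np.testing.assert_array_equal(
            bky_stepup_oracle([0.001, 0.2, 0.3, 0.9]),
            [True, False, False, False],
        )

    def test_null_familywise_discovery_rate_bounded(self):
        rng = np.random.default_rng(109)
        any_disc = 0
        reps = 800
        for _ in range(reps):
            out = multiple_t_bky(
                self._table_from_p_targets(rng, [0.0] * 4), "v", "cond", "group"
            )
            if out["discovery"].fillna(False).any():
                any_disc += 1
        assert any_disc / reps <= 0.065

    def test_insufficient_condition_reported_na(self):
        table = pd.DataFrame({
            "cond": ["c0"] * 4 + ["c1"] * 3,
            "group": ["a", "a", "b", "b", "a", "b", "b"],
            "v": [1.0, 2.0, 1.5, 2.5, 1.0, 2.0, 2.2],
        })
        out = multiple_t_bky(table, "v", "cond", "group").set_index("condition")
        assert np.isnan(out.loc["c1", "p_raw"])
        assert not np.isnan(out.loc["c0", "p_raw"])
        assert out.loc["c1", "discovery"] is pd.NA or out.loc["c1", "discovery"] is None


class TestMannWhitney:
    def test_identical_multisets_central_u_and_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)
        assert res.pvalue == pytest.approx(1.0)
        assert res.details["method"] == "exact-enumeration"

    def test_fully_separated_tiny_samples_exact_enumeration(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.pvalue == pytest.approx(1 / 3)

    def test_exact_and_asymptotic_agree_for_moderate_n(self):
        rng = np.random.default_rng(110)
        for _ in range(6):
            n1, n2 = rng.integers(8, 13, size=2)
            a, b = rng.normal(size=int(n1)), rng.normal(size=int(n2))
            u = _mw_u_statistic(a, b)
            p_exact = _mw_exact_p(a, b, u)
            p_asym = mann_whitney(a, b, exact=False).pvalue
            assert abs(p_exact - p_asym) <= 0.01

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(111)
        rej = sum(
            mann_whitney(rng.normal(size=30), rng.normal(size=30)).pvalue < 0.05
            for _ in range(2000)
        )
        assert 0.035 <= rej / 2000 <= 0.065

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestRegionCounts:
    def test_no_cells_counts_zero(self):
        assert count_cells_per_region([], 0.0)["all"] == 0

    def test_half_open_boundary_convention(self):
        counts = count_cells_per_region([-100.0, 0.0, 99.999, 100.0], 0.0,
                                        region_span=200.0)
        assert counts["all"] == 3

    def test_row_of_forty_cells_at_five_micron_pitch(self):
        positions = {"OHC": np.arange(40) * 5.0, "IHC": np.arange(10) * 20.0}
        counts = count_cells_per_region(positions, region_center=97.5,
                                        region_span=200.0)
        assert counts["OHC"] == 40
        assert counts["IHC"] == 10


class TestOnsetAnalysis:
    def test_single_age_reduces_to_welch_t(self):
        rng = np.random.default_rng(112)
        table = pd.DataFrame({
            "age": "P14", "group": np.repeat(["a", "b"], 12),
            "v": np.concatenate([rng.normal(0, 1, 12), rng.normal(1, 1, 12)]),
        })
        out, onset = onset_analysis(table, "v")
        a = table.loc[table.group == "a", "v"]
        b = table.loc[table.group == "b", "v"]
        _, p_welch = sps.ttest_ind(a, b, equal_var=False)
        assert out.loc[0, "p_raw"] == pytest.approx(p_welch, rel=1e-12)
        assert len(out) == 1

    def test_onset_design_detects_true_ages_with_high_power(self):
        both_found = 0
        clean = 0
        reps = 200
        for rep in range(reps):
            df, _ = generate_cohort(onset_cohort_spec(seed=rep))
            out, _ = onset_analysis(df, "relative_position")
            disc = set(out.loc[out["discovery"].fillna(False).astype(bool),
                               "condition"])
            if {"P12", "P14"} <= disc:
                both_found += 1
            if disc == {"P12", "P14"}:
                clean += 1
        assert both_found / reps >= 0.95
        # BKY trades familywise error for power: with two strong effects the
        # null ages run at an effective level ~ q·m/m0 = 0.10 each, so the
        # clean-set rate is bounded near (1 − 0.1)² ≈ 0.8, not near 0.95
        assert clean / reps >= 0.75

    def test_all_null_cohort_rarely_declares_onset(self):
        false_onset = 0
        reps = 200
        for rep in range(reps):
            df, _ = generate_cohort(onset_cohort_spec(onset_age=None,
                                                      seed=10_000 + rep))
            _, onset = onset_analysis(df, "relative_position")
            if onset is not None:
                false_onset += 1
        assert false_onset / reps <= 0.10


class TestAdjustmentMonotonicity:
    def test_sorted_raw_p_yields_nondecreasing_adjusted_p(self):
        rng = np.random.default_rng(113)
        from statsmodels.stats.multitest import multipletests
        for _ in range(50):
            p = np.sort(rng.uniform(size=8))
            _, q_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_tsbh")
            assert np.all(np.diff(q_adj) >= -1e-12)
        res = kruskal_dunn({"a": rng.normal(size=6), "b": rng.normal(size=6),
                            "c": rng.normal(1.5, 1, 6)})
        comp = res.comparisons.sort_values("p_raw")
        assert np.all(np.diff(comp["p_adjusted"]) >= -1e-12)
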