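"""Inference machinery, each operation checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import cogstage as cs
from cogstage.stats import (
    PowerSpec,
    SeparationError,
    _fisher_exact_rxc,
    bh_fdr,
    change_ancova,
    cliffs_delta,
    cramers_v,
    exact_binomial_ci,
    group_compare,
    logistic_progression,
    two_proportion_power,
    wald_binomial_ci,
)


def brute_force_delta(x, y):
    d = 0
    for xi in x:
        for yj in y:
            d += (xi > yj) - (xi < yj)
    return d / (len(x) * len(y))


class TestCliffsDelta:
    @pytest.mark.parametrize(
        "x, y, expect",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([4, 5, 6], [1, 2, 3], 1.0),
            ([2, 4], [1, 3], 0.5),
        ],
    )
    def test_examples(self, x, y, expect):
        assert cliffs_delta(x, y).estimate == pytest.approx(expect)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cliffs_delta([], [1.0])

    @given(
        x=st.lists(st.integers(-5, 5), min_size=1, max_size=12),
        y=st.lists(st.integers(-5, 5), min_size=1, max_size=12),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_pair_enumeration_and_antisymmetry(self, x, y):
        d = cliffs_delta(x, y).estimate
        assert d == pytest.approx(brute_force_delta(x, y), abs=1e-12)
        assert d == pytest.approx(-cliffs_delta(y, x).estimate, abs=1e-12)
        # invariance under a strictly monotone transform of both samples
        f = lambda v: [np.exp(t) + 3 * t for t in v]
        assert cliffs_delta(f(x), f(y)).estimate == pytest.approx(d, abs=1e-12)

    @pytest.mark.parametrize(
        "d, label",
        [(0.1, "negligible"), (0.2, "small"), (-0.4, "medium"), (0.6, "large")],
    )
    def test_magnitude_bands(self, d, label):
        n = 40
        k = int(round((d + 1) / 2 * n))  # construct sample pair with exact delta
        x = [1] * k + [-1] * (n - k)
        y = [0] * n
        res = cliffs_delta(x, y)
        assert res.estimate == pytest.approx(2 * k / n - 1)
        assert res.magnitude_label == label


class TestCramersV:
    def test_examples(self):
        assert cramers_v([[10, 0], [0, 10]]).estimate == pytest.approx(1.0)
        assert cramers_v([[5, 5], [5, 5]]).estimate == pytest.approx(0.0)
        # hand-computed chi2 = 20/3 on the 2x2 table below
        assert cramers_v([[20, 10], [10, 20]]).estimate == pytest.approx(
            np.sqrt((20 / 3) / 60), abs=1e-12
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            cramers_v([[0, 0], [5, 5]])


class TestExactBinomialCI:
    def cp_oracle(self, k, n, level=0.95):
        # invert the binomial tail tests directly (independent of beta quantiles)
        a = (1 - level) / 2
        lo = 0.0 if k == 0 else brentq(lambda p: sps.binom.sf(k - 1, n, p) - a, 1e-12, 1 - 1e-12)
        hi = 1.0 if k == n else brentq(lambda p: sps.binom.cdf(k, n, p) - a, 1e-12, 1 - 1e-12)
        return lo, hi

    @pytest.mark.parametrize("k, n", [(13, 43), (9, 43), (1, 10), (269, 558), (42, 43)])
    def test_matches_tail_inversion_oracle(self, k, n):
        ci = exact_binomial_ci(k, n)
        lo, hi = self.cp_oracle(k, n)
        assert ci.lower == pytest.approx(lo, abs=1e-9)
        assert ci.upper == pytest.approx(hi, abs=1e-9)

    def test_printed_reversion_intervals(self):
        # printed intervals 17.7-46.3 and 10.6-36.5 are approximate; the exact
        # Clopper-Pearson bounds agree within one percentage point
        ci = exact_binomial_ci(13, 43)
        assert ci.lower == pytest.approx(0.177, abs=0.01)
        assert ci.upper == pytest.approx(0.463, abs=0.01)
        ci = exact_binomial_ci(9, 43)
        assert ci.lower == pytest.approx(0.106, abs=0.01)
        assert ci.upper == pytest.approx(0.365, abs=0.01)

    def test_boundaries(self):
        assert exact_binomial_ci(0, 10).lower == 0.0
        assert exact_binomial_ci(10, 10).upper == 1.0
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 0)
        with pytest.raises(ValueError):
            exact_binomial_ci(11, 10)

    def test_coverage_at_least_nominal(self):
        rng = np.random.default_rng(5)
        for p in (0.05, 0.2, 0.5):
            for n in (10, 43, 200):
                ks = rng.binomial(n, p, 4000)
                cover = np.array([
                    exact_binomial_ci(k, n).lower <= p <= exact_binomial_ci(k, n).upper
                    for k in np.unique(ks)
                ])
                rate = sum(
                    cover[i] * (ks == k).mean() for i, k in enumerate(np.unique(ks))
                )
                assert rate >= 0.95 - 3 * np.sqrt(0.95 * 0.05 / 4000)

    def test_wald_interval_matches_closed_form(self):
        ci = wald_binomial_ci(269, 558)
        p = 269 / 558
        half = 1.959963984540054 * np.sqrt(p * (1 - p) / 558)
        assert ci.lower == pytest.approx(p - half)
        assert ci.upper == pytest.approx(p + half)


def stepup_oracle(p, q):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    ks = [k for k in range(1, m + 1) if p[order[k - 1]] <= k * q / m]
    out = np.zeros(m, bool)
    if ks:
        out[order[: max(ks)]] = True
    return out


class TestBHFDR:
    @pytest.mark.parametrize(
        "p, expect",
        [
            ([0.001] * 5, [True] * 5),
            ([0.6, 0.7], [False, False]),
            ([0.01, 0.02, 0.04, 0.6], [True, True, False, False]),
        ],
    )
    def test_examples(self, p, expect):
        assert bh_fdr(p, 0.05).tolist() == expect

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12),
        q=st.sampled_from([0.01, 0.05, 0.1, 0.25]),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_stepup_definition(self, p, q):
        assert bh_fdr(p, q).tolist() == stepup_oracle(p, q).tolist()


class TestTwoProportionPower:
    def test_null_case_power_is_alpha(self):
        spec = PowerSpec(0.3, 0.3, 200, 200, alpha=0.05)
        assert two_proportion_power(spec) == pytest.approx(0.05, abs=0.002)

    def test_extreme_effect_power_is_one(self):
        assert two_proportion_power(PowerSpec(0.01, 0.9, 1000, 1000)) == pytest.approx(1.0)

    def test_design_point_exceeds_eighty_percent(self):
        power = two_proportion_power(PowerSpec(0.025, 0.101, 1110, 119))
        assert power > 0.80

    def test_agrees_with_monte_carlo_rejection_rate(self):
        spec = PowerSpec(0.025, 0.101, 1110, 119)
        rng = np.random.default_rng(17)
        reps = 100_000
        k1 = rng.binomial(spec.n1, spec.p1, reps)
        k2 = rng.binomial(spec.n2, spec.p2, reps)
        p1h, p2h = k1 / spec.n1, k2 / spec.n2
        pbar = (k1 + k2) / (spec.n1 + spec.n2)
        se0 = np.sqrt(pbar * (1 - pbar) * (1 / spec.n1 + 1 / spec.n2))
        with np.errstate(invalid="ignore"):
            z = (p1h - p2h) / se0
        reject = np.abs(z) > sps.norm.ppf(0.975)
        assert two_proportion_power(spec) == pytest.approx(reject.mean(), abs=0.02)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_power(PowerSpec(0.0, 0.5, 10, 10))


class TestChangeAncova:
    def test_hand_solvable_normal_equations(self):
        # two groups x three points; oracle = direct least squares
        change = [1.0, 2.0, 3.0, -1.0, 0.0, 1.0]
        group = ["a", "a", "a", "b", "b", "b"]
        base = [10.0, 12.0, 14.0, 11.0, 13.0, 15.0]
        itv = [2.0, 2.5, 3.0, 3.0, 2.0, 2.5]
        res = change_ancova(change, group, base, itv)
        G = np.column_stack([
            [1, 1, 1, 0, 0, 0],
            [0, 0, 0, 1, 1, 1],
            base,
            itv,
        ]).astype(float)
        beta, *_ = np.linalg.lstsq(G, np.array(change), rcond=None)
        bm, im = np.mean(base), np.mean(itv)
        assert res["adjusted_means"]["a"] == pytest.approx(beta[0] + beta[2] * bm + beta[3] * im)
        assert res["adjusted_means"]["b"] == pytest.approx(beta[1] + beta[2] * bm + beta[3] * im)

    def test_null_groups_show_no_effect(self):
        rng = np.random.default_rng(3)
        n = 300
        base = rng.normal(100, 10, n)
        change = rng.normal(0, 5, n) - 0.3 * (base - 100)
        group = rng.choice(["x", "y", "z"], n)
        itv = rng.uniform(1.5, 3.0, n)
        res = change_ancova(change, group, base, itv)
        assert res["omnibus_p"] > 0.001
        means = list(res["adjusted_means"].values())
        assert max(means) - min(means) < 3.0

    def test_recovers_injected_group_difference(self):
        rng = np.random.default_rng(4)
        n = 400
        base = rng.normal(100, 10, n)
        group = rng.choice(["CU_S", "CU_D"], n)
        change = rng.normal(0, 6, n) - 0.2 * (base - 100) - 10.0 * (group == "CU_D")
        itv = rng.uniform(1.5, 3.0, n)
        res = change_ancova(change, group, base, itv)
        c = res["contrasts"][("CU_D", "CU_S")]
        assert c["estimate"] == pytest.approx(-10.0, abs=3 * c["se"])
        assert res["kruskal_p"] < 0.001

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            change_ancova([1, 2, 3], ["a", "a", "b"], [1, 2, 3], [1, 1, 1])


class TestLogisticProgression:
    def test_reproduces_two_by_two_odds_ratio(self):
        # printed progression counts: (16 of 119) CU_D vs (32 of 1110) CU_S
        a, b, c, d = 16, 103, 32, 1078
        y = [1] * a + [0] * b + [1] * c + [0] * d
        x = [1] * (a + b) + [0] * (c + d)
        out = logistic_progression(y, {"cu_d": x})
        assert out.iloc[0]["odds_ratio"] == pytest.approx((a * d) / (b * c), abs=1e-6)

    def test_null_covariate_or_near_one(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.integers(0, 2, n)
        y = rng.random(n) < 0.1
        out = logistic_progression(y.astype(int), {"x": x})
        r = out.iloc[0]
        assert r["ci_lower"] < 1.0 < r["ci_upper"]

    def test_recovers_injected_log_odds(self):
        rng = np.random.default_rng(9)
        n = 4000
        x = rng.integers(0, 2, n)
        logit = -3.0 + 1.5 * x
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        out = logistic_progression(y.astype(int), {"x": x})
        est = np.log(out.iloc[0]["odds_ratio"])
        se = (np.log(out.iloc[0]["ci_upper"]) - np.log(out.iloc[0]["odds_ratio"])) / 1.96
        assert est == pytest.approx(1.5, abs=3 * se)

    def test_complete_separation_raises(self):
        y = [0] * 20 + [1] * 20
        x = [0.0] * 20 + [1.0] * 20
        with pytest.raises(SeparationError):
            logistic_progression(y, {"x": x})

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_progression([1, 1, 1], {"x": [1, 2, 3]})


class TestGroupCompare:
    def test_fisher_two_by_two_matches_hypergeometric_sum(self):
        T = [[1, 9], [9, 1]]
        res = group_compare(T, family="fisher_exact")
        # two-sided Fisher: sum hypergeometric probabilities <= P(observed)
        pm = [sps.hypergeom.pmf(k, 20, 10, 10) for k in range(11)]
        p_obs = sps.hypergeom.pmf(1, 20, 10, 10)
        expect = sum(p for p in pm if p <= p_obs + 1e-12)
        assert res["omnibus_p"] == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize(
        "table, expect",
        [
            ([[3, 1, 4], [2, 5, 0]], 0.04972805),
            ([[40, 179], [11, 20], [8, 4]], 0.00018162771),
        ],
    )
    def test_rxc_exact_matches_reference_values(self, table, expect):
        # reference p-values computed with R's fisher.test
        assert _fisher_exact_rxc(np.array(table)) == pytest.approx(expect, rel=1e-6)

    def test_identical_groups_reject_at_alpha_rate(self):
        rng = np.random.default_rng(12)
        hits = 0
        reps = 400
        for _ in range(reps):
            vals = rng.normal(size=60)
            labels = np.repeat(["a", "b", "c"], 20)
            if group_compare(vals, labels, family="kruskal_wallis")["omnibus_p"] < 0.05:
                hits += 1
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) < 3.5 * se

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(13)
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.normal(2, 1, 50)])
        labels = np.repeat(["a", "b", "c"], 50)
        res = group_compare(vals, labels, family="anova", fdr_q=0.05)
        assert res["omnibus_p"] < 0.001
        pw = res["pairwise"]
        assert len(pw) == 3
        big = pw[(pw["group_a"] == "a") & (pw["group_b"] == "c")].iloc[0]
        assert big["magnitude"] == "large"

    def test_family_data_mismatch_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0], ["a", "b"], family="fisher_exact")
        with pytest.raises(ValueError):
            group_compare([[1, 2], [3, 4]], family="anova")
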