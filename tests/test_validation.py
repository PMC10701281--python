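"""Enrichment, proportions, ICC, r-squared and ELISA calling rules."""

import math

import numpy as np
import pandas as pd
import pytest

from episcope.validation import (
    average_elisa_replicates,
    elisa_call_positives,
    enrichment,
    fraction_sweep,
    icc_band,
    icc_from_variance_components,
    prob_at_least_binomial,
    prob_at_least_hypergeometric,
    simple_r2,
    two_proportion_test,
)


def hypergeom_enumeration(x, n, K, N):
    """Exhaustive tail probability by enumerating all draws."""
    total = math.comb(N, n)
    hits = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(x, min(n, K) + 1)
    )
    return hits / total


class TestHypergeometric:
    def test_hand_example(self):
        # (C(5,2)C(5,1) + C(5,3)) / C(10,3) = 60/120
        assert prob_at_least_hypergeometric(2, 3, 5, 10) == pytest.approx(0.5)

    def test_zero_successes_is_certain(self):
        assert prob_at_least_hypergeometric(0, 5, 3, 20) == 1.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            prob_at_least_hypergeometric(6, 5, 3, 20)
        with pytest.raises(ValueError):
            prob_at_least_hypergeometric(1, 5, 30, 20)

    def test_matches_enumeration_small_pools(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(1, N + 1):
                    for x in range(n + 1):
                        assert prob_at_least_hypergeometric(
                            x, n, K, N
                        ) == pytest.approx(
                            hypergeom_enumeration(x, n, K, N), abs=1e-12
                        )

    def test_converges_to_binomial_at_study_scale(self):
        N, K, n, x = 6_090_593, 60_906, 14, 8
        h = prob_at_least_hypergeometric(x, n, K, N)
        b = prob_at_least_binomial(x, n, K / N)
        assert abs(h - b) / b < 0.05


class TestBinomial:
    def test_study_scale_value(self):
        # P(X >= 8 | n=14, p=0.01), to two significant figures
        p = prob_at_least_binomial(8, 14, 0.01)
        assert p == pytest.approx(2.85e-13, rel=0.005)

    def test_trivial_cases(self):
        assert prob_at_least_binomial(0, 14, 0.01) == 1.0
        assert prob_at_least_binomial(1, 1, 0.3) == pytest.approx(0.3)


class TestFractionSweep:
    def test_study_fraction_count(self):
        table = fraction_sweep([0.01], 8, 14, 6_090_593)
        assert table.K.iloc[0] == 60_906

    def test_monotone_in_fraction(self):
        table = fraction_sweep([0.001, 0.01, 0.1, 0.5, 0.9], 8, 14, 10_000)
        assert table.p_hypergeom.is_monotonic_increasing
        assert table.p_binomial.is_monotonic_increasing
        assert table.p_hypergeom.iloc[-1] > 0.9

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            fraction_sweep([1.5], 1, 14, 100)


class TestTwoProportions:
    def test_equal_proportions_null(self):
        z, p = two_proportion_test(5, 10, 5, 10)
        assert z == 0.0 and p == 1.0

    def test_study_counts(self):
        # random peptides 1/200 vs selected peptides 48/240 at OD >= 2
        z, p = two_proportion_test(1, 200, 48, 240)
        assert z == pytest.approx(6.47, abs=0.01)
        assert p < 0.001

    def test_hand_formula_oracle(self):
        k1, n1, k2, n2 = 3, 40, 11, 50
        pooled = (k1 + k2) / (n1 + n2)
        se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        expected = (k2 / n2 - k1 / n1) / se
        z, _ = two_proportion_test(k1, n1, k2, n2)
        assert z == pytest.approx(expected, rel=1e-12)

    def test_symmetric_under_swap(self):
        z1, p1 = two_proportion_test(1, 200, 48, 240)
        z2, p2 = two_proportion_test(48, 240, 1, 200)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_continuity_correction_shrinks_z(self):
        z, _ = two_proportion_test(1, 20, 8, 25)
        zc, _ = two_proportion_test(1, 20, 8, 25, continuity=True)
        assert abs(zc) < abs(z)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(0, 0, 1, 10)


def one_way_icc_anova(df, group_col, value_col):
    """Closed-form one-way random-effects ICC from ANOVA mean squares."""
    groups = [g[value_col].to_numpy() for _, g in df.groupby(group_col)]
    k = len(groups[0])
    grand = df[value_col].mean()
    msb = k * sum((g.mean() - grand) ** 2 for g in groups) / (len(groups) - 1)
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (
        len(groups) * (k - 1)
    )
    return (msb - msw) / (msb + (k - 1) * msw)


class TestICC:
    def make_crossed(self, sd_inst, sd_sample, sd_resid, seed=0,
                     n_inst=3, n_sample=40, n_rep=3):
        rng = np.random.default_rng(seed)
        inst_eff = rng.normal(0, sd_inst, n_inst)
        samp_eff = rng.normal(0, sd_sample, n_sample)
        rows = []
        for i in range(n_inst):
            for s in range(n_sample):
                for _ in range(n_rep):
                    rows.append(
                        {
                            "instrument": f"I{i}",
                            "sample": f"S{s}",
                            "reading": inst_eff[i]
                            + samp_eff[s]
                            + rng.normal(0, sd_resid),
                        }
                    )
        return pd.DataFrame(rows)

    def test_zero_instrument_variance_is_poor(self):
        df = self.make_crossed(0.0, 1.0, 1.0, seed=1)
        icc, band, comps = icc_from_variance_components(df, "reading")
        assert icc < 0.1
        assert band == "poor"
        assert comps["residual"] > 0

    def test_one_way_balanced_matches_anova_oracle(self):
        # single random factor with sigma2_group = sigma2_resid -> ICC 0.5
        rng = np.random.default_rng(2)
        rows = []
        for g in range(100):
            eff = rng.normal(0, 1.0)
            for _ in range(20):
                rows.append(
                    {"instrument": f"G{g}", "reading": eff + rng.normal(0, 1.0)}
                )
        df = pd.DataFrame(rows)
        df["sample"] = [f"S{i}" for i in range(len(df))]  # unused leveller
        oracle = one_way_icc_anova(df, "instrument", "reading")
        icc, _, _ = icc_from_variance_components(
            df, "reading", target="instrument", random=("instrument",)
        )
        assert icc == pytest.approx(0.5, abs=0.05)
        assert icc == pytest.approx(oracle, abs=0.02)

    @pytest.mark.parametrize("share", [0.1, 0.5, 0.9])
    def test_variance_share_recovery(self, share):
        total = 4.0
        sd_inst = math.sqrt(share * total)
        sd_resid = math.sqrt((1 - share) * total)
        rng_rows = []
        rng = np.random.default_rng(int(share * 10))
        for g in range(100):
            eff = rng.normal(0, sd_inst)
            for _ in range(10):
                rng_rows.append(
                    {"instrument": f"G{g}", "reading": eff + rng.normal(0, sd_resid)}
                )
        df = pd.DataFrame(rng_rows)
        icc, _, _ = icc_from_variance_components(
            df, "reading", target="instrument", random=("instrument",)
        )
        assert icc == pytest.approx(share, abs=0.05)

    @pytest.mark.parametrize(
        "value,band",
        [(0.3, "poor"), (0.6, "moderate"), (0.87, "good"), (0.95, "excellent")],
    )
    def test_reliability_bands(self, value, band):
        assert icc_band(value) == band

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            icc_from_variance_components(
                pd.DataFrame({"reading": [1.0]}), "reading"
            )


class TestSimpleR2:
    def test_exact_line_and_sign_free(self):
        x = np.arange(10.0)
        assert simple_r2(x, 2 * x + 1) == pytest.approx(1.0)
        assert simple_r2(x, -x) == pytest.approx(1.0)

    def test_null_expectation(self):
        rng = np.random.default_rng(9)
        n = 8
        values = [
            simple_r2(rng.normal(size=n), rng.normal(size=n))
            for _ in range(4000)
        ]
        assert np.mean(values) == pytest.approx(1 / (n - 1), abs=0.02)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            simple_r2([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            simple_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestElisaCalls:
    def test_threshold_inclusive_at_exactly_two(self):
        od = pd.DataFrame({"s1.r1": [2.0], "s1.r2": [2.0]}, index=["pep"])
        calls = elisa_call_positives(od, {"immune": ["s1"]})
        assert calls.validated.iloc[0]
        assert calls.n_positive.iloc[0] == 1

    def test_replicates_averaged_before_thresholding(self):
        od = pd.DataFrame({"s1.r1": [1.9], "s1.r2": [2.1]}, index=["pep"])
        averaged = average_elisa_replicates(od)
        assert averaged.loc["pep", "s1"] == pytest.approx(2.0)
        calls = elisa_call_positives(od, {"immune": ["s1"]})
        assert calls.n_positive.iloc[0] == 1

    def test_quarter_rule_boundary(self):
        columns = {f"s{i}.r1": [2.5 if i < 5 else 0.2] for i in range(20)}
        od = pd.DataFrame(columns, index=["pep"])
        calls = elisa_call_positives(
            od, {"immune": [f"s{i}" for i in range(20)]}
        )
        assert calls.fraction.iloc[0] == pytest.approx(0.25)
        assert calls.validated.iloc[0]

    def test_groups_reported_separately(self):
        od = pd.DataFrame(
            {"i1.r1": [3.0], "n1.r1": [0.1]}, index=["pep"]
        )
        calls = elisa_call_positives(
            od, {"immune": ["i1"], "naive": ["n1"]}
        )
        by_group = calls.set_index("group")
        assert by_group.loc["immune", "validated"]
        assert not by_group.loc["naive", "validated"]

    def test_unknown_serum_rejected(self):
        od = pd.DataFrame({"s1.r1": [1.0]}, index=["pep"])
        with pytest.raises(KeyError):
            elisa_call_positives(od, {"immune": ["ghost"]})

    def test_invalid_threshold_rejected(self):
        od = pd.DataFrame({"s1.r1": [1.0]}, index=["pep"])
        with pytest.raises(ValueError):
            elisa_call_positives(od, {"immune": ["s1"]}, threshold=0.0)


def test_enrichment_bundle_consistency():
    res = enrichment(8, 14, 60_906, 6_090_593)
    assert res.p_binomial == pytest.approx(
        prob_at_least_binomial(8, 14, 60_906 / 6_090_593)
    )
    assert res.p_hypergeom < res.p_binomial  # without replacement is rarer
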