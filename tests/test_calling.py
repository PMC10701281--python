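"""Probe/epitope/protein call statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from episcope.calling import (
    CategoryThresholds,
    EpitopeRegion,
    assign_sd_tier,
    bh_adjust,
    combine_wilkinson_max,
    consensus_sequence,
    differential_pvalue,
    epitope_pvalue,
    global_pvalue,
    protein_pvalue,
    remove_singletons,
    segment_epitopes,
    summarize_epitopes,
    tabulate_k_of_n,
)


def brute_force_bh(p):
    """Step-up q-values by direct definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, m * p[i] / rank))
        q[i] = running
    return q


class TestGlobalPvalue:
    def test_at_mean_is_half(self):
        assert global_pvalue(5.0, 5.0, 1.0) == pytest.approx(0.5)

    def test_normal_quantile(self):
        assert global_pvalue(5.0 + 1.96, 5.0, 1.0) == pytest.approx(0.025, abs=1e-3)

    def test_monotone_decreasing_in_signal(self):
        p = global_pvalue(np.linspace(0, 30, 50), 5.0, 1.0)
        assert (np.diff(p) < 0).all()

    def test_degenerate_sd_rejected(self):
        with pytest.raises(ValueError):
            global_pvalue(1.0, 0.0, 0.0)


class TestDifferentialPvalue:
    def test_at_naive_mean_is_half(self):
        assert differential_pvalue(2.0, [1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_constant_naive_with_floor_is_half(self):
        assert differential_pvalue(1.0, [1.0, 1.0, 1.0], 0.01) == pytest.approx(0.5)

    def test_matches_t_tail_oracle(self):
        # naive all zero, sd floored at 0.1, immune 10
        n = 4
        t = (10 - 0.0) / (0.1 * np.sqrt(1 + 1 / n))
        expected = stats.t.sf(t, df=n - 1)
        got = differential_pvalue(10.0, [0.0] * 4, var_floor=0.1)
        assert got == pytest.approx(expected, rel=1e-12)
        # the heavy t3 tail keeps this above 1e-6 despite t ~ 89
        assert got < 1e-5

    def test_too_few_naive_rejected(self):
        with pytest.raises(ValueError):
            differential_pvalue(1.0, [1.0])


class TestWilkinsonMax:
    def test_closed_form(self):
        assert combine_wilkinson_max([0.1, 0.2]) == pytest.approx(0.04)

    def test_boundary_one(self):
        assert combine_wilkinson_max([1.0, 0.3]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine_wilkinson_max([])

    def test_uniform_under_null(self):
        rng = np.random.default_rng(5)
        draws = combine_wilkinson_max(rng.uniform(size=(20_000, 2)))
        assert stats.kstest(draws, "uniform").pvalue > 0.01


class TestBhAdjust:
    def test_textbook_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_and_all_ones(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            m = rng.integers(1, 50)
            p = rng.uniform(size=m)
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_q_dominates_p_and_preserves_order(self):
        rng = np.random.default_rng(19)
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        # q is a monotone non-decreasing function of p (ties allowed)
        assert (np.diff(q[np.argsort(p)]) >= -1e-15).all()


class TestSdTier:
    thresholds = CategoryThresholds()

    @pytest.mark.parametrize(
        "excess,expected",
        [
            (10.1, "restrictive"),
            (7.0, "moderate"),
            (3.0, "none"),  # strict >
            (3.001, "inclusive"),
            (6.0, "inclusive"),
            (10.0, "moderate"),
            (-1.0, "none"),
        ],
    )
    def test_boundaries(self, excess, expected):
        assert assign_sd_tier(5.0 + excess, 5.0, 1.0, self.thresholds) == expected

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            CategoryThresholds(inclusive_sd=6, moderate_sd=3)


class TestSingletonRemoval:
    def call_frame(self, flags, samples=("a",)):
        idx = [f"P1:{1 + 2 * i}" for i in range(len(flags))]
        return pd.DataFrame(
            {s: list(flags) for s in samples}, index=idx, dtype=bool
        )

    def grid(self, n):
        return (
            np.array(["P1"] * n),
            np.array([1 + 2 * i for i in range(n)]),
            {"P1": 2},
        )

    def test_consecutive_calls_retained(self):
        called = self.call_frame([True, True, True, False])
        out = remove_singletons(called, *self.grid(4))
        assert out["a"].tolist() == [True, True, True, False]

    def test_isolated_call_removed(self):
        called = self.call_frame([False, True, False, False])
        out = remove_singletons(called, *self.grid(4))
        assert not out["a"].any()

    def test_replicate_rescue(self):
        called = self.call_frame([False, True, False], samples=("a", "b"))
        out = remove_singletons(
            called, *self.grid(3), replicate_groups={"a": ["b"], "b": ["a"]}
        )
        assert out["a"].tolist() == [False, True, False]

    def test_unknown_replicate_sample_rejected(self):
        called = self.call_frame([True])
        with pytest.raises(KeyError):
            remove_singletons(
                called, *self.grid(1), replicate_groups={"a": ["ghost"]}
            )

    def test_protein_boundary_not_a_neighbour(self):
        idx = ["P1:1", "P2:1"]
        called = pd.DataFrame({"a": [True, True]}, index=idx)
        out = remove_singletons(
            called,
            np.array(["P1", "P2"]),
            np.array([1, 1]),
            {"P1": 2, "P2": 2},
        )
        assert not out["a"].any()


class TestSegmentation:
    def test_homogeneous_chain_single_region(self):
        starts = [1, 3, 5, 7, 9]
        feats = np.full((5, 2), 4.0)
        regions = segment_epitopes("P1", starts, feats, tiling_step=2)
        assert len(regions) == 1
        assert regions[0].member_starts == starts

    def test_gap_splits_chains(self):
        starts = [1, 3, 5, 45, 47]
        feats = np.full((5, 1), 4.0)
        regions = segment_epitopes("P1", starts, feats, tiling_step=2)
        assert [r.member_starts for r in regions] == [[1, 3, 5], [45, 47]]

    def test_orthogonal_features_cut_at_boundary(self):
        # first 5 probes recognized only by mouse A, last 5 only by B
        starts = list(range(1, 20, 2))
        feats = np.zeros((10, 2))
        feats[:5, 0] = 8.0
        feats[5:, 1] = 8.0
        regions = segment_epitopes("P1", starts, feats, tiling_step=2)
        # the best single cut (exhaustive-search oracle) is the feature
        # boundary; recursion must produce it as a region border
        borders = {tuple(r.member_starts) for r in regions}
        assert any(r.member_starts[-1] == 9 for r in regions)
        assert any(r.member_starts[0] == 11 for r in regions)
        assert borders  # non-empty partition

    def test_best_single_cut_matches_exhaustive_oracle(self):
        from episcope.calling import _best_cut, _ssd

        rng = np.random.default_rng(23)
        x = rng.normal(size=(12, 3))
        cut, gain = _best_cut(x)
        total = _ssd(x)
        gains = [total - _ssd(x[:i]) - _ssd(x[i:]) for i in range(1, 12)]
        assert gain == pytest.approx(max(gains))
        assert cut == int(np.argmax(gains)) + 1

    def test_unordered_starts_rejected(self):
        with pytest.raises(ValueError):
            segment_epitopes("P1", [3, 1], np.zeros((2, 1)), tiling_step=2)


class TestMetaPvalues:
    def test_epitope_second_highest_beta_oracle(self):
        # members (0.001, 0.01, 0.02): Beta(2,2) CDF at the 2nd highest
        p = epitope_pvalue([0.001, 0.01, 0.02])
        closed_form = 3 * 0.01**2 - 2 * 0.01**3
        assert p == pytest.approx(closed_form, rel=1e-9)

    def test_epitope_pair_closed_form(self):
        p0 = 0.07
        assert epitope_pvalue([p0, p0]) == pytest.approx(2 * p0 - p0**2, rel=1e-12)

    def test_epitope_singleton_passthrough(self):
        assert epitope_pvalue([0.3]) == 0.3

    def test_epitope_empty_rejected(self):
        with pytest.raises(ValueError):
            epitope_pvalue([])

    @pytest.mark.parametrize("n", [2, 4, 7])
    def test_epitope_uniform_under_null(self, n):
        rng = np.random.default_rng(n)
        draws = np.array(
            [epitope_pvalue(rng.uniform(size=n)) for _ in range(5000)]
        )
        assert stats.kstest(draws, "uniform").pvalue > 0.01

    def test_protein_tippett_closed_form(self):
        assert protein_pvalue([0.01, 0.5, 0.9, 0.2, 0.7]) == pytest.approx(
            1 - 0.99**5, rel=1e-12
        )

    def test_protein_single_unchanged(self):
        assert protein_pvalue([0.123]) == pytest.approx(0.123)

    def test_protein_uniform_under_null(self):
        rng = np.random.default_rng(31)
        draws = np.array(
            [protein_pvalue(rng.uniform(size=5)) for _ in range(5000)]
        )
        assert stats.kstest(draws, "uniform").pvalue > 0.01


class TestConsensus:
    seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"  # 40 aa

    def region(self, starts):
        return EpitopeRegion(accession="P1", member_starts=list(starts))

    def test_five_members_step2_share_8aa(self):
        r = consensus_sequence(self.region([1, 3, 5, 7, 9]), self.seq)
        assert len(r.consensus_seq) == 8
        assert r.consensus_seq == self.seq[8:16]
        assert (r.consensus_start, r.consensus_end) == (9, 16)
        assert not r.no_common_core

    def test_single_member_full_probe(self):
        r = consensus_sequence(self.region([5]), self.seq)
        assert r.consensus_seq == self.seq[4:20]
        assert len(r.consensus_seq) == 16

    def test_nine_members_step2_no_common_core(self):
        r = consensus_sequence(self.region(list(range(1, 19, 2))), self.seq)
        assert r.no_common_core
        assert (r.aa_start, r.aa_end) == (1, 32)

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6, 7])
    def test_length_formula(self, k):
        starts = [1 + 2 * i for i in range(k)]
        r = consensus_sequence(self.region(starts), self.seq)
        assert len(r.consensus_seq) == 16 - 2 * (k - 1)


class TestKofN:
    def test_five_of_six(self):
        calls = pd.DataFrame(
            {f"m{i}": [i < 5] for i in range(6)}, index=["item"]
        )
        k, n = tabulate_k_of_n(calls, {f"m{i}": f"M{i}" for i in range(6)})
        assert (k["item"], n) == (5, 6)

    def test_all_false(self):
        calls = pd.DataFrame({"a": [False], "b": [False]}, index=["x"])
        k, n = tabulate_k_of_n(calls, {"a": "M1", "b": "M2"})
        assert (k["x"], n) == (0, 2)

    def test_replicate_pair_counts_once(self):
        calls = pd.DataFrame({"r1": [True], "r2": [True]}, index=["x"])
        k, n = tabulate_k_of_n(calls, {"r1": "M1", "r2": "M1"})
        assert (k["x"], n) == (1, 1)


class TestSummarize:
    def test_binning_and_empty(self):
        r = EpitopeRegion("P1", [1, 3, 5, 7, 9], consensus_seq="ABCDEFGH")
        r.tier = {"s": "moderate"}
        table = summarize_epitopes([r])
        row = table[(table.tier == "moderate")]
        assert row.iloc[0]["bin"] == "7-8"
        # nests into inclusive as well, but not restrictive
        assert set(table.tier) == {"inclusive", "moderate"}
        assert summarize_epitopes([]).empty
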