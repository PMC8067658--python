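"""Coincidence counters, classification, weighting and counter summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from extsim import (
    classify_counters,
    coincidence_counters,
    coincidence_threshold,
    delta,
    pair_counters,
    summarize,
    weight_functions,
)
from extsim.counters import (
    batch_summaries,
    coincidence_count_matrix,
    weight_vector,
)

from conftest import PAIR_A, PAIR_B, random_set


def naive_coincidence_counts(data: np.ndarray, subset) -> list[int]:
    """Independent per-position oracle: count positions with exactly k ones."""
    n = len(subset)
    counts = [0] * (n + 1)
    for pos in range(data.shape[1]):
        k = sum(int(data[i, pos]) for i in subset)
        counts[k] += 1
    return counts


class TestPairCounters:
    def test_worked_pair(self):
        pc = pair_counters(PAIR_A, PAIR_B)
        assert (pc.a, pc.b, pc.c, pc.d) == (2, 2, 1, 3)
        assert pc.p == 8

    def test_self_comparison(self, rng):
        x = (rng.random(40) < 0.4).astype(np.uint8)
        pc = pair_counters(x, x)
        assert pc.a == int(x.sum())
        assert pc.b == pc.c == 0
        assert pc.d == 40 - pc.a

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=60))
    @settings(derandomize=True, max_examples=50)
    def test_argument_swap_exchanges_b_and_c(self, bit_pairs):
        x = [p[0] for p in bit_pairs]
        y = [p[1] for p in bit_pairs]
        fwd, rev = pair_counters(x, y), pair_counters(y, x)
        assert (fwd.a, fwd.d) == (rev.a, rev.d)
        assert (fwd.b, fwd.c) == (rev.c, rev.b)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="lengths differ"):
            pair_counters([1, 0], [1, 0, 1])


class TestDeltaAndThreshold:
    @pytest.mark.parametrize("n,k,expected", [(2, 2, 2), (2, 1, 0), (4, 3, 2)])
    def test_indicator_values(self, n, k, expected):
        assert delta(n, k) == expected

    @given(st.integers(2, 20), st.data())
    @settings(derandomize=True, max_examples=50)
    def test_indicator_symmetric_in_k(self, n, data):
        k = data.draw(st.integers(0, n))
        assert delta(n, k) == delta(n, n - k)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            delta(4, 5)

    @pytest.mark.parametrize("n,mode,expected", [(4, "mod2", 0), (5, "mod2", 1), (2, "mod2", 0), (5, "ceil-half", 3)])
    def test_threshold_modes(self, n, mode, expected):
        assert coincidence_threshold(n, mode) == expected

    def test_fixed_threshold(self):
        assert coincidence_threshold(6, "fixed:2") == 2
        assert coincidence_threshold(6, 3) == 3
        with pytest.raises(ValueError):
            coincidence_threshold(4, "fixed:4")
        with pytest.raises(ValueError):
            coincidence_threshold(4, -1)


class TestClassification:
    @pytest.mark.parametrize(
        "n,gamma,one,zero,dis",
        [
            (2, 0, {2}, {0}, {1}),
            (4, 0, {3, 4}, {0, 1}, {2}),
            (5, 1, {4, 5}, {0, 1}, {2, 3}),
        ],
    )
    def test_known_partitions(self, n, gamma, one, zero, dis):
        cls = classify_counters(n, gamma)
        assert set(cls.one_sim_ks) == one
        assert set(cls.zero_sim_ks) == zero
        assert set(cls.dissim_ks) == dis

    @given(st.integers(2, 16), st.data())
    @settings(derandomize=True, max_examples=100)
    def test_three_sets_partition_k_range(self, n, data):
        gamma = data.draw(st.integers(0, n - 1))
        cls = classify_counters(n, gamma)
        ks = set(range(n + 1))
        assert cls.one_sim_ks | cls.zero_sim_ks | cls.dissim_ks == ks
        assert not cls.one_sim_ks & cls.zero_sim_ks
        assert not cls.one_sim_ks & cls.dissim_ks
        assert not cls.zero_sim_ks & cls.dissim_ks
        for k in cls.one_sim_ks:
            assert 2 * k - n > gamma
        for k in cls.zero_sim_ks:
            assert n - 2 * k > gamma
        for k in cls.dissim_ks:
            assert abs(2 * k - n) <= gamma


class TestCoincidenceCounters:
    def test_worked_pair_bridge(self, worked_pair):
        cc = coincidence_counters(worked_pair, [0, 1])
        assert cc.counts == (3, 3, 2)  # d, b+c, a

    def test_bridge_on_random_pairs(self, rng):
        for _ in range(20):
            fps = random_set(rng, 2, 37, rng.uniform(0.2, 0.8))
            pc = pair_counters(fps.data[0], fps.data[1])
            cc = coincidence_counters(fps, [0, 1])
            assert cc.counts == (pc.d, pc.b + pc.c, pc.a)

    def test_quad_set_column_sums(self, quad_set):
        cc = coincidence_counters(quad_set, [0, 1, 2, 3])
        assert cc.counts == (0, 1, 1, 1, 1)

    def test_duplicated_fingerprint(self, rng):
        x = (rng.random(25) < 0.5).astype(np.uint8)
        data = np.tile(x, (5, 1))
        cc = coincidence_counters(data, range(5))
        pop = int(x.sum())
        assert cc.counts[5] == pop and cc.counts[0] == 25 - pop
        assert sum(cc.counts[1:5]) == 0

    def test_order_invariance(self, rng):
        fps = random_set(rng, 6, 30)
        a = coincidence_counters(fps, [0, 2, 4])
        b = coincidence_counters(fps, [4, 0, 2])
        assert a == b

    def test_matches_naive_oracle_every_n(self, rng):
        fps = random_set(rng, 5, 20, 0.4)
        for n in range(2, 6):
            for subset in __import__("itertools").combinations(range(5), n):
                cc = coincidence_counters(fps, subset)
                assert list(cc.counts) == naive_coincidence_counts(fps.data, subset)
                assert cc.m == 20  # conservation

    @pytest.mark.parametrize("subset", [[0], [0, 0], [0, 9]])
    def test_invalid_subsets(self, subset, rng):
        fps = random_set(rng, 4, 10)
        with pytest.raises(ValueError):
            coincidence_counters(fps, subset)

    def test_batch_matrix_agrees_with_single_calls(self, rng):
        fps = random_set(rng, 8, 64)
        subsets = list(__import__("itertools").combinations(range(8), 3))
        mat = coincidence_count_matrix(fps, subsets)
        for row, subset in zip(mat, subsets):
            assert row.tolist() == list(coincidence_counters(fps, subset).counts)


class TestWeights:
    @pytest.mark.parametrize("scheme", ["fraction", "power2", "none"])
    @pytest.mark.parametrize("n", [2, 3, 4, 7])
    def test_normalization_boundaries(self, scheme, n):
        f_s, f_d = weight_functions(n, scheme)
        assert f_s(n) == pytest.approx(1.0)
        assert f_d(n % 2) == pytest.approx(1.0)

    def test_fraction_values_n4(self):
        f_s, f_d = weight_functions(4, "fraction")
        assert f_s(4) == 1.0 and f_s(2) == 0.5 and f_d(0) == 1.0

    def test_power2_values_n4(self):
        f_s, f_d = weight_functions(4, "power2")
        assert f_s(2) == 0.25

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="scheme"):
            weight_functions(4, "bogus")

    def test_weight_vector_in_unit_interval(self):
        for n in range(2, 10):
            cls = classify_counters(n, coincidence_threshold(n))
            w = weight_vector(cls, "fraction")
            assert ((w > 0) & (w <= 1)).all()


class TestSummarize:
    def test_quad_worked_example(self, quad_set):
        cc = coincidence_counters(quad_set, range(4))
        s = summarize(cc, classify_counters(4, 0))
        assert (s.w1s, s.w0s, s.wd) == (1.5, 0.5, 1.0)
        assert (s.u1s, s.u0s, s.ud) == (2, 1, 1)
        assert s.u1s + s.u0s + s.ud == s.m == 4

    def test_pair_weights_inert(self, worked_pair):
        cc = coincidence_counters(worked_pair, [0, 1])
        s = summarize(cc, classify_counters(2, 0))
        assert (s.w1s, s.w0s, s.wd) == (2.0, 3.0, 3.0)
        assert (s.u1s, s.u0s, s.ud) == (2, 3, 3)

    def test_identical_fingerprints_have_no_dissimilarity(self, rng):
        x = (rng.random(30) < 0.5).astype(np.uint8)
        cc = coincidence_counters(np.tile(x, (4, 1)), range(4))
        s = summarize(cc, classify_counters(4, 0))
        assert s.wd == s.ud == 0
        assert s.u1s + s.u0s == 30

    def test_weighting_inert_up_to_ternary(self, rng):
        # no effect of weighting for binary and ternary comparisons
        for n in (2, 3):
            for _ in range(10):
                fps = random_set(rng, n, 40, rng.uniform(0.2, 0.8))
                cc = coincidence_counters(fps, range(n))
                s = summarize(cc, classify_counters(n, coincidence_threshold(n)))
                assert (s.w1s, s.w0s, s.wd) == (s.u1s, s.u0s, s.ud)

    def test_inconsistent_n_rejected(self, quad_set):
        cc = coincidence_counters(quad_set, range(4))
        with pytest.raises(ValueError, match="inconsistent n"):
            summarize(cc, classify_counters(3, 1))

    def test_conservation_on_random_sets(self, rng):
        import itertools

        for _ in range(5):
            fps = random_set(rng, 6, 17, rng.uniform(0.1, 0.9))
            for n in range(2, 7):
                for subset in itertools.combinations(range(6), n):
                    cc = coincidence_counters(fps, subset)
                    s = summarize(cc, classify_counters(n, coincidence_threshold(n)))
                    assert s.u1s + s.u0s + s.ud == 17
                    assert 0 <= s.w1s <= s.u1s
                    assert 0 <= s.w0s <= s.u0s
                    assert 0 <= s.wd <= s.ud

    def test_batch_summaries_match_scalar_path(self, rng):
        import itertools

        fps = random_set(rng, 7, 33)
        subsets = list(itertools.combinations(range(7), 4))
        batch = batch_summaries(fps, subsets)
        cls = classify_counters(4, 0)
        for i, subset in enumerate(subsets):
            s = summarize(coincidence_counters(fps, subset), cls)
            assert batch.w1s[i] == pytest.approx(s.w1s)
            assert batch.w0s[i] == pytest.approx(s.w0s)
            assert batch.wd[i] == pytest.approx(s.wd)
            assert (batch.u1s[i], batch.u0s[i], batch.ud[i]) == (s.u1s, s.u0s, s.ud)
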