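"""I-Sim metrics: support, cosine, saturation, rescaling, RCC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rcf.network import InteractomeNetwork, build_iw_matrix, feature_vector, pair_key
from rcf.rcc import (RCCParams, SupportStats, cosine_similarity,
                     rescaling_coefficient, rcc_score, saturated_denominator,
                     score_all_pairs, support, support_stats,
                     _normal_cdf_series)

from conftest import (dense_cosine_scores, dense_iw, dense_rcc_scores,
                      dense_support_stats, random_network)


class TestSupport:
    def test_disjoint_closed_neighborhoods(self):
        assert support(np.array([1, 0, 0, 0]), np.array([0, 0, 1, 1])) == 0

    def test_identical_vectors(self):
        v = np.array([1, 1, 0, 1])
        assert support(v, v) == 3

    def test_adjacent_pair_counts_shared_plus_endpoints(self, toy6_network):
        # i,j adjacent with shared neighbors x and w -> support = 2 + 2
        iw = build_iw_matrix(toy6_network)
        yi = feature_vector(iw, "i")
        yj = feature_vector(iw, "j")
        assert support(yi, yj) == 4

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            support(np.ones(3), np.ones(4))


class TestCosine:
    def test_identical_rows(self):
        v = np.array([1, 1, 0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_rows(self):
        assert cosine_similarity(np.array([1, 0]), np.array([0, 1])) == 0.0

    def test_hand_arithmetic(self):
        # 2 ones vs 8 ones with 2 shared -> 2 / (sqrt(2)*sqrt(8)) = 0.5
        y_i = np.array([1, 1] + [0] * 8)
        y_j = np.array([1, 1] + [1] * 6 + [0, 0])
        assert cosine_similarity(y_i, y_j) == pytest.approx(0.5)


class TestSaturatedDenominator:
    @pytest.mark.parametrize("c_y", [1.0, 20.0, 30.0, 500.0])
    def test_monotone_non_decreasing_in_each_norm(self, c_y):
        assert (saturated_denominator(2, 2, c_y)
                <= saturated_denominator(2, 10, c_y)
                <= saturated_denominator(10, 10, c_y))

    @pytest.mark.parametrize("c_y", [5.0, 30.0])
    def test_bounded_by_saturation_ceiling(self, c_y):
        assert saturated_denominator(1e6, 1e6, c_y) <= c_y
        assert saturated_denominator(1e3, 1e3, c_y) == pytest.approx(c_y)

    def test_gap_shrunk_order_preserved(self):
        # equal support, one pair with a hub endpoint: saturated scores keep
        # the order of the plain cosine but with a strictly smaller gap
        n_ij, c_y = 2.0, 20.0
        lo = (math.sqrt(2), math.sqrt(3))   # both small neighborhoods
        hi = (math.sqrt(2), math.sqrt(60))  # one hub endpoint
        cos_lo = n_ij / (lo[0] * lo[1])
        cos_hi = n_ij / (hi[0] * hi[1])
        sat_lo = n_ij / saturated_denominator(*lo, c_y)
        sat_hi = n_ij / saturated_denominator(*hi, c_y)
        assert cos_hi < cos_lo and sat_hi < sat_lo  # order preserved
        assert (sat_lo - sat_hi) < (cos_lo - cos_hi)  # gap shrunk
        assert sat_lo > cos_lo and sat_hi > cos_hi  # values enlarged

    def test_non_positive_cy_rejected(self):
        with pytest.raises(ValueError):
            saturated_denominator(1, 1, 0.0)

    @given(st.floats(1, 50), st.floats(1, 50), st.floats(0.5, 100))
    @settings(max_examples=50, deadline=None)
    def test_positive_and_below_norm_product(self, x1, x2, c_y):
        g = saturated_denominator(x1, x2, c_y)
        assert 0 < g <= min(c_y, x1 * x2)


class TestSupportStats:
    def test_all_supports_equal(self):
        # single isolated edge: the only nonzero off-diagonal support is 2
        net = InteractomeNetwork(("a", "b"), frozenset({("a", "b")}))
        stats = support_stats(build_iw_matrix(net))
        assert stats.mu == 2.0 and stats.sigma2 == 0.0 and stats.n_y == 1

    def test_degenerate_network_rejected(self):
        net = InteractomeNetwork(("a", "b", "c"), frozenset())
        with pytest.raises(ValueError):
            support_stats(build_iw_matrix(net))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, 30, 0.12)
        stats = support_stats(build_iw_matrix(net))
        mu, sigma2, n_y = dense_support_stats(dense_iw(net))
        assert stats.mu == pytest.approx(mu, rel=1e-12)
        assert stats.sigma2 == pytest.approx(sigma2, rel=1e-12)
        assert stats.n_y == n_y


class TestRescalingCoefficient:
    def test_mean_support_maps_to_half(self):
        stats = SupportStats(mu=3.0, sigma2=4.0, n_y=10)
        assert rescaling_coefficient(3.0, stats) == pytest.approx(0.5)

    def test_cdf_limits(self):
        stats = SupportStats(mu=3.0, sigma2=4.0, n_y=10)
        assert rescaling_coefficient(1e6, stats) == pytest.approx(1.0)
        assert rescaling_coefficient(-1e6, stats) == pytest.approx(0.0)

    def test_phi_of_one(self):
        stats = SupportStats(mu=3.0, sigma2=4.0, n_y=10)
        assert rescaling_coefficient(5.0, stats) == pytest.approx(
            0.8413447460685429, rel=1e-9)

    def test_strictly_increasing(self):
        stats = SupportStats(mu=3.0, sigma2=4.0, n_y=10)
        vals = [rescaling_coefficient(n, stats) for n in range(0, 12)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_series_mode_cross_checks_exact(self):
        stats = SupportStats(mu=5.0, sigma2=9.0, n_y=10)
        for n in np.linspace(-1, 11, 13):
            exact = rescaling_coefficient(n, stats, method="exact")
            series = rescaling_coefficient(n, stats, method="series")
            assert series == pytest.approx(exact, abs=1e-9)

    def test_degenerate_sigma_step_function(self, caplog):
        stats = SupportStats(mu=2.0, sigma2=0.0, n_y=3)
        assert rescaling_coefficient(1.0, stats) == 0.0
        assert rescaling_coefficient(2.0, stats) == 0.5
        assert rescaling_coefficient(3.0, stats) == 1.0

    def test_series_helper_is_maclaurin_cdf(self):
        from scipy.stats import norm
        z = np.linspace(-2, 2, 9)
        assert np.allclose(_normal_cdf_series(z), norm.cdf(z), atol=1e-10)


class TestRCCScore:
    def test_zero_support_scores_zero(self):
        stats = SupportStats(mu=2.0, sigma2=1.0, n_y=5)
        y_i = np.array([1, 0, 0, 0])
        y_j = np.array([0, 0, 1, 1])
        for d in (0.0, 2.0, 5.0):
            assert rcc_score(y_i, y_j, RCCParams(30.0, d), stats) == 0.0

    def test_d_zero_reduces_to_saturated_cosine(self, toy6_network):
        iw = build_iw_matrix(toy6_network)
        stats = support_stats(iw)
        params = RCCParams(c_y=30.0, d=0.0)
        for a, b in [("i", "j"), ("i", "x"), ("x", "w")]:
            y_a, y_b = feature_vector(iw, a), feature_vector(iw, b)
            n_ab = support(y_a, y_b)
            expected = n_ab / saturated_denominator(
                np.linalg.norm(y_a), np.linalg.norm(y_b), 30.0)
            assert rcc_score(y_a, y_b, params, stats) == pytest.approx(
                expected, rel=1e-12)

    def test_strictly_decreasing_in_d(self, toy6_network):
        # r in (0,1), so larger exponents shrink the score
        iw = build_iw_matrix(toy6_network)
        stats = support_stats(iw)
        y_i, y_j = feature_vector(iw, "i"), feature_vector(iw, "j")
        scores = [rcc_score(y_i, y_j, RCCParams(30.0, d), stats)
                  for d in (0.0, 2.0, 5.0, 8.0)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_strictly_increasing_in_support_at_fixed_norms(self):
        # synthetic vectors with constant norms and growing overlap
        stats = SupportStats(mu=3.0, sigma2=2.0, n_y=20)
        params = RCCParams()
        length = 12
        scores = []
        for overlap in (1, 2, 3, 4, 5):
            y_i = np.zeros(length); y_j = np.zeros(length)
            y_i[:5] = 1          # norm sqrt(5)
            y_j[5 - overlap:10 - overlap] = 1  # norm sqrt(5), overlap ones shared
            assert support(y_i, y_j) == overlap
            scores.append(rcc_score(y_i, y_j, params, stats))
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_symmetry(self, toy6_network):
        iw = build_iw_matrix(toy6_network)
        stats = support_stats(iw)
        params = RCCParams()
        for a, b in [("i", "j"), ("i", "z"), ("x", "w")]:
            y_a, y_b = feature_vector(iw, a), feature_vector(iw, b)
            assert rcc_score(y_a, y_b, params, stats) == rcc_score(
                y_b, y_a, params, stats)


class TestScoreAllPairs:
    def test_observed_edges_on_single_edge(self):
        net = InteractomeNetwork(("a", "b"), frozenset({("a", "b")}))
        scores = score_all_pairs(build_iw_matrix(net),
                                 candidates="observed-edges")
        assert set(scores.scores) == {("a", "b")}

    def test_star_graph_candidates(self):
        # K_{1,k}: every leaf pair shares the hub, plus the k hub-leaf edges
        k = 5
        proteins = ("hub",) + tuple(f"l{i}" for i in range(k))
        edges = frozenset(pair_key("hub", f"l{i}") for i in range(k))
        net = InteractomeNetwork(proteins, edges)
        scores = score_all_pairs(build_iw_matrix(net),
                                 candidates="common-neighbor-pairs")
        assert len(scores) == k * (k - 1) // 2 + k

    def test_pair_cap_guard(self, toy6_network):
        iw = build_iw_matrix(toy6_network)
        with pytest.raises(ValueError, match="common-neighbor-pairs"):
            score_all_pairs(iw, candidates="all-pairs", pair_cap=3)

    def test_unknown_strategy_and_metric(self, toy6_network):
        iw = build_iw_matrix(toy6_network)
        with pytest.raises(ValueError):
            score_all_pairs(iw, candidates="everything")
        with pytest.raises(ValueError):
            score_all_pairs(iw, metric="jaccard")

    @pytest.mark.parametrize("seed", range(8))
    def test_sparse_equals_dense_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_network(rng, 40, 0.08)
        if net.n_edges == 0:
            pytest.skip("degenerate draw")
        iw = build_iw_matrix(net)
        params = RCCParams()
        got = score_all_pairs(iw, params, candidates="common-neighbor-pairs")
        want = dense_rcc_scores(net, params)
        assert set(got.scores) == set(want)
        for pair, val in want.items():
            assert got.scores[pair] == pytest.approx(val, rel=1e-12)
        got_cos = score_all_pairs(iw, candidates="common-neighbor-pairs",
                                  metric="cosine")
        want_cos = dense_cosine_scores(net)
        for pair, val in want_cos.items():
            assert got_cos.scores[pair] == pytest.approx(val, rel=1e-12)

    def test_all_pairs_equals_common_neighbor_restriction(self):
        rng = np.random.default_rng(7)
        net = random_network(rng, 25, 0.1)
        iw = build_iw_matrix(net)
        sparse = score_all_pairs(iw, candidates="common-neighbor-pairs")
        full = score_all_pairs(iw, candidates="all-pairs", pair_cap=10_000)
        nonzero_full = {p: s for p, s in full.scores.items()
                        if full.support(*p) > 0}
        assert nonzero_full == sparse.scores
        assert all(s == 0.0 for p, s in full.scores.items()
                   if full.support(*p) == 0)


class TestParams:
    def test_defaults(self):
        p = RCCParams()
        assert p.c_y == 30.0 and p.d == 5.0

    @pytest.mark.parametrize("c_y,d", [(0.0, 5.0), (-1.0, 5.0), (30.0, -0.1)])
    def test_invalid_rejected(self, c_y, d):
        with pytest.raises(ValueError):
            RCCParams(c_y, d)
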