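import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskfix import (
    EmptyParentSetError,
    Power,
    Proportional,
    Sigmoid,
    TruncationAbsolute,
    TruncationRank,
    power_weights,
    proportional_weights,
    selection_from_dict,
    sigmoid_weights,
    truncation_absolute_weights,
    truncation_rank_weights,
)
from riskfix.selection import truncation_count

payoff_vectors = st.lists(
    st.floats(0.1, 1e4), min_size=2, max_size=30
).map(np.array)


class TestProportional:
    def test_worked_examples(self):
        # the two-player parenthood probabilities 10/(10+5) and 10/(10+15)
        np.testing.assert_allclose(proportional_weights([10, 5]), [2 / 3, 1 / 3])
        np.testing.assert_allclose(proportional_weights([10, 15]), [0.4, 0.6])

    def test_equal_payoffs_uniform(self):
        np.testing.assert_allclose(proportional_weights([7.0] * 5), [0.2] * 5)

    def test_negative_payoff_rejected(self):
        with pytest.raises(ValueError):
            proportional_weights([5, -1.0])

    def test_zero_payoff_gets_zero_weight(self):
        np.testing.assert_allclose(proportional_weights([0.0, 10.0]), [0.0, 1.0])


class TestPower:
    def test_arithmetic_example(self):
        np.testing.assert_allclose(power_weights([5, 15], z=2), [0.1, 0.9])

    @given(payoff_vectors)
    @settings(max_examples=100, deadline=None)
    def test_z1_is_proportional_bit_exact(self, payoffs):
        assert np.array_equal(power_weights(payoffs, 1.0), proportional_weights(payoffs))
        assert np.array_equal(
            Power(1.0).weights(payoffs), Proportional().weights(payoffs)
        )

    def test_z0_uniform(self):
        np.testing.assert_allclose(power_weights([5, 10, 15], 0.0), [1 / 3] * 3)


class TestSigmoid:
    def test_inflection_value_is_half(self):
        # the individual whose normalized payoff equals beta maps to 0.5
        w = 1.0 / (1.0 + np.exp(-10 * (np.array([1.0, 2 / 3]) - 2 / 3)))
        np.testing.assert_allclose(
            sigmoid_weights([15.0, 10.0], xi=10, beta=2 / 3), w / w.sum()
        )

    def test_direct_evaluation(self):
        payoffs = np.array([15.0, 10.0, 5.0])
        pn = payoffs / 15.0
        t = 1.0 / (1.0 + np.exp(-10.0 * (pn - 2 / 3)))
        np.testing.assert_allclose(
            sigmoid_weights(payoffs, 10.0, 2 / 3), t / t.sum()
        )
        assert t[1] == pytest.approx(0.5)

    @given(payoff_vectors, st.floats(1.0, 50.0), st.floats(0.05, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, payoffs, xi, beta):
        w1 = sigmoid_weights(payoffs, xi, beta)
        w2 = sigmoid_weights(17.3 * payoffs, xi, beta)
        np.testing.assert_allclose(w1, w2, rtol=1e-9)

    def test_steepness_limit_approaches_step(self):
        payoffs = np.array([15.0, 10.0, 5.0])
        w = sigmoid_weights(payoffs, xi=5000.0, beta=2 / 3 + 0.01)
        np.testing.assert_allclose(w, [1.0, 0.0, 0.0], atol=1e-9)


class TestTruncationRank:
    def test_forced_by_rank(self, rng):
        w = truncation_rank_weights([15, 15, 10, 5], t=0.5, rng=rng)
        np.testing.assert_allclose(w, [0.5, 0.5, 0, 0])

    def test_everyone_reproduces_at_t1(self, rng):
        np.testing.assert_allclose(
            truncation_rank_weights([5, 10, 15], 1.0, rng), [1 / 3] * 3
        )

    def test_boundary_tie_broken_uniformly(self, rng):
        # (15, 10, 10, 5), T=0.5: slot 1 always the 15; the two tied 10s
        # share the second slot half the time each
        hits = np.zeros(4)
        n = 4000
        for _ in range(n):
            hits += truncation_rank_weights([15, 10, 10, 5], 0.5, rng) > 0
        assert hits[0] == n and hits[3] == 0
        se = np.sqrt(0.25 * n)
        assert abs(hits[1] - n / 2) < 3 * se
        assert abs(hits[2] - n / 2) < 3 * se

    @given(payoff_vectors, st.floats(0.05, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_exactly_k_winners_each_one_over_k(self, payoffs, t):
        w = truncation_rank_weights(payoffs, t, np.random.default_rng(0))
        k = truncation_count(len(payoffs), t)
        assert np.count_nonzero(w) == k
        np.testing.assert_allclose(w[w > 0], 1.0 / k)

    def test_count_rounds_half_up_with_floor_one(self):
        assert truncation_count(100, 0.5) == 50
        assert truncation_count(100, 0.47) == 47
        assert truncation_count(10, 0.01) == 1
        assert truncation_count(3, 0.5) == 2  # round-half-up


class TestTruncationAbsolute:
    def test_threshold_examples(self):
        np.testing.assert_allclose(
            truncation_absolute_weights([5, 10, 15], 10.0), [0, 0.5, 0.5]
        )
        np.testing.assert_allclose(
            truncation_absolute_weights([5, 10, 15], 0.0), [1 / 3] * 3
        )

    def test_empty_parent_set_errors(self):
        with pytest.raises(EmptyParentSetError):
            truncation_absolute_weights([5, 5, 5], 10.0)

    def test_uniform_fallback_policy(self):
        w = TruncationAbsolute(10.0, on_empty="uniform").weights([5.0, 5.0])
        np.testing.assert_allclose(w, [0.5, 0.5])


SCHEMES = [
    Proportional(),
    Power(1.7),
    Power(0.6),
    Sigmoid(10.0, 2 / 3),
    TruncationRank(0.4),
    TruncationAbsolute(0.05),
]


@pytest.mark.parametrize("scheme", SCHEMES)
@given(payoffs=payoff_vectors)
@settings(max_examples=60, deadline=None)
def test_weights_are_probability_distributions(scheme, payoffs):
    w = scheme.weights(payoffs, np.random.default_rng(1))
    assert np.all(w >= 0)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize(
    "scheme", [Proportional(), Power(1.7), Sigmoid(10.0, 2 / 3), TruncationAbsolute(0.05)],
    ids=lambda s: s.kind,
)
@given(payoffs=payoff_vectors, seed=st.integers(0, 2**16))
@settings(max_examples=60, deadline=None)
def test_permutation_equivariance(scheme, payoffs, seed):
    perm = np.random.default_rng(seed).permutation(len(payoffs))
    w = scheme.weights(payoffs, np.random.default_rng(0))
    w_perm = scheme.weights(payoffs[perm], np.random.default_rng(0))
    np.testing.assert_allclose(w_perm, w[perm], rtol=1e-12, atol=1e-15)


def test_truncation_rank_eligibility_distribution_is_equivariant(rng):
    # deterministic weights are not permutation-equivariant draw-by-draw
    # (tie-breaking is random) but eligibility frequencies are
    payoffs = np.array([10.0, 10.0, 5.0, 10.0])
    freq = np.zeros(4)
    n = 3000
    for _ in range(n):
        freq += truncation_rank_weights(payoffs, 0.5, rng) > 0
    freq /= n
    assert freq[2] == 0.0
    se = np.sqrt((2 / 3) * (1 / 3) / n)
    np.testing.assert_allclose(freq[[0, 1, 3]], 2 / 3, atol=3 * se)


class TestSelectionFromDict:
    def test_round_trip_kinds(self):
        assert selection_from_dict({"kind": "proportional"}) == Proportional()
        assert selection_from_dict({"kind": "power", "z": 1.26}) == Power(1.26)
        assert selection_from_dict(
            {"kind": "sigmoid", "xi": 10.0, "beta": 0.5}
        ) == Sigmoid(10.0, 0.5)
        assert selection_from_dict({"kind": "truncation_rank", "t": 0.2}) == TruncationRank(0.2)

    def test_strict_validation(self):
        with pytest.raises(ValueError, match="extraneous"):
            selection_from_dict({"kind": "proportional", "z": 2})
        with pytest.raises(ValueError, match="missing"):
            selection_from_dict({"kind": "power"})
        with pytest.raises(ValueError, match="unknown selection kind"):
            selection_from_dict({"kind": "rank"})
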