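import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from infogrowth import (
    EnvironmentSpec,
    expected_kl_multinomial,
    growth_rate_general,
    growth_rate_multinomial,
    invert_growth_rate,
    kelly_decomposition,
    mutual_information_multinomial,
    nats_to_bits,
    sample,
    to_joint,
    volatility_multinomial,
)
from infogrowth.learning import degenerate_pattern


def oracle_growth_rate(l: int, p: float, x: float) -> float:
    """Independent double-sum oracle: sum_{e,s} P(e,s) log[B(e|s) w_e]."""
    joint = to_joint(EnvironmentSpec(l, p)).matrix
    policy = degenerate_pattern(l, x)  # symmetric, so row/column convention agrees
    total = 0.0
    for e in range(l):
        for s in range(l):
            total += joint[e, s] * math.log(policy[e, s] * l)
    return total


def oracle_mutual_information(l: int, p: float) -> float:
    joint = to_joint(EnvironmentSpec(l, p)).matrix
    total = 0.0
    for e in range(l):
        for s in range(l):
            if joint[e, s] > 0:
                total += joint[e, s] * math.log(joint[e, s] * l * l)
    return total


PARAM_GRID = [(l, p, x) for l in (2, 3, 5, 10) for p in (0.2, 0.5, 0.7, 0.9) for x in (0.15, 0.5, 0.7, 0.85)]


class TestClosedForms:
    def test_mutual_information_anchors(self):
        assert mutual_information_multinomial(2, 0.5) == pytest.approx(0.0, abs=1e-15)
        # noiseless limit: 1 bit of environmental entropy
        assert nats_to_bits(mutual_information_multinomial(2, 1.0)) == pytest.approx(1.0)
        assert mutual_information_multinomial(2, 0.7) == pytest.approx(
            oracle_mutual_information(2, 0.7), abs=1e-14
        )
        assert mutual_information_multinomial(2, 0.7) == pytest.approx(0.0823, abs=5e-5)

    @pytest.mark.parametrize("l,p,x", PARAM_GRID)
    def test_growth_rate_matches_double_sum_oracle(self, l, p, x):
        assert growth_rate_multinomial(l, p, x) == pytest.approx(
            oracle_growth_rate(l, p, x), abs=1e-12
        )

    @pytest.mark.parametrize("l,p,x", PARAM_GRID)
    def test_information_decomposition_identity(self, l, p, x):
        gamma = growth_rate_multinomial(l, p, x)
        mi = mutual_information_multinomial(l, p)
        ekl = expected_kl_multinomial(l, p, x)
        assert gamma == pytest.approx(mi - ekl, abs=1e-12)
        assert ekl >= 0.0
        assert gamma <= mi + 1e-12

    def test_expected_kl_anchors(self):
        assert expected_kl_multinomial(2, 0.7, 0.7) == 0.0
        # at x = 1/l the rate is zero, so the penalty equals the full information
        assert expected_kl_multinomial(2, 0.7, 0.5) == pytest.approx(
            mutual_information_multinomial(2, 0.7), abs=1e-12
        )
        assert expected_kl_multinomial(2, 0.7, 0.4) > 0

    def test_growth_rate_zero_at_independence(self):
        assert growth_rate_multinomial(2, 0.7, 0.5) == pytest.approx(0.0, abs=1e-15)

    def test_growth_rate_maximized_at_x_equals_p(self):
        xs = np.linspace(1e-6, 1 - 1e-6, 200001)
        gammas = [growth_rate_multinomial(2, 0.7, x) for x in xs]
        assert xs[int(np.argmax(gammas))] == pytest.approx(0.7, abs=1e-5)

    def test_infinity_sentinels(self):
        assert growth_rate_multinomial(2, 0.7, 0.0) == -math.inf
        assert expected_kl_multinomial(2, 0.7, 1.0) == math.inf
        assert volatility_multinomial(2, 0.7, 0.0) == math.inf


class TestVolatility:
    @pytest.mark.parametrize("l,p", [(2, 0.7), (3, 0.5), (5, 0.9)])
    def test_zero_at_uniform_allocation(self, l, p):
        assert volatility_multinomial(l, p, 1.0 / l) == pytest.approx(0.0, abs=1e-15)

    def test_monotone_away_from_uniform(self):
        left = [volatility_multinomial(2, 0.7, x) for x in (0.4, 0.3, 0.2)]
        right = [volatility_multinomial(2, 0.7, x) for x in (0.6, 0.7, 0.8)]
        assert left == sorted(left) and right == sorted(right)

    @pytest.mark.parametrize("x", [0.3, 0.65, 0.9])
    def test_uncertain_environment_is_most_volatile(self, x):
        assert volatility_multinomial(2, 0.5, x) >= volatility_multinomial(2, 0.9, x)

    def test_monte_carlo_moments(self, env27, rng):
        """Per-bet log returns sampled from the environment reproduce the
        closed-form mean and SD."""
        n, x = 10**5, 0.7
        e, s = sample(env27, n, rng)
        policy = degenerate_pattern(2, x)
        logret = np.log(policy[s - 1, e - 1] * 2.0)
        gamma = growth_rate_multinomial(2, 0.7, x)
        sigma = volatility_multinomial(2, 0.7, x)
        assert abs(logret.mean() - gamma) < 4 * sigma / np.sqrt(n)
        m4 = ((logret - gamma) ** 4).mean()
        se_var = np.sqrt((m4 - sigma**4) / n)
        assert abs(logret.var() - sigma**2) < 4 * se_var


class TestGeneralCalculator:
    def test_true_conditional_reaches_mutual_information(self, joint27):
        policy = joint27.conditional_given_signal()
        assert growth_rate_general(joint27, policy) == pytest.approx(
            mutual_information_multinomial(2, 0.7), abs=1e-12
        )

    def test_uniform_policy_breaks_even_under_fair_odds(self, joint27):
        policy = np.full((2, 2), 0.5)
        assert growth_rate_general(joint27, policy) == pytest.approx(0.0, abs=1e-15)

    def test_zero_mass_on_live_event_ruins(self, joint27):
        policy = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert growth_rate_general(joint27, policy) == -math.inf

    def test_shape_mismatch(self, joint27):
        with pytest.raises(ValueError):
            growth_rate_general(joint27, np.full((3, 3), 1 / 3))

    def test_custom_odds(self, joint27):
        # doubling all odds adds log 2 to the rate
        policy = joint27.conditional_given_signal()
        base = growth_rate_general(joint27, policy)
        boosted = growth_rate_general(joint27, policy, odds=np.array([4.0, 4.0]))
        assert boosted == pytest.approx(base + math.log(2), abs=1e-12)


class TestKellyDecomposition:
    def test_perfect_belief(self, joint27):
        gs = kelly_decomposition(joint27, joint27.conditional_given_signal())
        assert gs.expected_kl == pytest.approx(0.0, abs=1e-14)
        assert gs.gamma == pytest.approx(gs.mutual_info, abs=1e-12)

    def test_independent_environment_cannot_grow(self):
        joint = to_joint(EnvironmentSpec(2, 0.5))
        gs = kelly_decomposition(joint, degenerate_pattern(2, 0.6))
        assert gs.mutual_info == pytest.approx(0.0, abs=1e-14)
        assert gs.gamma <= 1e-14

    @pytest.mark.parametrize("l,p,x", PARAM_GRID)
    def test_agrees_with_closed_form_and_general_route(self, l, p, x):
        joint = to_joint(EnvironmentSpec(l, p))
        X = degenerate_pattern(l, x)
        gs = kelly_decomposition(joint, X)
        assert gs.gamma == pytest.approx(growth_rate_multinomial(l, p, x), abs=1e-10)
        assert gs.gamma == pytest.approx(growth_rate_general(joint, X), abs=1e-10)
        assert gs.sigma == pytest.approx(volatility_multinomial(l, p, x), abs=1e-10)

    def test_zero_belief_mass_signalled(self, joint27):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        gs = kelly_decomposition(joint27, X)
        assert gs.expected_kl == math.inf and gs.gamma == -math.inf


class TestInversion:
    def test_maximum_maps_to_p_on_both_branches(self):
        mi = mutual_information_multinomial(2, 0.7)
        assert invert_growth_rate(2, 0.7, mi, "conservative") == pytest.approx(0.7)
        assert invert_growth_rate(2, 0.7, mi, "aggressive") == pytest.approx(0.7)

    def test_known_conservative_solution(self):
        x = invert_growth_rate(2, 0.7, 0.03, "conservative")
        assert x == pytest.approx(0.54, abs=0.005)
        assert 0.5 < x <= 0.7

    @given(frac=st.floats(1e-6, 1 - 1e-6), branch=st.sampled_from(["conservative", "aggressive"]))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, frac, branch):
        mi = mutual_information_multinomial(2, 0.7)
        target = frac * mi
        x = invert_growth_rate(2, 0.7, target, branch)
        assert growth_rate_multinomial(2, 0.7, x) == pytest.approx(target, abs=1e-12)
        if branch == "conservative":
            assert 0.5 < x <= 0.7
        else:
            assert 0.7 <= x < 1.0

    def test_branch_contract_and_errors(self):
        mi = mutual_information_multinomial(2, 0.7)
        with pytest.raises(ValueError):
            invert_growth_rate(2, 0.7, mi * 1.01)
        with pytest.raises(ValueError):
            invert_growth_rate(2, 0.7, 0.0)
        with pytest.raises(ValueError):
            invert_growth_rate(2, 0.7, 0.03, branch="bold")

    def test_two_roots_of_gamma(self):
        """gamma has exactly its trivial root at 1/l and one upper root."""
        from infogrowth.infotheory import _upper_root

        upper = _upper_root(2, 0.7)
        assert growth_rate_multinomial(2, 0.7, upper) == pytest.approx(0.0, abs=1e-12)
        assert upper > 0.7
        xs = np.linspace(0.501, upper - 1e-6, 2000)
        assert all(growth_rate_multinomial(2, 0.7, x) > 0 for x in xs)
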