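"""The sigma rule, critical thresholds, and containment-order comparisons."""

import math
from fractions import Fraction as F

import pytest
from hypothesis import given
from hypothesis import strategies as st

import graphgames as gg
from graphgames.coefficients import (
    cycle_coefficients,
    cycle_overlapping_coefficients,
    normalize,
    regular_graph_coefficients,
    wellmixed_coefficients,
)
from graphgames.games import (
    MultiplayerGame,
    game_from_pairwise,
    linear_game,
    swap_strategies,
    vd_cost_sharing,
    volunteers_dilemma,
)
from graphgames.selection import (
    containment_compare,
    critical_bc_vd,
    critical_bc_vd_cs,
    is_favored,
    linear_condition,
    pairwise_condition,
    sigma_rule_lhs,
    sign_changes,
)

INF = math.inf

finite_payoffs = st.lists(
    st.floats(min_value=-20, max_value=20, allow_nan=False), min_size=3, max_size=3
)


class TestSigmaRule:
    def test_large_cycle_boundary_condition(self):
        # on the large cycle the rule reads a1 + a2 > b1 + b0
        sc = cycle_coefficients(INF)
        game = MultiplayerGame(a=[9, 2, 5], b=[1, 3, 7])
        assert sigma_rule_lhs(sc, game) == F(2 + 5 - 3 - 1, 2)

    def test_zero_game_is_boundary(self):
        sc = wellmixed_coefficients(INF, 3)
        verdict = is_favored(sc, MultiplayerGame(a=[0, 0, 0], b=[0, 0, 0]))
        assert not verdict.favored and verdict.boundary

    def test_pareto_dominant_mutual_cooperation_payoff_decides(self):
        # (a1 + a2 - b1 - b0)/2 = (0 + 5 - 1 - 1)/2 = 3/2 on the large cycle
        sc = cycle_coefficients(INF)
        verdict = is_favored(sc, MultiplayerGame(a=[0, 0, 5], b=[1, 1, 1]))
        assert verdict.lhs == F(3, 2) and verdict.favored

    def test_strictly_dominated_strategy_can_be_favored_on_cycle(self):
        # a_j < b_j for every j, yet the cluster-boundary rule favors A
        # because the mutual-cooperation payoff a_2 exceeds b_0 + (b_1 - a_1)
        sc = cycle_coefficients(INF)
        game = MultiplayerGame(a=[0, 0.9, 2.0], b=[1, 1, 2.1])
        assert all(a < b for a, b in zip(game.a, game.b))
        assert is_favored(sc, game).favored

    def test_dominated_strategy_never_favored_well_mixed(self):
        sc = wellmixed_coefficients(50, 3)
        game = MultiplayerGame(a=[0, 0, 5], b=[1, 1, 6])
        assert not is_favored(sc, game).favored

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            sigma_rule_lhs(cycle_coefficients(INF), volunteers_dilemma(3, 1, 4))

    @given(finite_payoffs, finite_payoffs, finite_payoffs, finite_payoffs)
    def test_linearity_in_payoffs(self, a1, b1, a2, b2):
        sc = regular_graph_coefficients(3)
        sc = normalize([float(s) for s in sc.sigma])
        g1 = MultiplayerGame(a=a1 + [0.0], b=b1 + [0.0])
        g2 = MultiplayerGame(a=a2 + [0.0], b=b2 + [0.0])
        gsum = MultiplayerGame(
            a=[x + y for x, y in zip(g1.a, g2.a)],
            b=[x + y for x, y in zip(g1.b, g2.b)],
        )
        lhs = sigma_rule_lhs(sc, gsum)
        assert lhs == pytest.approx(
            sigma_rule_lhs(sc, g1) + sigma_rule_lhs(sc, g2), abs=1e-9
        )

    @given(finite_payoffs, finite_payoffs)
    def test_swap_antisymmetry_under_uniform_coefficients(self, a, b):
        sc = wellmixed_coefficients(INF, 3)
        game = MultiplayerGame(a=a, b=b)
        assert sigma_rule_lhs(sc, swap_strategies(game)) == pytest.approx(
            -float(sigma_rule_lhs(sc, game)), abs=1e-9
        )


class TestVDThresholds:
    def test_large_cycle_thresholds(self):
        sc = cycle_coefficients(INF)
        assert critical_bc_vd(sc) == 2
        assert critical_bc_vd_cs(sc) == F(5, 6)

    def test_finite_cycle_closed_forms(self):
        for N in (4, 10, 100):
            sc = cycle_coefficients(N)
            assert critical_bc_vd(sc) == F(2 * (N - 2), N - 3)
            assert critical_bc_vd_cs(sc) == F(5 * N - 6, 6 * (N - 3))

    def test_wellmixed_thresholds(self):
        k = 5
        sc = wellmixed_coefficients(INF, k + 1)
        assert critical_bc_vd(sc) == k + 1
        assert critical_bc_vd_cs(sc) == sum(F(1, j + 1) for j in range(k + 1))
        assert critical_bc_vd_cs(wellmixed_coefficients(INF, 3)) == F(11, 6)

    def test_vanishing_top_coefficient_means_unreachable_threshold(self):
        sc = normalize([1, 1, 0])
        assert critical_bc_vd(sc) == math.inf

    def test_favored_on_either_side_of_large_cycle_threshold(self):
        sc = cycle_coefficients(INF)
        assert is_favored(sc, volunteers_dilemma(3, 1, 3)).favored
        assert not is_favored(sc, volunteers_dilemma(1.5, 1, 3)).favored
        boundary = is_favored(sc, volunteers_dilemma(2, 1, 3))
        assert boundary.boundary and not boundary.favored

    @pytest.mark.parametrize(
        "sc",
        [cycle_coefficients(17), regular_graph_coefficients(4),
         wellmixed_coefficients(40, 5)],
        ids=["cycle", "regular", "wellmixed"],
    )
    @pytest.mark.parametrize("family,threshold_fn",
                             [(volunteers_dilemma, critical_bc_vd),
                              (vd_cost_sharing, critical_bc_vd_cs)])
    def test_threshold_matches_bisection_root(self, sc, family, threshold_fn):
        """The closed-form threshold is the sign-change root of the sigma rule."""
        d = sc.d
        lo, hi = 1e-6, 1e6
        def lhs(bc):
            return float(sigma_rule_lhs(sc, family(bc, 1, d)))
        assert lhs(lo) < 0 < lhs(hi)
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if lhs(mid) > 0:
                hi = mid
            else:
                lo = mid
        assert 0.5 * (lo + hi) == pytest.approx(float(threshold_fn(sc)), abs=1e-9)


class TestReducedConditions:
    def test_donation_game_threshold_is_k(self):
        k = 3
        # donation game: alpha = B-C, beta = -C, gamma = B, delta = 0; C = 1
        assert not pairwise_condition(3.0 - 1, -1.0, 3.0, 0.0, k)  # B/C = k: boundary
        assert pairwise_condition(3.5 - 1, -1.0, 3.5, 0.0, k)
        assert not pairwise_condition(2.5 - 1, -1.0, 2.5, 0.0, k)

    def test_symmetric_game_is_boundary(self):
        assert not pairwise_condition(2, 5, 5, 2, 4)

    def test_linear_condition_reduces_to_bc_gt_k(self):
        assert linear_condition(3.01, 1, 0, 3)
        assert not linear_condition(3.0, 1, 0, 3)

    def test_linear_condition_large_k_needs_d_above_2c(self):
        k = 10_000
        assert linear_condition(0, 1, 2.01, k)
        assert not linear_condition(0, 1, 1.99, k)

    @given(
        st.tuples(*[st.floats(min_value=-5, max_value=5, allow_nan=False)] * 4),
        st.integers(min_value=3, max_value=12),
    )
    def test_pairwise_condition_agrees_with_full_sigma_rule(self, params, k):
        alpha, beta, gamma, delta = params
        sc = regular_graph_coefficients(k)
        game = game_from_pairwise(alpha, beta, gamma, delta, k)
        lhs = float(sigma_rule_lhs(sc, game))
        reduced = (k + 1) * alpha + (k - 1) * beta - (k - 1) * gamma - (k + 1) * delta
        if abs(reduced) > 1e-9:
            assert (lhs > 0) == (reduced > 0)

    @given(
        st.tuples(*[st.floats(min_value=-5, max_value=5, allow_nan=False)] * 3),
        st.integers(min_value=3, max_value=12),
    )
    def test_linear_condition_agrees_with_full_sigma_rule(self, params, k):
        B, C, D = params
        sc = regular_graph_coefficients(k)
        lhs = float(sigma_rule_lhs(sc, linear_game(B, C, D, k)))
        reduced = 2 * B + D * (k + 1) - 2 * C * k
        if abs(reduced) > 1e-9:
            assert (lhs > 0) == (reduced > 0)


class TestSignChanges:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ((-1, -2, 3, 4), (1, "-+")),
            ((1, -1, 1), (2, "+-+")),
            ((0, -1, 0, 2), (1, "-+")),
            ((5, 5), (0, "+")),
        ],
    )
    def test_patterns(self, vec, expected):
        assert sign_changes(vec) == expected

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            sign_changes((0, 0, 0))

    @given(st.lists(st.integers(min_value=-5, max_value=5), min_size=2, max_size=10)
           .filter(lambda v: any(x != 0 for x in v)))
    def test_pattern_consistent_with_count(self, vec):
        count, pattern = sign_changes(vec)
        assert len(pattern) == count + 1
        nonzero = [x for x in vec if x != 0]
        assert pattern[0] == ("+" if nonzero[0] > 0 else "-")
        assert pattern[-1] == ("+" if nonzero[-1] > 0 else "-")
        assert all(a != b for a, b in zip(pattern, pattern[1:]))


class TestContainment:
    def test_regular_graph_contains_well_mixed(self):
        a = regular_graph_coefficients(5)
        b = wellmixed_coefficients(INF, 6)
        assert containment_compare(a, b) == "a_contains_b"
        assert containment_compare(b, a) == "b_contains_a"

    def test_structure_does_not_contain_itself(self):
        sc = cycle_coefficients(10)
        assert containment_compare(sc, sc) == "incomparable_by_this_test"

    @pytest.mark.parametrize("N", [5, 6, 20, 100])
    def test_single_game_beats_overlapping_games_on_cycle(self, N):
        assert (
            containment_compare(
                cycle_coefficients(N), cycle_overlapping_coefficients(N)
            )
            == "a_contains_b"
        )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            containment_compare(cycle_coefficients(5), regular_graph_coefficients(3))

    def test_containment_transfers_favored_games(self):
        """If the graph contains the well-mixed structure, every cooperation
        game favored in the well-mixed population is favored on the graph."""
        k = 4
        graph_sc = regular_graph_coefficients(k)
        wm = wellmixed_coefficients(INF, k + 1)
        assert containment_compare(graph_sc, wm) == "a_contains_b"
        for bc in (2.0, 3.0, 5.0, 5.5, 8.0):
            game = volunteers_dilemma(bc, 1, k + 1)
            if is_favored(wm, game).favored:
                assert is_favored(graph_sc, game).favored
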