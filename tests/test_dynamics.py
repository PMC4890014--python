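"""Fermi imitation, win-stay/lose-shift, resource allocation and survival."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from visipd import (
    PayoffMatrix,
    PopulationExtinctionError,
    accumulate_payoffs,
    allocate_resources,
    apply_survival_rule,
    build_square_lattice,
    fermi_adoption_probability,
    init_population,
    invisible_strategy_update,
    topology_from_edges,
    visible_strategy_update,
)

finite = st.floats(min_value=-50, max_value=50, allow_nan=False)


class TestFermiRule:
    def test_equal_payoffs_give_half(self):
        assert fermi_adoption_probability(3.0, 3.0, 10.0) == pytest.approx(0.5)

    def test_unit_gap_at_kappa_ten(self):
        w = fermi_adoption_probability(0.0, 1.0, 10.0)
        assert w == pytest.approx(1.0 / (1.0 + math.exp(-10.0)))

    def test_limits(self):
        assert fermi_adoption_probability(0.0, 500.0, 10.0) == pytest.approx(1.0)
        assert fermi_adoption_probability(500.0, 0.0, 10.0) == pytest.approx(0.0)

    @given(a=finite, b=finite, kappa=st.floats(min_value=0.01, max_value=50))
    @settings(deadline=None)
    def test_complement_identity(self, a, b, kappa):
        total = fermi_adoption_probability(a, b, kappa) + fermi_adoption_probability(
            b, a, kappa
        )
        assert total == pytest.approx(1.0)

    def test_monotone_in_payoff_gap(self):
        # stay below |kappa*gap| ~ 36 where the logistic saturates in float64
        gaps = np.linspace(-1.5, 1.5, 41)
        w = fermi_adoption_probability(np.zeros_like(gaps), gaps, 10.0)
        assert (np.diff(w) > 0).all()

    def test_nonpositive_kappa_rejected(self):
        with pytest.raises(ValueError):
            fermi_adoption_probability(0.0, 1.0, 0.0)


class TestVisibleUpdate:
    def _state_on_star(self, payoffs, strategies, rng):
        topo = topology_from_edges([(0, j) for j in range(1, len(payoffs))])
        state = init_population(topo, alpha=1.0, beta=1.0, rng=rng)
        state.strategies[:] = strategies
        state.payoff_now = np.asarray(payoffs, dtype=float)
        return topo, state

    def test_tied_best_neighbors_chosen_uniformly(self, rng):
        # neighbours 1..3 earn {2, 5, 5}: j* must split evenly between 2 and 3
        topo, state = self._state_on_star(
            [0.0, 2.0, 5.0, 5.0], [1, 1, 1, -1], rng
        )
        picks = {2: 0, 3: 0}
        for _ in range(4000):
            s = visible_strategy_update(0, state, topo, kappa=10.0, rng=rng)
            picks[3 if s == -1 else 2] += 1
        frac = picks[2] / 4000
        assert 0.45 < frac < 0.55

    def test_adoption_probability_matches_closed_form(self, rng):
        topo, state = self._state_on_star([0.0, 4.0], [1, -1], rng)
        w_expected = 1.0 / (1.0 + math.exp(-10.0 * 4.0))
        flips = sum(
            visible_strategy_update(0, state, topo, kappa=10.0, rng=rng) == -1
            for _ in range(2000)
        )
        assert flips / 2000 == pytest.approx(w_expected, abs=0.02)

    def test_imitating_same_strategy_is_idempotent(self, rng):
        topo, state = self._state_on_star([0.0, 9.0], [1, 1], rng)
        for _ in range(50):
            assert visible_strategy_update(0, state, topo, kappa=10.0, rng=rng) == 1

    def test_isolated_node_keeps_strategy(self, rng):
        topo = topology_from_edges([(0, 1)], node_count=3)
        state = init_population(topo, alpha=1.0, beta=1.0, rng=rng)
        assert visible_strategy_update(2, state, topo, kappa=10.0, rng=rng) == 1


class TestInvisibleUpdate:
    @pytest.mark.parametrize(
        "s_i,f1,f2,expected",
        [
            (1, 3.0, 1.0, 1),
            (-1, 3.0, 1.0, -1),
            (1, 1.0, 3.0, -1),
            (-1, 1.0, 3.0, 1),
        ],
    )
    def test_win_stay_lose_shift_truth_table(self, s_i, f1, f2, expected, rng):
        assert invisible_strategy_update(s_i, f1, f2, rng) == expected

    @pytest.mark.parametrize("f1,f2", [(2.0, 2.0), (None, 1.0), (math.nan, 2.0)])
    def test_tie_or_missing_history_randomises_evenly(self, f1, f2, rng):
        draws = [invisible_strategy_update(1, f1, f2, rng) for _ in range(10_000)]
        frac_coop = draws.count(1) / len(draws)
        assert abs(frac_coop - 0.5) <= 0.02

    def test_invalid_strategy_rejected(self, rng):
        with pytest.raises(ValueError):
            invisible_strategy_update(2, 1.0, 0.0, rng)


class TestResourceAllocation:
    def test_uniform_payoffs_split_evenly(self):
        alloc = allocate_resources(np.full(10, 3.0), r=1.7)
        assert np.allclose(alloc.gross, 1.7)
        assert np.allclose(alloc.net, 0.7)

    def test_two_player_proportional_split(self):
        alloc = allocate_resources(np.array([1.0, 3.0]), r=1.0)
        assert np.allclose(alloc.gross, [0.5, 1.5])
        assert np.allclose(alloc.net, [-0.5, 0.5])

    def test_zero_total_payoff_splits_equally(self):
        alloc = allocate_resources(np.zeros(5), r=1.1)
        assert np.allclose(alloc.gross, 1.1)

    def test_budget_conserved_on_random_payoffs(self):
        # Σ D_i = r·N whenever Σf > 0
        gen = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(gen.integers(2, 60))
            payoffs = gen.random(n) * gen.integers(1, 10)
            r = float(gen.random() * 3 + 0.05)
            alloc = allocate_resources(payoffs, r)
            assert math.isclose(alloc.gross.sum(), r * n, rel_tol=1e-9)
            assert np.allclose(alloc.net, alloc.gross - 1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            allocate_resources(np.array([1.0, -0.1]), r=1.0)
        with pytest.raises(ValueError):
            allocate_resources(np.ones(3), r=0.0)


class TestSurvivalRule:
    def test_no_deaths_leaves_state_unchanged(self, small_lattice, rng):
        state = init_population(small_lattice, alpha=1.0, beta=0.5, rng=rng)
        f = accumulate_payoffs(state, small_lattice, PayoffMatrix())
        state.payoff_now = f
        alloc = allocate_resources(f, r=1.5)
        new, dead = apply_survival_rule(state, alloc, 0.0, small_lattice, rng)
        assert dead.sum() == 0
        assert (new.strategies == state.strategies).all()
        assert (new.visible == state.visible).all()

    def test_dead_node_inherits_from_only_surviving_neighbor(self, rng):
        # path 0-1-2: node 1's only surviving neighbour is a visible cooperator
        topo = topology_from_edges([(0, 1), (1, 2)])
        state = init_population(topo, alpha=1.0, beta=1.0, rng=rng)
        state.strategies[:] = [1, -1, 1]
        state.visible[:] = [True, False, False]
        state.payoff_now = np.array([5.0, 0.0, 5.0])
        # nets: node 1 dies, node 2 dies, node 0 survives
        alloc = allocate_resources(np.array([5.0, 0.0, 0.1]), r=1.0)
        assert (alloc.net < 0).tolist() == [False, True, True]
        new, dead = apply_survival_rule(state, alloc, 0.0, topo, rng)
        assert new.strategies[1] == 1 and bool(new.visible[1]) is True
        assert dead.sum() == 2

    def test_death_count_matches_threshold_definition(self, small_lattice, rng):
        state = init_population(small_lattice, alpha=0.3, beta=0.5, rng=rng)
        f = accumulate_payoffs(state, small_lattice, PayoffMatrix())
        state.payoff_now = f
        alloc = allocate_resources(f, r=1.1)
        _, dead = apply_survival_rule(state, alloc, 0.0, small_lattice, rng)
        assert dead.sum() == (alloc.net < 0.0).sum()

    def test_offspring_history_cleared(self, rng):
        topo = topology_from_edges([(0, 1), (1, 2)])
        state = init_population(topo, alpha=1.0, beta=1.0, rng=rng)
        state.payoff_prev[:] = 2.0
        state.payoff_prev2[:] = 1.0
        alloc = allocate_resources(np.array([5.0, 0.0, 5.0]), r=1.0)
        new, dead = apply_survival_rule(state, alloc, 0.0, topo, rng)
        assert dead.tolist() == [False, True, False]
        assert math.isnan(new.payoff_prev[1]) and math.isnan(new.payoff_prev2[1])
        assert new.payoff_prev[0] == 2.0

    def test_orphan_draws_parent_from_all_survivors(self, rng):
        # isolated pair dies; parents must come from the surviving component
        topo = topology_from_edges([(0, 1), (2, 3)])
        state = init_population(topo, alpha=1.0, beta=1.0, rng=rng)
        state.strategies[:] = [1, 1, -1, -1]
        state.visible[:] = [True, True, False, False]
        alloc = allocate_resources(np.array([4.0, 4.0, 0.0, 0.0]), r=1.0)
        new, dead = apply_survival_rule(state, alloc, 0.0, topo, rng)
        assert dead.tolist() == [False, False, True, True]
        assert (new.strategies[2:] == 1).all()
        assert new.visible[2:].all()

    def test_total_extinction_raises(self, small_lattice, rng):
        state = init_population(small_lattice, alpha=0.0, beta=0.5, rng=rng)
        n = small_lattice.node_count
        alloc = allocate_resources(np.zeros(n), r=0.5)  # net −0.5 for everyone
        with pytest.raises(PopulationExtinctionError):
            apply_survival_rule(state, alloc, 0.0, small_lattice, rng)

    def test_best_payoff_parent_rule(self, rng):
        # node 1 dies; its surviving neighbours 0 (payoff 2, defector) and
        # 2 (payoff 6, cooperator): best-payoff parentage must pick node 2
        topo = topology_from_edges([(0, 1), (1, 2)])
        state = init_population(topo, alpha=0.0, beta=1.0, rng=rng)
        state.strategies[:] = [-1, -1, 1]
        state.payoff_now = np.array([2.0, 0.0, 6.0])
        alloc = allocate_resources(np.array([2.0, 0.0, 6.0]), r=1.5)
        assert (alloc.net < 0).tolist() == [False, True, False]
        new, _ = apply_survival_rule(
            state, alloc, 0.0, topo, rng, parent_rule="best_payoff"
        )
        assert new.strategies[1] == 1
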