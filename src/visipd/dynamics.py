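"""The three co-evolutionary mechanisms.

1. Strategy updating, conditioned on visibility: visible players imitate
   their best-paid neighbour through the Fermi (logistic) rule; invisible
   players apply a win-stay/lose-shift rule to their own payoff history.
2. Resource allocation: a fixed global budget G = r·N is split among the
   players in proportion to their round payoffs; net resource L_i = D_i − 1.
3. Survival: players whose net resource falls below the critical value δ
   are replaced by the offspring of a surviving neighbour, inheriting the
   parent's strategy and visibility.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.special import expit

from .game import COOPERATE, DEFECT, InvalidStrategyError, PopulationState
from .networks import NetworkTopology

__all__ = [
    "ResourceAllocation",
    "PopulationExtinctionError",
    "fermi_adoption_probability",
    "visible_strategy_update",
    "invisible_strategy_update",
    "allocate_resources",
    "apply_survival_rule",
]

PARENT_RULES = ("uniform", "best_payoff")


class PopulationExtinctionError(RuntimeError):
    """Raised when every player dies in the same round."""


@dataclasses.dataclass(frozen=True)
class ResourceAllocation:
    """One round's resource split: gross shares D_i, net L_i = D_i − 1."""

    gross: np.ndarray
    net: np.ndarray
    budget: float


def fermi_adoption_probability(f_i, f_j, kappa: float):
    """W = 1 / (1 + exp(−κ·(f_j − f_i))), the probability that the focal
    player adopts the model player's strategy.

    κ is the selection intensity (inverse noise amplitude): small κ makes
    players insensitive to payoff differences, large κ makes adoption of the
    better-paid strategy near-deterministic.  Accepts scalars or arrays.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    w = expit(kappa * (np.asarray(f_j, dtype=float) - np.asarray(f_i, dtype=float)))
    return float(w) if np.ndim(w) == 0 else w


def visible_strategy_update(
    i: int,
    state: PopulationState,
    topology: NetworkTopology,
    kappa: float,
    rng: np.random.Generator,
) -> int:
    """Next strategy of visible player ``i``.

    The player targets the neighbour j* with the maximum current payoff
    (ties broken uniformly at random) and adopts s_{j*} with the Fermi
    probability, otherwise keeps its own strategy.  An isolated node keeps
    its strategy.
    """
    s_i = int(state.strategies[i])
    nbrs = sorted(topology.adjacency[i])
    if not nbrs:
        return s_i
    payoffs = state.payoff_now[nbrs]
    best = payoffs.max()
    ties = [j for j, p in zip(nbrs, payoffs) if p == best]
    j_star = ties[int(rng.integers(len(ties)))]
    w = fermi_adoption_probability(
        state.payoff_now[i], state.payoff_now[j_star], kappa
    )
    return int(state.strategies[j_star]) if rng.random() < w else s_i


def _absent(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def invisible_strategy_update(
    s_i: int, f_prev1, f_prev2, rng: np.random.Generator
) -> int:
    """Win-stay/lose-shift on the player's own last two payoffs.

    Keep the strategy if the more recent payoff improved, switch to the
    opposite strategy (−s_i) if it dropped, and choose uniformly at random
    when the two payoffs are equal or either is unknown.
    """
    if s_i not in (COOPERATE, DEFECT):
        raise InvalidStrategyError(f"strategy must be +1 or -1, got {s_i}")
    if _absent(f_prev1) or _absent(f_prev2) or f_prev1 == f_prev2:
        return COOPERATE if rng.random() < 0.5 else DEFECT
    return s_i if f_prev1 > f_prev2 else -s_i


def allocate_resources(payoffs: np.ndarray, r: float) -> ResourceAllocation:
    """Split the global budget G = r·N in proportion to payoffs.

    When the total payoff is zero (e.g. an all-defector round in the
    rescaled game) the budget is split equally — Eq-proportionality is
    undefined there and the equal split is the unique strategy-neutral
    choice that conserves G.
    """
    f = np.asarray(payoffs, dtype=float)
    if r <= 0:
        raise ValueError(f"environment parameter r must be positive, got {r}")
    if (f < 0).any():
        raise ValueError("payoffs must be non-negative")
    n = f.size
    budget = r * n
    total = f.sum()
    gross = budget * f / total if total > 0 else np.full(n, budget / n)
    return ResourceAllocation(gross=gross, net=gross - 1.0, budget=budget)


def _choose_parents(
    dead: np.ndarray,
    state: PopulationState,
    topology: NetworkTopology,
    rng: np.random.Generator,
    parent_rule: str,
) -> np.ndarray:
    """Parent node for every dead player (entries of alive players unused)."""
    alive = ~dead
    if parent_rule == "uniform":
        choice, ok = topology.segments.pick_uniform(alive, rng)
    elif parent_rule == "best_payoff":
        choice, ok = topology.segments.pick_max(
            state.payoff_now, rng, eligible=alive
        )
    else:
        raise ValueError(
            f"parent_rule must be one of {PARENT_RULES}, got {parent_rule!r}"
        )
    orphan = dead & ~ok  # no surviving neighbour: draw from all survivors
    if orphan.any():
        pool = np.flatnonzero(alive)
        choice[orphan] = pool[rng.integers(pool.size, size=int(orphan.sum()))]
    return choice


def apply_survival_rule(
    state: PopulationState,
    allocation: ResourceAllocation,
    delta: float,
    topology: NetworkTopology,
    rng: np.random.Generator,
    parent_rule: str = "uniform",
) -> tuple[PopulationState, np.ndarray]:
    """Replace every player whose net resource L_i fell below δ.

    The death mask is evaluated simultaneously for all players before any
    replacement, so the outcome is independent of replacement order.  Each
    dead player is overwritten with the strategy and visibility of a parent
    drawn from its surviving neighbours (uniformly by default, or the
    best-paid one under ``parent_rule="best_payoff"``); if none survive, the
    parent is drawn uniformly from all survivors.  Offspring start with a
    cleared payoff history.
    """
    dead = allocation.net < delta
    if dead.all():
        raise PopulationExtinctionError(
            f"all {dead.size} players fell below the survival threshold "
            f"delta={delta} in one round"
        )
    new = state.copy()
    new.resource = allocation.net.copy()
    if dead.any():
        parents = _choose_parents(dead, state, topology, rng, parent_rule)
        new.strategies[dead] = state.strategies[parents[dead]]
        new.visible[dead] = state.visible[parents[dead]]
        new.payoff_prev[dead] = np.nan
        new.payoff_prev2[dead] = np.nan
    return new, dead
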