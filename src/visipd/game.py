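"""Prisoner's-dilemma payoff structure and the evolving population state.

Strategies are encoded +1 (cooperator) and −1 (defector).  The default
payoff matrix is the rescaled one-parameter ("weak") prisoner's dilemma
R = 1, S = P = 0, leaving the temptation T as the single game parameter
with admissible interval 1 < T < 2.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .networks import NetworkTopology

__all__ = [
    "PayoffMatrix",
    "PopulationState",
    "InvalidStrategyError",
    "pairwise_payoff",
    "accumulate_payoffs",
]

COOPERATE = 1
DEFECT = -1


class InvalidStrategyError(ValueError):
    """Raised when a strategy value is outside {+1, −1}."""


@dataclasses.dataclass(frozen=True)
class PayoffMatrix:
    """The four PD payoffs from the row player's perspective.

    The constructor enforces the relaxed ordering T > R ≥ P ≥ S together
    with 2R > T + S (cooperation not dominated in repeated pairings).
    With ``strict=True`` a warning is issued if the classical strict chain
    T > R > P > S does not hold — the rescaled matrix forces P = S = 0.
    """

    R: float = 1.0
    S: float = 0.0
    T: float = 1.1
    P: float = 0.0
    strict: bool = False

    def __post_init__(self):
        if not (self.T > self.R >= self.P >= self.S):
            raise ValueError(
                f"payoff ordering T > R >= P >= S violated: "
                f"T={self.T}, R={self.R}, P={self.P}, S={self.S}"
            )
        if not (2 * self.R > self.T + self.S):
            raise ValueError(
                f"2R > T + S required, got 2R={2 * self.R}, T+S={self.T + self.S}"
            )
        if self.strict and not (self.T > self.R > self.P > self.S):
            warnings.warn(
                "payoff chain is not strict (R > P > S fails); "
                "the rescaled game has P == S == 0",
                stacklevel=2,
            )


@dataclasses.dataclass
class PopulationState:
    """Per-player state vectors, all of length N.

    ``payoff_prev`` / ``payoff_prev2`` hold the payoffs of the one and two
    preceding rounds (NaN where no history exists, e.g. freshly replaced
    players); deeper history is never needed.
    """

    strategies: np.ndarray  # int8, +1 / −1
    visible: np.ndarray  # bool
    payoff_now: np.ndarray  # float, payoff of the current round f_i(t)
    payoff_prev: np.ndarray  # float, f_i(t−1); NaN = absent
    payoff_prev2: np.ndarray  # float, f_i(t−2); NaN = absent
    resource: np.ndarray  # float, net resource L_i of the last allocation
    round_index: int = 0

    @property
    def n(self) -> int:
        return self.strategies.shape[0]

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.strategies.copy(),
            self.visible.copy(),
            self.payoff_now.copy(),
            self.payoff_prev.copy(),
            self.payoff_prev2.copy(),
            self.resource.copy(),
            self.round_index,
        )

    def to_frame(self) -> pd.DataFrame:
        """Columnar snapshot (node_id, strategy, visible, payoff, resource)."""
        return pd.DataFrame(
            {
                "node_id": np.arange(self.n),
                "strategy": self.strategies.astype(int),
                "visible": self.visible,
                "payoff": self.payoff_now,
                "resource": self.resource,
            }
        )


def _check_strategies(values: np.ndarray) -> None:
    if not np.isin(values, (COOPERATE, DEFECT)).all():
        bad = values[~np.isin(values, (COOPERATE, DEFECT))][0]
        raise InvalidStrategyError(f"strategy must be +1 or -1, got {bad}")


def pairwise_payoff(s_i: int, s_j: int, matrix: PayoffMatrix) -> float:
    """Payoff of the row player with strategy ``s_i`` against ``s_j``.

    (C,C) → R, (C,D) → S, (D,C) → T, (D,D) → P.
    """
    for s in (s_i, s_j):
        if s not in (COOPERATE, DEFECT):
            raise InvalidStrategyError(f"strategy must be +1 or -1, got {s}")
    if s_i == COOPERATE:
        return matrix.R if s_j == COOPERATE else matrix.S
    return matrix.T if s_j == COOPERATE else matrix.P


def accumulate_payoffs(
    state: PopulationState, topology: NetworkTopology, matrix: PayoffMatrix
) -> np.ndarray:
    """Total round payoff f_i = Σ_{j ∈ N_i} f_ij for every player.

    Each edge contributes independently to both endpoints (the two sides of
    one edge generally earn different amounts).
    """
    s = np.asarray(state.strategies)
    if s.shape[0] != topology.node_count:
        raise ValueError(
            f"state has {s.shape[0]} players but topology has "
            f"{topology.node_count} nodes"
        )
    _check_strategies(s)
    coop = s == COOPERATE
    coop_nbrs = topology.segments.count_true(coop)
    deg = topology.degrees
    defect_nbrs = deg - coop_nbrs
    return np.where(
        coop,
        matrix.R * coop_nbrs + matrix.S * defect_nbrs,
        matrix.T * coop_nbrs + matrix.P * defect_nbrs,
    ).astype(float)
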