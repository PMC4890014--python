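"""Monte-Carlo round loop, ensemble runner and statistical indices.

A round is synchronous: (1) every player plays the one-shot PD with all
neighbours and accumulates the round payoff; (2) the round's densities and
visibility-stratified payoff means are recorded; (3) the resource budget
G = r·N is allocated in proportion to payoff and players with L_i < δ are
replaced; (4) every surviving player simultaneously selects its next
strategy — visible players through best-neighbour imitation with the Fermi
rule, invisible players through win-stay/lose-shift on their own last two
payoffs; replaced players keep their inherited strategy for this
transition; (5) the payoff history shifts for survivors.

Reported indices follow the usual conventions: ρ_c(t) cooperator fraction,
ρ_v(t) visible fraction, ρ_d(t) deaths/N, and E(ρ_x) the time average over
the final M rounds, averaged again across independent runs.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .dynamics import (
    PopulationExtinctionError,
    allocate_resources,
    apply_survival_rule,
)
from .game import COOPERATE, PayoffMatrix, PopulationState, accumulate_payoffs
from .networks import (
    NetworkTopology,
    build_ba_network,
    build_square_lattice,
    read_edge_list,
)

__all__ = [
    "SimulationConfig",
    "RoundRecord",
    "TrajectorySummary",
    "EnsembleSummary",
    "SimulationResult",
    "init_population",
    "step",
    "run_simulation",
    "run_ensemble",
    "summarize_trajectory",
    "summarize_ensemble",
    "records_to_dataframe",
    "write_trajectory_csv",
]

_NETWORK_KINDS = ("lattice", "scale_free", "custom")


@dataclasses.dataclass
class SimulationConfig:
    """All model parameters, run lengths and seeding.

    Defaults are the canonical study conditions: N = 2500 players
    (50×50 lattice or BA with m = 2), initial cooperator fraction α = 0.1,
    initial visibility fraction β = 0.5, environment parameter r = 1.1,
    survival threshold δ = 0, temptation T = 1.1, selection intensity
    κ = 10, averaging window M = 500 and 100 independent runs.
    """

    network: str = "lattice"
    side: int = 50
    boundary: str = "periodic"
    n: int = 2500
    m: int = 2
    network_path: str | None = None
    alpha: float = 0.1
    beta: float = 0.5
    r: float = 1.1
    delta: float = 0.0
    T: float = 1.1
    kappa: float = 10.0
    total_rounds: int = 1000
    M: int = 500
    seed: int = 0
    n_runs: int = 100
    parent_rule: str = "uniform"

    def validate(self) -> None:
        if self.network not in _NETWORK_KINDS:
            raise ValueError(
                f"network must be one of {_NETWORK_KINDS}, got {self.network!r}"
            )
        if self.network == "lattice" and self.side < 2:
            raise ValueError("side must be >= 2")
        if self.network == "lattice" and self.boundary not in ("periodic", "open"):
            raise ValueError(f"boundary must be periodic or open, got {self.boundary!r}")
        if self.network == "scale_free" and not self.n > self.m >= 1:
            raise ValueError(f"scale-free network needs n > m >= 1, got n={self.n}, m={self.m}")
        if self.network == "custom" and not self.network_path:
            raise ValueError("custom network requires network_path")
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.r <= 0:
            raise ValueError(f"r must be positive, got {self.r}")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if self.total_rounds < 0:
            raise ValueError("total_rounds must be non-negative")
        if self.M < 1:
            raise ValueError("M must be a positive integer")
        if self.total_rounds > 0 and self.M > self.total_rounds:
            raise ValueError(f"M={self.M} exceeds total_rounds={self.total_rounds}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        PayoffMatrix(T=self.T)  # raises on an inadmissible temptation

    def payoff_matrix(self) -> PayoffMatrix:
        return PayoffMatrix(T=self.T)

    def build_topology(self, rng: np.random.Generator) -> NetworkTopology:
        """Build the substrate; scale-free graphs are regenerated per run."""
        if self.network == "lattice":
            return build_square_lattice(self.side, self.boundary)
        if self.network == "scale_free":
            return build_ba_network(self.n, self.m, rng)
        return read_edge_list(self.network_path)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class RoundRecord:
    """Statistical indices of a single round.

    ``ef_visible`` / ``ef_invisible`` are the mean payoffs of the visible
    and invisible strata and are NaN (not zero) when a stratum is empty.
    """

    round: int
    rho_c: float
    rho_v: float
    rho_d: float
    ef_visible: float
    ef_invisible: float


@dataclasses.dataclass(frozen=True)
class TrajectorySummary:
    """Time averages over the final M rounds of one trajectory."""

    E_rho_c: float
    E_rho_v: float
    E_rho_d: float
    ef_visible: float
    ef_invisible: float


@dataclasses.dataclass
class SimulationResult:
    records: list[RoundRecord]
    final_state: PopulationState
    topology: NetworkTopology
    run_index: int


@dataclasses.dataclass
class EnsembleSummary:
    """Cross-run means of the per-round indices and their E-values.

    ``per_run`` holds one row per run (the primary data — every aggregate
    here is recomputable from it); ``per_round`` holds the across-run mean
    trajectory.
    """

    master_seed: int
    run_count: int
    E_rho_c: float
    E_rho_v: float
    E_rho_d: float
    sem_rho_c: float
    sem_rho_v: float
    sem_rho_d: float
    ef_visible: float
    ef_invisible: float
    per_run: pd.DataFrame
    per_round: pd.DataFrame


def run_rng(master_seed: int, run_index: int) -> np.random.Generator:
    """Independent, reproducible stream for one run of an ensemble.

    Streams are derived from the master seed by spawn key, so run ``i`` is
    identical no matter how many runs the ensemble contains.
    """
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(run_index,))
    )


def init_population(
    topology: NetworkTopology,
    alpha: float,
    beta: float,
    rng: np.random.Generator,
) -> PopulationState:
    """Independent Bernoulli initialisation: cooperator w.p. α, visible w.p. β."""
    if not (0.0 <= alpha <= 1.0 and 0.0 <= beta <= 1.0):
        raise ValueError("alpha and beta must lie in [0, 1]")
    n = topology.node_count
    strategies = np.where(rng.random(n) < alpha, 1, -1).astype(np.int8)
    visible = rng.random(n) < beta
    nan = np.full(n, np.nan)
    return PopulationState(
        strategies=strategies,
        visible=visible,
        payoff_now=np.zeros(n),
        payoff_prev=nan.copy(),
        payoff_prev2=nan.copy(),
        resource=np.zeros(n),
        round_index=0,
    )


def _stratum_mean(values: np.ndarray, mask: np.ndarray) -> float:
    return float(values[mask].mean()) if mask.any() else math.nan


def step(
    state: PopulationState,
    topology: NetworkTopology,
    config: SimulationConfig,
    rng: np.random.Generator,
    matrix: PayoffMatrix | None = None,
) -> tuple[PopulationState, RoundRecord]:
    """Advance the population by one synchronous round."""
    if matrix is None:
        matrix = config.payoff_matrix()
    played = state.copy()
    f = accumulate_payoffs(played, topology, matrix)
    played.payoff_now = f

    coop = played.strategies == COOPERATE
    vis = played.visible
    rho_c = float(coop.mean())
    rho_v = float(vis.mean())
    ef_v = _stratum_mean(f, vis)
    ef_iv = _stratum_mean(f, ~vis)

    allocation = allocate_resources(f, config.r)
    new, dead = apply_survival_rule(
        played, allocation, config.delta, topology, rng, config.parent_rule
    )

    # --- next-round strategies, selected simultaneously by all survivors ---
    s = played.strategies.astype(np.int64)
    j_star, has_model = topology.segments.pick_max(f, rng)
    j_safe = np.where(j_star >= 0, j_star, 0)
    w = expit(config.kappa * (f[j_safe] - f))
    adopt = has_model & (rng.random(s.size) < w)
    s_visible_next = np.where(adopt, s[j_safe], s)

    prev1 = played.payoff_prev
    stay = f > prev1  # NaN history compares False on both sides -> random
    shift = f < prev1
    random_s = np.where(rng.random(s.size) < 0.5, 1, -1)
    s_invisible_next = np.where(stay, s, np.where(shift, -s, random_s))

    next_s = np.where(vis, s_visible_next, s_invisible_next)
    next_s = np.where(dead, new.strategies, next_s)  # offspring keep inherited
    new.strategies = next_s.astype(np.int8)

    # payoff history shifts for survivors; offspring start fresh (NaN)
    new.payoff_prev2 = np.where(dead, np.nan, prev1)
    new.payoff_prev = np.where(dead, np.nan, f)
    new.payoff_now = f
    new.round_index = state.round_index + 1

    record = RoundRecord(
        round=state.round_index,
        rho_c=rho_c,
        rho_v=rho_v,
        rho_d=float(dead.mean()),
        ef_visible=ef_v,
        ef_invisible=ef_iv,
    )
    return new, record


def run_simulation(
    config: SimulationConfig,
    run_index: int = 0,
    topology: NetworkTopology | None = None,
    progress: Callable[[int], None] | None = None,
) -> SimulationResult:
    """One full trajectory, bit-reproducible for a fixed (seed, run_index)."""
    config.validate()
    rng = run_rng(config.seed, run_index)
    if topology is None:
        topology = config.build_topology(rng)
    matrix = config.payoff_matrix()
    state = init_population(topology, config.alpha, config.beta, rng)
    records: list[RoundRecord] = []
    for t in range(config.total_rounds):
        try:
            state, record = step(state, topology, config, rng, matrix)
        except PopulationExtinctionError as err:
            err.records = records  # partial trajectory retained
            raise
        records.append(record)
        if progress is not None:
            progress(t + 1)
    return SimulationResult(records, state, topology, run_index)


def summarize_trajectory(
    records: Sequence[RoundRecord], M: int
) -> TrajectorySummary:
    """Arithmetic means of the indices over the last M rounds."""
    if M < 1:
        raise ValueError("M must be a positive integer")
    if len(records) < M:
        raise ValueError(
            f"trajectory has {len(records)} rounds, shorter than the "
            f"averaging window M={M}"
        )
    tail = records[-M:]

    def _nanmean(values: list[float]) -> float:
        arr = np.asarray(values, dtype=float)
        finite = arr[~np.isnan(arr)]
        return float(finite.mean()) if finite.size else math.nan

    return TrajectorySummary(
        E_rho_c=float(np.mean([rec.rho_c for rec in tail])),
        E_rho_v=float(np.mean([rec.rho_v for rec in tail])),
        E_rho_d=float(np.mean([rec.rho_d for rec in tail])),
        ef_visible=_nanmean([rec.ef_visible for rec in tail]),
        ef_invisible=_nanmean([rec.ef_invisible for rec in tail]),
    )


def records_to_dataframe(records: Sequence[RoundRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(rec) for rec in records],
        columns=["round", "rho_c", "rho_v", "rho_d", "ef_visible", "ef_invisible"],
    )


def write_trajectory_csv(records: Sequence[RoundRecord], path) -> None:
    """One row per round; empty fields mark undefined stratum means."""
    records_to_dataframe(records).to_csv(path, index=False)


def summarize_ensemble(
    config: SimulationConfig, results: Sequence[SimulationResult]
) -> EnsembleSummary:
    """Aggregate independent trajectories into the cross-run indices."""
    summaries = [summarize_trajectory(res.records, config.M) for res in results]
    per_run = pd.DataFrame(
        {
            "run": [res.run_index for res in results],
            "E_rho_c": [s.E_rho_c for s in summaries],
            "E_rho_v": [s.E_rho_v for s in summaries],
            "E_rho_d": [s.E_rho_d for s in summaries],
            "ef_visible": [s.ef_visible for s in summaries],
            "ef_invisible": [s.ef_invisible for s in summaries],
        }
    )
    frames = [records_to_dataframe(res.records) for res in results]
    stacked = pd.concat(frames).groupby("round", sort=True)
    per_round = stacked.mean().reset_index()

    n_runs = len(results)
    sem = lambda col: float(per_run[col].std(ddof=1) / math.sqrt(n_runs)) if n_runs > 1 else 0.0
    return EnsembleSummary(
        master_seed=config.seed,
        run_count=n_runs,
        E_rho_c=float(per_run["E_rho_c"].mean()),
        E_rho_v=float(per_run["E_rho_v"].mean()),
        E_rho_d=float(per_run["E_rho_d"].mean()),
        sem_rho_c=sem("E_rho_c"),
        sem_rho_v=sem("E_rho_v"),
        sem_rho_d=sem("E_rho_d"),
        ef_visible=float(per_run["ef_visible"].mean(skipna=True)),
        ef_invisible=float(per_run["ef_invisible"].mean(skipna=True)),
        per_run=per_run,
        per_round=per_round,
    )


def run_ensemble(
    config: SimulationConfig,
    progress: Callable[[int], None] | None = None,
) -> EnsembleSummary:
    """n_runs independent trajectories with per-run seeds derived from the
    master seed; extending n_runs reproduces the earlier runs exactly."""
    config.validate()
    results = []
    for i in range(config.n_runs):
        results.append(run_simulation(config, run_index=i))
        if progress is not None:
            progress(i + 1)
    return summarize_ensemble(config, results)
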