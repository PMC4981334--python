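"""Moran death-Birth dynamics on regular graphs.

One elementary update: a uniformly chosen individual dies, and its k
neighbors compete to place a copy of themselves on the vacated vertex with
probability proportional to fitness ``1 - w + w * payoff``, where ``w`` is
the selection intensity.  Each individual's payoff comes from a single
(k+1)-player game with its k neighbors; competitors' payoffs are evaluated
on the state just before the focal death, so the dying individual still
counts in its neighbors' groups.

The module provides a Monte-Carlo estimator of fixation probabilities (with
a compiled kernel that skips the no-op updates in which the dying vertex and
all its neighbors agree — an exact acceleration, since such updates cannot
change the state), and an exact absorbing-Markov-chain solver for small
graphs used as an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .games import MultiplayerGame, volunteers_dilemma, vd_cost_sharing
from .graphs import RegularGraph

__all__ = [
    "SimulationConfig",
    "FixationEstimate",
    "ExactChainResult",
    "focal_payoff",
    "replacement_probability_A",
    "db_step",
    "fixation_probability",
    "exact_fixation",
    "sweep_bc",
]

_EXACT_MAX_N = 14

try:  # compiled Monte-Carlo kernel; a pure-Python twin exists for fallback
    from ._kernel import run_batch as _run_batch_numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class SimulationConfig:
    """Run parameters for the Monte-Carlo fixation estimator.

    A single mutant is placed at a uniformly random vertex at the start of
    each realization.  ``mutant`` selects which strategy invades.
    """

    w: float
    runs: int
    seed: int
    mutant: str = "A"

    def __post_init__(self):
        if self.w < 0:
            raise ValueError(f"selection intensity w must be >= 0, got {self.w}")
        if self.runs < 1:
            raise ValueError(f"runs must be >= 1, got {self.runs}")
        if self.mutant not in ("A", "B"):
            raise ValueError(f"mutant must be 'A' or 'B', got {self.mutant!r}")


@dataclass(frozen=True)
class FixationEstimate:
    """Monte-Carlo fixation probability with its binomial standard error."""

    rho: float
    runs: int
    fixations: int
    stderr: float

    @classmethod
    def from_counts(cls, fixations: int, runs: int) -> "FixationEstimate":
        rho = fixations / runs
        return cls(
            rho=rho,
            runs=runs,
            fixations=fixations,
            stderr=math.sqrt(rho * (1.0 - rho) / runs),
        )


@dataclass(frozen=True)
class ExactChainResult:
    """Fixation probabilities from the full-state Markov chain.

    ``prob_all_A[s]`` is the probability that the chain started from the
    state with A-occupation bitmask ``s`` absorbs in the all-A state.
    ``rho_single_mutant`` averages the mutant's fixation probability over
    the N single-mutant initial states.
    """

    prob_all_A: np.ndarray
    rho_single_mutant: float
    mutant: str


def _check_game_graph(game: MultiplayerGame, g: RegularGraph) -> None:
    if game.d != g.k + 1:
        raise ValueError(
            f"group size mismatch: the game has d={game.d} players but the "
            f"graph has degree k={g.k} (need d = k + 1)"
        )


def _check_fitness_positivity(game: MultiplayerGame, w: float) -> None:
    fmin = 1.0 - w + w * float(game.min_payoff)
    if fmin <= 0:
        raise ValueError(
            f"fitness positivity violated: 1 - w + w*payoff reaches {fmin} "
            f"for the minimum payoff {float(game.min_payoff)} at w={w}"
        )


def focal_payoff(vertex: int, state: Sequence[int], game: MultiplayerGame,
                 g: RegularGraph) -> float:
    """Payoff of ``vertex`` in the current state (1 = plays A, 0 = plays B)."""
    _check_game_graph(game, g)
    j = int(sum(state[u] for u in g.adjacency[vertex]))
    return game.a[j] if state[vertex] else game.b[j]


def replacement_probability_A(vertex: int, state: Sequence[int],
                              game: MultiplayerGame, g: RegularGraph,
                              w: float) -> float:
    """Probability that the vacancy at ``vertex`` is filled by strategy A.

    The k neighbors compete with weights ``1 - w + w * payoff`` evaluated on
    the state before the death.
    """
    _check_game_graph(game, g)
    total = 0.0
    total_A = 0.0
    for u in g.adjacency[vertex]:
        u = int(u)
        f = 1.0 - w + w * float(focal_payoff(u, state, game, g))
        if f <= 0:
            raise ValueError(f"non-positive competition weight {f} at vertex {u}")
        total += f
        if state[u]:
            total_A += f
    return total_A / total


def db_step(state: np.ndarray, game: MultiplayerGame, g: RegularGraph,
            w: float, rng: np.random.Generator,
            dying: Optional[int] = None) -> np.ndarray:
    """One death-Birth update; returns the new state (the input is not modified).

    ``dying`` forces the vertex chosen to die (used in tests); by default it
    is uniform over all vertices.
    """
    state = np.asarray(state)
    v = int(rng.integers(g.N)) if dying is None else dying
    p_A = replacement_probability_A(v, state, game, g, w)
    new = state.copy()
    new[v] = 1 if rng.random() < p_A else 0
    return new


# -- Monte-Carlo fixation probabilities --------------------------------------


def _mutant_payoff_tables(game: MultiplayerGame, mutant: str,
                          k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Payoff lookup tables indexed by the number of *mutant-type* neighbors.

    The kernel encodes the mutant strategy as 1.  For an invading B,
    ``c`` mutant-type (B) neighbors means ``k - c`` A-co-players.
    """
    a = np.array([float(x) for x in game.a])
    b = np.array([float(x) for x in game.b])
    if mutant == "A":
        return a, b
    return b[::-1].copy(), a[::-1].copy()


def fixation_probability(g: RegularGraph, game: MultiplayerGame,
                         config: SimulationConfig) -> FixationEstimate:
    """Estimate the fixation probability of a single mutant by simulation.

    Runs ``config.runs`` independent realizations from a single mutant at a
    uniformly random vertex until absorption, and returns the fixation
    fraction with its binomial standard error.  Deterministic given the
    seed: per-run generator states are derived by counter from
    ``config.seed``, so the result does not depend on execution order.
    """
    _check_game_graph(game, g)
    _check_fitness_positivity(game, config.w)
    pay1, pay0 = _mutant_payoff_tables(game, config.mutant, g.k)
    seeds = np.random.SeedSequence(config.seed).generate_state(
        config.runs, dtype=np.uint64
    )
    adj = np.ascontiguousarray(g.adjacency, dtype=np.int64)
    if _HAVE_NUMBA:
        fixations = int(_run_batch_numba(adj, pay1, pay0, float(config.w), seeds))
    else:  # pragma: no cover
        from ._kernel_py import run_batch_py

        fixations = run_batch_py(adj, pay1, pay0, float(config.w), seeds)
    return FixationEstimate.from_counts(fixations, config.runs)


# -- exact absorbing-chain oracle ---------------------------------------------


def exact_fixation(g: RegularGraph, game: MultiplayerGame, w: float,
                   mutant: str = "A") -> ExactChainResult:
    """Solve the death-Birth chain exactly on a small graph (N <= 14).

    Enumerates all ``2^N`` strategy configurations (bit v set = vertex v
    plays A), assembles the one-step transition structure, and solves the
    absorption linear system: the all-A state maps to probability 1 and the
    all-B state to 0.
    """
    _check_game_graph(game, g)
    _check_fitness_positivity(game, w)
    if mutant not in ("A", "B"):
        raise ValueError(f"mutant must be 'A' or 'B', got {mutant!r}")
    N, k = g.N, g.k
    if N > _EXACT_MAX_N:
        raise ValueError(
            f"exact chain needs N <= {_EXACT_MAX_N} (state space 2^N); got N={N}"
        )
    a = [float(x) for x in game.a]
    b = [float(x) for x in game.b]
    adj = g.adjacency
    n_states = 1 << N
    all_A = n_states - 1

    rows, cols, vals = [], [], []
    rhs = np.zeros(n_states)
    for s in range(n_states):
        if s == 0 or s == all_A:
            rows.append(s); cols.append(s); vals.append(1.0)
            rhs[s] = 1.0 if s == all_A else 0.0
            continue
        # transient: rho(s) - sum_s' P(s, s') rho(s') = 0
        trans = {}
        for v in range(N):
            total = 0.0
            total_A = 0.0
            for u in adj[v]:
                u = int(u)
                j = sum((s >> int(x)) & 1 for x in adj[u])
                pay = a[j] if (s >> u) & 1 else b[j]
                f = 1.0 - w + w * pay
                total += f
                if (s >> u) & 1:
                    total_A += f
            p_A = total_A / total
            s_with = s | (1 << v)
            s_without = s & ~(1 << v)
            trans[s_with] = trans.get(s_with, 0.0) + p_A / N
            trans[s_without] = trans.get(s_without, 0.0) + (1.0 - p_A) / N
        rows.append(s); cols.append(s); vals.append(1.0)
        for s2, p in trans.items():
            rows.append(s); cols.append(s2); vals.append(-p)
    M = sp.csr_matrix((vals, (rows, cols)), shape=(n_states, n_states))
    prob_all_A = spla.spsolve(M.tocsc(), rhs)
    prob_all_A = np.clip(prob_all_A, 0.0, 1.0)

    if mutant == "A":
        starts = [1 << v for v in range(N)]
        rho = float(np.mean([prob_all_A[s] for s in starts]))
    else:
        starts = [all_A & ~(1 << v) for v in range(N)]
        rho = float(np.mean([1.0 - prob_all_A[s] for s in starts]))
    return ExactChainResult(prob_all_A=prob_all_A, rho_single_mutant=rho,
                            mutant=mutant)


# -- benefit-to-cost sweeps ----------------------------------------------------

_GAME_FAMILIES = {
    "vd": volunteers_dilemma,
    "vd_cs": vd_cost_sharing,
}


def sweep_bc(g: RegularGraph, game_family: str, bc_grid: Sequence[float],
             config: SimulationConfig, C: float = 1.0) -> pd.DataFrame:
    """Fixation-probability difference across a grid of benefit-to-cost ratios.

    For each ``B/C`` value, builds the requested volunteer's-dilemma variant
    with cost ``C``, estimates the fixation probability of a single A-mutant
    and of a single B-mutant, and tabulates the difference.  Per-point seeds
    are derived from ``config.seed`` by counter.
    """
    if game_family not in _GAME_FAMILIES:
        raise ValueError(
            f"unknown game family {game_family!r}; choose from {sorted(_GAME_FAMILIES)}"
        )
    make = _GAME_FAMILIES[game_family]
    records = []
    for i, bc in enumerate(bc_grid):
        game = make(bc * C, C, g.k + 1)
        ests = {}
        for mi, mutant in enumerate(("A", "B")):
            sub_seed = np.random.SeedSequence((config.seed, i, mi)).generate_state(1)[0]
            cfg = SimulationConfig(w=config.w, runs=config.runs,
                                   seed=int(sub_seed) % (2**31), mutant=mutant)
            ests[mutant] = fixation_probability(g, game, cfg)
        records.append(
            {
                "bc": bc,
                "rho_A": ests["A"].rho,
                "stderr_A": ests["A"].stderr,
                "rho_B": ests["B"].rho,
                "stderr_B": ests["B"].stderr,
                "diff": ests["A"].rho - ests["B"].rho,
            }
        )
    return pd.DataFrame.from_records(records)
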