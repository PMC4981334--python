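"""d-player two-strategy symmetric games.

A game between ``d`` players with strategies A and B is fully described by
two payoff vectors: ``a[j]`` is the payoff to an A-player facing ``j``
A-co-players (among its ``d - 1`` opponents), and ``b[j]`` the payoff to a
B-player in the same situation.  All evolutionary quantities in this package
enter through the *gains from flipping* ``f[j] = a[j] - b[d-1-j]``: the
payoff change a B-focal with ``j`` A-co-players would experience if every
player in the group simultaneously swapped strategies.

Payoff entries are kept as exact :class:`~fractions.Fraction` objects when
the inputs are integers or rationals, and as floats otherwise, so that
downstream threshold computations can be carried out in exact arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Sequence, Union

Number = Union[int, float, Fraction]

__all__ = [
    "MultiplayerGame",
    "gains_from_flipping",
    "is_cooperation_game",
    "swap_strategies",
    "game_from_pairwise",
    "linear_game",
    "volunteers_dilemma",
    "vd_cost_sharing",
    "game_to_json",
    "game_from_json",
    "game_to_tsv",
    "game_from_tsv",
]


def _exactify(x: Number) -> Number:
    """Turn integers and rationals into Fractions; leave floats alone."""
    if isinstance(x, Rational):
        return Fraction(x)
    return float(x)


@dataclass(frozen=True)
class MultiplayerGame:
    """Payoff table of a symmetric d-player game with strategies A and B.

    Parameters
    ----------
    a, b
        Length-``d`` payoff vectors indexed by the number ``j = 0 .. d-1``
        of A-players among the ``d - 1`` co-players.
    """

    a: tuple
    b: tuple

    def __init__(self, a: Sequence[Number], b: Sequence[Number]):
        a = tuple(_exactify(x) for x in a)
        b = tuple(_exactify(x) for x in b)
        if len(a) != len(b):
            raise ValueError(
                f"payoff vectors must have equal length, got {len(a)} and {len(b)}"
            )
        if len(a) < 2:
            raise ValueError(f"group size d must be at least 2, got {len(a)}")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def d(self) -> int:
        """Number of players in the game (group size)."""
        return len(self.a)

    @property
    def min_payoff(self) -> float:
        return min(min(self.a), min(self.b))

    @property
    def max_payoff(self) -> float:
        return max(max(self.a), max(self.b))


def gains_from_flipping(game: MultiplayerGame) -> tuple:
    """Gains from flipping ``f[j] = a[j] - b[d-1-j]``.

    ``f[j]`` is the payoff change for a focal B-player with ``j`` A-co-players
    when every member of the group swaps strategy simultaneously.  The sigma
    rule depends on the payoffs only through this vector.
    """
    d = game.d
    return tuple(game.a[j] - game.b[d - 1 - j] for j in range(d))


def is_cooperation_game(game: MultiplayerGame) -> bool:
    """True if both payoff vectors are nondecreasing in the number of A-co-players.

    This is the defining property of "cooperation games" (volunteer's
    dilemmas, snowdrift games, stag hunts, public-goods games, ...): having
    more A-players around never hurts anyone, whatever the focal strategy.
    Ties are allowed.
    """
    d = game.d
    return all(game.a[j + 1] >= game.a[j] for j in range(d - 1)) and all(
        game.b[j + 1] >= game.b[j] for j in range(d - 1)
    )


def swap_strategies(game: MultiplayerGame) -> MultiplayerGame:
    """The same game with the labels of A and B exchanged.

    A B-player with ``j`` A-co-players becomes an A-player with ``d-1-j``
    A-co-players, so the swapped payoffs are the reversed vectors with roles
    exchanged.
    """
    return MultiplayerGame(a=tuple(reversed(game.b)), b=tuple(reversed(game.a)))


def game_from_pairwise(
    alpha: Number, beta: Number, gamma: Number, delta: Number, k: int
) -> MultiplayerGame:
    """Multiplayer game obtained by summing k pairwise games.

    Each player plays the 2x2 matrix game ``[[alpha, beta], [gamma, delta]]``
    (row = own strategy A/B, column = opponent strategy A/B) with each of its
    ``k`` neighbours and collects the payoffs, giving ``a[j] = j*alpha +
    (k-j)*beta`` and ``b[j] = j*gamma + (k-j)*delta``.
    """
    if k < 1:
        raise ValueError(f"degree k must be at least 1, got {k}")
    alpha, beta, gamma, delta = map(_exactify, (alpha, beta, gamma, delta))
    a = [j * alpha + (k - j) * beta for j in range(k + 1)]
    b = [j * gamma + (k - j) * delta for j in range(k + 1)]
    return MultiplayerGame(a=a, b=b)


def linear_game(B: Number, C: Number, D: Number, k: int) -> MultiplayerGame:
    """Linear public-goods game: ``a[j] = -C + (B+D) j/k``, ``b[j] = B j/k``.

    Cooperators pay a cost ``C`` to give each co-player a benefit ``B/k``,
    plus a synergy/discount bonus ``D/k`` per other cooperator.  For ``D = 0``
    this is the additive prisoner's dilemma (donation game) summed over
    neighbours.
    """
    if k < 1:
        raise ValueError(f"degree k must be at least 1, got {k}")
    B, C, D = map(_exactify, (B, C, D))
    if isinstance(B, float) or isinstance(D, float):
        frac = [j / k for j in range(k + 1)]
    else:
        frac = [Fraction(j, k) for j in range(k + 1)]
    a = [-C + (B + D) * f for f in frac]
    b = [B * f for f in frac]
    return MultiplayerGame(a=a, b=b)


def volunteers_dilemma(B: Number, C: Number, d: int) -> MultiplayerGame:
    """Volunteer's dilemma: one cooperator suffices to produce the public good.

    A cooperator always pays the cost: ``a[j] = B - C``.  A defector gets the
    good for free whenever at least one co-player volunteers: ``b[0] = 0`` and
    ``b[j] = B`` for ``j >= 1``.
    """
    if d < 2:
        raise ValueError(f"group size d must be at least 2, got {d}")
    B, C = _exactify(B), _exactify(C)
    a = [B - C] * d
    b = [0 * B] + [B] * (d - 1)
    return MultiplayerGame(a=a, b=b)


def vd_cost_sharing(B: Number, C: Number, d: int) -> MultiplayerGame:
    """Volunteer's dilemma with the production cost shared among cooperators.

    ``a[j] = B - C/(j+1)`` (the focal cooperator splits the cost with its
    ``j`` cooperating co-players), ``b[0] = 0``, ``b[j] = B`` for ``j >= 1``.
    """
    if d < 2:
        raise ValueError(f"group size d must be at least 2, got {d}")
    B, C = _exactify(B), _exactify(C)
    if isinstance(C, float):
        a = [B - C / (j + 1) for j in range(d)]
    else:
        a = [B - C * Fraction(1, j + 1) for j in range(d)]
    b = [0 * B] + [B] * (d - 1)
    return MultiplayerGame(a=a, b=b)


# -- serialization ------------------------------------------------------------


def game_to_json(game: MultiplayerGame) -> str:
    """Serialize to a small JSON object ``{"d": ..., "a": [...], "b": [...]}``."""
    return json.dumps(
        {
            "d": game.d,
            "a": [float(x) for x in game.a],
            "b": [float(x) for x in game.b],
        }
    )


def game_from_json(text: str) -> MultiplayerGame:
    obj = json.loads(text)
    game = MultiplayerGame(a=obj["a"], b=obj["b"])
    if "d" in obj and obj["d"] != game.d:
        raise ValueError(f"declared d={obj['d']} does not match payoff length {game.d}")
    return game


def game_to_tsv(game: MultiplayerGame) -> str:
    """Two payoff rows, one per strategy, in the standard payoff-table layout."""
    header = "strategy\t" + "\t".join(str(j) for j in range(game.d))
    row_a = "A\t" + "\t".join(repr(float(x)) for x in game.a)
    row_b = "B\t" + "\t".join(repr(float(x)) for x in game.b)
    return "\n".join([header, row_a, row_b]) + "\n"


def game_from_tsv(text: str) -> MultiplayerGame:
    rows = {}
    lines = [ln for ln in text.strip().splitlines() if ln and not ln.startswith("#")]
    for ln in lines[1:]:
        parts = ln.split("\t")
        rows[parts[0]] = [float(x) for x in parts[1:]]
    if set(rows) != {"A", "B"}:
        raise ValueError("expected exactly one payoff row for each of A and B")
    return MultiplayerGame(a=rows["A"], b=rows["B"])
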