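"""The sigma rule: deciding which strategy weak selection favors.

Given normalized structure coefficients ``sigma`` and a d-player game, the
expected gains from flipping ``E[f(J)] = sum_j sigma_j f_j`` decide whether
strategy A fixes more readily than strategy B.  This module evaluates the
rule, derives critical benefit-to-cost thresholds for the volunteer's
dilemma families in closed form, provides the reduced conditions for
pairwise-sum and linear games on regular graphs, and compares population
structures in the containment order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence, Tuple, Union

from .coefficients import StructureCoefficients
from .games import MultiplayerGame, gains_from_flipping

__all__ = [
    "SelectionVerdict",
    "sigma_rule_lhs",
    "is_favored",
    "critical_bc_vd",
    "critical_bc_vd_cs",
    "pairwise_condition",
    "linear_condition",
    "sign_changes",
    "containment_compare",
]


@dataclass(frozen=True)
class SelectionVerdict:
    """Outcome of the sigma rule for one (structure, game) pair.

    ``lhs`` is the expected gain from flipping ``E[f(J)]``; ``favored`` is
    True iff it is strictly positive.  A boundary case (``lhs == 0``), where
    the comparison of fixation probabilities is a tie to first order in the
    selection intensity, is reported as not favored with ``boundary`` set.
    """

    lhs: Union[Fraction, float]
    favored: bool
    boundary: bool
    coefficients_source: str


def _check_dims(sc: StructureCoefficients, game: MultiplayerGame) -> None:
    if sc.d != game.d:
        raise ValueError(
            f"structure coefficients are for d={sc.d} players "
            f"but the game has d={game.d}"
        )


def sigma_rule_lhs(
    sc: StructureCoefficients, game: MultiplayerGame
) -> Union[Fraction, float]:
    """Expected gains from flipping ``sum_j sigma_j f_j``."""
    _check_dims(sc, game)
    f = gains_from_flipping(game)
    return sum(s * fj for s, fj in zip(sc.sigma, f))


def is_favored(sc: StructureCoefficients, game: MultiplayerGame) -> SelectionVerdict:
    """Apply the sigma rule: is A favored over B under weak selection?"""
    lhs = sigma_rule_lhs(sc, game)
    return SelectionVerdict(
        lhs=lhs,
        favored=lhs > 0,
        boundary=lhs == 0,
        coefficients_source=sc.source,
    )


def critical_bc_vd(sc: StructureCoefficients) -> Union[Fraction, float]:
    """Critical B/C for the volunteer's dilemma: ``1/sigma_{d-1}``.

    For the volunteer's dilemma the gains from flipping are ``-C`` except at
    ``j = d-1``, where they are ``B - C``; the sigma rule therefore reduces
    to ``B/C > 1/sigma_{d-1}``.  Returns ``math.inf`` when the top
    coefficient vanishes (cooperation can then never be favored).
    """
    top = sc.sigma[-1]
    if top == 0:
        return math.inf
    return 1 / top if isinstance(top, float) else Fraction(1) / top

def critical_bc_vd_cs(sc: StructureCoefficients) -> Union[Fraction, float]:
    """Critical B/C for the cost-sharing volunteer's dilemma.

    With the production cost split evenly among cooperators the threshold is
    ``(1/sigma_{d-1}) * sum_j sigma_j/(j+1)``.
    """
    top = sc.sigma[-1]
    if top == 0:
        return math.inf
    harm = sum(
        s * Fraction(1, j + 1) if isinstance(s, Fraction) else s / (j + 1)
        for j, s in enumerate(sc.sigma)
    )
    return harm / top


def pairwise_condition(alpha, beta, gamma, delta, k: int) -> bool:
    """Sigma rule for a sum of pairwise games on a large k-regular graph.

    Using ``E[J] = (k+1)/2`` the multiplayer condition collapses to
    ``(k+1) alpha + (k-1) beta - (k-1) gamma - (k+1) delta > 0``, the
    classical pairwise-game rule for death-Birth updating (for the donation
    game it is ``B/C > k``).
    """
    if k < 2:
        raise ValueError(f"degree k must be at least 2, got {k}")
    return (k + 1) * alpha + (k - 1) * beta - (k - 1) * gamma - (k + 1) * delta > 0


def linear_condition(B, C, D, k: int) -> bool:
    """Sigma rule for the linear game on a large k-regular graph.

    Reduces to ``2B + D (k+1) > 2 C k``; with no synergy (``D = 0``) this is
    the ``B/C > k`` rule, and for large ``k`` it approaches ``D > 2C``.
    """
    if k < 2:
        raise ValueError(f"degree k must be at least 2, got {k}")
    return 2 * B + D * (k + 1) > 2 * C * k


def sign_changes(x: Sequence) -> Tuple[int, str]:
    """Count strict sign alternations in a sequence, skipping zeros.

    Returns the number of alternations and the run pattern as a string of
    ``+``/``-`` characters (one per maximal run of equal sign).  Zeros
    neither create nor break a run.  Raises on an all-zero vector, whose
    pattern is undefined.
    """
    if len(x) < 2:
        raise ValueError("need at least two entries")
    signs = [1 if v > 0 else -1 for v in x if v != 0]
    if not signs:
        raise ValueError("sign pattern of the all-zero vector is undefined")
    pattern = ["+" if signs[0] > 0 else "-"]
    count = 0
    for prev, cur in zip(signs, signs[1:]):
        if cur != prev:
            count += 1
            pattern.append("+" if cur > 0 else "-")
    return count, "".join(pattern)


def containment_compare(sc_a: StructureCoefficients, sc_b: StructureCoefficients) -> str:
    """Compare two structures in the containment order for cooperation games.

    If ``sigma_a - sigma_b`` has exactly one sign change from - to +, then
    every cooperation game favored under structure ``b`` is also favored
    under structure ``a`` (``a`` is the stronger promoter of cooperation):
    returns ``"a_contains_b"``.  The mirrored pattern gives
    ``"b_contains_a"``.  Anything else returns
    ``"incomparable_by_this_test"`` — the single-sign-change criterion is
    sufficient, not necessary.
    """
    if sc_a.d != sc_b.d:
        raise ValueError(f"dimension mismatch: d={sc_a.d} vs d={sc_b.d}")
    diff = [a - b for a, b in zip(sc_a.sigma, sc_b.sigma)]
    if all(v == 0 for v in diff):
        return "incomparable_by_this_test"
    count, pattern = sign_changes(diff)
    if count == 1 and pattern == "-+":
        return "a_contains_b"
    if count == 1 and pattern == "+-":
        return "b_contains_a"
    return "incomparable_by_this_test"
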