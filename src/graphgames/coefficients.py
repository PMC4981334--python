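"""Structure coefficients of population structures under death-Birth updating.

Under weak selection, whether strategy A is favored over B (fixation
probability of a single A-mutant exceeds that of a single B-mutant) is
decided by the sigma rule: ``sum_j sigma_j * f_j > 0``, where ``f`` are the
gains from flipping of the game and the ``sigma_j`` are payoff-independent
*structure coefficients* that encode the population structure and update
rule.  Normalized to sum to one, the coefficients define a probability
distribution over the number ``J`` of A-co-players, and the sigma rule reads
``E[f(J)] > 0``.

This module computes the normalized coefficients for

* well-mixed populations with random group formation (Moran/Wright-Fisher),
* the cycle (degree ``k = 2``), where the result is exact,
* regular graphs of degree ``k >= 3`` in the large-population limit, via a
  pair approximation + diffusion approximation that treats the graph as a
  Bethe lattice,
* the cycle when each individual accumulates payoffs from the overlapping
  games centered on itself and on its neighbours,

as well as the single pairwise-game coefficient of transitive graphs and the
corresponding scaled relatedness of inclusive-fitness theory.

All computations with integer inputs are carried out in exact rational
arithmetic (:class:`fractions.Fraction`); the printed reference values are
exact fractions and exactness costs little here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from math import comb, lcm
from typing import Mapping, Sequence, Tuple, Union

__all__ = [
    "StructureCoefficients",
    "wellmixed_coefficients",
    "cycle_coefficients",
    "regular_graph_coefficients",
    "cycle_overlapping_coefficients",
    "pairwise_sigma_transitive",
    "scaled_relatedness",
    "normalize",
    "mean_coplayers",
]

_SUM_TOL = 1e-12

SizeLike = Union[int, float]  # finite int or math.inf


def _is_inf(N: SizeLike) -> bool:
    return isinstance(N, float) and math.isinf(N)


@dataclass(frozen=True)
class StructureCoefficients:
    """Normalized structure coefficients ``sigma_0 .. sigma_{d-1}``.

    ``sigma`` is a tuple of nonnegative entries summing to one (exactly, when
    the entries are Fractions).  ``source`` records which population
    structure and formula produced the vector; ``params`` the parameters
    (``N`` and/or ``k``) it was evaluated at.
    """

    sigma: Tuple
    source: str = "custom"
    params: Mapping = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "sigma", tuple(self.sigma))
        object.__setattr__(self, "params", dict(self.params))
        if len(self.sigma) < 2:
            raise ValueError("need at least two coefficients")
        if any(s < 0 for s in self.sigma):
            raise ValueError(f"structure coefficients must be nonnegative: {self.sigma}")
        total = sum(self.sigma)
        if abs(total - 1) > _SUM_TOL:
            raise ValueError(f"structure coefficients must sum to 1, got {float(total)!r}")

    @property
    def d(self) -> int:
        """Group size of the games this vector applies to."""
        return len(self.sigma)

    def as_floats(self) -> Tuple[float, ...]:
        return tuple(float(s) for s in self.sigma)


def normalize(
    raw: Sequence, source: str = "custom", params: Mapping = ()
) -> StructureCoefficients:
    """Divide a nonnegative vector by its sum.

    Raises ``ValueError`` on negative entries or an all-zero vector.
    """
    raw = list(raw)
    if any(x < 0 for x in raw):
        raise ValueError(f"cannot normalize a vector with negative entries: {raw}")
    total = sum(raw)
    if total == 0:
        raise ValueError("cannot normalize the all-zero vector")
    if all(isinstance(x, (int, Fraction)) for x in raw):
        sigma = tuple(Fraction(x) / Fraction(total) for x in raw)
    else:
        sigma = tuple(x / total for x in raw)
    return StructureCoefficients(sigma=sigma, source=source, params=params)


def mean_coplayers(sc: StructureCoefficients) -> Union[Fraction, float]:
    """Expected number of A-co-players ``E[J] = sum_j sigma_j * j``."""
    return sum(j * s for j, s in enumerate(sc.sigma))


def wellmixed_coefficients(N: SizeLike, d: int) -> StructureCoefficients:
    """Coefficients of a well-mixed population with random group formation.

    ``sigma_j = N / (d (N-1))`` for ``j <= d-2`` and
    ``sigma_{d-1} = (N-d) / (d (N-1))``; in the large-population limit the
    distribution of ``J`` is uniform, ``sigma_j = 1/d``.
    """
    if d < 2:
        raise ValueError(f"group size d must be at least 2, got {d}")
    if _is_inf(N):
        sigma = (Fraction(1, d),) * d
        return StructureCoefficients(sigma, "well_mixed", {"N": math.inf, "d": d})
    if N <= d:
        raise ValueError(f"population size N={N} must exceed group size d={d}")
    common = Fraction(N, d * (N - 1))
    sigma = (common,) * (d - 1) + (Fraction(N - d, d * (N - 1)),)
    return StructureCoefficients(sigma, "well_mixed", {"N": N, "d": d})


def cycle_coefficients(N: SizeLike) -> StructureCoefficients:
    """Exact coefficients of the cycle (``k = 2``, ``d = 3``), death-Birth.

    ``sigma = (1/(2(N-2)), 1/2, (N-3)/(2(N-2)))``; for large ``N`` this tends
    to ``(0, 1/2, 1/2)``, under which the sigma rule reads
    ``a_1 + a_2 > b_1 + b_0`` — the condition for the boundary between a
    cluster of A-players and a cluster of B-players to drift in A's favor.
    """
    if _is_inf(N):
        sigma = (Fraction(0), Fraction(1, 2), Fraction(1, 2))
        return StructureCoefficients(sigma, "cycle_exact", {"N": math.inf, "k": 2})
    if N < 4:
        raise ValueError(f"cycle population size N={N} must be at least 4")
    sigma = (
        Fraction(1, 2 * (N - 2)),
        Fraction(1, 2),
        Fraction(N - 3, 2 * (N - 2)),
    )
    return StructureCoefficients(sigma, "cycle_exact", {"N": N, "k": 2})


def _poly_mul(A: Sequence[int], B: Sequence[int]) -> list:
    out = [0] * (len(A) + len(B) - 1)
    for i, ai in enumerate(A):
        if ai:
            for j, bj in enumerate(B):
                out[i + j] += ai * bj
    return out


@lru_cache(maxsize=None)
def _regular_sigma_raw(k: int) -> Tuple[Fraction, ...]:
    """Unnormalized coefficients of a large k-regular graph (k >= 3).

    Pair approximation on a Bethe lattice gives, at the neutral
    quasi-equilibrium of local frequencies, conditional probabilities
    ``q_{A|A} = p + r x`` and ``q_{A|B} = r x`` with ``p = 1/(k-1)``,
    ``r = (k-2)/(k-1)`` and global A-frequency ``x``.  The weak-selection
    drift at an A-B boundary, weighted by the diffusion measure, yields

        sigma_j  ∝  ∫₀¹ [ C(k-1, j) (1 - r x) (p + r x)^j (r (1-x))^(k-1-j)
                        + C(k-1, j-1) (p + r x)^j (r (1-x))^(k-j) ] dx,

    where the first term collects the payoff to a boundary player whose
    group does not include the vacated site's occupant strategy and the
    second the shifted count when it does.  The integrand is a polynomial in
    ``x``; putting everything over the common denominator ``(k-1)^k`` (which
    normalizes away) we integrate exactly in integer arithmetic.

    This computation is pinned by three independent printed anchors: the
    exact k=3 vector (7, 31, 61, 45)/144, the mean identity
    ``E[J] = (k+1)/2``, and the closed-form volunteer's-dilemma threshold
    ``1/sigma_k = k(k+1)(k-2) / ((k-1)^2 - (k-1)^(1-k))``.
    """
    c = k - 2
    L = lcm(*range(1, k + 3))  # scale so all term integrals are integers
    raw = []
    for j in range(k + 1):
        # (1 + c x)^j over denominator (k-1)^j, folded into the common one
        p1 = [comb(j, i) * c**i for i in range(j + 1)]
        tot = [0] * (k + 2)
        if j <= k - 1:
            m = k - 1 - j
            q = [c**m * comb(m, i) * (-1) ** i for i in range(m + 1)]  # (c(1-x))^m
            t1 = _poly_mul(_poly_mul([k - 1, -c], p1), q)  # (k-1-cx) == (k-1)(1-rx)
            w = comb(k - 1, j)
            for i, v in enumerate(t1):
                tot[i] += w * v
        if j >= 1:
            m = k - j
            q = [c**m * comb(m, i) * (-1) ** i for i in range(m + 1)]
            t2 = _poly_mul(p1, q)
            w = comb(k - 1, j - 1)
            for i, v in enumerate(t2):
                tot[i] += w * v
        raw.append(sum(v * (L // (i + 1)) for i, v in enumerate(tot)))
    total = sum(raw)
    return tuple(Fraction(v, total) for v in raw)


def regular_graph_coefficients(k: int) -> StructureCoefficients:
    """Approximate coefficients of a large regular graph of degree ``k >= 3``.

    Valid in the limit ``N >> k`` with weak selection (``w k << 1``); the
    graph is treated as locally tree-like (Bethe lattice), so the result is
    accurate for random regular graphs but systematically optimistic for
    graphs with many short loops such as rings and lattices.  For ``k = 2``
    use :func:`cycle_coefficients`, which is exact.
    """
    if k < 3:
        raise ValueError(
            f"regular-graph approximation requires k >= 3 (got k={k}); "
            "for k = 2 use cycle_coefficients"
        )
    return StructureCoefficients(
        _regular_sigma_raw(k), "regular_approx", {"k": k, "N": math.inf}
    )


def cycle_overlapping_coefficients(N: SizeLike) -> StructureCoefficients:
    """Cycle coefficients when payoffs accumulate over overlapping games.

    If a focal player collects payoffs from the game centered on itself and
    from the two games centered on its neighbours (so that second-order
    neighbours matter), the exact cycle coefficients become
    ``((N+1)/(3(2N-3)), (2N-1)/(3(2N-3)), (N-3)/(2N-3))``.
    """
    if _is_inf(N):
        sigma = (Fraction(1, 6), Fraction(1, 3), Fraction(1, 2))
        return StructureCoefficients(sigma, "cycle_overlapping", {"N": math.inf, "k": 2})
    if N < 4:
        raise ValueError(f"cycle population size N={N} must be at least 4")
    sigma = (
        Fraction(N + 1, 3 * (2 * N - 3)),
        Fraction(2 * N - 1, 3 * (2 * N - 3)),
        Fraction(N - 3, 2 * N - 3),
    )
    return StructureCoefficients(sigma, "cycle_overlapping", {"N": N, "k": 2})


def pairwise_sigma_transitive(N: SizeLike, k: int) -> Union[Fraction, float]:
    """Single structure coefficient of transitive graphs for pairwise games.

    ``sigma = ((k+1) N - 4k) / ((k-1) N)``, applicable to two-player games
    (and to the delta-weak-selection analysis of mixed strategies) on
    vertex-transitive graphs of size ``N`` and degree ``k`` under
    death-Birth updating; the large-``N`` limit is ``(k+1)/(k-1)``.
    """
    if k < 2:
        raise ValueError(f"degree k must be at least 2, got {k}")
    if _is_inf(N):
        return Fraction(k + 1, k - 1)
    if N <= k:
        raise ValueError(f"population size N={N} must exceed degree k={k}")
    return Fraction((k + 1) * N - 4 * k, (k - 1) * N)


def scaled_relatedness(N: SizeLike, k: int) -> Union[Fraction, float]:
    """Scaled relatedness ``kappa = (N - 2k) / (k (N-2))``.

    The inclusive-fitness transform of the pairwise structure coefficient,
    ``kappa = (sigma - 1)/(sigma + 1)``; it tends to ``1/k`` for large
    populations and vanishes at ``N = 2k``.
    """
    if k < 1:
        raise ValueError(f"degree k must be at least 1, got {k}")
    if _is_inf(N):
        return Fraction(1, k)
    if N <= 2:
        raise ValueError(f"population size N={N} must exceed 2")
    return Fraction(N - 2 * k, k * (N - 2))
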