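"""Core model of the two-player iterated survival game.

Two players play an ``n``-step game. In each step both behave either
cooperatively (``C``) or defectively (``D``); the probability an individual
survives the step is ``a`` (both C), ``c`` (individual D, partner C), ``b``
(individual C, partner D) or ``d`` (both D). A player whose partner has died
finishes the game alone, surviving each remaining step with probability
``a0`` regardless of strategy. The payoff of a strategy is the probability
of being alive after all ``n`` steps.

Strategies are restricted to the switch-once family ``S_i``: cooperate for
the first ``n - i`` steps, defect for the final ``i``. ``S_0`` is all-C and
``S_n`` is all-D, so a strategy is identified with its number of end-game
defections.

The per-player process is a three-state absorbing Markov chain over
{paired, alone, dead}. Each phase of the game (CC, DC, CD or DD pairs) has a
3x3 row-stochastic single-step transition matrix whose powers have closed
forms; the overall payoff ``A(S_j; S_i)`` is the probability of not being
absorbed in the dead state after the product of the three phase blocks.

All closed forms route quotients of the type ``(x^k - y^k)/(x - y)`` through
:func:`geometric_ratio_sum`, so the removable singularities at
``a0 = a^2``, ``a0 = bc`` and ``a0 = d^2`` need no special-case branches.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AmbiguousGameError, NotPrisonersDilemmaError, ParameterError

__all__ = [
    "GameParams",
    "PairState",
    "PlayerState",
    "GameClass",
    "PayoffSurface",
    "make_game",
    "classify_single_step",
    "step_matrix",
    "step_matrix_power",
    "geometric_ratio_sum",
    "payoff",
    "payoff_oracle",
    "payoff_surface",
    "swap_bc",
]


class PlayerState(enum.Enum):
    """The three Markov states of the focal player."""

    PAIRED = 0
    ALONE = 1
    DEAD = 2


class PairState(enum.Enum):
    """Single-step behavior pair, the individual's behavior listed first."""

    CC = "CC"
    DC = "DC"
    CD = "CD"
    DD = "DD"


class GameClass(enum.Enum):
    """Classes of symmetric single-step games by sign of (c-a, d-b)."""

    PRISONERS_DILEMMA = "PrisonersDilemma"  # c > a, d > b
    STAG_HUNT = "StagHunt"                  # c < a, d > b
    HAWK_DOVE = "HawkDove"                  # c > a, d < b
    HARMONY = "Harmony"                     # c < a, d < b


@dataclass(frozen=True)
class GameParams:
    """One fully specified iterated survival game.

    Parameters
    ----------
    a, b, c, d : float
        Single-step survival probabilities of an individual whose own /
        partner's behaviors are CC, CD, DC, DD respectively; each strictly
        in (0, 1), with ``a > d`` (C is the more cooperative behavior).
    a0 : float
        Loner survival probability per step, strictly in (0, 1).
    n : int
        Game length in steps, at least 1.

    The pair-survival eigenvalues ``a^2``, ``bc`` and ``d^2`` of the
    single-step matrices are cached on construction.
    """

    a: float
    b: float
    c: float
    d: float
    a0: float
    n: int
    a2: float = field(init=False, repr=False)
    bc: float = field(init=False, repr=False)
    d2: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d", "a0"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and 0.0 < v < 1.0):
                raise ParameterError(
                    f"{name} must be strictly between 0 and 1, got {v!r}"
                )
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ParameterError(f"n must be a positive integer, got {self.n!r}")
        if not self.a > self.d:
            raise ParameterError(
                f"a must exceed d (C is the more cooperative behavior); "
                f"got a={self.a}, d={self.d}"
            )
        object.__setattr__(self, "a2", self.a * self.a)
        object.__setattr__(self, "bc", self.b * self.c)
        object.__setattr__(self, "d2", self.d * self.d)

    @property
    def is_strict_pd(self) -> bool:
        """True if c > a > d > b and a^2 > bc (strict Prisoner's Dilemma)."""
        return (
            self.c > self.a > self.d > self.b and self.a2 > self.bc
        )

    def require_strict_pd(self) -> None:
        if not self.is_strict_pd:
            raise NotPrisonersDilemmaError(
                f"strict Prisoner's Dilemma requires c > a > d > b and "
                f"a^2 > bc; got a={self.a}, b={self.b}, c={self.c}, "
                f"d={self.d} (a^2={self.a2:.6g}, bc={self.bc:.6g})"
            )

    def with_n(self, n: int) -> "GameParams":
        return replace(self, n=n)

    def with_a0(self, a0: float) -> "GameParams":
        return replace(self, a0=a0)


def make_game(
    a: float,
    b: float,
    c: float,
    d: float,
    a0: float,
    n: int,
    require_pd: bool = False,
) -> GameParams:
    """Validate parameters and build a :class:`GameParams`.

    With ``require_pd`` the strict Prisoner's Dilemma conditions
    ``c > a > d > b`` and ``a^2 > bc`` are additionally enforced.
    """
    g = GameParams(a=a, b=b, c=c, d=d, a0=a0, n=int(n))
    if require_pd:
        g.require_strict_pd()
    return g


def swap_bc(g: GameParams) -> GameParams:
    """The game with the roles of b and c exchanged.

    ``A(S_j; S_i)`` for the original game equals ``A(S_i; S_j)`` for the
    swapped game (the payoff is symmetric in b <-> c together with i <-> j).
    """
    return replace(g, b=g.c, c=g.b)


def classify_single_step(g: GameParams, tol: float = 1e-12) -> GameClass:
    """Class of the single-step game by the signs of c - a and d - b."""
    ca = g.c - g.a
    db = g.d - g.b
    if abs(ca) <= tol or abs(db) <= tol:
        raise AmbiguousGameError(
            f"single-step payoffs equal within tolerance (c-a={ca:.3g}, "
            f"d-b={db:.3g}); game class undefined"
        )
    if ca > 0:
        return GameClass.PRISONERS_DILEMMA if db > 0 else GameClass.HAWK_DOVE
    return GameClass.STAG_HUNT if db > 0 else GameClass.HARMONY


#: individual / partner single-step survival probabilities per behavior pair
def _pair_probs(g: GameParams, s: PairState) -> tuple[float, float]:
    return {
        PairState.CC: (g.a, g.a),
        PairState.DC: (g.c, g.b),
        PairState.CD: (g.b, g.c),
        PairState.DD: (g.d, g.d),
    }[s]


def step_matrix(g: GameParams, s: PairState) -> np.ndarray:
    """Single-step 3x3 transition matrix over {paired, alone, dead}.

    First row: both survive (x*y), individual survives alone (x*(1-y)),
    individual dies (1-x), where x / y are the individual's / partner's
    step survival probabilities for the behavior pair ``s``. The lower rows
    are common to all four matrices: a loner survives with ``a0`` and the
    dead state is absorbing.
    """
    x, y = _pair_probs(g, s)
    return np.array(
        [
            [x * y, x * (1.0 - y), 1.0 - x],
            [0.0, g.a0, 1.0 - g.a0],
            [0.0, 0.0, 1.0],
        ]
    )


def geometric_ratio_sum(x: float, y: float, k: int) -> float:
    """Sum_{m=0}^{k-1} x^m * y^(k-1-m).

    The continuous extension of ``(x^k - y^k) / (x - y)`` to ``x == y``,
    where it equals ``k * x^(k-1)``; the empty sum (k == 0) is 0. Evaluating
    the sum directly keeps the matrix-power and payoff closed forms exact at
    the removable singularities ``a0 = a^2``, ``a0 = bc`` and ``a0 = d^2``.
    """
    if k < 0:
        raise ParameterError(f"k must be nonnegative, got {k}")
    k = int(k)
    return math.fsum(x ** m * y ** (k - 1 - m) for m in range(k))


def step_matrix_power(g: GameParams, s: PairState, k: int) -> np.ndarray:
    """Closed-form k-th power of :func:`step_matrix`.

    With pair-survival eigenvalue ``e = x*y``:
    entry (1,1) = e^k, (1,2) = x(1-y) * geometric_ratio_sum(a0, e, k),
    rows 2 and 3 as for the single step with ``a0 -> a0^k``. Equals repeated
    multiplication of the single-step matrix for all k >= 0, including the
    degenerate case ``a0 == e``.
    """
    if k < 0:
        raise ParameterError(f"k must be nonnegative, got {k}")
    x, y = _pair_probs(g, s)
    e = x * y
    p11 = e ** k
    p12 = x * (1.0 - y) * geometric_ratio_sum(g.a0, e, k)
    a0k = g.a0 ** k
    return np.array(
        [
            [p11, p12, 1.0 - p11 - p12],
            [0.0, a0k, 1.0 - a0k],
            [0.0, 0.0, 1.0],
        ]
    )


def _check_indices(g: GameParams, j: int, i: int) -> None:
    if not (0 <= i <= g.n and 0 <= j <= g.n):
        raise IndexError(
            f"strategy indices must lie in [0, n={g.n}]; got j={j}, i={i}"
        )


def payoff(g: GameParams, j: int, i: int) -> float:
    """Survival probability A(S_j; S_i) of an S_j individual against S_i.

    Closed form: for j >= i the game decomposes into an all-CC phase of
    n - j steps, a DC phase of j - i steps and a DD phase of i steps, and

        A = a^{2(n-j)} (bc)^{j-i} d^{2i}
            + a(1-a)   a0^j            G(a0, a^2, n-j)
            + c(1-b)   a^{2(n-j)} a0^i G(a0, bc,  j-i)
            + d(1-d)   a^{2(n-j)} (bc)^{j-i} G(a0, d^2, i)

    with ``G = geometric_ratio_sum``. The first term is the probability both
    players survive throughout; the rest cover the partner dying in each of
    the three phases. For j <= i the same form applies with b <-> c and
    i <-> j exchanged.
    """
    _check_indices(g, j, i)
    if j < i:
        return payoff(swap_bc(g), i, j)
    a, b, c, d, a0 = g.a, g.b, g.c, g.d, g.a0
    aa, bc, dd = g.a2, g.bc, g.d2
    ncc = g.n - j
    acc = aa ** ncc
    both = acc * bc ** (j - i) * dd ** i
    die_cc = a * (1.0 - a) * a0 ** j * geometric_ratio_sum(a0, aa, ncc)
    die_dc = c * (1.0 - b) * acc * a0 ** i * geometric_ratio_sum(a0, bc, j - i)
    die_dd = d * (1.0 - d) * acc * bc ** (j - i) * geometric_ratio_sum(a0, dd, i)
    return both + die_cc + die_dc + die_dd


def payoff_oracle(g: GameParams, j: int, i: int) -> float:
    """A(S_j; S_i) by explicit multiplication of the n single-step matrices.

    Independent of the closed forms: builds the product of the per-step
    transition matrices in game order and sums the (paired) + (alone)
    entries of the first row. Retained in the public API as the package's
    cross-check of :func:`payoff`.
    """
    _check_indices(g, j, i)
    m = np.eye(3)
    for t in range(g.n):
        ind_d = t >= g.n - j
        part_d = t >= g.n - i
        s = {
            (False, False): PairState.CC,
            (True, False): PairState.DC,
            (False, True): PairState.CD,
            (True, True): PairState.DD,
        }[(ind_d, part_d)]
        m = m @ step_matrix(g, s)
    return float(m[0, 0] + m[0, 1])


@dataclass(frozen=True)
class PayoffSurface:
    """The full (n+1) x (n+1) payoff table, entry [j, i] = A(S_j; S_i)."""

    n: int
    values: np.ndarray

    def __getitem__(self, ji: tuple[int, int]) -> float:
        return float(self.values[ji])


def payoff_surface(g: GameParams) -> PayoffSurface:
    """All payoffs A(S_j; S_i), j, i in [0, n], from the closed form."""
    vals = np.empty((g.n + 1, g.n + 1))
    for j in range(g.n + 1):
        for i in range(g.n + 1):
            vals[j, i] = payoff(g, j, i)
    return PayoffSurface(n=g.n, values=vals)
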