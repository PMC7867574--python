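"""One-step incentives, stability, and incentive-structure classification.

A strategy S_i is *locally stable* against itself when neither defecting one
more time nor cooperating one more time raises the individual's survival:
A(S_i;S_i) > A(S_{i+1};S_i) and A(S_i;S_i) > A(S_{i-1};S_i), with only the
applicable condition at the endpoints i = 0 and i = n. Local stability is
equivalent to global stability (strict Nash / ESS) in these games; both are
exposed here, global stability by brute force over the payoff surface.

For a strict single-step Prisoner's Dilemma the locally stable strategies
form a stretch of consecutive integers [ceil(i_D), floor(i_C)] governed by
the cutoffs in :mod:`itersurv.thresholds`. Depending on where the loner
survival probability a0 falls relative to a0', a0'' there are ten parameter
regimes binned into five qualitative incentive structures:

1. additional defection always favored,
2. unbounded stretch of equilibria [ceil(i_D), n],
3. bounded stretch of equilibria (3a) or a single equilibrium point (3b),
4. unbounded stretch of disequilibria [ceil(i_C), n],
5. bounded stretch of disequilibria (5a) or incentives switching between two
   adjacent states (5b),

where a *disequilibrium* is a state from which both one more defection and
one more cooperation pay.

Payoff ties (|difference| below tolerance) raise :class:`PayoffTieError`
rather than silently choosing a sign; the analysis assumes
A(S_j;S_i) != A(S_i;S_i) for j != i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import PayoffTieError
from .game import GameParams, geometric_ratio_sum, payoff
from .thresholds import (
    a0_double_prime,
    a0_prime,
    i_C_real,
    i_D_real,
)

__all__ = [
    "IntInterval",
    "IncentiveClass",
    "defect_gain",
    "cooperate_gain",
    "diagonal_difference",
    "is_locally_stable",
    "is_globally_stable",
    "stable_stretch",
    "classify_incentives",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class IntInterval:
    """Closed integer interval [lo, hi]; empty when lo > hi."""

    lo: float  # extended integers (may be +/- inf)
    hi: float

    @property
    def empty(self) -> bool:
        return self.lo > self.hi

    def members(self) -> list[int]:
        if self.empty:
            return []
        if not (math.isfinite(self.lo) and math.isfinite(self.hi)):
            raise ValueError("cannot enumerate an unbounded interval")
        return list(range(int(self.lo), int(self.hi) + 1))

    def __contains__(self, i: int) -> bool:
        return not self.empty and self.lo <= i <= self.hi

    @staticmethod
    def empty_interval() -> "IntInterval":
        return IntInterval(lo=1, hi=0)


def _defect_bracket(g: GameParams, i: int) -> float:
    """Sign-defining part of A(S_{i+1};S_i) - A(S_i;S_i) (scale a^{2(n-1)}
    removed).

    Regrouped so the a0 = d^2 singularity is removable:
    (a^2-bc)(a0-d) G(a0,d^2,i)/a^{2i} + (c-a)(a0/a^2)^i
    with G the geometric-ratio sum.
    """
    a0, aa = g.a0, g.a2
    return (aa - g.bc) * (a0 - g.d) * geometric_ratio_sum(a0, g.d2, i) / aa ** i \
        + (g.c - g.a) * (a0 / aa) ** i


def _cooperate_bracket(g: GameParams, i: int) -> float:
    """Sign-defining part of A(S_{i-1};S_i) - A(S_i;S_i):
    (b-d)(a0/a^2)^{i-1} - (bc-d^2)(a0-d) G(a0,d^2,i-1)/a^{2(i-1)}."""
    a0, aa = g.a0, g.a2
    return (g.b - g.d) * (a0 / aa) ** (i - 1) \
        - (g.bc - g.d2) * (a0 - g.d) \
        * geometric_ratio_sum(a0, g.d2, i - 1) / aa ** (i - 1)


def defect_gain(g: GameParams, i: int) -> float:
    """Payoff change A(S_{i+1};S_i) - A(S_i;S_i) from one more defection."""
    if not 0 <= i <= g.n - 1:
        raise IndexError(f"defect_gain requires 0 <= i <= n-1; got i={i}")
    return g.a2 ** (g.n - 1) * _defect_bracket(g, i)


def cooperate_gain(g: GameParams, i: int) -> float:
    """Payoff change A(S_{i-1};S_i) - A(S_i;S_i) from one more cooperation."""
    if not 1 <= i <= g.n:
        raise IndexError(f"cooperate_gain requires 1 <= i <= n; got i={i}")
    return g.a2 ** (g.n - 1) * _cooperate_bracket(g, i)


def diagonal_difference(g: GameParams, i: int) -> float:
    """A(S_{i+1};S_{i+1}) - A(S_i;S_i); negative for every i when a > d.

    Closed form a^{2(n-i-1)} a0^i (d-a)
    [1 - (a+d)(a0-d) G(a0,d^2,i)/a0^i], the a0 = d^2 singularity removed via
    the geometric-ratio sum.
    """
    if not 0 <= i <= g.n - 1:
        raise IndexError(f"diagonal_difference requires 0 <= i <= n-1; got {i}")
    a0 = g.a0
    bracket = 1.0 - (g.a + g.d) * (a0 - g.d) \
        * geometric_ratio_sum(a0, g.d2, i) / a0 ** i
    return g.a2 ** (g.n - i - 1) * a0 ** i * (g.d - g.a) * bracket


def _checked_sign(value: float, what: str) -> bool:
    """True iff value < 0; raises on a tie within tolerance."""
    if abs(value) < _TIE_TOL:
        raise PayoffTieError(
            f"{what} is zero within tolerance ({value:.3e}); the analysis "
            "assumes no payoff ties"
        )
    return value < 0.0


def is_locally_stable(g: GameParams, i: int) -> bool:
    """Whether S_i is protected against one more defection and one more
    cooperation (only the applicable condition at i = 0 and i = n)."""
    if not 0 <= i <= g.n:
        raise IndexError(f"strategy index must lie in [0, n={g.n}]; got {i}")
    ok = True
    if i <= g.n - 1:
        ok &= _checked_sign(_defect_bracket(g, i), f"defection gain at i={i}")
    if ok and i >= 1:
        ok &= _checked_sign(
            _cooperate_bracket(g, i), f"cooperation gain at i={i}"
        )
    return ok


def is_globally_stable(g: GameParams, i: int) -> bool:
    """Whether S_i is a strict Nash equilibrium: A(S_i;S_i) > A(S_j;S_i) for
    every j != i, checked by brute force over all n+1 responses."""
    if not 0 <= i <= g.n:
        raise IndexError(f"strategy index must lie in [0, n={g.n}]; got {i}")
    own = payoff(g, i, i)
    for j in range(g.n + 1):
        if j == i:
            continue
        diff = payoff(g, j, i) - own
        if abs(diff) < _TIE_TOL:
            raise PayoffTieError(
                f"A(S_{j};S_{i}) ties A(S_{i};S_{i}) within tolerance"
            )
        if diff > 0.0:
            return False
    return True


def stable_stretch(g: GameParams, large_n: bool = False) -> IntInterval:
    """The interval of locally stable strategies.

    With ``large_n=False`` (default) this matches ``{i: is_locally_stable}``
    exactly for the concrete game length n, including the endpoint effect
    that S_n needs only the cooperation condition — so S_n stays stable even
    when i_D does not exist. With ``large_n=True`` that n-induced endpoint
    stability is excluded, giving the stretch in the idealized
    arbitrarily-long game (empty when i_D does not exist).
    """
    g.require_strict_pd()
    iD = i_D_real(g)
    iC = i_C_real(g)
    if math.isinf(iD):
        if large_n:
            return IntInterval.empty_interval()
        lo = g.n
    else:
        lo = min(max(math.ceil(iD), 1), g.n)
    hi = g.n if math.isinf(iC) else min(math.floor(iC), g.n)
    if lo > hi:
        return IntInterval.empty_interval()
    return IntInterval(lo=lo, hi=hi)


@dataclass(frozen=True)
class IncentiveClass:
    """Classification of one game's incentive structure.

    ``case_id`` is the fine-grained regime 1-10; ``type_id`` bins it into
    the five qualitative types; ``label`` carries the sub-lettered name
    (e.g. "3a", "5b"). At most one of the two stretches is non-empty;
    ``switch_pair`` is set only for the adjacent-states switching regime
    (type 5b).
    """

    case_id: int
    type_id: int
    label: str
    equilibrium_stretch: IntInterval
    disequilibrium_stretch: IntInterval
    switch_pair: tuple[int, int] | None = None
    i_D: float = math.inf
    i_C: float = math.inf

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "type_id": self.type_id,
            "label": self.label,
            "equilibrium_stretch": None
            if self.equilibrium_stretch.empty
            else [self.equilibrium_stretch.lo, self.equilibrium_stretch.hi],
            "disequilibrium_stretch": None
            if self.disequilibrium_stretch.empty
            else [self.disequilibrium_stretch.lo, self.disequilibrium_stretch.hi],
            "switch_pair": self.switch_pair,
            "i_D": self.i_D,
            "i_C": self.i_C,
        }


def classify_incentives(g: GameParams, large_n: bool = True) -> IncentiveClass:
    """Bin a strict-PD game into one of the ten incentive regimes.

    Decision tree: first bc vs d^2, then the ordering of the cutoffs a0' and
    a0'', then where a0 falls relative to them, and finally — in the
    crossing regime — the comparison of floor(i_D) and floor(i_C). The
    sub-lettered cases map onto five types; see the module docstring.

    With ``large_n=False`` the stretches are capped at the concrete game
    length n and re-examined for emptiness (and the equilibrium stretch
    includes the n-endpoint stability of S_n).
    """
    g.require_strict_pd()
    a0 = g.a0
    ap = a0_prime(g)
    iD = i_D_real(g)
    iC = i_C_real(g)
    empty = IntInterval.empty_interval()
    eq = stable_stretch(g, large_n=large_n)
    diseq = empty
    switch_pair = None

    if g.bc <= g.d2:
        case = 1 if a0 >= ap else 2
    else:
        app = a0_double_prime(g)
        if ap >= app:
            if a0 >= ap:
                case = 3
            elif a0 >= app:
                case = 4
            else:
                case = 5
        else:
            if a0 >= app:
                case = 6
            elif a0 >= ap:
                case = 7
                diseq = IntInterval(lo=math.ceil(iC), hi=g.n)
                if not large_n and diseq.lo > g.n:
                    diseq = empty
            else:
                fd, fc = math.floor(iD), math.floor(iC)
                if fd > fc:
                    case = 8
                    diseq = IntInterval(lo=math.ceil(iC), hi=fd)
                    if not large_n:
                        diseq = IntInterval(
                            lo=diseq.lo, hi=min(diseq.hi, g.n)
                        )
                        if diseq.lo > diseq.hi:
                            diseq = empty
                elif fd == fc:
                    case = 9
                    switch_pair = (fd, math.ceil(iD))
                else:
                    case = 10

    type_id = {1: 1, 2: 2, 3: 1, 4: 2, 5: 3, 6: 1, 7: 4, 8: 5, 9: 5, 10: 3}[case]
    label = {1: "1", 2: "2", 3: "1", 4: "2", 5: "3a", 6: "1", 7: "4",
             8: "5a", 9: "5b", 10: "3b"}[case]
    return IncentiveClass(
        case_id=case,
        type_id=type_id,
        label=label,
        equilibrium_stretch=eq,
        disequilibrium_stretch=diseq,
        switch_pair=switch_pair,
        i_D=iD,
        i_C=iC,
    )
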