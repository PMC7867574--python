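"""Analytic cutoffs of the Prisoner's-Dilemma iterated survival game.

Four loner-survival cutoffs organize the incentive structure:

* ``a0_star``   -- largest a0 for which a finite optimal number of end-game
  defections against an all-C partner exists; a weighted average of a^2 and
  a with weights (c - a) and (a^2 - bc).
* ``a0_prime``  -- largest a0 for which additional defection eventually
  becomes disfavored as the partner's defection count i grows; the same
  weighted average of d^2 and d.
* ``a0_double_prime`` -- largest a0 for which additional cooperation
  eventually becomes favored; defined only when bc > d^2; average of d^2 and
  d with weights (d - b) and (bc - d^2).
* ``a0_triple_prime`` -- the a0 at which the defection cutoff i_D and the
  cooperation cutoff i_C cross, separating single-equilibrium regimes from
  disequilibrium regimes when a0_prime < a0_double_prime.

The partner-strategy cutoffs:

* ``i_D`` -- one more defection pays iff the partner's defection count
  i < i_D; exists iff a0 < a0_prime.
* ``i_C`` -- one more cooperation pays iff i > i_C; exists iff bc > d^2 and
  a0 < a0_double_prime.
* ``j_opt`` / ``J_opt`` -- real and integer optimal defection counts against
  an all-C partner; j_opt exists iff a0 < a0_star.
* ``j_star`` / ``k_star(i)`` -- closed-form best responses: against heavy
  defectors (i >= ceil(i_C)) the best reply defects ceil(j_star) = floor(i_C)
  times; against light defectors (i <= floor(i_D)) it adds ceil(k_star(i))
  defections.

Nonexistence is encoded as ``math.inf``, never as an exception: the Table-2
style classification treats nonexistence as a parameter regime. When a0 sits
within 1e-12 of a cutoff the threshold is reported nonexistent (the paper-
convention ">=" side of the boundary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from scipy.optimize import brentq

from .errors import ThresholdDomainError
from .game import GameParams, payoff

__all__ = [
    "ThresholdSet",
    "a0_star",
    "a0_prime",
    "a0_double_prime",
    "a0_triple_prime",
    "j_opt_real",
    "J_opt",
    "i_D_real",
    "i_C_real",
    "j_star",
    "k_star",
    "H_aux",
    "a0_solving_i_D",
    "threshold_set",
]

_BOUNDARY_TOL = 1e-12


def a0_star(g: GameParams) -> float:
    """Cutoff for existence of an optimal defection count against all-C.

    Weighted average ((c-a) a^2 + (a^2-bc) a) / (c-a + a^2-bc); lies
    strictly between a^2 and a for a strict PD.
    """
    g.require_strict_pd()
    ca = g.c - g.a
    w = g.a2 - g.bc
    return (ca * g.a2 + w * g.a) / (ca + w)


def a0_prime(g: GameParams) -> float:
    """Cutoff for existence of i_D: ((c-a) d^2 + (a^2-bc) d)/(c-a + a^2-bc).

    Same weights as :func:`a0_star` but averaging d^2 and d, because the
    marginal defection under scrutiny happens while the partner still
    cooperates but is followed by i rounds of mutual defection.
    """
    g.require_strict_pd()
    ca = g.c - g.a
    w = g.a2 - g.bc
    return (ca * g.d2 + w * g.d) / (ca + w)


def a0_double_prime(g: GameParams) -> float:
    """Cutoff for existence of i_C: ((d-b) d^2 + (bc-d^2) d)/(d-b + bc-d^2).

    Defined only when bc > d^2 (otherwise an extra cooperation never gains
    enough pair survival to offset the individual cost b - d < 0).
    """
    g.require_strict_pd()
    if g.bc <= g.d2:
        raise ThresholdDomainError(
            f"a0'' requires bc > d^2; got bc={g.bc:.6g}, d^2={g.d2:.6g}"
        )
    db = g.d - g.b
    w = g.bc - g.d2
    return (db * g.d2 + w * g.d) / (db + w)


def a0_triple_prime(g: GameParams) -> float:
    """The a0 at which i_D(a0) == i_C(a0).

    Only meaningful in the crossing regime bc > d^2 with
    a0_prime < a0_double_prime; below it the stretch between i_D and i_C
    holds equilibria, above it disequilibria.
    """
    g.require_strict_pd()
    if g.bc <= g.d2:
        raise ThresholdDomainError("a0''' requires bc > d^2")
    if not a0_prime(g) < a0_double_prime(g):
        raise ThresholdDomainError(
            "a0''' requires the crossing case a0' < a0''"
        )
    num = g.b * g.d * (g.c - g.d) * (g.a2 - g.bc)
    den = (g.a2 - g.bc + g.c - g.a) * (g.bc - g.d2)
    return num / den


def _ratio_pow(x: float, k: float) -> float:
    """(x^k - 1)/(x - 1) extended continuously to x == 1 (value k)."""
    if abs(x - 1.0) < 1e-9:
        # x^k - 1 = expm1(k log x); series-safe near 1
        lx = math.log(x) if x != 1.0 else 0.0
        if lx == 0.0:
            return float(k)
        return math.expm1(k * lx) / (x - 1.0)
    return (x ** k - 1.0) / (x - 1.0)


def i_D_real(g: GameParams) -> float:
    """Partner defection count above which one more defection stops paying.

    i_D = ln(1 + (c-a)/(a^2-bc) * (a0-d^2)/(a0-d)) / ln(d^2/a0);
    exists iff a0 < a0_prime (returns inf otherwise). The a0 = d^2
    degenerate point folds in continuously with value
    (c-a)/(a^2-bc) * d/(1-d).
    """
    g.require_strict_pd()
    if g.a0 >= a0_prime(g) - _BOUNDARY_TOL:
        return math.inf
    r = (g.c - g.a) / (g.a2 - g.bc)
    if abs(g.a0 - g.d2) < 1e-9:
        return r * g.d / (1.0 - g.d)
    arg = 1.0 + r * (g.a0 - g.d2) / (g.a0 - g.d)
    if arg <= 0.0:
        return math.inf
    return math.log(arg) / math.log(g.d2 / g.a0)


def i_C_real(g: GameParams) -> float:
    """Partner defection count above which one more cooperation pays.

    i_C = 1 + ln(1 + (d-b)/(bc-d^2) * (a0-d^2)/(a0-d)) / ln(d^2/a0);
    exists iff bc > d^2 and a0 < a0_double_prime (inf otherwise); continuous
    at a0 = d^2 with value 1 + (d-b)/(bc-d^2) * d/(1-d).
    """
    g.require_strict_pd()
    if g.bc <= g.d2:
        return math.inf
    if g.a0 >= a0_double_prime(g) - _BOUNDARY_TOL:
        return math.inf
    r = (g.d - g.b) / (g.bc - g.d2)
    if abs(g.a0 - g.d2) < 1e-9:
        return 1.0 + r * g.d / (1.0 - g.d)
    arg = 1.0 + r * (g.a0 - g.d2) / (g.a0 - g.d)
    if arg <= 0.0:
        return math.inf
    return 1.0 + math.log(arg) / math.log(g.d2 / g.a0)


def _allc_bracket(g: GameParams, j: float) -> float:
    """The j-dependent bracket of A(S_j;S_0), free of the a^{2n} scale.

    Evaluated in a form regular at a0 == bc and a0 == a^2 so it can be
    maximized numerically in the degenerate cases: the singular coefficient
    pairs are regrouped through (x^j - 1)/(x - 1) ratios.
    """
    a, b, c, a0 = g.a, g.b, g.c, g.a0
    aa, bc = g.a2, g.bc
    u = bc / aa
    v = a0 / aa
    # (a0-c)/(a0-bc) u^j + (c-bc)/(a0-bc) v^j
    #   = u^j + c(1-b)/aa * (v^j - u^j)/(v - u)
    if abs(v - u) < 1e-9:
        dvu = j * u ** (j - 1.0) if j > 0 else 0.0
    else:
        dvu = (v ** j - u ** j) / (v - u)
    term = u ** j + c * (1.0 - b) / aa * dvu
    # -(a - a^2)/(a0 - a^2) v^j = -a(1-a)/aa * (v^j - 1)/(v - 1) - v^j ... :
    # (a0 - a)/(a0 - aa) = 1 + a(1-a)/aa * 1/(v-1); multiply by v^j:
    if abs(v - 1.0) < 1e-9:
        rv = float(j)
    else:
        rv = (v ** j - 1.0) / (v - 1.0)
    # -(a-a^2)/(a0-a^2) * v^j  ==  -a(1-a)/(a0-aa) * v^j
    #   = -a(1-a)/aa * [ (v^j - 1)/(v - 1) + v^j/(v-1) - (v^j-1)/(v-1) ] ...
    # use directly when regular:
    if abs(g.a0 - aa) > 1e-9:
        term -= a * (1.0 - a) / (g.a0 - aa) * v ** j
    else:
        # a0 == a^2: -(a(1-a)/aa) * lim (v^j)/(v-1) diverges termwise but the
        # combination with the n-dependent constant is what matters for the
        # argmax; the j-derivative of A reduces to the logarithmic form below,
        # so approximate v^j/(v-1) via its finite difference ratio: v^j =
        # 1 + (v-1) rv  =>  v^j/(v-1) = 1/(v-1) + rv; the 1/(v-1) piece is
        # j-independent and drops from the argmax.
        term -= a * (1.0 - a) / aa * rv
    return term


def j_opt_real(g: GameParams) -> float:
    """Real-valued optimal defection count against an all-C partner.

    From the stationarity of A(S_j;S_0) in continuous j:

        j_opt = ln[ (a(1-a)(a0-bc)/((a0-c)(a0-a^2)) - c(1-b)/(a0-c))
                    * ln(a0/a^2)/ln(bc/a^2) ] / ln(bc/a0)

    Exists (is finite) iff a0 < a0_star; returns inf otherwise. The
    degenerate points a0 = a^2 and a0 = bc are handled by the derivative
    zero of the logarithm-free form and by numerical maximization of a
    singularity-free bracket, respectively.
    """
    g.require_strict_pd()
    if g.a0 >= a0_star(g) - _BOUNDARY_TOL:
        return math.inf
    a, b, c, a0 = g.a, g.b, g.c, g.a0
    aa, bc = g.a2, g.bc
    if abs(a0 - aa) < 1e-9:
        # d/dj of a^{2n}[ (a^2-c)/(a^2-bc) (bc/a^2)^j + (n-j)(1-a)/a + ... ]
        rhs = ((1.0 - a) / a) / ((aa - c) / (aa - bc) * math.log(bc / aa))
        return math.log(rhs) / math.log(bc / aa)
    if abs(a0 - bc) < 1e-9 or abs(a0 - c) < 1e-12:
        return _j_opt_numeric(g)
    arg = (
        a * (1.0 - a) * (a0 - bc) / ((a0 - c) * (a0 - aa))
        - c * (1.0 - b) / (a0 - c)
    ) * (math.log(a0 / aa) / math.log(bc / aa))
    if arg <= 0.0:
        return math.inf
    return math.log(arg) / math.log(bc / a0)


def _j_opt_numeric(g: GameParams) -> float:
    """Argmax of the all-C bracket over continuous j by golden search."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda j: -_allc_bracket(g, j), bounds=(0.0, 4000.0), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def J_opt(g: GameParams):
    """Integer optimal defection count against an all-C partner.

    floor or ceil of j_opt, whichever yields the larger A(S_j;S_0); equal to
    n when the game is too short (n <= j_opt); inf when j_opt does not exist
    (every additional defection keeps paying, so the optimum is only capped
    by n).
    """
    jo = j_opt_real(g)
    if math.isinf(jo):
        return math.inf
    if g.n <= jo:
        return g.n
    lo = max(0, math.floor(jo))
    hi = min(g.n, math.ceil(jo))
    if lo == hi:
        return lo
    return lo if payoff(g, lo, 0) >= payoff(g, hi, 0) else hi


def j_star(g: GameParams) -> float:
    """Closed-form best-response locator against heavy defectors.

    Zero in continuous j of the multi-step cooperation gain
    A(S_j;S_i) - A(S_{j+1};S_i) on the j <= i side:

        (a0/d^2)^{j*} = (bc-d^2)(a0-d) /
                        [ (bc-d^2)(a0-d) - (b-d)(a0-d^2) ]

    identically equal to i_C - 1, so ceil(j*) = floor(i_C): against heavy
    defectors the best reply on the cooperation side defects exactly
    floor(i_C) times, independent of i. Requires i_C to exist.
    """
    g.require_strict_pd()
    if math.isinf(i_C_real(g)):
        raise ThresholdDomainError("j* requires i_C to exist")
    bcd = (g.bc - g.d2) * (g.a0 - g.d)
    num = bcd / (bcd - (g.b - g.d) * (g.a0 - g.d2))
    return math.log(num) / math.log(g.a0 / g.d2)


def H_aux(g: GameParams, i: int) -> float:
    """Auxiliary coefficient of the multi-step defection-gain bracket.

    H = (a^2-bc) ( c(1-b)/(a0-bc) - d(1-d)/(a0-d^2)
                   - (a0-d)/(a0-d^2) (d^2/a0)^i ).
    """
    g.require_strict_pd()
    a0 = g.a0
    return (g.a2 - g.bc) * (
        g.c * (1.0 - g.b) / (a0 - g.bc)
        - g.d * (1.0 - g.d) / (a0 - g.d2)
        - (a0 - g.d) / (a0 - g.d2) * (g.d2 / a0) ** i
    )


def _defection_run_bracket(g: GameParams, i: int, k: float) -> float:
    """Sign-defining bracket of A(S_{i+k+1};S_i) - A(S_{i+k};S_i) in
    continuous k, regular at a0 == bc and a0 == d^2.

    Equals H + (c-a+a^2-bc) (a0-a0*)/(a0-bc) (a0/bc)^k after removing the
    exactly cancelling (a0-bc) and (a0-d^2) quotients via
    (x^k - 1)/(x - 1) ratios.
    """
    a, b, c, d, a0 = g.a, g.b, g.c, g.d, g.a0
    aa, bc, dd = g.a2, g.bc, g.d2
    w = (a0 / bc) ** k
    # regular part of H: -(a^2-bc) [ d(1-d) rho(d^2/a0, i)/a0 + (d^2/a0)^i ]
    reg_h = -(aa - bc) * (
        d * (1.0 - d) * _ratio_pow(dd / a0, i) / a0 + (dd / a0) ** i
    )
    return (
        reg_h
        + (c - a + aa - bc) * w
        - (aa - bc) * c * (1.0 - b) * _ratio_pow(a0 / bc, k) / bc
    )


def k_star(g: GameParams, i: int) -> float:
    """Real-valued additional-defection optimum against an S_i partner.

    Zero in continuous k of the one-extra-defection gain
    A(S_{i+k+1};S_i) - A(S_{i+k};S_i):

        k*(i) = ln( -H (a0-bc) / ((c-a+a^2-bc)(a0-a0*)) ) / ln(a0/bc)

    Defined for i <= floor(i_D) or when i_D does not exist; returns inf when
    the gain never changes sign (additional defection pays for every k, the
    a0 >= a0_star regime). Near the cancellation-prone spots a0 ~ bc and
    a0 ~ a0_star the root is found by bisection on a regularized bracket.
    """
    g.require_strict_pd()
    if i < 0:
        raise ThresholdDomainError("k* requires i >= 0")
    iD = i_D_real(g)
    if not (math.isinf(iD) or i <= math.floor(iD)):
        raise ThresholdDomainError(
            f"k* is defined for i <= floor(i_D)={math.floor(iD)}; got i={i}"
        )
    a0s = a0_star(g)
    if g.a0 >= a0s - _BOUNDARY_TOL:
        return math.inf
    a0 = g.a0
    safe = abs(a0 - g.bc) > 1e-6 and abs(a0 - a0s) > 1e-6
    if safe:
        arg = -H_aux(g, i) * (a0 - g.bc) / (
            (g.c - g.a + g.a2 - g.bc) * (a0 - a0s)
        )
        if arg > 0.0:
            ks = math.log(arg) / math.log(a0 / g.bc)
            if ks >= 0.0 or i == 0:
                return ks
    # bisection fallback on the regularized bracket
    f0 = _defection_run_bracket(g, i, 0.0)
    if f0 <= 0.0:
        return 0.0
    hi = 1.0
    while _defection_run_bracket(g, i, hi) > 0.0:
        hi *= 2.0
        if hi > 1e6:
            return math.inf
    return float(brentq(lambda k: _defection_run_bracket(g, i, k), 0.0, hi,
                        xtol=1e-12))


def a0_solving_i_D(g: GameParams, target: float) -> float:
    """The loner survival probability at which i_D equals ``target``.

    i_D is continuous and strictly increasing in a0 on (0, a0_prime), from 0
    to +inf, so the equation i_D(a0) = target has a unique root found by
    Brent's method.
    """
    g.require_strict_pd()
    ap = a0_prime(g)
    lo, hi = 1e-9, ap - 1e-9

    def f(a0: float) -> float:
        return i_D_real(g.with_a0(a0)) - target

    return float(brentq(f, lo, hi, xtol=1e-12))


@dataclass(frozen=True)
class ThresholdSet:
    """All cutoffs of one game; nonexistent quantities are +inf / None."""

    a0_star: float
    a0_prime: float
    a0_double_prime: float | None
    a0_triple_prime: float | None
    j_opt: float
    J_opt: float
    i_D: float
    i_C: float
    j_star: float
    H: float  # at i = 0

    @property
    def i_D_exists(self) -> bool:
        return math.isfinite(self.i_D)

    @property
    def i_C_exists(self) -> bool:
        return math.isfinite(self.i_C)

    @property
    def j_opt_exists(self) -> bool:
        return math.isfinite(self.j_opt)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(
            i_D_exists=self.i_D_exists,
            i_C_exists=self.i_C_exists,
            j_opt_exists=self.j_opt_exists,
        )
        return d


def threshold_set(g: GameParams) -> ThresholdSet:
    """Evaluate every cutoff for one game (strict PD required)."""
    g.require_strict_pd()
    app = a0_double_prime(g) if g.bc > g.d2 else None
    try:
        appp = a0_triple_prime(g)
    except ThresholdDomainError:
        appp = None
    iC = i_C_real(g)
    try:
        js = j_star(g)
    except ThresholdDomainError:
        js = math.inf
    return ThresholdSet(
        a0_star=a0_star(g),
        a0_prime=a0_prime(g),
        a0_double_prime=app,
        a0_triple_prime=appp,
        j_opt=j_opt_real(g),
        J_opt=J_opt(g),
        i_D=i_D_real(g),
        i_C=iC,
        j_star=js,
        H=H_aux(g, 0),
    )
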