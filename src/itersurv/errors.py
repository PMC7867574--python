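"""Exception types shared across the package."""


class ItersurvError(Exception):
    """Base class for all itersurv errors."""


class ParameterError(ItersurvError, ValueError):
    """A game parameter is outside its admissible range."""


class NotPrisonersDilemmaError(ItersurvError, ValueError):
    """Parameters violate the strict Prisoner's Dilemma conditions
    c > a > d > b and a^2 > bc."""


class AmbiguousGameError(ItersurvError, ValueError):
    """Single-step payoffs are equal within tolerance, so the game class
    (Prisoner's Dilemma / Stag Hunt / Hawk-Dove / Harmony) is undefined."""


class PayoffTieError(ItersurvError, ArithmeticError):
    """Two overall payoffs are equal within tolerance.

    The equilibrium analysis assumes A(S_j;S_i) != A(S_i;S_i) for j != i;
    ties are a measure-zero boundary and are reported rather than resolved
    by an arbitrary sign choice.
    """


class ThresholdDomainError(ItersurvError, ValueError):
    """A cutoff was requested outside the parameter regime where it is
    defined (e.g. the crossing cutoff when bc <= d^2)."""
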