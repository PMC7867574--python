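"""Stochastic simulation of actual game play.

Validates the closed-form payoffs by playing the game: in each step both
players survive independently with the probability set by their scheduled
behaviors; once the partner dies the focal individual survives each
remaining step with the loner probability a0. The estimator is the
proportion of replicate games the focal individual finishes alive, with a
normal-approximation 95% confidence interval.

Only the focal player's three-state chain plus the partner's aliveness are
tracked — the partner's own loner phase is irrelevant to the focal payoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ParameterError
from .game import GameParams

__all__ = ["EstimateWithCI", "play_once", "estimate_payoff"]


@dataclass(frozen=True)
class EstimateWithCI:
    """A Monte-Carlo survival estimate with its 95% half-width and seed."""

    estimate: float
    reps: int
    half_width: float
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _step_probs(g: GameParams, t: int, j: int, i: int) -> tuple[float, float]:
    """(individual, partner) survival probabilities in step t (0-based)."""
    ind_d = t >= g.n - j
    part_d = t >= g.n - i
    if ind_d and part_d:
        return g.d, g.d
    if ind_d:
        return g.c, g.b
    if part_d:
        return g.b, g.c
    return g.a, g.a


def play_once(g: GameParams, j: int, i: int, rng: np.random.Generator) -> bool:
    """Play one n-step game of S_j against S_i; True if the focal individual
    survives all n steps."""
    if not (0 <= i <= g.n and 0 <= j <= g.n):
        raise IndexError(
            f"strategy indices must lie in [0, n={g.n}]; got j={j}, i={i}"
        )
    partner_alive = True
    for t in range(g.n):
        if partner_alive:
            p_ind, p_part = _step_probs(g, t, j, i)
            if rng.random() >= p_ind:
                return False
            partner_alive = rng.random() < p_part
        else:
            if rng.random() >= g.a0:
                return False
    return True


def estimate_payoff(
    g: GameParams, j: int, i: int, reps: int, seed: int
) -> EstimateWithCI:
    """Monte-Carlo estimate of A(S_j; S_i) over ``reps`` independent games.

    Vectorized over replicates; one seeded generator per call so the result
    is bit-reproducible from (parameters, reps, seed).
    """
    if reps < 1:
        raise ParameterError(f"reps must be at least 1, got {reps}")
    if not (0 <= i <= g.n and 0 <= j <= g.n):
        raise IndexError(
            f"strategy indices must lie in [0, n={g.n}]; got j={j}, i={i}"
        )
    rng = np.random.default_rng(seed)
    alive = np.ones(reps, dtype=bool)
    partner = np.ones(reps, dtype=bool)
    for t in range(g.n):
        p_ind, p_part = _step_probs(g, t, j, i)
        u_ind = rng.random(reps)
        u_part = rng.random(reps)
        p_focal = np.where(partner, p_ind, g.a0)
        new_alive = alive & (u_ind < p_focal)
        # the partner's fate only matters while it is alive and paired; the
        # draw is consumed unconditionally to keep the stream layout simple
        partner = partner & (u_part < p_part)
        alive = new_alive
    p_hat = float(alive.mean())
    half = 1.96 * math.sqrt(p_hat * (1.0 - p_hat) / reps)
    return EstimateWithCI(estimate=p_hat, reps=reps, half_width=half, seed=seed)
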