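"""Shared fixtures: the worked example games and random strict-PD samplers."""

from __future__ import annotations

import numpy as np
import pytest

from itersurv import GameParams, make_game


@pytest.fixture
def pd_game():
    """The running Prisoner's Dilemma example (a linear transform of the
    classic R=3, S=0, T=5, P=1 payoffs), small loner survival, n=50."""
    return make_game(0.97, 0.94, 0.99, 0.95, 0.8, 50, require_pd=True)


@pytest.fixture
def equilibria_game():
    """Game with a bounded stretch of equilibria [4, 15] at n=20."""
    return make_game(0.97, 0.93, 0.98, 0.95, 0.86, 20, require_pd=True)


@pytest.fixture
def disequilibria_game():
    """Game with a bounded stretch of disequilibria [5, 13] at n=20 and a
    two-state best-response cycle {4, 11}."""
    return make_game(0.97, 0.94, 0.99, 0.95, 0.86, 20, require_pd=True)


@pytest.fixture
def capped_equilibria_game():
    """Game whose equilibrium stretch is capped by n: stable for i >= 12."""
    return make_game(0.97, 0.93, 0.98, 0.95, 0.92, 20, require_pd=True)


@pytest.fixture
def single_equilibrium_game():
    """Game with a unique globally stable strategy at i = 4."""
    return make_game(0.97, 0.93, 0.99, 0.949, 0.78, 20, require_pd=True)


@pytest.fixture
def defection_game():
    """bc < d^2 and a0 > a0': additional defection always favored."""
    return make_game(0.97, 0.91, 0.98, 0.95, 0.95, 20, require_pd=True)


def random_strict_pd(
    rng: np.random.Generator,
    n_range: tuple[int, int] = (1, 12),
    abcd_range: tuple[float, float] = (0.5, 0.999),
    a0_range: tuple[float, float] = (0.05, 0.95),
    require_bc_gt_d2: bool = False,
) -> GameParams:
    """One random strict-PD game (c > a > d > b, a^2 > bc) by rejection."""
    while True:
        b, d, a, c = np.sort(rng.uniform(*abcd_range, size=4))
        if a * a <= b * c:
            continue
        if require_bc_gt_d2 and b * c <= d * d:
            continue
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        return GameParams(
            a=float(a), b=float(b), c=float(c), d=float(d),
            a0=float(rng.uniform(*a0_range)), n=n,
        )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
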