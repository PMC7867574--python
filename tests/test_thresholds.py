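"""Analytic cutoffs: values, existence regimes, limits, monotonicity."""

import math

import numpy as np
import pytest

from itersurv import (
    GameParams,
    J_opt,
    NotPrisonersDilemmaError,
    ThresholdDomainError,
    a0_double_prime,
    a0_prime,
    a0_solving_i_D,
    a0_star,
    a0_triple_prime,
    i_C_real,
    i_D_real,
    j_opt_real,
    j_star,
    k_star,
    make_game,
    payoff,
    threshold_set,
)
from conftest import random_strict_pd


FIG6_ABCD = (0.97, 0.94, 0.99, 0.95)  # running example PD
FIG5_ABCD = (0.97, 0.93, 0.98, 0.95)  # same with b, c lowered by 0.01


def _game(abcd, a0, n=20):
    return make_game(*abcd, a0, n, require_pd=True)


class TestA0Cutoffs:
    def test_a0_star_value_and_bounds(self):
        g = _game(FIG6_ABCD, 0.8)
        s = a0_star(g)
        assert s == pytest.approx(0.9508, abs=5e-5)
        assert g.a2 < s < g.a

    def test_a0_star_flags_sign_change_of_allc_gain(self):
        """Just below a0*, A(S_j;S_0)-A(S_0;S_0) peaks and falls; just
        above, it keeps growing (middle coefficient changes sign)."""
        g = _game(FIG6_ABCD, 0.8, n=400)
        s = a0_star(g)
        below = g.with_a0(s - 1e-3)
        above = g.with_a0(s + 1e-3)
        tail_below = [payoff(below, j, 0) for j in (396, 398, 400)]
        tail_above = [payoff(above, j, 0) for j in (396, 398, 400)]
        assert tail_below[0] > tail_below[-1]  # decreasing: finite optimum
        assert tail_above[0] < tail_above[-1]  # increasing: defect forever

    def test_a0_star_decreases_toward_a2_as_bc_approaches_a2(self):
        """a0* sits closer to a^2 when the pair-survival cost a^2 - bc is
        small relative to the individual gain c - a."""
        a, _, c, d = FIG6_ABCD
        gaps = []
        for b in (0.94, 0.945, 0.9499):  # bc -> a^2 = 0.9409 from below
            g = make_game(a, b, c, d, 0.5, 10, require_pd=True)
            gaps.append(a0_star(g) - g.a2)
        assert all(x > 0 for x in gaps)
        assert gaps == sorted(gaps, reverse=True)
        assert gaps[-1] < 0.002  # nearly collapsed onto a^2

    def test_a0_prime_value(self):
        g = _game(FIG6_ABCD, 0.8)
        assert a0_prime(g) == pytest.approx(0.9186, abs=5e-5)
        assert g.d2 < a0_prime(g) < g.d

    def test_a0_double_prime_value(self):
        g = _game(FIG6_ABCD, 0.8)
        assert a0_double_prime(g) == pytest.approx(0.9375, abs=5e-5)

    def test_a0_double_prime_requires_bc_gt_d2(self):
        g = make_game(0.97, 0.91, 0.98, 0.95, 0.5, 20, require_pd=True)
        assert g.bc < g.d2
        with pytest.raises(ThresholdDomainError):
            a0_double_prime(g)

    def test_a0_triple_prime_value_and_defining_property(self):
        g = _game(FIG6_ABCD, 0.8)
        appp = a0_triple_prime(g)
        assert appp == pytest.approx(0.43, abs=5e-3)
        gx = g.with_a0(appp)
        assert i_D_real(gx) == pytest.approx(i_C_real(gx), abs=1e-9)

    def test_a0_triple_prime_outside_crossing_case_is_domain_error(self):
        g = _game(FIG5_ABCD, 0.5)  # a0' > a0'': no crossing
        with pytest.raises(ThresholdDomainError):
            a0_triple_prime(g)

    def test_crossing_criterion_equivalence(self, rng):
        """a0' < a0''  <=>  (a^2-bc)/(c-a) < (bc-d^2)/(d-b)."""
        for _ in range(100):
            g = random_strict_pd(rng, require_bc_gt_d2=True)
            lhs = a0_prime(g) < a0_double_prime(g)
            rhs = (g.a2 - g.bc) / (g.c - g.a) < (g.bc - g.d2) / (g.d - g.b)
            assert lhs == rhs

    def test_non_pd_game_rejected(self):
        g = make_game(0.97, 0.94, 0.96, 0.95, 0.5, 10)  # Stag Hunt
        with pytest.raises(NotPrisonersDilemmaError):
            a0_star(g)


class TestJOpt:
    def test_value_and_brackets_brute_force_argmax(self):
        g = make_game(*FIG6_ABCD, 0.8, 50, require_pd=True)
        jo = j_opt_real(g)
        assert jo == pytest.approx(6.10, abs=5e-3)
        best = max(range(51), key=lambda j: payoff(g, j, 0))
        assert math.floor(jo) <= best <= math.ceil(jo)
        assert J_opt(g) == best

    def test_brute_force_argmax_across_random_games(self, rng):
        for _ in range(50):
            g = random_strict_pd(rng, n_range=(5, 15))
            if g.a0 >= a0_star(g):
                assert math.isinf(j_opt_real(g))
                continue
            best = max(range(g.n + 1), key=lambda j: payoff(g, j, 0))
            assert J_opt(g) == best

    def test_nonexistent_above_a0_star(self):
        g = _game(FIG6_ABCD, 0.96)  # a0 > a0* = 0.9508
        assert math.isinf(j_opt_real(g))
        assert math.isinf(J_opt(g))

    def test_j_opt_small_for_small_a0_and_diverges_at_a0_star(self):
        g = _game(FIG6_ABCD, 0.8)
        assert j_opt_real(g.with_a0(1e-4)) < 1.0
        assert j_opt_real(g.with_a0(a0_star(g) - 1e-6)) > 50.0

    def test_J_opt_tends_to_1_at_small_a0(self):
        g = _game(FIG6_ABCD, 1e-5, n=50)
        assert J_opt(g) == 1

    def test_J_opt_capped_by_short_games(self):
        g = make_game(*FIG6_ABCD, 0.8, 3, require_pd=True)  # n=3 < j_opt=6.1
        assert J_opt(g) == 3

    def test_J_opt_nondecreasing_in_a0(self):
        g = make_game(*FIG6_ABCD, 0.5, 200, require_pd=True)
        s = a0_star(g)
        grid = np.linspace(1e-4, s - 1e-4, 100)
        vals = [J_opt(g.with_a0(a0)) for a0 in grid]
        assert all(x <= y for x, y in zip(vals, vals[1:]))

    def test_degenerate_a0_equals_a2(self):
        g = make_game(*FIG6_ABCD, 0.9409, 100, require_pd=True)
        jo = j_opt_real(g)
        assert math.isfinite(jo)
        best = max(range(101), key=lambda j: payoff(g, j, 0))
        assert math.floor(jo) <= best <= math.ceil(jo)

    def test_degenerate_a0_equals_bc(self):
        g = make_game(*FIG6_ABCD, 0.9306, 100, require_pd=True)
        jo = j_opt_real(g)
        assert math.isfinite(jo)
        best = max(range(101), key=lambda j: payoff(g, j, 0))
        assert math.floor(jo) <= best <= math.ceil(jo)


class TestIDIC:
    def test_i_D_fig7a_value(self):
        assert i_D_real(_game(FIG5_ABCD, 0.86)) == pytest.approx(
            3.08, abs=5e-3
        )

    def test_i_C_fig7b_value(self):
        assert i_C_real(_game(FIG6_ABCD, 0.86)) == pytest.approx(
            4.22, abs=5e-3
        )

    def test_existence_regimes(self):
        g = _game(FIG6_ABCD, 0.8)
        assert math.isfinite(i_D_real(g))
        assert math.isinf(i_D_real(g.with_a0(a0_prime(g) + 1e-6)))
        assert math.isfinite(i_C_real(g))
        assert math.isinf(i_C_real(g.with_a0(a0_double_prime(g) + 1e-6)))
        g_no_ic = make_game(0.97, 0.91, 0.98, 0.95, 0.3, 20, require_pd=True)
        assert g_no_ic.bc < g_no_ic.d2
        assert math.isinf(i_C_real(g_no_ic))

    def test_limits_at_small_a0(self):
        # the approach is logarithmically slow, hence the tiny a0
        g = _game(FIG6_ABCD, 1e-12)
        assert i_D_real(g) == pytest.approx(0.0, abs=0.05)
        assert i_C_real(g) == pytest.approx(1.0, abs=0.05)

    def test_divergence_at_cutoffs(self):
        g = _game(FIG6_ABCD, 0.8)
        assert i_D_real(g.with_a0(a0_prime(g) - 1e-9)) > 100.0
        assert i_C_real(g.with_a0(a0_double_prime(g) - 1e-9)) > 100.0

    def test_strictly_increasing_in_a0(self):
        """i_D and i_C both increase with loner survivability over a fine
        grid of their existence intervals."""
        g = _game(FIG6_ABCD, 0.5)
        grid_d = np.linspace(1e-4, a0_prime(g) - 1e-4, 200)
        vals_d = [i_D_real(g.with_a0(x)) for x in grid_d]
        assert all(x < y for x, y in zip(vals_d, vals_d[1:]))
        grid_c = np.linspace(1e-4, a0_double_prime(g) - 1e-4, 200)
        vals_c = [i_C_real(g.with_a0(x)) for x in grid_c]
        assert all(x < y for x, y in zip(vals_c, vals_c[1:]))

    def test_continuous_at_a0_equals_d2(self):
        g = _game(FIG6_ABCD, 0.9025)  # a0 == d^2 exactly
        eps = 1e-7
        for f in (i_D_real, i_C_real):
            below, at, above = (
                f(g.with_a0(g.d2 - eps)), f(g), f(g.with_a0(g.d2 + eps))
            )
            assert below <= at <= above  # increasing through the junction
            assert above - below < 1e-3

    def test_a0_solving_i_D(self):
        g = _game(FIG6_ABCD, 0.8)
        root = a0_solving_i_D(g, 2.0)
        assert i_D_real(g.with_a0(root)) == pytest.approx(2.0, abs=1e-9)
        assert root == pytest.approx(0.548, abs=1e-3)


class TestBestResponseLocators:
    def test_j_star_equals_i_C_minus_1(self, rng):
        count = 0
        while count < 100:
            g = random_strict_pd(rng, require_bc_gt_d2=True)
            ic = i_C_real(g)
            if math.isinf(ic):
                continue
            assert j_star(g) == pytest.approx(ic - 1.0, abs=1e-9)
            count += 1

    def test_j_star_requires_i_C(self):
        g = make_game(0.97, 0.91, 0.98, 0.95, 0.5, 20, require_pd=True)
        with pytest.raises(ThresholdDomainError):
            j_star(g)

    def test_ceil_k_star_0_equals_J_opt(self, rng):
        count = 0
        while count < 50:
            g = random_strict_pd(rng, n_range=(30, 60))
            ks = k_star(g, 0)
            jo = J_opt(g)
            if math.isinf(ks) or math.isinf(jo) or jo >= g.n:
                continue
            if abs(ks - round(ks)) < 1e-6:
                continue  # ceiling ambiguous at machine precision
            assert math.ceil(ks) == jo
            count += 1

    def test_k_star_monotonicity_when_i_D_missing(self):
        """Without i_D the step size ceil(k*(i)) decreases with i when
        a0 < d, is constant when a0 == d, increases when a0 > d."""
        a, b, c, d = FIG6_ABCD
        base = make_game(a, b, c, d, 0.93, 40, require_pd=True)
        assert math.isinf(i_D_real(base))  # a0 > a0' = 0.9186

        def steps(g):
            out = []
            for i in range(0, 25):
                ks = k_star(g, i)
                out.append(math.inf if math.isinf(ks) else math.ceil(ks))
            return out

        down = steps(base)  # a0 = 0.93 < d = 0.95
        assert all(x >= y for x, y in zip(down, down[1:]))
        flat = steps(base.with_a0(d))
        assert len(set(flat)) == 1
        g_up = base.with_a0(0.9507)  # d < a0 < a0* = 0.9508
        up = steps(g_up)
        assert all(x <= y for x, y in zip(up, up[1:]))

    def test_k_star_domain(self):
        g = _game(FIG6_ABCD, 0.86)  # i_D = 13.49
        with pytest.raises(ThresholdDomainError):
            k_star(g, 14)


class TestThresholdSet:
    def test_full_set_consistent_fields(self):
        g = _game(FIG6_ABCD, 0.86)
        ts = threshold_set(g)
        assert ts.i_D == pytest.approx(13.49, abs=5e-3)
        assert ts.i_C == pytest.approx(4.22, abs=5e-3)
        assert ts.i_D_exists and ts.i_C_exists
        assert ts.a0_triple_prime == pytest.approx(0.43, abs=5e-3)
        assert ts.j_star == pytest.approx(ts.i_C - 1, abs=1e-9)
        d = ts.to_dict()
        assert d["i_D_exists"] is True

    def test_no_crossing_game_has_none_triple_prime(self):
        ts = threshold_set(_game(FIG5_ABCD, 0.5))
        assert ts.a0_triple_prime is None
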