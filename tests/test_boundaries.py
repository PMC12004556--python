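import math

import numpy as np
import pytest
from scipy import stats

from tsameta import LookSchedule, clip_fractions, compute_boundaries, \
    obf_alpha_spent


def independent_recursion(fractions, alpha=0.05, m=4001):
    """Independent high-resolution boundary solver used as an oracle.

    Same probability model, different numerics: z-scale grids, Simpson
    integration, and sequential bisection instead of the package's
    score-scale trapezoid recursion with Brent root-finding.
    """
    from scipy.integrate import simpson

    cum = [obf_alpha_spent(t, alpha) for t in fractions]
    inc = [cum[0]] + [b - a for a, b in zip(cum, cum[1:])]
    bounds = []
    b1 = stats.norm.isf(inc[0] / 2)
    bounds.append(b1)
    c = b1 * math.sqrt(fractions[0])
    x = np.linspace(-c, c, m)
    h = stats.norm.pdf(x, scale=math.sqrt(fractions[0]))
    for j in range(1, len(fractions)):
        dt = fractions[j] - fractions[j - 1]
        sd = math.sqrt(dt)
        mass = simpson(h, x=x)

        def crossing(b):
            cj = b * math.sqrt(fractions[j])
            s = np.linspace(-cj, cj, m)
            g = np.array([simpson(h * stats.norm.pdf((si - x) / sd) / sd, x=x)
                          for si in s])
            return mass - simpson(g, x=s), s, g

        lo, hi = 0.5, 8.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            val, _, _ = crossing(mid)
            if val > inc[j]:
                lo = mid
            else:
                hi = mid
        bj = 0.5 * (lo + hi)
        bounds.append(bj)
        _, x, h = crossing(bj)
    return bounds


class TestSpendingFunction:
    def test_full_information_spends_all_alpha(self):
        assert obf_alpha_spent(1.0, 0.05) == pytest.approx(0.05)

    def test_half_information_value(self):
        # 2 * (1 - Phi(1.959964 / sqrt(0.5)))
        assert obf_alpha_spent(0.5, 0.05) == pytest.approx(0.005574, abs=1e-6)

    def test_vanishes_at_tiny_fractions(self):
        assert obf_alpha_spent(1e-4, 0.05) < 1e-12

    def test_monotone_in_t(self):
        grid = np.linspace(0.05, 1.0, 30)
        vals = [obf_alpha_spent(t, 0.05) for t in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("t", [0.0, -0.2, 1.2])
    def test_domain_errors(self, t):
        with pytest.raises(ValueError):
            obf_alpha_spent(t, 0.05)


class TestBoundaries:
    def test_single_look_is_fixed_sample_critical_value(self):
        res = compute_boundaries(LookSchedule((1.0,)), alpha=0.05)
        assert res.boundary_z[0] == pytest.approx(1.959964, abs=1e-6)
        assert not res.capped[0]

    def test_two_look_matches_independent_recursion(self):
        res = compute_boundaries(LookSchedule((0.5, 1.0)), alpha=0.05)
        oracle = independent_recursion((0.5, 1.0), m=2001)
        for got, want in zip(res.boundary_z, oracle):
            assert got == pytest.approx(want, abs=1e-2)

    def test_grid_convergence(self):
        lo = compute_boundaries(LookSchedule((0.5, 1.0)), grid_points=512)
        hi = compute_boundaries(LookSchedule((0.5, 1.0)), grid_points=4096)
        for a, b in zip(lo.boundary_z, hi.boundary_z):
            assert a == pytest.approx(b, abs=5e-3)

    def test_five_look_monotone_decreasing_toward_one(self):
        res = compute_boundaries(LookSchedule((0.2, 0.4, 0.6, 0.8, 1.0)))
        bz = res.boundary_z
        assert all(b < a for a, b in zip(bz, bz[1:]))
        assert bz[-1] > 1.959964  # multiplicity keeps the final look above z

    def test_incremental_spend_sums_to_cumulative(self):
        res = compute_boundaries(LookSchedule((0.13, 0.42, 0.55, 0.9, 1.0)))
        assert all(s >= 0 for s in res.incremental_spend)
        assert sum(res.incremental_spend) == pytest.approx(
            res.cumulative_spend[-1], abs=1e-6)

    def test_extra_interim_look_never_lowers_earlier_boundaries(self):
        base = compute_boundaries(LookSchedule((0.5, 1.0)))
        more = compute_boundaries(LookSchedule((0.25, 0.5, 1.0)))
        assert more.boundary_z[1] >= base.boundary_z[0] - 1e-9
        assert more.boundary_z[2] >= base.boundary_z[1] - 1e-9

    def test_tiny_fraction_is_capped(self):
        res = compute_boundaries(LookSchedule((0.01, 1.0)), cap=8.0)
        assert res.capped[0]
        assert res.boundary_z[0] == 8.0

    def test_monte_carlo_crossing_matches_spend_at_every_look(self):
        """Brownian-path oracle: cumulative crossing probability equals the
        cumulative alpha spend at each look, within 3 MC standard errors."""
        ts = (0.2, 0.4, 0.6, 0.8, 1.0)
        res = compute_boundaries(LookSchedule(ts))
        rng = np.random.default_rng(987654321)
        n = 200_000
        dt = np.diff(np.concatenate([[0.0], np.array(ts)]))
        s = np.cumsum(rng.normal(0.0, np.sqrt(dt), size=(n, len(ts))), axis=1)
        z = s / np.sqrt(np.array(ts))[None, :]
        exceed = np.abs(z) >= np.array(res.boundary_z)[None, :]
        for j in range(len(ts)):
            p_hat = exceed[:, : j + 1].any(axis=1).mean()
            spend = res.cumulative_spend[j]
            se = math.sqrt(max(spend * (1 - spend), 1e-12) / n)
            assert abs(p_hat - spend) <= 3 * se + 1e-9


class TestClipFractions:
    def test_flooring_and_clipping_with_index_map(self):
        schedule, index_map = clip_fractions([0.001, 0.005, 0.4, 1.3, 2.0])
        assert schedule.fractions == (0.01, 0.4, 1.0)
        assert index_map == [0, 0, 1, 2, 2]
        assert schedule.raw_fractions == (0.001, 0.005, 0.4, 1.3, 2.0)

    def test_rejects_non_increasing_raw_fractions(self):
        with pytest.raises(ValueError):
            clip_fractions([0.5, 0.5, 1.0])

    def test_schedule_invariants_enforced(self):
        with pytest.raises(ValueError):
            LookSchedule((0.5, 0.4))
        with pytest.raises(ValueError):
            LookSchedule((0.5, 1.2))
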