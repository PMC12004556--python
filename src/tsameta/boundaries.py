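"""Two-sided alpha-spending monitoring boundaries (Lan-DeMets recursion).

The spending function is the O'Brien-Fleming-type rule

    alpha*(t) = 2 * (1 - Phi(z_{1 - alpha/2} / sqrt(t))),

the total two-sided type-I error allowed by information fraction t; it is
nearly flat for small t and reaches alpha at t = 1, so a single look at
full information recovers the fixed-sample critical value z_{1-alpha/2}.

Boundaries are found by the standard group-sequential recursion: under the
null the score process S_j = Z_j * sqrt(t_j) is Brownian motion observed at
the look times, so the sub-density of paths that have not yet crossed is
propagated from look to look by convolution with the Gaussian increment
kernel on a numerical grid, and each boundary is the root (in the critical
value b_j) of "incremental crossing probability = incremental spend".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "DEFAULT_CAP",
    "MIN_FRACTION",
    "LookSchedule",
    "BoundaryResult",
    "obf_alpha_spent",
    "clip_fractions",
    "compute_boundaries",
]

DEFAULT_CAP = 8.0       # |z| ceiling when the incremental spend underflows
MIN_FRACTION = 0.01     # information fractions below this are floored
DEFAULT_GRID = 512      # grid points per look for the density recursion


@dataclass(frozen=True)
class LookSchedule:
    """Strictly increasing information fractions in (0, 1]."""

    fractions: tuple[float, ...]
    raw_fractions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        fr = self.fractions
        if not fr:
            raise ValueError("schedule needs at least one look")
        if any(not (0.0 < t <= 1.0) for t in fr):
            raise ValueError("information fractions must lie in (0, 1]")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("information fractions must be strictly increasing")


def clip_fractions(
    raw: Sequence[float], floor: float = MIN_FRACTION
) -> tuple[LookSchedule, list[int]]:
    """Clip raw information fractions into a valid LookSchedule.

    Fractions below ``floor`` are floored; fractions above 1 are clipped to
    1 (all remaining spend occurs at the first such look).  Duplicates
    produced by clipping are merged; the returned index map sends each raw
    look to its position in the deduplicated schedule, so post-clip looks
    share the boundary of the look they merged into.
    """
    if any(t <= 0 for t in raw):
        raise ValueError("raw information fractions must be positive")
    if any(b <= a for a, b in zip(raw, list(raw)[1:])):
        raise ValueError("raw information fractions must be strictly increasing")
    clipped = [min(max(t, floor), 1.0) for t in raw]
    uniq: list[float] = []
    index_map: list[int] = []
    for t in clipped:
        if not uniq or t > uniq[-1]:
            uniq.append(t)
        index_map.append(len(uniq) - 1)
    return LookSchedule(tuple(uniq), tuple(float(t) for t in raw)), index_map


@dataclass(frozen=True)
class BoundaryResult:
    """Per-look spending and two-sided boundary z-values (+/- b_j)."""

    fractions: tuple[float, ...]
    cumulative_spend: tuple[float, ...]
    incremental_spend: tuple[float, ...]
    boundary_z: tuple[float, ...]
    capped: tuple[bool, ...]
    alpha: float
    cap: float


def obf_alpha_spent(t: float, alpha: float) -> float:
    """Cumulative two-sided alpha spent by information fraction t."""
    if not 0.0 < t <= 1.0:
        raise ValueError("information fraction must be in (0, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    z = stats.norm.isf(alpha / 2.0)
    return float(2.0 * stats.norm.sf(z / math.sqrt(t)))


def compute_boundaries(
    schedule: LookSchedule,
    alpha: float = 0.05,
    grid_points: int = DEFAULT_GRID,
    cap: float = DEFAULT_CAP,
) -> BoundaryResult:
    """Solve the symmetric two-sided boundaries for an alpha-spending schedule.

    At each look the boundary b_j >= 0 makes the probability of first
    exiting (-b_j, b_j) (on the z scale; (-b_j sqrt(t_j), b_j sqrt(t_j)) on
    the score scale) equal to the spend increment.  When the increment is
    too small for a finite solution below ``cap``, the boundary is set to
    ``cap`` and flagged.
    """
    ts = schedule.fractions
    cum = [obf_alpha_spent(t, alpha) for t in ts]
    inc = [cum[0]] + [b - a for a, b in zip(cum, cum[1:])]

    m = int(grid_points)
    bounds: list[float] = []
    capped: list[bool] = []

    # -- first look: marginal normal, closed form -------------------------
    spend = inc[0]
    b1 = float(stats.norm.isf(spend / 2.0)) if spend > 0 else math.inf
    if b1 > cap:
        bounds.append(cap)
        capped.append(True)
    else:
        bounds.append(b1)
        capped.append(False)
    c_prev = bounds[0] * math.sqrt(ts[0])
    x_prev = np.linspace(-c_prev, c_prev, m)
    h_prev = stats.norm.pdf(x_prev, scale=math.sqrt(ts[0]))

    # -- subsequent looks: propagate the non-crossing sub-density ---------
    for j in range(1, len(ts)):
        dt = ts[j] - ts[j - 1]
        sd = math.sqrt(dt)
        trap_w = np.full(m, x_prev[1] - x_prev[0])
        trap_w[0] *= 0.5
        trap_w[-1] *= 0.5
        mass_prev = float(np.sum(h_prev * trap_w))

        c_max = cap * math.sqrt(ts[j])
        s_grid = np.linspace(-c_max, c_max, m)
        # convolved sub-density of the score at look j, before truncation
        kernel = stats.norm.pdf((s_grid[:, None] - x_prev[None, :]) / sd) / sd
        g = kernel @ (h_prev * trap_w)
        # cumulative integral of g for fast interval masses
        ds = s_grid[1] - s_grid[0]
        G = np.concatenate([[0.0], np.cumsum((g[1:] + g[:-1]) * 0.5 * ds)])

        def inside_mass(b: float) -> float:
            c = b * math.sqrt(ts[j])
            hi = float(np.interp(c, s_grid, G))
            lo = float(np.interp(-c, s_grid, G))
            return hi - lo

        def crossing(b: float) -> float:
            return mass_prev - inside_mass(b)

        spend = inc[j]
        if spend <= 0 or crossing(cap) > spend:
            bj, is_capped = cap, True
        else:
            bj = float(brentq(lambda b: crossing(b) - spend, 1e-8, cap,
                              xtol=1e-10))
            is_capped = False
        bounds.append(bj)
        capped.append(is_capped)

        c_j = bj * math.sqrt(ts[j])
        x_new = np.linspace(-c_j, c_j, m)
        kernel_new = stats.norm.pdf((x_new[:, None] - x_prev[None, :]) / sd) / sd
        h_prev = kernel_new @ (h_prev * trap_w)
        x_prev = x_new

    return BoundaryResult(
        fractions=ts,
        cumulative_spend=tuple(cum),
        incremental_spend=tuple(inc),
        boundary_z=tuple(bounds),
        capped=tuple(capped),
        alpha=alpha,
        cap=cap,
    )
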