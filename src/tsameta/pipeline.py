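"""Full trial sequential analysis for one tau^2 estimator.

Pipeline: pool the complete data under the chosen estimator -> diversity
D^2 -> adjustment factor AF = 1/(1-D^2) -> required information size
(unadjusted and diversity-adjusted) -> cumulative z-curve over the
accumulation order -> alpha-spending boundaries at the realized
information fractions -> conclusiveness verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from scipy import stats

from . import boundaries as bnd
from .meta import (EffectEstimate, PooledResult, StudyRecord,
                   effect_estimates, pool_fixed, pool_random, sort_records)
from .tau2 import estimate_tau2

__all__ = [
    "TSAConfig",
    "Look",
    "TSAResult",
    "diversity",
    "adjustment_factor",
    "implied_log_or",
    "required_information_size",
    "cumulative_z_curve",
    "run_tsa",
]

CONCLUSIVE = "conclusive_crossed"
RIS_REACHED = "ris_reached_not_crossed"
INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class TSAConfig:
    """Settings for a trial sequential analysis.

    The expected effect is set either through an assumed relative risk
    reduction ``rrr`` (converted to a log odds ratio via the control event
    rate) or directly as ``expected_log_or``.  ``ris_mode`` chooses between
    the participant-scale sample-size formula for two proportions
    ("proportion", the default) and the literal information-units formula
    4 (z_{a/2}+z_b)^2 nu_random / mu^2 ("eq1_literal").
    """

    alpha: float = 0.05
    beta: float = 0.20
    rrr: Optional[float] = 0.20
    expected_log_or: Optional[float] = None
    control_rate: Optional[float] = None  # None: observed pooled control rate
    ris_mode: str = "proportion"
    estimator: str = "DL"
    zero_cell_correction: float = 0.5
    reestimate_tau2: bool = True
    boundary_cap: float = bnd.DEFAULT_CAP
    grid_points: int = bnd.DEFAULT_GRID

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must be in (0, 1)")
        if self.ris_mode not in ("proportion", "eq1_literal"):
            raise ValueError("ris_mode must be 'proportion' or 'eq1_literal'")
        if self.rrr is None and self.expected_log_or is None:
            raise ValueError("either rrr or expected_log_or must be given")
        if self.rrr is not None and not 0.0 < self.rrr < 1.0:
            raise ValueError("rrr must be in (0, 1)")
        if self.expected_log_or is not None and self.expected_log_or == 0.0:
            raise ValueError("expected_log_or must be non-zero")


@dataclass(frozen=True)
class Look:
    """One interim look of the cumulative analysis."""

    study_id: str
    k: int
    cumulative_n: int
    information_fraction: float
    tau2_hat: float
    z: float
    boundary_z: float
    boundary_capped: bool


@dataclass(frozen=True)
class TSAResult:
    estimator: str
    tau2_hat: float
    d2: float
    af: float
    ris_unadjusted: float
    ris_adjusted: float
    pooled: PooledResult
    looks: tuple[Look, ...]
    conclusion: str
    min_boundary: float
    extreme_z: float
    config: TSAConfig


def diversity(variance_fixed: float, variance_random: float) -> float:
    """Diversity D^2 = (nu_random - nu_fixed) / nu_random, in [0, 1).

    The relative increase in pooled-effect variance when moving from the
    common-effect to the random-effects model.
    """
    if variance_fixed <= 0:
        raise ValueError("fixed-effect variance must be positive")
    if variance_random < variance_fixed:
        raise ValueError(
            "random-effects variance below fixed-effect variance: "
            "inconsistent inputs"
        )
    d2 = (variance_random - variance_fixed) / variance_random
    return min(max(d2, 0.0), math.nextafter(1.0, 0.0))


def adjustment_factor(d2: float) -> float:
    """Heterogeneity adjustment factor AF = 1 / (1 - D^2)."""
    if not 0.0 <= d2 < 1.0:
        raise ValueError("D^2 must lie in [0, 1)")
    return 1.0 / (1.0 - d2)


def implied_log_or(control_rate: float, rrr: float) -> float:
    """|log odds ratio| implied by a control event rate and an assumed RRR.

    The intervention rate is p_I = p_C (1 - rrr); the returned magnitude is
    |ln(odds_I / odds_C)|.
    """
    if not 0.0 < control_rate < 1.0:
        raise ValueError("control rate must be in (0, 1)")
    if not 0.0 < rrr < 1.0:
        raise ValueError("rrr must be in (0, 1)")
    p_c = control_rate
    p_i = p_c * (1.0 - rrr)
    return abs(math.log((p_i / (1.0 - p_i)) / (p_c / (1.0 - p_c))))


def _expected_effect(config: TSAConfig, control_rate: float) -> float:
    if config.expected_log_or is not None:
        return abs(config.expected_log_or)
    return implied_log_or(control_rate, config.rrr)


def required_information_size(
    config: TSAConfig,
    variance_random: float,
    control_rate: float,
    af: float = 1.0,
) -> tuple[float, float]:
    """Unadjusted and diversity-adjusted required information size.

    proportion mode (participants): 4 (z_{1-a/2} + z_{1-b})^2 pbar(1-pbar)
    / (p_C - p_I)^2, with pbar the mean of the two arm rates; the adjusted
    size is rounded up to whole participants.  eq1_literal mode
    (information units): 4 (z_{1-a/2} + z_{1-b})^2 nu_random / mu^2.
    """
    za = stats.norm.isf(config.alpha / 2.0)
    zb = stats.norm.isf(config.beta)
    zz = (za + zb) ** 2
    if af < 1.0:
        raise ValueError("adjustment factor must be >= 1")
    if config.ris_mode == "eq1_literal":
        mu = _expected_effect(config, control_rate)
        if mu == 0.0:
            raise ValueError("expected effect must be non-zero")
        unadj = 4.0 * zz * variance_random / mu ** 2
        return unadj, unadj * af
    if not 0.0 < control_rate < 1.0:
        raise ValueError("control rate must be in (0, 1)")
    if config.rrr is not None:
        p_c = control_rate
        p_i = p_c * (1.0 - config.rrr)
    else:
        # anchor the intervention rate through the supplied log OR
        p_c = control_rate
        odds_i = math.exp(-abs(config.expected_log_or)) * p_c / (1.0 - p_c)
        p_i = odds_i / (1.0 + odds_i)
    pbar = 0.5 * (p_c + p_i)
    unadj = 4.0 * zz * pbar * (1.0 - pbar) / (p_c - p_i) ** 2
    return unadj, float(math.ceil(unadj * af))


def _prefix_tau2(effects: Sequence[EffectEstimate], estimator: str) -> float:
    kept = [e for e in effects if e.included]
    if len(kept) < 2:
        return 0.0  # a single study carries no heterogeneity information
    return estimate_tau2(kept, estimator).value


def cumulative_z_curve(
    records: Sequence[StudyRecord],
    estimator: str = "DL",
    zero_cell_correction: float = 0.5,
    fixed_tau2: Optional[float] = None,
) -> list[tuple[str, int, int, float, float]]:
    """Cumulative random-effects z-score after each accumulated study.

    Returns, per look: (study_id, k included, cumulative participants over
    included studies, tau^2 at that look, z).  tau^2 is re-estimated on
    every prefix unless ``fixed_tau2`` pins it.
    """
    ordered = sort_records(records)
    if not ordered:
        raise ValueError("need at least one study")
    out: list[tuple[str, int, int, float, float]] = []
    cum_n = 0
    effects: list[EffectEstimate] = []
    for rec in ordered:
        eff = effect_estimates([rec], zero_cell_correction)[0]
        effects.append(eff)
        if not eff.included:
            continue
        cum_n += rec.total
        t2 = (fixed_tau2 if fixed_tau2 is not None
              else _prefix_tau2(effects, estimator))
        pooled = pool_random(effects, t2, estimator)
        out.append((rec.study_id, pooled.k, cum_n, t2, pooled.z_score))
    if not out:
        raise ValueError("no included studies")
    return out


def run_tsa(records: Sequence[StudyRecord], config: TSAConfig) -> TSAResult:
    """Run the complete trial sequential analysis for one estimator."""
    effects = effect_estimates(sort_records(records),
                               config.zero_cell_correction)
    kept = [e for e in effects if e.included]
    if len(kept) < 2:
        raise ValueError("trial sequential analysis requires k >= 2 included studies")

    tau2 = estimate_tau2(kept, config.estimator).value
    fixed = pool_fixed(kept)
    random = pool_random(kept, tau2, config.estimator)
    d2 = diversity(fixed.variance, random.variance)
    af = adjustment_factor(d2)

    if config.control_rate is not None:
        p_c = config.control_rate
    else:
        ids = {e.study_id for e in kept}
        inc = [r for r in records if r.study_id in ids]
        p_c = sum(r.events_ctl for r in inc) / sum(r.total_ctl for r in inc)
    ris_unadj, ris_adj = required_information_size(
        config, random.variance, p_c, af)

    curve = cumulative_z_curve(
        records, config.estimator, config.zero_cell_correction,
        fixed_tau2=None if config.reestimate_tau2 else tau2)
    raw_fractions = [n / ris_adj for (_, _, n, _, _) in curve]
    schedule, index_map = bnd.clip_fractions(raw_fractions)
    bres = bnd.compute_boundaries(schedule, config.alpha,
                                  config.grid_points, config.boundary_cap)

    looks = tuple(
        Look(
            study_id=sid, k=k, cumulative_n=n,
            information_fraction=raw_fractions[i],
            tau2_hat=t2, z=z,
            boundary_z=bres.boundary_z[index_map[i]],
            boundary_capped=bres.capped[index_map[i]],
        )
        for i, (sid, k, n, t2, z) in enumerate(curve)
    )

    crossed = any(abs(lk.z) >= lk.boundary_z for lk in looks)
    if crossed:
        conclusion = CONCLUSIVE
    elif looks[-1].cumulative_n >= ris_adj:
        conclusion = RIS_REACHED
    else:
        conclusion = INCONCLUSIVE

    sign = -1.0 if random.theta_hat < 0 else 1.0
    uncapped = [lk.boundary_z for lk in looks if not lk.boundary_capped]
    min_boundary = sign * (max(uncapped) if uncapped else config.boundary_cap)
    extreme_z = max((lk.z for lk in looks), key=abs)

    return TSAResult(
        estimator=config.estimator, tau2_hat=tau2, d2=d2, af=af,
        ris_unadjusted=ris_unadj, ris_adjusted=ris_adj, pooled=random,
        looks=looks, conclusion=conclusion, min_boundary=min_boundary,
        extreme_z=extreme_z, config=config,
    )
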