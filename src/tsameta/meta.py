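"""Effect estimation and inverse-variance pooling for 2x2 tables.

Each randomized trial contributes a 2x2 table (events / total in the
intervention and control arms).  The effect measure is the log odds ratio
with its large-sample within-study variance; pooling is inverse-variance,
either under the common-effect (fixed) model or the random-effects model
with a supplied between-study variance tau^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import stats

__all__ = [
    "Z_975",
    "StudyRecord",
    "EffectEstimate",
    "PooledResult",
    "log_odds_ratio",
    "effect_estimates",
    "sort_records",
    "pool_fixed",
    "pool_random",
    "cochran_q",
]

# normal quantile for the two-sided 95% Wald interval
Z_975 = 1.959964


@dataclass(frozen=True)
class StudyRecord:
    """One trial's 2x2 table plus its position in the accumulation order."""

    study_id: str
    order_key: int
    events_int: int
    total_int: int
    events_ctl: int
    total_ctl: int
    subgroup: Optional[str] = None

    def __post_init__(self) -> None:
        for events, total, arm in (
            (self.events_int, self.total_int, "intervention"),
            (self.events_ctl, self.total_ctl, "control"),
        ):
            if total <= 0:
                raise ValueError(
                    f"study {self.study_id!r}: {arm} arm total must be positive"
                )
            if not 0 <= events <= total:
                raise ValueError(
                    f"study {self.study_id!r}: {arm} arm needs 0 <= events <= total"
                )

    @property
    def total(self) -> int:
        return self.total_int + self.total_ctl


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study log odds ratio y and within-study variance v.

    ``included`` is False for tables carrying no information about the odds
    ratio (zero events, or all events, in both arms); such studies never
    raise, they are simply dropped from pooling.
    """

    y: float
    v: float
    corrected: bool
    included: bool
    study_id: str = ""

    def __post_init__(self) -> None:
        if self.included:
            if not math.isfinite(self.y):
                raise ValueError("included effect must have finite y")
            if not (self.v > 0 and math.isfinite(self.v)):
                raise ValueError("included effect must have v > 0")


@dataclass(frozen=True)
class PooledResult:
    model: str  # "common" or "random"
    estimator: Optional[str]
    theta_hat: float
    variance: float
    se: float
    z_score: float
    ci_low: float
    ci_high: float
    k: int
    Q: float
    q_df: int
    q_pvalue: float
    tau2_hat: float = 0.0


def _is_double_degenerate(a: int, n1: int, c: int, n2: int) -> bool:
    # no events in both arms, or all events in both arms: OR undefined
    return (a == 0 and c == 0) or (a == n1 and c == n2)


def log_odds_ratio(
    record: StudyRecord, zero_cell_correction: float = 0.5
) -> EffectEstimate:
    """Log odds ratio and its variance from a 2x2 table.

    With cells a = events_int, b = total_int - events_int, c = events_ctl,
    d = total_ctl - events_ctl: y = ln(ad/(bc)), v = 1/a + 1/b + 1/c + 1/d.
    If any cell is zero, ``zero_cell_correction`` (default 0.5) is added to
    all four cells.  Double-zero and double-full tables are returned with
    ``included=False``.
    """
    a = float(record.events_int)
    b = float(record.total_int - record.events_int)
    c = float(record.events_ctl)
    d = float(record.total_ctl - record.events_ctl)

    if _is_double_degenerate(record.events_int, record.total_int,
                             record.events_ctl, record.total_ctl):
        return EffectEstimate(
            y=float("nan"), v=float("nan"), corrected=False, included=False,
            study_id=record.study_id,
        )

    corrected = False
    if min(a, b, c, d) == 0.0:
        a += zero_cell_correction
        b += zero_cell_correction
        c += zero_cell_correction
        d += zero_cell_correction
        corrected = True

    y = math.log((a * d) / (b * c))
    v = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return EffectEstimate(y=y, v=v, corrected=corrected, included=True,
                          study_id=record.study_id)


def effect_estimates(
    records: Sequence[StudyRecord], zero_cell_correction: float = 0.5
) -> list[EffectEstimate]:
    """Vector version of :func:`log_odds_ratio`, preserving order."""
    return [log_odds_ratio(r, zero_cell_correction) for r in records]


def sort_records(records: Sequence[StudyRecord]) -> list[StudyRecord]:
    """Accumulation order: order_key, then study_id, then input position."""
    return [
        r for _, r in sorted(
            enumerate(records),
            key=lambda ir: (ir[1].order_key, ir[1].study_id, ir[0]),
        )
    ]


def _included(effects: Sequence[EffectEstimate]) -> list[EffectEstimate]:
    kept = [e for e in effects if e.included]
    if not kept:
        raise ValueError("no included effect estimates to pool")
    return kept


def cochran_q(effects: Sequence[EffectEstimate]) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic with chi-square p-value.

    Q = sum w_i (y_i - theta_fixed)^2, w_i = 1/v_i, df = k - 1.
    """
    kept = _included(effects)
    k = len(kept)
    if k < 2:
        raise ValueError("Cochran's Q requires at least two included studies")
    w = [1.0 / e.v for e in kept]
    theta = sum(wi * e.y for wi, e in zip(w, kept)) / sum(w)
    q = sum(wi * (e.y - theta) ** 2 for wi, e in zip(w, kept))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def _assemble(model: str, estimator: Optional[str], theta: float,
              variance: float, k: int, q: float, q_df: int, q_p: float,
              tau2: float) -> PooledResult:
    se = math.sqrt(variance)
    return PooledResult(
        model=model, estimator=estimator, theta_hat=theta, variance=variance,
        se=se, z_score=theta / se, ci_low=theta - Z_975 * se,
        ci_high=theta + Z_975 * se, k=k, Q=q, q_df=q_df, q_pvalue=q_p,
        tau2_hat=tau2,
    )


def pool_fixed(effects: Sequence[EffectEstimate]) -> PooledResult:
    """Common-effect (fixed-effect) inverse-variance pooling."""
    kept = _included(effects)
    w = [1.0 / e.v for e in kept]
    sw = sum(w)
    theta = sum(wi * e.y for wi, e in zip(w, kept)) / sw
    variance = 1.0 / sw
    if len(kept) >= 2:
        q, df, p = cochran_q(kept)
    else:
        q, df, p = 0.0, 0, float("nan")
    return _assemble("common", None, theta, variance, len(kept), q, df, p, 0.0)


def pool_random(
    effects: Sequence[EffectEstimate],
    tau2: float,
    estimator: Optional[str] = None,
) -> PooledResult:
    """Random-effects pooling with weights 1/(v_i + tau^2).

    ``tau2`` is the between-study variance estimate; at tau2 = 0 the result
    coincides with :func:`pool_fixed` apart from the model label.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    kept = _included(effects)
    w = [1.0 / (e.v + tau2) for e in kept]
    sw = sum(w)
    theta = sum(wi * e.y for wi, e in zip(w, kept)) / sw
    variance = 1.0 / sw
    if len(kept) >= 2:
        q, df, p = cochran_q(kept)
    else:
        q, df, p = 0.0, 0, float("nan")
    return _assemble("random", estimator, theta, variance, len(kept),
                     q, df, p, tau2)
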