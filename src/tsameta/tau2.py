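"""Between-study variance (tau^2) estimators for random-effects meta-analysis.

Six estimators are provided, all taking per-study log odds ratios y_i and
within-study variances v_i:

DL    DerSimonian-Laird method of moments (closed form).
HS    Hunter-Schmidt (closed form).
SJ    Sidik-Jonkman two-step (closed form).
PM    Paule-Mandel, the root of the generalized Q equation.
ML    maximum likelihood under y_i ~ N(theta, v_i + tau^2).
REML  restricted maximum likelihood (adds the profile correction for theta).

All estimates are truncated at zero.  ML and REML iterate a fixed-point
(Fisher-scoring-type) update with a bisection fallback on the score
function; non-convergence is reported through ``converged=False`` with the
last iterate, never silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .meta import EffectEstimate

__all__ = ["METHODS", "Tau2Estimate", "estimate_tau2", "generalized_q"]

METHODS = ("DL", "REML", "ML", "PM", "SJ", "HS")

_TOL = 1e-10
_MAX_ITER = 100


@dataclass(frozen=True)
class Tau2Estimate:
    value: float
    method: str
    iterations: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("tau^2 estimate must be non-negative")


def _arrays(effects: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    kept = [e for e in effects if e.included]
    if len(kept) < 2:
        raise ValueError("tau^2 estimation requires at least two included studies")
    y = np.array([e.y for e in kept], dtype=float)
    v = np.array([e.v for e in kept], dtype=float)
    return y, v


def generalized_q(effects: Sequence[EffectEstimate], tau2: float) -> float:
    """Generalized Q statistic at a candidate tau^2.

    sum (y_i - mu(tau^2))^2 / (v_i + tau^2) with mu(tau^2) the
    inverse-variance weighted mean at that tau^2.  Strictly decreasing in
    tau^2; equals Cochran's Q at tau^2 = 0.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    y, v = _arrays(effects)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    return float(np.sum(w * (y - mu) ** 2))


def _dl(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    sw = w.sum()
    theta = float((w * y).sum() / sw)
    q = float((w * (y - theta) ** 2).sum())
    k = y.size
    c = sw - (w ** 2).sum() / sw
    return max(0.0, (q - (k - 1)) / c)


def _hs(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    theta = float((w * y).sum() / w.sum())
    q = float((w * (y - theta) ** 2).sum())
    return max(0.0, (q - y.size) / float(w.sum()))


def _sj(y: np.ndarray, v: np.ndarray, initial_divisor: str = "k") -> float:
    k = y.size
    ybar = float(y.mean())
    div = k if initial_divisor == "k" else k - 1
    tau0 = float(((y - ybar) ** 2).sum()) / div
    if tau0 == 0.0:
        return 0.0
    q_i = v / tau0 + 1.0
    w = 1.0 / q_i
    mu = float((w * y).sum() / w.sum())
    return float(((y - mu) ** 2 / q_i).sum() / (k - 1))


def _pm(y: np.ndarray, v: np.ndarray) -> float:
    from scipy.optimize import brentq

    k = y.size

    def gq(t2: float) -> float:
        w = 1.0 / (v + t2)
        mu = (w * y).sum() / w.sum()
        return float((w * (y - mu) ** 2).sum())

    target = k - 1
    if gq(0.0) <= target:
        return 0.0
    # bracket: generalized Q is strictly decreasing in tau^2
    upper = max(float(np.var(y)), 1e-8)
    while gq(upper) > target:
        upper *= 2.0
        if upper > 1e12:  # pragma: no cover - pathological inputs
            raise RuntimeError("failed to bracket the Paule-Mandel root")
    return float(brentq(lambda t2: gq(t2) - target, 0.0, upper,
                        xtol=1e-12, rtol=8.9e-16))


def _ml_score(y: np.ndarray, v: np.ndarray, t2: float) -> float:
    w = 1.0 / (v + t2)
    mu = (w * y).sum() / w.sum()
    return float((w ** 2 * ((y - mu) ** 2 - (v + t2))).sum())


def _reml_score(y: np.ndarray, v: np.ndarray, t2: float) -> float:
    w = 1.0 / (v + t2)
    mu = (w * y).sum() / w.sum()
    return float((w ** 2 * ((y - mu) ** 2 - (v + t2))).sum()
                 + (w ** 2).sum() / w.sum())


def _likelihood_iterate(
    y: np.ndarray, v: np.ndarray, restricted: bool
) -> tuple[float, int, bool]:
    """Fixed-point iteration for the (restricted) ML estimate of tau^2.

    Update: tau^2 <- sum w^2 [(y - mu)^2 - v] / sum w^2 (ML), with the
    usual +1/sum(w) correction inside the bracket for REML.  Falls back to
    bisection on the score function when the iteration cycles.
    """
    score = _reml_score if restricted else _ml_score
    t2 = max(_dl(y, v), 1e-8)
    for it in range(1, _MAX_ITER + 1):
        w = 1.0 / (v + t2)
        mu = (w * y).sum() / w.sum()
        resid2 = (y - mu) ** 2
        new = float((w ** 2 * (resid2 - v)).sum() / (w ** 2).sum())
        if restricted:
            new += float(1.0 / w.sum())
        new = max(0.0, new)
        if abs(new - t2) < _TOL * (1.0 + t2):
            if new == 0.0 and score(y, v, 0.0) > 0:
                break  # boundary mis-truncation: hand over to bisection
            return new, it, True
        t2 = new
    # bisection fallback on the score (decreasing in tau^2 near the root)
    if score(y, v, 0.0) <= 0:
        return 0.0, _MAX_ITER, True
    lo, hi = 0.0, max(t2, float(np.var(y)), 1e-6)
    while score(y, v, hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            return t2, _MAX_ITER, False
    for it in range(200):
        mid = 0.5 * (lo + hi)
        if score(y, v, mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < _TOL * (1.0 + mid):
            return mid, _MAX_ITER + it + 1, True
    return 0.5 * (lo + hi), _MAX_ITER + 200, False


def estimate_tau2(
    effects: Sequence[EffectEstimate],
    method: str,
    sj_initial_divisor: str = "k",
) -> Tau2Estimate:
    """Estimate tau^2 by one of DL, REML, ML, PM, SJ, HS.

    ``sj_initial_divisor`` selects the divisor of the crude initial
    variance in the Sidik-Jonkman two-step ("k", the original definition,
    or "k-1").
    """
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown tau^2 estimator {method!r}; choose from {METHODS}")
    y, v = _arrays(effects)

    if method == "DL":
        return Tau2Estimate(_dl(y, v), "DL")
    if method == "HS":
        return Tau2Estimate(_hs(y, v), "HS")
    if method == "SJ":
        return Tau2Estimate(_sj(y, v, sj_initial_divisor), "SJ")
    if method == "PM":
        return Tau2Estimate(_pm(y, v), "PM")
    value, iters, ok = _likelihood_iterate(y, v, restricted=(method == "REML"))
    return Tau2Estimate(value, method, iterations=iters, converged=ok)
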