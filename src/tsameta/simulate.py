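"""Synthetic meta-analysis data with the random-effects structure TSA assumes.

Each simulated trial i has a true log odds ratio theta_i ~ N(theta, tau2);
the control event rate p_C,i is fixed or drawn uniformly from a range, the
intervention rate follows from theta_i on the odds scale, and event counts
are binomial per arm.  Everything flows through one seeded generator, so a
spec is fully reproducible.

Also provides the repeated-testing error-rate simulation that motivates
TSA: the chance that a cumulative z-curve crosses either the alpha-spending
boundaries or a naive fixed +/-1.96 threshold applied at every look.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from . import boundaries as bnd
from .meta import Z_975, StudyRecord
from .pipeline import TSAConfig, cumulative_z_curve, required_information_size

__all__ = ["SimulationSpec", "PRESETS", "generate_meta_dataset",
           "simulate_error_rates"]


@dataclass(frozen=True)
class SimulationSpec:
    """Generative model for a k-study binary-outcome meta-analysis."""

    k: int
    theta: float = 0.0
    tau2: float = 0.0
    p_control: Union[float, tuple[float, float]] = 0.2
    n_min: int = 50
    n_max: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        lo, hi = self.p_control_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("p_control must lie in (0, 1)")
        if self.n_min < 2 or self.n_max < self.n_min:
            raise ValueError("need 2 <= n_min <= n_max")

    @property
    def p_control_range(self) -> tuple[float, float]:
        if isinstance(self.p_control, tuple):
            return self.p_control
        return (self.p_control, self.p_control)


# Scenario shapes mirroring a Cochrane-style case study: a small and a
# large meta-analysis, each with and without between-study heterogeneity.
PRESETS: dict[str, SimulationSpec] = {
    "small_homogeneous": SimulationSpec(k=7, theta=-0.4, tau2=0.0,
                                        p_control=(0.05, 0.30), seed=7),
    "small_heterogeneous": SimulationSpec(k=9, theta=-0.4, tau2=0.15,
                                          p_control=(0.05, 0.30), seed=9),
    "large_homogeneous": SimulationSpec(k=48, theta=-0.4, tau2=0.0,
                                        p_control=(0.05, 0.30), seed=48),
    "large_heterogeneous": SimulationSpec(k=62, theta=-0.4, tau2=0.15,
                                          p_control=(0.05, 0.30), seed=62),
}


def generate_meta_dataset(spec: SimulationSpec) -> list[StudyRecord]:
    """Draw one meta-analysis dataset; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.p_control_range
    records: list[StudyRecord] = []
    for i in range(spec.k):
        theta_i = rng.normal(spec.theta, math.sqrt(spec.tau2)) \
            if spec.tau2 > 0 else spec.theta
        p_c = rng.uniform(lo, hi) if hi > lo else lo
        odds_i = math.exp(theta_i) * p_c / (1.0 - p_c)
        p_i = odds_i / (1.0 + odds_i)
        n_int = int(rng.integers(spec.n_min, spec.n_max + 1))
        n_ctl = int(rng.integers(spec.n_min, spec.n_max + 1))
        records.append(StudyRecord(
            study_id=f"S{i + 1:03d}", order_key=i + 1,
            events_int=int(rng.binomial(n_int, p_i)), total_int=n_int,
            events_ctl=int(rng.binomial(n_ctl, p_c)), total_ctl=n_ctl,
        ))
    return records


# ---------------------------------------------------------------------------
# vectorized cumulative DerSimonian-Laird z-curves for the error-rate study
# ---------------------------------------------------------------------------

def _simulate_effects(
    rng: np.random.Generator, spec: SimulationSpec, n_arm: int, reps: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(reps, k) arrays of y, v and an inclusion mask, equal arms of n_arm."""
    lo, hi = spec.p_control_range
    shape = (reps, spec.k)
    theta_i = rng.normal(spec.theta, math.sqrt(spec.tau2), size=shape) \
        if spec.tau2 > 0 else np.full(shape, spec.theta)
    p_c = rng.uniform(lo, hi, size=shape) if hi > lo else np.full(shape, lo)
    odds_i = np.exp(theta_i) * p_c / (1.0 - p_c)
    p_i = odds_i / (1.0 + odds_i)
    a = rng.binomial(n_arm, p_i).astype(float)
    c = rng.binomial(n_arm, p_c).astype(float)
    b = n_arm - a
    d = n_arm - c
    include = ~(((a == 0) & (c == 0)) | ((b == 0) & (d == 0)))
    needs = (np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0) & include
    corr = np.where(needs, 0.5, 0.0)
    a, b, c, d = a + corr, b + corr, c + corr, d + corr
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.log((a * d) / (b * c))
        v = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    y = np.where(include, y, 0.0)
    v = np.where(include, v, 1.0)
    return y, v, include


def _cumulative_dl_z(y: np.ndarray, v: np.ndarray,
                     include: np.ndarray) -> np.ndarray:
    """(reps, k) cumulative random-effects z with DL tau^2 at every prefix."""
    w = np.where(include, 1.0 / v, 0.0)
    kk = np.cumsum(include, axis=1).astype(float)
    sw = np.cumsum(w, axis=1)
    swy = np.cumsum(w * y, axis=1)
    swy2 = np.cumsum(w * y * y, axis=1)
    sw2 = np.cumsum(w * w, axis=1)
    q = swy2 - swy ** 2 / sw
    c_dl = sw - sw2 / sw
    with np.errstate(divide="ignore", invalid="ignore"):
        tau2 = np.where((kk >= 2) & (c_dl > 0),
                        np.maximum(0.0, (q - (kk - 1)) / c_dl), 0.0)
    reps, k = y.shape
    z = np.empty((reps, k))
    for j in range(k):
        wr = np.where(include[:, :j + 1],
                      1.0 / (v[:, :j + 1] + tau2[:, j, None]), 0.0)
        swr = wr.sum(axis=1)
        # z = theta / se with theta = S/sum(w), se = 1/sqrt(sum(w))
        z[:, j] = (wr * y[:, :j + 1]).sum(axis=1) / np.sqrt(swr)
    return z


def simulate_error_rates(
    spec: SimulationSpec,
    config: TSAConfig,
    n_replicates: int,
    mode: str = "tsa_boundaries",
    seed: int | None = None,
    estimator: str = "CE",
) -> float:
    """Proportion of replicate meta-analyses that declare significance.

    Trials are planned so the k looks span the full required information
    size implied by ``config`` (equal arms of RIS/(2k) participants).  In
    mode "tsa_boundaries" a replicate counts when its cumulative z-curve
    crosses the alpha-spending boundaries at any look; in mode
    "naive_repeated" when it exceeds the fixed +/-1.96 threshold at any
    look.

    ``estimator`` selects the cumulative curve: "CE" (default) uses the
    common-effect z-statistic, which isolates the behaviour of the
    sequential procedure itself; "DL" re-estimates tau^2 by
    DerSimonian-Laird at every look, as the full pipeline does, which is
    slightly conservative when the generative truth is homogeneous.
    """
    if n_replicates < 100:
        raise ValueError("use at least 100 replicates")
    if mode not in ("tsa_boundaries", "naive_repeated"):
        raise ValueError("mode must be 'tsa_boundaries' or 'naive_repeated'")
    if estimator not in ("CE", "DL"):
        raise ValueError("estimator must be 'CE' or 'DL'")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    lo, hi = spec.p_control_range
    p_plan = 0.5 * (lo + hi)
    _, ris = required_information_size(config, variance_random=1.0,
                                       control_rate=p_plan, af=1.0)
    n_arm = int(math.ceil(ris / (2 * spec.k)))
    cum_n = 2 * n_arm * np.arange(1, spec.k + 1)
    fractions = (cum_n / ris).tolist()
    schedule, index_map = bnd.clip_fractions(fractions)
    if mode == "tsa_boundaries":
        bres = bnd.compute_boundaries(schedule, config.alpha,
                                      config.grid_points, config.boundary_cap)
        thresh = np.array([bres.boundary_z[i] for i in index_map])
    else:
        thresh = np.full(spec.k, Z_975)

    crossed = 0
    done = 0
    batch = max(1, min(n_replicates, 500))
    while done < n_replicates:
        reps = min(batch, n_replicates - done)
        y, v, include = _simulate_effects(rng, spec, n_arm, reps)
        if estimator == "CE":
            w = np.where(include, 1.0 / v, 0.0)
            z = np.cumsum(w * y, axis=1) / np.sqrt(np.cumsum(w, axis=1))
        else:
            z = _cumulative_dl_z(y, v, include)
        valid = include.cumsum(axis=1) >= 1
        crossed += int(np.any((np.abs(z) >= thresh[None, :]) & valid,
                              axis=1).sum())
        done += reps
    return crossed / n_replicates
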