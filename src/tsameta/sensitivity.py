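"""Sensitivity of the trial sequential analysis to the tau^2 estimator.

Runs the full TSA once per estimator on the same data and summarizes how
much the key quantities (tau^2, D^2, AF, adjusted RIS, boundary, cumulative
z) move across estimators, using the range and the quartile coefficient of
variation (QCV).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .meta import StudyRecord
from .pipeline import CONCLUSIVE, TSAConfig, TSAResult, run_tsa
from .tau2 import METHODS

__all__ = ["SensitivityRow", "SensitivityReport", "sweep_estimators",
           "qcv", "range_summary"]

SUMMARY_COLUMNS = ("tau2_hat", "d2", "af", "ris_adjusted",
                   "min_boundary", "extreme_z")


@dataclass(frozen=True)
class SensitivityRow:
    estimator: str
    tau2_hat: float = float("nan")
    d2: float = float("nan")
    af: float = float("nan")
    ris_adjusted: float = float("nan")
    min_boundary: float = float("nan")
    extreme_z: float = float("nan")
    conclusion: str = ""
    error: Optional[str] = None


@dataclass(frozen=True)
class SensitivityReport:
    rows: tuple[SensitivityRow, ...]
    results: dict[str, TSAResult]
    summaries: dict[str, dict[str, float]]
    agreement: bool
    conclusive_estimators: tuple[str, ...]


def range_summary(values: Sequence[float]) -> tuple[float, float]:
    """Exact (min, max) of one or more values."""
    if len(values) == 0:
        raise ValueError("range_summary needs at least one value")
    return (min(values), max(values))


def qcv(values: Sequence[float], rule: str = "linear") -> float:
    """Quartile coefficient of variation, (Q3-Q1)/(Q3+Q1), as a percentage.

    ``rule`` selects the quartile convention: "linear" interpolates between
    order statistics; "tukey" uses the inclusive-median (hinge) rule.
    Inputs must be non-negative; all-zero input yields 0 by convention.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("qcv needs at least two values")
    if np.any(vals < 0):
        raise ValueError("qcv is defined for non-negative values")
    if np.all(vals == 0):
        return 0.0
    if rule == "linear":
        q1, q3 = np.percentile(vals, [25, 75])
    elif rule == "tukey":
        q1, q3 = _tukey_hinges(vals)
    else:
        raise ValueError("rule must be 'linear' or 'tukey'")
    if q3 == q1:  # includes Q1 = Q3 = 0, where the ratio is 0/0
        return 0.0
    return float((q3 - q1) / (q3 + q1) * 100.0)


def _tukey_hinges(vals: np.ndarray) -> tuple[float, float]:
    s = np.sort(vals)
    n = s.size
    half = (n + 1) // 2
    lower, upper = s[:half], s[n - half:]
    return float(np.median(lower)), float(np.median(upper))


def sweep_estimators(
    records: Sequence[StudyRecord],
    config: TSAConfig,
    estimators: Sequence[str] = METHODS,
    qcv_rule: str = "linear",
) -> SensitivityReport:
    """Run the TSA under every estimator and summarize the disagreement.

    Per-estimator failures are recorded in the corresponding row rather
    than aborting the sweep.  QCV for signed quantities (boundaries,
    z-scores) is computed on magnitudes.
    """
    rows: list[SensitivityRow] = []
    results: dict[str, TSAResult] = {}
    for method in estimators:
        try:
            res = run_tsa(records, replace(config, estimator=method))
        except Exception as exc:  # recorded, not fatal
            rows.append(SensitivityRow(estimator=method, error=str(exc)))
            continue
        results[method] = res
        rows.append(SensitivityRow(
            estimator=method, tau2_hat=res.tau2_hat, d2=res.d2, af=res.af,
            ris_adjusted=res.ris_adjusted, min_boundary=res.min_boundary,
            extreme_z=res.extreme_z, conclusion=res.conclusion,
        ))

    summaries: dict[str, dict[str, float]] = {}
    for col in SUMMARY_COLUMNS:
        vals = [getattr(r, col) for r in rows if r.error is None]
        if not vals:
            continue
        lo, hi = range_summary(vals)
        mags = [abs(v) for v in vals]
        summaries[col] = {"min": lo, "max": hi, "qcv": qcv(mags, qcv_rule)}

    conclusions = [r.conclusion for r in rows if r.error is None]
    agreement = len(set(conclusions)) <= 1
    conclusive = tuple(r.estimator for r in rows
                       if r.error is None and r.conclusion == CONCLUSIVE)
    return SensitivityReport(
        rows=tuple(rows), results=results, summaries=summaries,
        agreement=agreement, conclusive_estimators=conclusive,
    )
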