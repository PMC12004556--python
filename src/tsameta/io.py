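"""CSV input, structured reports, and TSA plots."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .meta import Z_975, StudyRecord
from .pipeline import TSAConfig, TSAResult
from .sensitivity import SensitivityReport

__all__ = ["REQUIRED_COLUMNS", "ReportBundle", "read_studies_csv",
           "write_studies_csv", "write_report", "plot_tsa"]

REQUIRED_COLUMNS = ("study_id", "order_key", "events_int", "total_int",
                    "events_ctl", "total_ctl")


def read_studies_csv(path: Union[str, Path]) -> list[StudyRecord]:
    """Read study 2x2 tables from CSV, validating every row.

    Required columns: study_id, order_key, events_int, total_int,
    events_ctl, total_ctl; optional: subgroup.  Rows are returned sorted by
    order_key (ties by study_id, then file order).  Validation failures
    name the offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records: list[StudyRecord] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            counts = {c: int(row[c]) for c in REQUIRED_COLUMNS[1:]}
            if any(counts[c] != row[c] for c in counts):
                raise ValueError("non-integer count")
            sub = row.get("subgroup")
            records.append(StudyRecord(
                study_id=str(row["study_id"]),
                subgroup=None if pd.isna(sub) else str(sub),
                **counts,
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {pos}: {exc}") from exc
    records.sort(key=lambda r: (r.order_key, r.study_id))
    return records


def write_studies_csv(records: Sequence[StudyRecord],
                      path: Union[str, Path]) -> None:
    """Write records in the same schema :func:`read_studies_csv` reads."""
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        path, index=False)


def _checksum(records: Sequence[StudyRecord]) -> str:
    text = ";".join(
        f"{r.study_id},{r.order_key},{r.events_int},{r.total_int},"
        f"{r.events_ctl},{r.total_ctl},{r.subgroup or ''}"
        for r in records
    )
    return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclasses.dataclass(frozen=True)
class ReportBundle:
    """Everything needed to reproduce and inspect one sensitivity run."""

    report: SensitivityReport
    config: TSAConfig
    records: tuple[StudyRecord, ...]

    def to_dict(self) -> dict:
        from . import __version__

        rows = []
        for r in self.report.rows:
            d = dataclasses.asdict(r)
            # display-rounded copies in the style of published TSA tables
            d["display"] = {
                "tau2_hat": round(r.tau2_hat, 4),
                "d2": round(r.d2, 2),
                "af": round(r.af, 2),
                "ris_adjusted": round(r.ris_adjusted, 0),
                "min_boundary": round(r.min_boundary, 2),
                "extreme_z": round(r.extreme_z, 2),
            } if r.error is None else None
            rows.append(d)
        looks = {
            method: [dataclasses.asdict(lk) for lk in res.looks]
            for method, res in self.report.results.items()
        }
        return {
            "version": __version__,
            "input_checksum": _checksum(self.records),
            "config": dataclasses.asdict(self.config),
            "rows": rows,
            "summaries": self.report.summaries,
            "agreement": self.report.agreement,
            "conclusive_estimators": list(self.report.conclusive_estimators),
            "looks": looks,
        }


def write_report(bundle: ReportBundle, path: Union[str, Path],
                 fmt: str = "json") -> None:
    """Serialize a report as JSON (full) or a flat CSV table (rows only)."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(bundle.to_dict(), indent=2,
                                   sort_keys=False) + "\n")
    elif fmt == "csv_table":
        rows = [dataclasses.asdict(r) for r in bundle.report.rows]
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError("fmt must be 'json' or 'csv_table'")


def plot_tsa(results: Union[TSAResult, Sequence[TSAResult]],
             path: Union[str, Path]) -> None:
    """Render TSA panels: cumulative z-curve, +/- boundaries, RIS line.

    One panel per estimator when a sequence is given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(results, TSAResult):
        results = [results]
    n = len(results)
    ncols = min(3, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, squeeze=False,
                             figsize=(4.5 * ncols, 3.5 * nrows))
    for ax, res in zip(axes.flat, results):
        ns = [lk.cumulative_n for lk in res.looks]
        ax.plot(ns, [lk.z for lk in res.looks], "o-", color="black",
                label="cumulative z")
        ax.plot(ns, [lk.boundary_z for lk in res.looks], "--", color="red",
                label="boundary")
        ax.plot(ns, [-lk.boundary_z for lk in res.looks], "--", color="red")
        ax.axhline(Z_975, color="grey", lw=0.8)
        ax.axhline(-Z_975, color="grey", lw=0.8)
        ax.axvline(res.ris_adjusted, color="blue", lw=0.8,
                   label=f"RIS = {res.ris_adjusted:.0f}")
        ax.set_title(f"{res.estimator} "
                     f"(tau2={res.tau2_hat:.3f}, {res.conclusion})",
                     fontsize=9)
        ax.set_xlabel("cumulative participants")
        ax.set_ylabel("z")
        ax.legend(fontsize=7)
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
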