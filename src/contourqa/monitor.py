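"""Pipeline orchestration, control-chart data and weekly outlier reports.

The monitoring loop mirrors the clinical workflow: structure-set pairs
are evaluated into metric records, records accumulate into per-ROI time
series, SPC parameters are frozen once from a baseline window, and every
series is then screened with the adapted Nelson rules.  Control charts
show the individual points, the target and control-limit lines, and a
moving average over the 30 nearest neighbouring points.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import geometry, rtstruct_io, spc
from .config import Config
from .rtstruct_io import METRIC_NAMES, MetricRecord
from .rules import Alarm, apply_rules
from .spc import SPCParameters

logger = logging.getLogger(__name__)

CHART_COLUMNS = ["index", "time", "value", "target", "lcl", "ucl", "moving_avg", "alarm_rule"]


def moving_average(values: Sequence[float], k: int = 30) -> np.ndarray:
    """Average of the k nearest points by index distance, including self.

    Near the edges the window truncates by taking the k nearest available
    points (the whole series when it is shorter than k); index-distance
    ties go to the earlier point.  For a contiguous index line this makes
    every window a contiguous block of ``min(k, n)`` points.
    """
    if k < 1:
        raise ValueError("moving-average window must be at least 1")
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("series must be non-empty")
    w = min(k, n)
    half_before = int(np.ceil((w - 1) / 2))  # ties toward earlier indices
    starts = np.clip(np.arange(n) - half_before, 0, n - w)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    return (csum[starts + w] - csum[starts]) / w


@dataclass
class ChartSeries:
    """Everything needed to draw one ROI/metric control chart."""

    roi_name: str
    metric: str
    times: list[datetime]
    values: np.ndarray
    target: float | None
    lcl: float | None
    ucl: float | None
    moving_avg: np.ndarray
    alarms: list[Alarm] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self.values)
        rule_marks = [""] * n
        for a in self.alarms:
            mark = str(a.rule)
            rule_marks[a.index_end] = (
                mark if not rule_marks[a.index_end] else rule_marks[a.index_end] + ";" + mark
            )
        return pd.DataFrame(
            {
                "index": np.arange(n),
                "time": [t.isoformat() for t in self.times],
                "value": self.values,
                "target": np.repeat(np.nan if self.target is None else self.target, n),
                "lcl": np.repeat(np.nan if self.lcl is None else self.lcl, n),
                "ucl": np.repeat(np.nan if self.ucl is None else self.ucl, n),
                "moving_avg": self.moving_avg,
                "alarm_rule": rule_marks,
            },
            columns=CHART_COLUMNS,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def build_chart(
    roi_name: str,
    metric: str,
    records: Sequence[MetricRecord],
    params: SPCParameters | None,
    alarms: Sequence[Alarm] = (),
    k: int = 30,
) -> ChartSeries:
    """Assemble chart data for one ROI/metric from time-ordered records."""
    recs = sorted(
        (r for r in records if r.roi_name == roi_name), key=lambda r: r.export_time
    )
    if not recs:
        raise ValueError(f"no records for ROI {roi_name!r}")
    values = np.array([float(getattr(r, metric)) for r in recs])
    own_alarms = [
        a for a in alarms if a.roi_name == roi_name and metric in a.metrics
    ]
    if params is None:
        logger.warning("ROI %r metric %s: no SPC parameters, chart has no limit lines",
                       roi_name, metric)
    return ChartSeries(
        roi_name=roi_name,
        metric=metric,
        times=[r.export_time for r in recs],
        values=values,
        target=None if params is None else params.target,
        lcl=None if params is None else params.lcl,
        ucl=None if params is None else params.ucl,
        moving_avg=moving_average(values, k=k),
        alarms=own_alarms,
    )


def render_chart(series: ChartSeries, path: str | Path) -> None:
    """Render a static control chart image (PNG) with matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3.2))
    idx = np.arange(len(series.values))
    ax.plot(idx, series.values, "o", ms=3, color="tab:blue", label="data")
    ax.plot(idx, series.moving_avg, "-", color="tab:orange", label="moving avg")
    for name, val, style in (
        ("target", series.target, "--"),
        ("LCL", series.lcl, ":"),
        ("UCL", series.ucl, ":"),
    ):
        if val is not None:
            ax.axhline(val, ls=style, color="tab:green", lw=1)
    for a in series.alarms:
        ax.plot(a.index_end, series.values[a.index_end], "rx", ms=8)
    ax.set_title(f"{series.roi_name} — {series.metric}")
    ax.set_xlabel("export index")
    ax.set_ylabel(series.metric)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# weekly outlier report
# ---------------------------------------------------------------------------


def outlier_frequency(
    records: Sequence[MetricRecord],
    alarms: Sequence[Alarm],
    min_roi_alarms: int = 0,
) -> pd.DataFrame:
    """Rule-1 alarms per ROI per ISO calendar week as counts and percentages.

    ``pct`` is the share of that week's total ROI records flagged for the
    given ROI name.  ROIs whose overall rule-1 alarm count does not exceed
    ``min_roi_alarms`` are dropped (the clinic's report only shows ROIs
    flagged more than twice); weeks without records are omitted.
    """
    recs = sorted(records, key=lambda r: r.export_time)
    week_totals: dict[tuple[int, int], int] = {}
    for r in recs:
        iso = r.export_time.isocalendar()
        week_totals[(iso.year, iso.week)] = week_totals.get((iso.year, iso.week), 0) + 1

    rule1 = [a for a in alarms if a.rule == 1 and a.timestamp is not None]
    roi_totals: dict[str, int] = {}
    for a in rule1:
        roi_totals[a.roi_name] = roi_totals.get(a.roi_name, 0) + 1

    rows = []
    counts: dict[tuple[int, int, str], int] = {}
    for a in rule1:
        if roi_totals[a.roi_name] <= min_roi_alarms:
            continue
        iso = a.timestamp.isocalendar()
        key = (iso.year, iso.week, a.roi_name)
        counts[key] = counts.get(key, 0) + 1
    for (year, week, roi), n_alarms in sorted(counts.items()):
        total = week_totals.get((year, week), 0)
        rows.append(
            {
                "iso_year": year,
                "iso_week": week,
                "roi_name": roi,
                "alarms": n_alarms,
                "week_total_records": total,
                "pct": 100.0 * n_alarms / total if total else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["iso_year", "iso_week", "roi_name", "alarms", "week_total_records", "pct"],
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def write_alarms(alarms: Sequence[Alarm], path: str | Path) -> None:
    """Persist alarms as JSON lines (one alarm per line, stable key order)."""
    with open(path, "w") as fh:
        for a in alarms:
            fh.write(json.dumps(a.to_dict(), sort_keys=True) + "\n")


def read_alarms(path: str | Path) -> list[Alarm]:
    alarms = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        alarms.append(
            Alarm(
                rule=int(d["rule"]),
                roi_name=d["roi"],
                metrics=tuple(d["metrics"]),
                direction=d["direction"],
                index_start=int(d["index_start"]),
                index_end=int(d["index_end"]),
                timestamp=datetime.fromisoformat(d["timestamp"]) if d["timestamp"] else None,
            )
        )
    return alarms


def evaluate_files(
    file_pairs: Sequence[tuple[str, str]],
    records_path: str | Path,
    config: Config = Config(),
) -> list[MetricRecord]:
    """Evaluate (DLS path, CS path) file pairs and append new records.

    Idempotent: a record keyed by (patient_id, roi_name, export_time)
    that is already present in the CSV is not appended again.  Per-pair
    failures are logged and skipped.
    """
    records_path = Path(records_path)
    existing: list[MetricRecord] = []
    if records_path.exists():
        existing = rtstruct_io.read_records(records_path)
    seen = {(r.patient_id, r.roi_name, r.export_time) for r in existing}

    new_records: list[MetricRecord] = []
    for dls_path, cs_path in file_pairs:
        try:
            dls_sets = rtstruct_io.read_rtstruct(dls_path)
            cs_sets = rtstruct_io.read_rtstruct(cs_path)
            ds = __import__("pydicom").dcmread(str(cs_path), stop_before_pixels=True)
            patient_id = str(getattr(ds, "PatientID", Path(cs_path).stem))
            export_time = rtstruct_io.read_export_time(cs_path)
        except Exception as exc:
            logger.error("skipping pair (%s, %s): %s", dls_path, cs_path, exc)
            continue
        pairing = rtstruct_io.pair_structures(
            dls_sets, cs_sets, patient_id, export_time, aliases=config.roi_aliases
        )
        for pair in pairing.pairs:
            key = (pair.patient_id, pair.roi_name, pair.export_time)
            if key in seen:
                logger.info("already processed: %s", key)
                continue
            rec = geometry.evaluate_pair(
                pair,
                in_plane_spacing_mm=config.in_plane_spacing_mm,
                sdsc_tol_mm=config.sdsc_tolerance_mm,
                apl_tol_mm=config.apl_tolerance_mm,
                hd_percentile=config.hd_percentile,
            )
            if rec is not None:
                new_records.append(rec)
                seen.add(key)
    if new_records:
        rtstruct_io.write_records(new_records, records_path, append=records_path.exists())
    return existing + new_records


def fit_parameters(
    records: Sequence[MetricRecord],
    config: Config = Config(),
    frozen_at: datetime | None = None,
) -> list[SPCParameters]:
    """Freeze SPC parameters per (ROI, metric) from a baseline record set.

    ROIs with fewer than ``spc_min_n`` records are skipped with a notice.
    ``frozen_at`` defaults to the latest export time in the baseline, so
    refitting the same baseline is fully reproducible.
    """
    if not records:
        return []
    if frozen_at is None:
        frozen_at = max(r.export_time for r in records)
    by_roi: dict[str, list[MetricRecord]] = {}
    for r in records:
        by_roi.setdefault(r.roi_name, []).append(r)
    params: list[SPCParameters] = []
    for roi, recs in sorted(by_roi.items()):
        recs = sorted(recs, key=lambda r: r.export_time)
        for metric in METRIC_NAMES:
            series = [float(getattr(r, metric)) for r in recs]
            try:
                params.append(
                    spc.estimate_parameters(
                        series,
                        metric=metric,
                        roi_name=roi,
                        alpha=config.spc_alpha,
                        min_n=config.spc_min_n,
                        shapiro_max_n=config.shapiro_max_n,
                        frozen_at=frozen_at,
                    )
                )
            except spc.InsufficientDataError as exc:
                logger.info("monitoring disabled: %s", exc)
    return params


def monitor_records(
    records: Sequence[MetricRecord],
    params: Sequence[SPCParameters],
    config: Config = Config(),
) -> list[Alarm]:
    """Apply the adapted Nelson rules to every ROI's record history."""
    by_roi: dict[str, list[MetricRecord]] = {}
    for r in records:
        by_roi.setdefault(r.roi_name, []).append(r)
    params_idx = spc.parameters_by_roi(params)
    alarms: list[Alarm] = []
    for roi, recs in sorted(by_roi.items()):
        roi_params = params_idx.get(roi, {})
        if not roi_params:
            logger.info("ROI %r has no frozen parameters; monitoring skipped", roi)
            continue
        alarms.extend(apply_rules(recs, roi_params, config.rules))
    for a in alarms:
        logger.warning(
            "ALARM rule %d: ROI %s %s (%s) at indices %d-%d",
            a.rule, a.roi_name, ",".join(a.metrics), a.direction,
            a.index_start, a.index_end,
        )
    return alarms


def run_pipeline(
    file_pairs: Sequence[tuple[str, str]],
    out_dir: str | Path,
    config: Config = Config(),
    params_path: str | Path | None = None,
) -> dict:
    """Evaluate pairs, then (if parameters are frozen) monitor and chart.

    Writes ``records.csv``, ``alarms.jsonl`` and one chart CSV per
    ROI/metric under ``out_dir``.  Alarms and charts are recomputed from
    the full record history on every run, so re-running on the same
    inputs is idempotent and byte-stable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = evaluate_files(file_pairs, out_dir / "records.csv", config)

    result = {"n_records": len(records), "n_alarms": 0, "charts": []}
    if params_path is None or not Path(params_path).exists():
        logger.info("no frozen SPC parameters; monitoring skipped")
        return result

    params = spc.load_parameters(params_path)
    alarms = monitor_records(records, params, config)
    write_alarms(alarms, out_dir / "alarms.jsonl")
    result["n_alarms"] = len(alarms)

    charts_dir = out_dir / "charts"
    charts_dir.mkdir(exist_ok=True)
    params_idx = spc.parameters_by_roi(params)
    roi_names = sorted({r.roi_name for r in records})
    for roi in roi_names:
        for metric in METRIC_NAMES:
            p = params_idx.get(roi, {}).get(metric)
            series = build_chart(roi, metric, records, p, alarms, k=config.moving_average_k)
            chart_path = charts_dir / f"{roi}_{metric}.csv"
            series.to_csv(chart_path)
            result["charts"].append(str(chart_path))
    return result
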