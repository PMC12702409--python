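"""Adapted Nelson run rules for segmentation monitoring.

Three of Nelson's eight control-chart rules are applied, adapted so that a
single noisy metric does not flood the clinic with alarms:

* **Rule 1 — outlier.** A data point where at least three of the four
  geometric metrics fall outside their control limits.  Each out-of-limit
  metric votes a direction: a similarity score (VDSC/SDSC) below its LCL
  or a distance/effort metric (HD95/APL) above its UCL means the clinician
  adjusted *more* than usual (``larger_adjustment``); the opposite sides
  mean *less* than usual.  The alarm carries the majority vote, ties
  resolved toward ``larger_adjustment`` (the safety-relevant direction).
* **Rule 2 — trend shift.** Nine consecutive points of one metric on the
  same side of the target outside a +-0.5 % tolerance band.  In-band
  points reset the run (configurable), and the counter resets after an
  alarm so one sustained shift fires once per completed run, not on every
  subsequent point.
* **Rule 3 — trend drift.** Six consecutive points of one metric strictly
  increasing or strictly decreasing (five strict increments); ties break
  the run.

Rule 1 is pointwise; rules 2 and 3 depend on the series order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from typing import Mapping, Sequence

from .rtstruct_io import METRIC_NAMES, MetricRecord
from .spc import SPCParameters

logger = logging.getLogger(__name__)

#: metrics where a larger value means a better match
HIGHER_IS_BETTER = frozenset({"vdsc", "sdsc3"})

LARGER = "larger_adjustment"
LESS = "less_adjustment"


@dataclass
class RuleConfig:
    """Tunable rule thresholds (defaults are the adapted clinical rules)."""

    rule1_min_metrics: int = 3
    rule2_run: int = 9
    rule2_tolerance: float = 0.005  # band half-width as a fraction of |target|
    rule2_tolerance_abs: float | None = None  # overrides the relative band
    rule2_reset_on_inband: bool = True  # False: in-band points pause the run
    rule3_run: int = 6  # points; run-1 strict increments

    def __post_init__(self) -> None:
        if not (1 <= self.rule1_min_metrics <= 4):
            raise ValueError("rule1_min_metrics must be in [1, 4]")
        if self.rule2_run < 2 or self.rule3_run < 2:
            raise ValueError("rule runs must be at least 2")
        if self.rule2_tolerance < 0:
            raise ValueError("rule2_tolerance must be non-negative")


@dataclass
class Alarm:
    rule: int  # 1, 2 or 3
    roi_name: str
    metrics: tuple[str, ...]
    direction: str
    index_start: int
    index_end: int
    timestamp: datetime | None = None

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "roi": self.roi_name,
            "metrics": list(self.metrics),
            "direction": self.direction,
            "index_start": self.index_start,
            "index_end": self.index_end,
            "timestamp": self.timestamp.isoformat() if self.timestamp else None,
        }


def _metric_direction(metric: str, value: float, p: SPCParameters) -> str | None:
    """Adjustment direction of one out-of-limit metric, None if in limits."""
    if value < p.lcl:
        return LARGER if metric in HIGHER_IS_BETTER else LESS
    if value > p.ucl:
        return LESS if metric in HIGHER_IS_BETTER else LARGER
    return None


def rule1_outlier(
    record: MetricRecord,
    params: Mapping[str, SPCParameters],
    cfg: RuleConfig = RuleConfig(),
    index: int = 0,
) -> Alarm | None:
    """Flag a record with >= ``rule1_min_metrics`` metrics out of limits."""
    missing = [m for m in METRIC_NAMES if m not in params]
    if missing:
        logger.warning(
            "ROI %r: no frozen parameters for %s; record skipped",
            record.roi_name,
            missing,
        )
        return None
    out_metrics: list[str] = []
    votes: list[str] = []
    for m in METRIC_NAMES:
        d = _metric_direction(m, float(getattr(record, m)), params[m])
        if d is not None:
            out_metrics.append(m)
            votes.append(d)
    if len(out_metrics) < cfg.rule1_min_metrics:
        return None
    n_larger = votes.count(LARGER)
    direction = LARGER if n_larger >= votes.count(LESS) else LESS
    return Alarm(
        rule=1,
        roi_name=record.roi_name,
        metrics=tuple(out_metrics),
        direction=direction,
        index_start=index,
        index_end=index,
        timestamp=record.export_time,
    )


def _band(p: SPCParameters, cfg: RuleConfig) -> float:
    if cfg.rule2_tolerance_abs is not None:
        return cfg.rule2_tolerance_abs
    return cfg.rule2_tolerance * abs(p.target)


def rule2_shift(
    values: Sequence[float],
    p: SPCParameters,
    cfg: RuleConfig = RuleConfig(),
    roi_name: str = "",
    metric: str = "",
    timestamps: Sequence[datetime] | None = None,
) -> list[Alarm]:
    """Detect runs of same-side points outside the target tolerance band.

    Returns every completed run in order; the run counter restarts after
    each alarm.
    """
    t = _band(p, cfg)
    lo, hi = p.target - t, p.target + t
    alarms: list[Alarm] = []
    side: str | None = None
    count = 0
    start = 0
    for i, v in enumerate(values):
        if v > hi:
            s = "above_target"
        elif v < lo:
            s = "below_target"
        else:
            if cfg.rule2_reset_on_inband:
                side, count = None, 0
            continue  # in-band: pause (or reset above)
        if s == side:
            count += 1
        else:
            side, count, start = s, 1, i
        if count >= cfg.rule2_run:
            alarms.append(
                Alarm(
                    rule=2,
                    roi_name=roi_name,
                    metrics=(metric,),
                    direction=s,
                    index_start=start,
                    index_end=i,
                    timestamp=timestamps[i] if timestamps is not None else None,
                )
            )
            side, count = None, 0
    return alarms


def rule3_drift(
    values: Sequence[float],
    cfg: RuleConfig = RuleConfig(),
    roi_name: str = "",
    metric: str = "",
    timestamps: Sequence[datetime] | None = None,
) -> list[Alarm]:
    """Detect strictly monotone runs of ``rule3_run`` points; ties reset."""
    alarms: list[Alarm] = []
    direction: int = 0  # +1 increasing, -1 decreasing, 0 none
    run_points = 1
    start = 0
    skip_diff = False  # increment into a just-alarmed point is consumed
    for i in range(1, len(values)):
        if skip_diff:
            skip_diff = False
            direction, run_points, start = 0, 1, i
            continue
        diff = values[i] - values[i - 1]
        if diff > 0:
            d = 1
        elif diff < 0:
            d = -1
        else:
            direction, run_points, start = 0, 1, i
            continue
        if d == direction:
            run_points += 1
        else:
            direction, run_points, start = d, 2, i - 1
        if run_points >= cfg.rule3_run:
            alarms.append(
                Alarm(
                    rule=3,
                    roi_name=roi_name,
                    metrics=(metric,),
                    direction="increasing" if d > 0 else "decreasing",
                    index_start=start,
                    index_end=i,
                    timestamp=timestamps[i] if timestamps is not None else None,
                )
            )
            direction, run_points, start = 0, 1, i
            skip_diff = True
    return alarms


def apply_rules(
    records: Sequence[MetricRecord],
    params: Mapping[str, SPCParameters],
    cfg: RuleConfig = RuleConfig(),
) -> list[Alarm]:
    """Run all three rules over one ROI's time-ordered record history.

    Rule 1 is evaluated on every record; rules 2 and 3 scan each metric's
    value series.  Alarms come back in chronological order of the index at
    which their condition first completes.
    """
    records = sorted(records, key=lambda r: r.export_time)
    times = [r.export_time for r in records]
    alarms: list[Alarm] = []
    roi = records[0].roi_name if records else ""

    have_all = all(m in params for m in METRIC_NAMES)
    if have_all:
        for i, rec in enumerate(records):
            a = rule1_outlier(rec, params, cfg, index=i)
            if a is not None:
                alarms.append(a)
    else:
        logger.warning("ROI %r: rule 1 disabled (incomplete parameter set)", roi)

    for m in METRIC_NAMES:
        series = [float(getattr(r, m)) for r in records]
        if m in params:
            alarms.extend(
                rule2_shift(series, params[m], cfg, roi_name=roi, metric=m, timestamps=times)
            )
        alarms.extend(rule3_drift(series, cfg, roi_name=roi, metric=m, timestamps=times))

    alarms.sort(key=lambda a: (a.index_end, a.rule, a.metrics))
    return alarms
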