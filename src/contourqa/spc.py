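"""Statistical-process-control parameters per ROI and metric.

For every monitored (ROI, metric) series a target line and lower/upper
control limits (LCL/UCL) are frozen from a baseline window:

* normally distributed data (Shapiro-Wilk p >= alpha): target = mean,
  limits = mean +- 2 sample standard deviations.  Two sigma rather than
  the classical three is used for sensitivity: with normal data ~4.6 % of
  points fall outside, 2.3 % per tail.
* non-normal data: target = median, limits = the 2.3rd and 97.7th
  percentiles — the same tail mass the 2-sigma limits would cut off were
  the data normal.
* constant series: a degenerate branch with target = LCL = UCL, so the
  first deviation of a fully-accepted ROI flags immediately.

Limits are clamped to the metric's valid range (Dice scores to [0, 1],
distances and voxel counts to >= 0).  Parameters are frozen at a fixed
point in time and persisted to JSON; monitoring always evaluates against
the frozen set, never a rolling estimate.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import asdict, dataclass
from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_N = 10
#: Shapiro-Wilk p-values are unreliable above this n; larger series are
#: tested on a deterministic evenly-strided subsample of this size.
DEFAULT_SHAPIRO_MAX_N = 5000
SIGMA_MULTIPLIER = 2.0
#: tail percentiles equivalent to +-2 sigma under normality
LOWER_PERCENTILE = 2.3
UPPER_PERCENTILE = 97.7

METRIC_RANGES: dict[str, tuple[float, float]] = {
    "vdsc": (0.0, 1.0),
    "sdsc3": (0.0, 1.0),
    "hd95": (0.0, math.inf),
    "apl": (0.0, math.inf),
}


class InsufficientDataError(ValueError):
    """Series shorter than the minimum baseline; monitoring stays disabled."""


class ParameterSchemaError(ValueError):
    """Persisted parameter file fails validation."""


@dataclass
class SPCParameters:
    roi_name: str
    metric: str
    target: float
    lcl: float
    ucl: float
    branch: str  # normal | nonparametric | degenerate
    n: int
    frozen_at: str  # ISO-8601

    def validate(self) -> None:
        if self.metric not in METRIC_RANGES:
            raise ParameterSchemaError(f"unknown metric {self.metric!r}")
        if self.branch not in ("normal", "nonparametric", "degenerate"):
            raise ParameterSchemaError(f"unknown branch {self.branch!r}")
        if not (self.lcl <= self.target <= self.ucl):
            raise ParameterSchemaError(
                f"{self.roi_name}/{self.metric}: lcl <= target <= ucl violated "
                f"({self.lcl}, {self.target}, {self.ucl})"
            )
        lo, hi = METRIC_RANGES[self.metric]
        if self.lcl < lo - 1e-12 or self.ucl > hi + 1e-12:
            raise ParameterSchemaError(
                f"{self.roi_name}/{self.metric}: limits outside metric range"
            )


def estimate_parameters(
    values: Sequence[float],
    metric: str,
    roi_name: str = "",
    alpha: float = DEFAULT_ALPHA,
    min_n: int = DEFAULT_MIN_N,
    shapiro_max_n: int = DEFAULT_SHAPIRO_MAX_N,
    frozen_at: datetime | str | None = None,
) -> SPCParameters:
    """Estimate (target, LCL, UCL) for one metric series.

    Raises :class:`InsufficientDataError` below ``min_n`` samples (ROIs
    seen fewer than ten times are not monitored).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if len(x) < min_n:
        raise InsufficientDataError(
            f"{roi_name}/{metric}: {len(x)} samples < minimum {min_n}"
        )
    if metric not in METRIC_RANGES:
        raise ValueError(f"unknown metric {metric!r}")

    if isinstance(frozen_at, datetime):
        frozen_at = frozen_at.isoformat()
    elif frozen_at is None:
        frozen_at = datetime.now().isoformat(timespec="seconds")

    if np.ptp(x) == 0:
        target = lcl = ucl = float(x[0])
        branch = "degenerate"
    else:
        test_sample = x
        if len(x) > shapiro_max_n:
            stride_idx = np.linspace(0, len(x) - 1, shapiro_max_n).astype(int)
            test_sample = x[stride_idx]
        p = stats.shapiro(test_sample).pvalue
        if p >= alpha:
            branch = "normal"
            target = float(np.mean(x))
            sigma = float(np.std(x, ddof=1))
            lcl = target - SIGMA_MULTIPLIER * sigma
            ucl = target + SIGMA_MULTIPLIER * sigma
        else:
            branch = "nonparametric"
            target = float(np.median(x))
            lcl = float(np.percentile(x, LOWER_PERCENTILE))
            ucl = float(np.percentile(x, UPPER_PERCENTILE))

    lo, hi = METRIC_RANGES[metric]
    lcl = min(max(lcl, lo), hi)
    ucl = min(max(ucl, lo), hi)
    target = min(max(target, lo), hi)
    params = SPCParameters(
        roi_name=roi_name,
        metric=metric,
        target=target,
        lcl=lcl,
        ucl=ucl,
        branch=branch,
        n=len(x),
        frozen_at=str(frozen_at),
    )
    params.validate()
    return params


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def freeze_parameters(
    params: Sequence[SPCParameters], path: str | os.PathLike
) -> None:
    """Persist a frozen parameter set to JSON.

    Re-freezing over an existing file preserves the previous version under
    a name suffixed with its own ``frozen_at`` stamp, so the history of
    control limits remains auditable.
    """
    for p in params:
        p.validate()
    path = Path(path)
    if path.exists():
        try:
            old = json.loads(path.read_text())
            stamp = old[0]["frozen_at"] if old else "empty"
        except Exception:
            stamp = "unreadable"
        stamp = stamp.replace(":", "").replace("-", "").replace("T", "_")
        backup = path.with_name(f"{path.stem}.{stamp}{path.suffix}")
        path.rename(backup)
        logger.info("previous SPC parameters preserved as %s", backup)
    path.write_text(json.dumps([asdict(p) for p in params], indent=2, sort_keys=True))


def load_parameters(path: str | os.PathLike) -> list[SPCParameters]:
    """Load and validate a frozen parameter set."""
    raw = json.loads(Path(path).read_text())
    required = {"roi_name", "metric", "target", "lcl", "ucl", "branch", "n", "frozen_at"}
    params = []
    for item in raw:
        missing = required - set(item)
        if missing:
            raise ParameterSchemaError(f"parameter entry missing fields: {sorted(missing)}")
        p = SPCParameters(**{k: item[k] for k in required})
        p.validate()
        params.append(p)
    return params


def parameters_by_roi(
    params: Sequence[SPCParameters],
) -> dict[str, dict[str, SPCParameters]]:
    """Index a flat parameter list as {roi_name: {metric: params}}."""
    out: dict[str, dict[str, SPCParameters]] = {}
    for p in params:
        out.setdefault(p.roi_name, {})[p.metric] = p
    return out
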