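"""Freeze SPC control limits from a baseline metric series.

Shows the two estimation branches: near-normal data keeps the mean and
mean +- 2 sigma; skewed data (typical for HD95 and APL) falls back to the
median with the 2.3rd / 97.7th percentiles — the same tail mass 2 sigma
would cut off were the data normal.
"""

import numpy as np

from contourqa import estimate_parameters

rng = np.random.default_rng(0)

# a well-behaved Dice series
vdsc_series = np.clip(rng.normal(0.95, 0.015, size=120), 0, 1)
p = estimate_parameters(vdsc_series, metric="vdsc", roi_name="Heart")
print(f"vdsc : branch={p.branch:14s} target={p.target:.4f} "
      f"limits=[{p.lcl:.4f}, {p.ucl:.4f}]  (limits are clamped to [0, 1])")

# a right-skewed added-path-length series
apl_series = 50 + rng.exponential(400.0, size=120)
q = estimate_parameters(apl_series, metric="apl", roi_name="Heart")
print(f"apl  : branch={q.branch:14s} target={q.target:.1f} "
      f"limits=[{q.lcl:.1f}, {q.ucl:.1f}]")

# a fully accepted ROI: degenerate limits flag the first deviation
r = estimate_parameters([1.0] * 15, metric="vdsc", roi_name="Femur_Head_R")
print(f"const: branch={r.branch:14s} target={r.target} limits=[{r.lcl}, {r.ucl}]")
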