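# contourqa

Continuous quality assurance for deep-learning auto-segmentation in
radiotherapy.

When a clinic adopts automatic organ/target delineation, the model's
performance must be watched *after* go-live, not just at commissioning:
software upgrades, protocol changes and shifting patient mix can all
degrade segmentations silently. `contourqa` implements a monitoring loop
for exactly this situation. The treatment-planning workflow exports each
patient's RT Structure Set twice — once immediately after deep-learning
segmentation (DLS) and once after clinical approval (CS). Because both
exports share one frame of reference, the contours can be compared
geometrically without the image series. Every pair yields four metrics
per ROI, and the per-ROI metric time series are screened with statistical
process control (SPC) and three adapted Nelson run rules.

## The metrics

For masks $A$ (DLS) and $B$ (CS) rasterised on a shared grid:

* **VDSC** — volumetric Dice, $2|A\cap B| / (|A|+|B|)$.
* **SDSC** — surface Dice at tolerance $\tau$ (default 3 mm): the
  fraction of the two discrete surfaces within $\tau$ of each other,
  $\bigl(|\{a\in S_A: d(a,S_B)\le\tau\}| + |\{b\in S_B: d(b,S_A)\le\tau\}|\bigr) / (|S_A|+|S_B|)$.
* **HD95** — the 95th percentile of the pooled directed surface
  distances $\{d(a,S_B)\}\cup\{d(b,S_A)\}$, in mm.
* **APL** — added path length: per slice, the number of in-plane
  boundary voxels of the CS that the DLS boundary does not share; a proxy
  for how much contour the clinician re-drew.

A pair whose masks are voxel-identical is *accepted without correction*
(AWC) and scores the identity values (1, 1, 0 mm, 0 voxels).

## The monitoring model

Per ROI and metric, a target and 2-sigma control limits are frozen from a
baseline window (at least 10 exports): mean ± 2s when a Shapiro–Wilk test
accepts normality, otherwise the median with the 2.3rd/97.7th percentiles
(the same tail mass, ≈2.3 % per side, that ±2σ cuts off under
normality). Incoming series are then screened with three adapted Nelson
rules: **rule 1** (outlier) fires when ≥3 of the 4 metrics leave their
limits at one export, with the direction classified as a larger or
smaller adjustment than usual; **rule 2** (trend shift) fires on 9
consecutive points on one side of the target ± 0.5 % band; **rule 3**
(trend drift) fires on 6 consecutive strictly monotone points.

## Worked example

`examples/01_compare_contours.py` builds a spherical contour stack,
shifts it by 2 mm (a stand-in for a clinical edit) and compares:

```
VDSC   = 0.877   (volume overlap, 1 = identical)
SDSC3  = 1.000   (surface agreement within 3 mm)
HD95   = 2.0 mm (robust worst-case surface separation)
APL    = 492 voxels (boundary the clinician re-drew)
AWC    = False    (accepted without correction?)

unchanged copy -> VDSC=1.0, SDSC3=1.0, HD95=0.0, APL=0, AWC=True
```

The 2 mm translation leaves every surface point within the 3 mm surface
tolerance (SDSC = 1) while HD95 reports the shift magnitude exactly, and
the untouched copy scores the identity pattern. The other examples show
the SPC branches (`02_control_limits.py`), alarm detection on a series
with an injected outlier, shift and drift (`03_nelson_rules.py`), and the
full evaluate → fit → monitor → chart pipeline on a synthetic cohort
(`04_full_pipeline.py`).

## Command line

The same stages are available as a thin CLI:

```bash
contourqa simulate cohort --patients 20 --seed 1   # synthetic DLS/CS pairs
contourqa evaluate cohort/dls cohort/cs --records records.csv
contourqa fit records.csv --params spc.json
contourqa monitor records.csv spc.json --alarms alarms.jsonl
contourqa chart records.csv Heart hd95 --params spc.json --alarms alarms.jsonl
contourqa report records.csv alarms.jsonl          # weekly outlier table
```

## Layout

* `src/contourqa/rtstruct_io.py` — RTSTRUCT parsing, DLS/CS pairing, CSV records
* `src/contourqa/geometry.py` — rasterisation and the four metrics
* `src/contourqa/spc.py` — control-limit estimation and freezing
* `src/contourqa/rules.py` — the three adapted Nelson rules
* `src/contourqa/monitor.py` — pipeline, charts, weekly report
* `src/contourqa/synth.py` — synthetic shapes, perturbations, series
* `docs/methods.md` — modelling choices, conventions and limitations
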