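# Methods

## Problem setting

A clinic monitors its auto-segmentation model by exporting every
patient's RT Structure Set twice: immediately after deep-learning
segmentation (DLS) and after clinical approval (CS). Both exports share
one frame of reference, so contours are compared directly in patient
coordinates; no image series is read. The per-ROI comparison metrics
form time series that are screened with statistical process control
(SPC) and three adapted Nelson rules.

## Grid convention

The structure sets carry no voxel grid, so one is imposed per DLS/CS
pair:

* in-plane spacing 1.0 mm (configurable) — typical dose-grid practice,
  and it makes APL voxel counts comparable across patients;
* slice spacing dz = the modal spacing of the contour z-planes, with
  grid z-levels aligned to the planes (a contour plane must land within
  dz/2 of a slice, otherwise the grid is rejected as malformed);
* the grid covers the joint bounding box of both contour stacks plus a
  margin of the surface-Dice tolerance + two voxels, so surface-distance
  queries never clip;
* in x/y the origin is offset half a voxel from the bounding box, so
  contour edges drawn at round millimetre coordinates do not coincide
  with voxel centres.

A voxel centre is occupied iff it lies strictly inside an odd number of
that plane's polygons (even-odd rule; a nested contour is a hole).
Strict containment makes an on-edge centre unoccupied; with the
half-voxel origin offset this case is practically unreachable, and
either way the rule is deterministic.

## Metric conventions

* Surfaces are occupied voxels with ≥1 unoccupied 6-neighbour
  (out-of-grid counts as unoccupied); surface elements are voxel centres
  with equal weight, not face areas. Absolute SDSC/HD values may
  therefore differ slightly from mesh-based implementations.
* HD95 is the pooled symmetric variant: the 95th percentile (linear
  interpolation) over the union of both directed distance sets, the
  common choice in segmentation QA. The percentile and both the pooled /
  max-of-directed conventions differ only in pathological cases; the
  percentile is configurable.
* APL uses zero distance tolerance and per-slice 2-D (4-connectivity)
  boundaries, counting CS boundary voxels absent from the DLS boundary;
  it is deliberately asymmetric (the DLS is the reference being
  corrected). A positive tolerance switches to a nearest-neighbour
  distance test within the slice.
* AWC (accepted without correction) is defined as voxel-identical
  occupancy arrays; it forces the identity metrics (1, 1, 0, 0) exactly.

## SPC parameter estimation

Per (ROI, metric), with at least `min_n = 10` baseline points (ROIs seen
fewer than ten times are not monitored — ten being the conventional
commissioning sample size):

1. constant series → degenerate branch, target = LCL = UCL; any later
   deviation of a fully-accepted ROI then flags immediately (the
   Shapiro–Wilk statistic is undefined on constant data);
2. Shapiro–Wilk p ≥ 0.05 → normal branch: target = mean, limits =
   mean ± 2 sample standard deviations (n−1 denominator). Two sigma is
   used instead of the classical three for sensitivity; ~4.6 % of
   in-control normal data falls outside, 2.3 % per tail;
3. otherwise → nonparametric branch: target = median, limits = the
   2.3rd and 97.7th percentiles (linear interpolation) — the same tail
   mass as ±2σ under normality, so both branches are calibrated alike.

Limits are clamped to the metric's valid range ([0, 1] for Dice scores,
[0, ∞) for distances/counts); clamping cannot invert the limit order.
The Shapiro–Wilk p-value is unreliable above n = 5000, so larger series
are tested on an evenly-strided subsample of 5000 points
(config-exposed); the moments/percentiles always use the full series.
Parameters are frozen at a fixed point in time and persisted to JSON;
monitoring always runs against the frozen set. `frozen_at` defaults to
the newest baseline export time, which keeps refits of the same baseline
bit-reproducible. Re-freezing preserves the previous file under a
versioned name.

## Adapted Nelson rules

* **Rule 1 (outlier)** — a record with ≥3 of the 4 metrics outside
  their control limits (threshold configurable). Requiring a majority of
  metrics, rather than any single one, is what keeps the false-alarm
  rate of a 2-sigma chart clinically tolerable. Each out-of-limit metric
  votes a direction: similarity below LCL or distance/effort above UCL
  means the clinician adjusted *more* than usual; the opposite sides
  mean *less*. The alarm takes the majority vote, ties resolved toward
  `larger_adjustment` (the safety-relevant direction).
* **Rule 2 (trend shift)** — nine consecutive points of one metric on
  one side of the target outside a band of half-width 0.5 % of
  |target| (zero band when the target is 0). In-band points reset the
  run by default — the conservative reading that limits false alarms;
  a pause-instead-of-reset switch and an absolute band width are
  config options since the clinical convention varies.
* **Rule 3 (trend drift)** — six consecutive points strictly increasing
  or decreasing (five strict increments); ties break the run. Counting
  points rather than increments follows the rule's classical wording.

After any alarm the corresponding run counter restarts from scratch, so
one sustained shift fires once per completed run instead of on every
subsequent record. Rule 1 is pointwise; permuting a series can change
rules 2–3 but never rule 1.

## Control charts and reports

Chart data per ROI/metric: the ordered points, target/LCL/UCL lines, a
moving average, and alarm markers, serialisable to CSV and renderable to
PNG. The moving average at index i is the mean of the 30 points nearest
to i by index distance (ties toward earlier points; truncated to the
available points near the edges) — a nearest-k window rather than a
trailing window, so the smoother is defined at both ends of the series.
The weekly outlier report bins rule-1 alarms by ISO calendar week and
reports per-ROI counts and the percentage of that week's total records,
optionally hiding ROIs flagged fewer than a configurable number of
times.

## Synthetic data

The generators stand in for clinical exports:

* **Shapes** — spheres, ellipsoids, boxes and tubes sampled as polygon
  stacks (spheres/ellipsoids on the absolute z-grid, like a scanner).
  Being analytic, their metric values are computable independently of
  the rasteriser, which separates geometry bugs from fixture bugs.
* **Perturbations** — `none` (the AWC case, an exact copy),
  `translate` (rigid offset; HD95 of the pair approaches the magnitude),
  `dilate` (in-plane radial expansion by a mm offset), `edit_slices`
  (a seeded smooth deformation of a fraction of planes) and `replace`
  (all planes deformed). Defaults for cohort fixtures — magnitudes of
  1–3 mm on organs of 8–13 mm radius, a quarter of cases accepted
  unchanged — mirror the situation where most automatic contours need
  only modest editing.
* **Metric series** — per-metric baselines (normal for the Dice scores,
  shifted-exponential for HD95/APL, matching their observed skewness)
  with additive outlier/shift/drift events, clamped to valid ranges.
  Every generator is a pure function of its spec including the seed.

What the fixtures do *not* emulate: anatomical shape variation,
inter-observer styles, protocol-specific ROI naming chaos, or imaging
artefacts. Passing tests therefore demonstrate the correctness of the
metric/SPC/rule machinery, not the clinical performance of any
segmentation model.

## Problem sizes and numerics

The test suite and the acceptance script use cohorts of 12–20 synthetic
patients, organs up to ~30 voxels across, oracle comparisons on 200
random mask pairs ≤ 30³ voxels, and seeded series of 10³–10⁵ points for
statistical checks — small enough to re-run anywhere in seconds while
still exercising every code path. Distances are exact Euclidean
centre-to-centre values (k-d tree queries, checked against all-pairs
brute force to 1e-9); percentiles use linear interpolation throughout;
all randomness flows through explicit `numpy.random.Generator` seeds.

## Known limitations

* Absolute SDSC/HD95/APL values depend on the imposed grid and the
  equal-weight voxel-surface convention; cross-software comparisons
  should compare trends, not raw magnitudes.
* APL in voxels depends on the in-plane spacing; keep it fixed within a
  monitored cohort.
* The rule-2 band semantics (relative band, reset-on-in-band) follow
  the conservative convention; both are configurable because published
  practice varies.
* Only rules 1–3 are implemented; the remaining classical run rules
  trade specificity for sensitivity and are out of scope, as are
  rolling/adaptive control limits and dosimetric (DVH-based) extensions.
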