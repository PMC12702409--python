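"""Synthetic fixtures: organ-like contour stacks, clinical-edit
perturbations, RTSTRUCT files and metric time series.

Real monitoring data are pairs of structure sets from a treatment
planning system.  For testing, this module generates analytic stand-ins:

* parametric 3-D shapes (sphere, ellipsoid, box, tube) sliced into planar
  polygon stacks, so that oracle metric values are computable
  independently of the rasteriser;
* perturbations emulating what clinicians do to automatic contours —
  accept unchanged, translate, dilate, partially re-draw slices;
* minimal standard-conformant RT Structure Set files that round-trip
  through :func:`contourqa.rtstruct_io.read_rtstruct`;
* per-ROI metric time series with injected outliers, level shifts and
  monotone drifts for exercising the run rules.

Every generator is a pure function of its spec (including the seed); no
global random state is touched.
"""

from __future__ import annotations

import copy
import datetime as dt
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .rtstruct_io import RTSTRUCT_SOP_CLASS_UID, ContourSet, MetricRecord

SHAPE_KINDS = ("sphere", "ellipsoid", "box", "tube")
PERTURB_KINDS = ("none", "translate", "dilate", "edit_slices", "replace")


@dataclass
class ShapeSpec:
    """Analytic 3-D shape sampled into a contour stack.

    ``size`` is the radius for a sphere, the three semi-axes for an
    ellipsoid, the full edge lengths for a box, and (radius, length) for a
    tube along z.
    """

    kind: str
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    size: tuple[float, ...] = (10.0,)
    z_spacing: float = 2.0
    points_per_contour: int = 32

    def __post_init__(self) -> None:
        if self.kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if any(s <= 0 for s in self.size) or self.z_spacing <= 0:
            raise ValueError("shape sizes and z_spacing must be positive")
        if self.points_per_contour < 8:
            raise ValueError("points_per_contour must be at least 8")


@dataclass
class PerturbationSpec:
    """Clinical-edit emulation applied to a contour stack.

    ``magnitude`` is mm: the offset for ``translate``, the in-plane radial
    expansion for ``dilate``, and the deformation amplitude for
    ``edit_slices``/``replace``.  ``fraction`` selects how many planes an
    ``edit_slices`` perturbation re-draws.
    """

    kind: str = "none"
    magnitude: float = 0.0
    fraction: float = 0.0
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PERTURB_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# shapes
# ---------------------------------------------------------------------------


def _circle(cx: float, cy: float, z: float, rx: float, ry: float, n: int) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack(
        [cx + rx * np.cos(theta), cy + ry * np.sin(theta), np.full(n, z)]
    )


def _rectangle(cx: float, cy: float, z: float, sx: float, sy: float, n: int) -> np.ndarray:
    """Axis-aligned rectangle sampled with >= n vertices including corners."""
    per_edge = max(int(np.ceil(n / 4)), 2)
    hx, hy = sx / 2, sy / 2
    corners = [(-hx, -hy), (hx, -hy), (hx, hy), (-hx, hy)]
    pts = []
    for (x0, y0), (x1, y1) in zip(corners, corners[1:] + corners[:1]):
        for t in np.linspace(0.0, 1.0, per_edge, endpoint=False):
            pts.append((x0 + t * (x1 - x0), y0 + t * (y1 - y0)))
    arr = np.array(pts)
    return np.column_stack([cx + arr[:, 0], cy + arr[:, 1], np.full(len(arr), z)])


def make_contours(spec: ShapeSpec, roi_name: str = "Synthetic") -> ContourSet:
    """Sample analytic cross-sections of the shape at regular z-planes.

    A sphere of radius r centred on the plane grid yields circles of
    radius sqrt(r^2 - dz^2) on every plane with |dz| < r.
    """
    cx, cy, cz = spec.center
    n = spec.points_per_contour
    planes: list[tuple[float, list[np.ndarray]]] = []

    # spheres/ellipsoids are sliced on the absolute z grid (multiples of
    # z_spacing), like a scanner: a shape between two planes yields nothing
    if spec.kind == "sphere":
        (r,) = spec.size[:1]
        k_lo = int(np.ceil((cz - r) / spec.z_spacing))
        k_hi = int(np.floor((cz + r) / spec.z_spacing))
        for k in range(k_lo, k_hi + 1):
            z = k * spec.z_spacing
            if abs(z - cz) >= r:
                continue
            rad = float(np.sqrt(r * r - (z - cz) ** 2))
            planes.append((z, [_circle(cx, cy, z, rad, rad, n)]))
    elif spec.kind == "ellipsoid":
        a, b, c = spec.size[:3]
        k_lo = int(np.ceil((cz - c) / spec.z_spacing))
        k_hi = int(np.floor((cz + c) / spec.z_spacing))
        for k in range(k_lo, k_hi + 1):
            z = k * spec.z_spacing
            if abs(z - cz) >= c:
                continue
            scale = float(np.sqrt(1.0 - ((z - cz) / c) ** 2))
            planes.append((z, [_circle(cx, cy, z, a * scale, b * scale, n)]))
    elif spec.kind == "box":
        sx, sy, sz = spec.size[:3]
        n_planes = max(int(round(sz / spec.z_spacing)), 1)
        z0 = cz - sz / 2 + spec.z_spacing / 2
        for i in range(n_planes):
            z = z0 + i * spec.z_spacing
            planes.append((z, [_rectangle(cx, cy, z, sx, sy, n)]))
    elif spec.kind == "tube":
        r, length = spec.size[:2]
        n_planes = max(int(round(length / spec.z_spacing)), 1)
        z0 = cz - length / 2 + spec.z_spacing / 2
        for i in range(n_planes):
            z = z0 + i * spec.z_spacing
            planes.append((z, [_circle(cx, cy, z, r, r, n)]))

    if not planes:
        raise ValueError(f"shape {spec.kind!r} intersects no z-plane")
    return ContourSet(roi_name=roi_name, planes=planes)


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------


def _deform_plane(poly: np.ndarray, magnitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth seeded radial bump about the plane centroid."""
    centroid = poly[:, :2].mean(axis=0)
    rel = poly[:, :2] - centroid
    r = np.linalg.norm(rel, axis=1)
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    lobes = int(rng.integers(2, 5))
    phase = float(rng.uniform(0, 2 * np.pi))
    bump = magnitude * np.sin(lobes * theta + phase)
    scale = np.where(r > 0, (r + bump) / np.where(r > 0, r, 1.0), 1.0)
    out = poly.copy()
    out[:, :2] = centroid + rel * scale[:, None]
    return out


def perturb(contours: ContourSet, spec: PerturbationSpec) -> ContourSet:
    """Apply a clinical-edit perturbation; ``kind='none'`` is an exact copy."""
    if spec.kind == "none":
        return copy.deepcopy(contours)

    rng = np.random.default_rng(spec.seed)
    planes: list[tuple[float, list[np.ndarray]]] = []

    if spec.kind == "translate":
        d = np.asarray(spec.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("translate direction must be non-zero")
        offset = spec.magnitude * d / norm
        for z, polys in contours.planes:
            planes.append((z + offset[2], [p + offset for p in polys]))
    elif spec.kind == "dilate":
        for z, polys in contours.planes:
            new_polys = []
            for p in polys:
                centroid = p[:, :2].mean(axis=0)
                rel = p[:, :2] - centroid
                r = np.linalg.norm(rel, axis=1)
                scale = np.where(r > 0, (r + spec.magnitude) / np.where(r > 0, r, 1.0), 1.0)
                q = p.copy()
                q[:, :2] = centroid + rel * scale[:, None]
                new_polys.append(q)
            planes.append((z, new_polys))
    elif spec.kind in ("edit_slices", "replace"):
        n_planes = len(contours.planes)
        if spec.kind == "replace":
            chosen = set(range(n_planes))
        else:
            n_edit = int(round(spec.fraction * n_planes))
            chosen = set(rng.choice(n_planes, size=n_edit, replace=False).tolist())
        for i, (z, polys) in enumerate(contours.planes):
            if i in chosen:
                planes.append((z, [_deform_plane(p, spec.magnitude, rng) for p in polys]))
            else:
                planes.append((z, [p.copy() for p in polys]))

    return ContourSet(roi_name=contours.roi_name, planes=planes)


# ---------------------------------------------------------------------------
# RTSTRUCT fixture files
# ---------------------------------------------------------------------------


def write_rtstruct_fixture(
    contour_sets: Sequence[ContourSet],
    path: str | os.PathLike,
    patient_id: str,
    export_time: dt.datetime | None = None,
    frame_of_reference_uid: str | None = None,
    label: str = "SYNTHETIC",
) -> None:
    """Write a minimal RT Structure Set file holding the given ROIs.

    UIDs are derived deterministically from the patient id and label so
    that repeated generation is byte-stable.  Coordinates round-trip
    through :func:`contourqa.rtstruct_io.read_rtstruct` to within 1e-4 mm
    (the DICOM decimal-string encoding below keeps far more digits).
    """
    if not contour_sets:
        raise ValueError("at least one ROI is required")
    export_time = export_time or dt.datetime(2024, 8, 28, 12, 0, 0)
    entropy = [patient_id, label, export_time.isoformat()]
    for_uid = frame_of_reference_uid or generate_uid(entropy_srcs=entropy + ["frame"])

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTSTRUCT_SOP_CLASS_UID
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=entropy + ["sop"])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = RTSTRUCT_SOP_CLASS_UID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.PatientID = patient_id
    ds.PatientName = patient_id
    ds.StructureSetLabel = label
    ds.StructureSetDate = export_time.strftime("%Y%m%d")
    ds.StructureSetTime = export_time.strftime("%H%M%S")
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=entropy + ["series"])
    ds.StudyInstanceUID = generate_uid(entropy_srcs=entropy + ["study"])
    ds.FrameOfReferenceUID = for_uid

    ref_frame = pydicom.Dataset()
    ref_frame.FrameOfReferenceUID = for_uid
    ds.ReferencedFrameOfReferenceSequence = [ref_frame]

    ss_rois = []
    roi_contours = []
    for num, cset in enumerate(contour_sets, start=1):
        roi = pydicom.Dataset()
        roi.ROINumber = num
        roi.ReferencedFrameOfReferenceUID = for_uid
        roi.ROIName = cset.roi_name
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ss_rois.append(roi)

        rc = pydicom.Dataset()
        rc.ReferencedROINumber = num
        contour_items = []
        for z, polys in cset.planes:
            for poly in polys:
                item = pydicom.Dataset()
                item.ContourGeometricType = "CLOSED_PLANAR"
                item.NumberOfContourPoints = poly.shape[0]
                item.ContourData = [f"{v:.6f}" for v in poly.ravel()]
                contour_items.append(item)
        rc.ContourSequence = contour_items
        roi_contours.append(rc)
    ds.StructureSetROISequence = ss_rois
    ds.ROIContourSequence = roi_contours

    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# metric time series
# ---------------------------------------------------------------------------


@dataclass
class SeriesSpec:
    """Seeded per-metric time series with injected monitoring events.

    ``baseline`` maps each metric to a distribution tuple:
    ``("normal", mu, sigma)`` or ``("exponential", scale, shift)``
    (shift + Exp(scale), right-skewed like HD95/APL in practice).
    Events are applied additively on top of the baseline draws:

    * ``outliers``: {index: {metric: offset}} single-point spikes,
    * ``shifts``: {index: {metric: offset}} persistent level changes from
      the index onward,
    * ``drifts``: {index: {metric: (step, length)}} monotone ramps.

    Values are clamped to each metric's valid range and APL is rounded to
    an integer count.
    """

    roi_name: str = "Heart"
    length: int = 60
    seed: int = 0
    start_time: dt.datetime = dt.datetime(2024, 8, 28, 8, 0, 0)
    interval_hours: float = 7.0
    baseline: Mapping[str, tuple] = field(
        default_factory=lambda: {
            "vdsc": ("normal", 0.95, 0.015),
            "sdsc3": ("normal", 0.92, 0.02),
            "hd95": ("exponential", 2.0, 0.0),
            "apl": ("exponential", 400.0, 50.0),
        }
    )
    outliers: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    shifts: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    drifts: Mapping[int, Mapping[str, tuple]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for events in (self.outliers, self.shifts, self.drifts):
            for idx in events:
                if not (0 <= idx < self.length):
                    raise ValueError(f"event index {idx} outside series length")


_RANGES = {"vdsc": (0.0, 1.0), "sdsc3": (0.0, 1.0), "hd95": (0.0, np.inf), "apl": (0.0, np.inf)}


def _draw_baseline(kind_params: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = kind_params[0]
    if kind == "normal":
        _, mu, sigma = kind_params
        return rng.normal(mu, sigma, size=n)
    if kind == "exponential":
        _, scale, shift = kind_params
        return shift + rng.exponential(scale, size=n)
    raise ValueError(f"unknown baseline distribution {kind!r}")


def make_metric_series(spec: SeriesSpec) -> list[MetricRecord]:
    """Generate an ordered, reproducible record series for one ROI."""
    rng = np.random.default_rng(spec.seed)
    n = spec.length
    values = {m: _draw_baseline(spec.baseline[m], n, rng) for m in _RANGES}

    for idx, offsets in spec.outliers.items():
        for m, off in offsets.items():
            values[m][idx] += off
    for idx, offsets in spec.shifts.items():
        for m, off in offsets.items():
            values[m][idx:] += off
    for idx, ramps in spec.drifts.items():
        for m, (step, length) in ramps.items():
            stop = min(idx + length, n)
            values[m][idx:stop] += step * np.arange(1, stop - idx + 1)

    for m, (lo, hi) in _RANGES.items():
        values[m] = np.clip(values[m], lo, hi)

    records = []
    for i in range(n):
        v, s = float(values["vdsc"][i]), float(values["sdsc3"][i])
        h, a = float(values["hd95"][i]), int(round(values["apl"][i]))
        awc = v == 1.0 and s == 1.0 and h == 0.0 and a == 0
        records.append(
            MetricRecord(
                patient_id=f"P{i:04d}",
                roi_name=spec.roi_name,
                export_time=spec.start_time + dt.timedelta(hours=spec.interval_hours * i),
                vdsc=v,
                sdsc3=s,
                hd95=h,
                apl=a,
                awc=awc,
            )
        )
    return records
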