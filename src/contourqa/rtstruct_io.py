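"""Reading DICOM RT Structure Sets and persisting comparison records.

An RT Structure Set (RTSTRUCT) stores each named region of interest (ROI)
as a stack of closed planar polygons in the patient coordinate system, in
millimetres.  A monitored segmentation workflow exports two structure sets
per patient: one written immediately after the deep-learning segmentation
(DLS) and one after clinical review and approval (CS).  Both originate from
the same scan, so their contour points live in the same frame of reference
and can be compared without the underlying image series.

This module parses structure sets into :class:`ContourSet` stacks, pairs
DLS and CS exports by ROI name, and round-trips the per-ROI comparison
results (:class:`MetricRecord`) through an append-safe CSV file.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pydicom

logger = logging.getLogger(__name__)

RTSTRUCT_SOP_CLASS_UID = "1.2.840.10008.5.1.4.1.1.481.3"

#: fixed column order of the metric-record CSV
RECORD_COLUMNS = [
    "patient_id",
    "roi_name",
    "export_time",
    "vdsc",
    "sdsc3",
    "hd95",
    "apl",
    "awc",
]

METRIC_NAMES = ("vdsc", "sdsc3", "hd95", "apl")


class RTStructReadError(ValueError):
    """Raised when a file is unreadable or is not an RT Structure Set."""


class RecordSchemaError(ValueError):
    """Raised when a persisted record table misses required columns."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ContourSet:
    """One ROI's geometry: planar polygons grouped by z-plane.

    ``planes`` is a list of ``(z, polygons)`` sorted by ascending z with
    unique z values; each polygon is an ``(n, 3)`` float array of vertices
    in mm whose z coordinates all equal the plane z (within 1e-6 mm).
    """

    roi_name: str
    planes: list[tuple[float, list[np.ndarray]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.planes = sorted(self.planes, key=lambda p: p[0])
        zs = [z for z, _ in self.planes]
        if len(set(zs)) != len(zs):
            raise ValueError(f"duplicate z-planes in ROI {self.roi_name!r}")
        for z, polys in self.planes:
            for poly in polys:
                if poly.shape[0] < 3:
                    raise ValueError("polygon with fewer than 3 vertices")
                if np.max(np.abs(poly[:, 2] - z)) > 1e-6:
                    raise ValueError(
                        f"non-planar polygon at z={z} in ROI {self.roi_name!r}"
                    )

    @property
    def n_planes(self) -> int:
        return len(self.planes)

    @property
    def n_polygons(self) -> int:
        return sum(len(p) for _, p in self.planes)

    def all_points(self) -> np.ndarray:
        """All vertices stacked into an (N, 3) array."""
        parts = [poly for _, polys in self.planes for poly in polys]
        if not parts:
            return np.empty((0, 3))
        return np.vstack(parts)

    def z_values(self) -> np.ndarray:
        return np.array([z for z, _ in self.planes])


@dataclass
class StructurePair:
    """A matched DLS/CS export of one ROI for one patient."""

    patient_id: str
    roi_name: str
    dls: ContourSet
    cs: ContourSet
    export_time: datetime


@dataclass
class MetricRecord:
    """One DLS-vs-CS comparison: the four geometric metrics plus identity.

    ``awc`` (accepted without correction) is true iff the clinical contour
    is voxel-identical to the automatic one, which forces the identity
    metric values (1, 1, 0, 0).
    """

    patient_id: str
    roi_name: str
    export_time: datetime
    vdsc: float
    sdsc3: float
    hd95: float
    apl: int
    awc: bool

    def __post_init__(self) -> None:
        for name in METRIC_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.hd95 < 0 or self.apl < 0:
            raise ValueError("hd95 and apl must be non-negative")
        if self.awc and not (
            self.vdsc == 1.0 and self.sdsc3 == 1.0 and self.hd95 == 0.0 and self.apl == 0
        ):
            raise ValueError("awc=True requires identity metric values (1,1,0,0)")


@dataclass
class PairingResult:
    """Matched pairs plus the ROI names left unmatched on either side."""

    pairs: list[StructurePair]
    unpaired_dls: list[str]
    unpaired_cs: list[str]


# ---------------------------------------------------------------------------
# RTSTRUCT parsing
# ---------------------------------------------------------------------------


def _contour_items(ds: pydicom.Dataset):
    """Yield (roi_number -> name, roi_number -> contour items) mappings."""
    names = {}
    for item in ds.get("StructureSetROISequence", []):
        names[int(item.ROINumber)] = str(item.ROIName)
    contours: dict[int, list] = {}
    for roi_item in ds.get("ROIContourSequence", []):
        num = int(roi_item.ReferencedROINumber)
        contours[num] = list(roi_item.get("ContourSequence", []))
    return names, contours


def read_rtstruct(path: str | os.PathLike) -> list[ContourSet]:
    """Parse an RT Structure Set file into one :class:`ContourSet` per ROI.

    Coordinates are taken verbatim (mm, patient coordinate system).
    Contour items that are not closed planar, have fewer than three points,
    or are non-planar are skipped with a warning; ROIs with no usable
    contour are omitted entirely.

    Raises
    ------
    RTStructReadError
        If the file cannot be read as DICOM or is not an RTSTRUCT.
    """
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # pydicom raises several error types
        raise RTStructReadError(f"cannot read DICOM file {path}: {exc}") from exc

    modality = getattr(ds, "Modality", None)
    sop_class = str(getattr(ds, "SOPClassUID", ""))
    if modality != "RTSTRUCT" and sop_class != RTSTRUCT_SOP_CLASS_UID:
        raise RTStructReadError(
            f"{path} is not an RT Structure Set (modality={modality!r})"
        )
    if not getattr(ds, "FrameOfReferenceUID", None) and not ds.get(
        "ReferencedFrameOfReferenceSequence"
    ):
        logger.warning(
            "%s has no frame-of-reference UID; pairing proceeds by patient/ROI name",
            path,
        )

    names, contours = _contour_items(ds)
    result = []
    for num, name in names.items():
        planes: dict[float, list[np.ndarray]] = {}
        for item in contours.get(num, []):
            gtype = str(getattr(item, "ContourGeometricType", "CLOSED_PLANAR"))
            if gtype != "CLOSED_PLANAR":
                logger.warning(
                    "ROI %r: skipping contour of geometric type %s", name, gtype
                )
                continue
            data = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
            if data.shape[0] < 3:
                logger.warning("ROI %r: skipping degenerate contour (<3 points)", name)
                continue
            z = float(data[0, 2])
            if np.max(np.abs(data[:, 2] - z)) > 1e-6:
                logger.warning("ROI %r: skipping non-planar contour", name)
                continue
            planes.setdefault(round(z, 6), []).append(data)
        if planes:
            result.append(
                ContourSet(roi_name=name, planes=[(z, p) for z, p in planes.items()])
            )
        else:
            logger.warning("ROI %r has no usable contours; omitted", name)
    return result


def read_export_time(path: str | os.PathLike) -> datetime:
    """Export timestamp of a structure set.

    Uses the StructureSetDate/StructureSetTime tags when present, else
    falls back to the file's modification time (the series must be
    orderable for monitoring).
    """
    ds = pydicom.dcmread(str(path), stop_before_pixels=True)
    date = str(getattr(ds, "StructureSetDate", "") or "")
    time = str(getattr(ds, "StructureSetTime", "") or "000000")
    if date:
        time = time.split(".")[0].ljust(6, "0")
        return datetime.strptime(date + time, "%Y%m%d%H%M%S")
    return datetime.fromtimestamp(os.path.getmtime(path))


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------


def _canonical(name: str, aliases: Mapping[str, str] | None) -> str:
    key = name.strip().lower()
    if aliases:
        # alias map entries are matched case-insensitively as well
        lowered = {k.strip().lower(): v.strip().lower() for k, v in aliases.items()}
        key = lowered.get(key, key)
    return key


def pair_structures(
    dls_sets: Iterable[ContourSet],
    cs_sets: Iterable[ContourSet],
    patient_id: str,
    export_time: datetime,
    aliases: Mapping[str, str] | None = None,
) -> PairingResult:
    """Match DLS and CS contour sets of one patient by ROI name.

    Matching is case-insensitive and whitespace-trimmed; an optional alias
    map folds known renamings onto a canonical name.  ROIs present in only
    one export are reported unpaired (and logged), never guessed.
    """
    dls_by = {_canonical(c.roi_name, aliases): c for c in dls_sets}
    cs_by = {_canonical(c.roi_name, aliases): c for c in cs_sets}
    common = sorted(set(dls_by) & set(cs_by))
    pairs = [
        StructurePair(
            patient_id=patient_id,
            roi_name=dls_by[k].roi_name,
            dls=dls_by[k],
            cs=cs_by[k],
            export_time=export_time,
        )
        for k in common
    ]
    unpaired_dls = sorted(dls_by[k].roi_name for k in set(dls_by) - set(cs_by))
    unpaired_cs = sorted(cs_by[k].roi_name for k in set(cs_by) - set(dls_by))
    for name in unpaired_dls:
        logger.warning("patient %s: DLS ROI %r has no CS counterpart", patient_id, name)
    for name in unpaired_cs:
        logger.warning("patient %s: CS ROI %r has no DLS counterpart", patient_id, name)
    if not pairs:
        logger.warning("patient %s: no ROI names in common", patient_id)
    return PairingResult(pairs=pairs, unpaired_dls=unpaired_dls, unpaired_cs=unpaired_cs)


# ---------------------------------------------------------------------------
# record persistence
# ---------------------------------------------------------------------------


def records_to_frame(records: Sequence[MetricRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "roi_name": r.roi_name,
            "export_time": r.export_time.isoformat(),
            "vdsc": r.vdsc,
            "sdsc3": r.sdsc3,
            "hd95": r.hd95,
            "apl": int(r.apl),
            "awc": bool(r.awc),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[MetricRecord]:
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise RecordSchemaError(f"record table is missing columns: {missing}")
    records = [
        MetricRecord(
            patient_id=str(row.patient_id),
            roi_name=str(row.roi_name),
            export_time=datetime.fromisoformat(str(row.export_time)),
            vdsc=float(row.vdsc),
            sdsc3=float(row.sdsc3),
            hd95=float(row.hd95),
            apl=int(row.apl),
            awc=_parse_bool(row.awc),
        )
        for row in df.itertuples(index=False)
    ]
    records.sort(key=lambda r: (r.export_time, r.patient_id, r.roi_name))
    return records


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("true", "1")


def write_records(
    records: Sequence[MetricRecord], path: str | os.PathLike, append: bool = False
) -> None:
    """Write comparison records to CSV (fixed column order, ISO timestamps).

    With ``append=True`` records are added below an existing file without
    rewriting it; the header is written only once.
    """
    df = records_to_frame(records)
    path = Path(path)
    if append and path.exists():
        df.to_csv(path, mode="a", header=False, index=False)
    else:
        df.to_csv(path, index=False)


def read_records(path: str | os.PathLike) -> list[MetricRecord]:
    """Read records back, ordered by export time."""
    df = pd.read_csv(path, dtype={"patient_id": str, "roi_name": str, "export_time": str})
    return frame_to_records(df)
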