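"""Voxelisation and geometric comparison metrics for contour pairs.

The clinical workflow compares the automatic (DLS) and approved (CS)
contour of each ROI with four metrics:

* **VDSC** — volumetric Dice similarity coefficient, ``2|A∩B|/(|A|+|B|)``
  on voxel volumes.
* **SDSC** — surface Dice similarity coefficient at a distance tolerance
  (3 mm by default): the fraction of the two discrete surfaces lying
  within the tolerance of each other.
* **HD95** — 95th-percentile Hausdorff distance over the pooled set of
  directed surface distances, in mm.
* **APL** — added path length: the number of in-plane boundary voxels of
  the clinical contour that the automatic contour's boundary does not
  share; a proxy for the length of contour the clinician re-drew.

Both contours of a pair are rasterised onto one shared regular grid.  The
structure-set export carries no grid (the scan is not needed), so a grid
convention is imposed here: 1 mm in-plane spacing by default, slice
spacing equal to the modal contour-plane spacing, and voxel centres offset
half a voxel from the joint bounding box so that contour edges drawn at
round coordinates never coincide with voxel centres.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .rtstruct_io import ContourSet, MetricRecord, StructurePair

logger = logging.getLogger(__name__)

DEFAULT_SDSC_TOL_MM = 3.0
DEFAULT_HD_PERCENTILE = 95.0


class GridError(ValueError):
    """Raised when a grid cannot be built or does not cover the contours."""


@dataclass(frozen=True)
class GridSpec:
    """Regular 3-D grid: ``origin`` is the centre of voxel (0,0,0), mm."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise GridError("grid spacing must be strictly positive")
        if any(n < 1 for n in self.shape):
            raise GridError("grid shape must be at least 1 voxel per axis")

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def z_index(self, z: float) -> int:
        """Slice index for a contour plane; must land within dz/2 of a slice."""
        dz = self.spacing[2]
        k = int(round((z - self.origin[2]) / dz))
        if not (0 <= k < self.shape[2]) or abs(z - (self.origin[2] + k * dz)) > dz / 2:
            raise GridError(f"contour plane z={z} falls outside the grid")
        return k


@dataclass
class VoxelMask:
    """Binary occupancy of one contour set on a :class:`GridSpec`."""

    grid: GridSpec
    occupancy: np.ndarray  # bool, shape (nx, ny, nz)

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != self.grid.shape:
            raise GridError("occupancy shape does not match grid shape")

    @property
    def n_voxels(self) -> int:
        return int(self.occupancy.sum())


@dataclass
class SurfaceSet:
    """Boundary voxels of a mask: mm centre coordinates plus slice index."""

    coords_mm: np.ndarray  # (n, 3)
    slice_index: np.ndarray  # (n,)

    def __len__(self) -> int:
        return self.coords_mm.shape[0]


# ---------------------------------------------------------------------------
# grid construction and rasterisation
# ---------------------------------------------------------------------------


def _modal_z_spacing(contour_sets: Sequence[ContourSet]) -> float:
    diffs: list[float] = []
    for cs in contour_sets:
        zs = cs.z_values()
        if len(zs) > 1:
            diffs.extend(np.round(np.diff(zs), 6))
    if not diffs:
        return 0.0
    return float(Counter(diffs).most_common(1)[0][0])


def build_grid(
    a: ContourSet,
    b: ContourSet,
    in_plane_spacing_mm: float = 1.0,
    margin_mm: float | None = None,
    sdsc_tol_mm: float = DEFAULT_SDSC_TOL_MM,
) -> GridSpec:
    """Common grid covering both contour sets plus a margin.

    The margin defaults to the surface-Dice tolerance plus two in-plane
    voxels, so surface-distance queries never clip.  dz equals the modal
    contour-plane spacing of the two stacks and the z levels are aligned
    with the contour planes.
    """
    pts = np.vstack([a.all_points(), b.all_points()])
    if pts.size == 0:
        raise GridError("cannot build a grid from empty contour sets")
    if margin_mm is None:
        margin_mm = sdsc_tol_mm + 2 * in_plane_spacing_mm
    dx = dy = float(in_plane_spacing_mm)
    dz = _modal_z_spacing([a, b])
    if dz <= 0:
        dz = dx  # single-plane structures: fall back to in-plane spacing

    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    # half-voxel offset keeps centres off contour edges drawn at round mm
    ox = lo[0] - margin_mm + dx / 2
    oy = lo[1] - margin_mm + dy / 2
    nx = int(np.ceil((hi[0] + margin_mm - ox) / dx)) + 1
    ny = int(np.ceil((hi[1] + margin_mm - oy) / dy)) + 1

    all_z = np.unique(np.concatenate([a.z_values(), b.z_values()]))
    extra = int(np.ceil(margin_mm / dz))
    oz = float(all_z.min() - extra * dz)
    nz = int(round((all_z.max() - oz) / dz)) + 1 + extra
    return GridSpec(origin=(ox, oy, float(oz)), spacing=(dx, dy, float(dz)), shape=(nx, ny, nz))


def rasterize(contours: ContourSet, grid: GridSpec) -> VoxelMask:
    """Fill voxel centres lying inside an odd number of a plane's polygons.

    The even-odd rule makes a nested contour a hole, which is how paired
    or annular structures are stored in structure sets.  Containment is
    strict: a centre exactly on a polygon edge is not occupied.
    """
    occ = np.zeros(grid.shape, dtype=bool)
    xs = grid.axis_centers(0)
    ys = grid.axis_centers(1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    flat_x = gx.ravel()
    flat_y = gy.ravel()
    for z, polys in contours.planes:
        k = grid.z_index(z)
        inside = np.zeros(flat_x.shape, dtype=bool)
        for poly in polys:
            shp = Polygon(poly[:, :2])
            inside ^= shapely.contains_xy(shp, flat_x, flat_y)
        occ[:, :, k] |= inside.reshape(gx.shape)
    return VoxelMask(grid=grid, occupancy=occ)


# ---------------------------------------------------------------------------
# surfaces and metrics
# ---------------------------------------------------------------------------

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def _require_same_grid(a: VoxelMask, b: VoxelMask) -> None:
    if a.grid != b.grid:
        raise GridError("masks must share an identical grid")


def extract_surface(m: VoxelMask) -> SurfaceSet:
    """Occupied voxels with at least one unoccupied 6-neighbour.

    Out-of-grid neighbours count as unoccupied, so voxels on the grid face
    are surface.
    """
    if m.n_voxels == 0:
        raise GridError("cannot extract the surface of an empty mask")
    interior = ndimage.binary_erosion(m.occupancy, structure=_STRUCT_6, border_value=0)
    surface = m.occupancy & ~interior
    idx = np.argwhere(surface)
    coords = np.asarray(m.grid.origin) + idx * np.asarray(m.grid.spacing)
    return SurfaceSet(coords_mm=coords, slice_index=idx[:, 2])


def vdsc(a: VoxelMask, b: VoxelMask) -> float:
    """Volumetric Dice similarity coefficient, in [0, 1]."""
    _require_same_grid(a, b)
    inter = int(np.count_nonzero(a.occupancy & b.occupancy))
    total = a.n_voxels + b.n_voxels
    if total == 0:
        raise GridError("both masks are empty")
    return 2.0 * inter / total


def _directed_distances(a: SurfaceSet, b: SurfaceSet) -> np.ndarray:
    tree = cKDTree(b.coords_mm)
    d, _ = tree.query(a.coords_mm, k=1)
    return np.asarray(d, dtype=float)


def sdsc(a: VoxelMask, b: VoxelMask, tol_mm: float = DEFAULT_SDSC_TOL_MM) -> float:
    """Surface Dice similarity coefficient at a mm tolerance.

    Surface elements are boundary voxels with equal weight; the score is
    the fraction of all surface voxels (of both masks pooled) whose
    Euclidean centre-to-centre distance to the other surface is within the
    tolerance.
    """
    if tol_mm < 0:
        raise ValueError("sdsc tolerance must be non-negative")
    _require_same_grid(a, b)
    sa, sb = extract_surface(a), extract_surface(b)
    da = _directed_distances(sa, sb)
    db = _directed_distances(sb, sa)
    hits = int(np.count_nonzero(da <= tol_mm)) + int(np.count_nonzero(db <= tol_mm))
    return hits / (len(sa) + len(sb))


def hd95(a: VoxelMask, b: VoxelMask, percentile: float = DEFAULT_HD_PERCENTILE) -> float:
    """Percentile Hausdorff distance (mm), pooled symmetric variant.

    The directed surface distances of both directions are pooled and the
    percentile (linear interpolation) is taken over the combined set.
    """
    _require_same_grid(a, b)
    sa, sb = extract_surface(a), extract_surface(b)
    pooled = np.concatenate([_directed_distances(sa, sb), _directed_distances(sb, sa)])
    return float(np.percentile(pooled, percentile))


def _slice_boundary_2d(occ: np.ndarray) -> np.ndarray:
    """In-plane (4-connectivity) boundary of one 2-D slice."""
    if not occ.any():
        return np.zeros_like(occ)
    interior = ndimage.binary_erosion(
        occ, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return occ & ~interior


def apl(dls: VoxelMask, cs: VoxelMask, tol_mm: float = 0.0) -> int:
    """Added path length in voxels: CS boundary not shared with the DLS.

    Evaluated slice by slice with 2-D in-plane boundaries, matching how
    contours are edited plane by plane.  With the default zero tolerance a
    CS boundary voxel counts unless the DLS boundary occupies the very
    same voxel; a positive tolerance instead requires the nearest DLS
    boundary voxel of the slice to be farther than ``tol_mm`` away.
    Asymmetric by construction: the DLS is the reference being corrected.
    """
    _require_same_grid(dls, cs)
    dx, dy, _ = dls.grid.spacing
    total = 0
    for k in range(cs.grid.shape[2]):
        cs_b = _slice_boundary_2d(cs.occupancy[:, :, k])
        if not cs_b.any():
            continue
        dls_b = _slice_boundary_2d(dls.occupancy[:, :, k])
        if tol_mm <= 0:
            total += int(np.count_nonzero(cs_b & ~dls_b))
        elif not dls_b.any():
            total += int(np.count_nonzero(cs_b))
        else:
            cs_pts = np.argwhere(cs_b) * np.array([dx, dy])
            dls_pts = np.argwhere(dls_b) * np.array([dx, dy])
            d, _ = cKDTree(dls_pts).query(cs_pts, k=1)
            total += int(np.count_nonzero(d > tol_mm))
    return total


# ---------------------------------------------------------------------------
# pair evaluation and cohort summary
# ---------------------------------------------------------------------------


def evaluate_pair(
    pair: StructurePair,
    in_plane_spacing_mm: float = 1.0,
    sdsc_tol_mm: float = DEFAULT_SDSC_TOL_MM,
    apl_tol_mm: float = 0.0,
    hd_percentile: float = DEFAULT_HD_PERCENTILE,
) -> MetricRecord | None:
    """Rasterise a DLS/CS pair on a shared grid and compute all metrics.

    ``awc`` is true iff the two occupancy arrays are identical, in which
    case the metrics are the identity values by construction.  Returns
    ``None`` (with a warning) when either mask is empty after
    rasterisation.
    """
    grid = build_grid(
        pair.dls, pair.cs, in_plane_spacing_mm=in_plane_spacing_mm, sdsc_tol_mm=sdsc_tol_mm
    )
    m_dls = rasterize(pair.dls, grid)
    m_cs = rasterize(pair.cs, grid)
    if m_dls.n_voxels == 0 or m_cs.n_voxels == 0:
        logger.warning(
            "patient %s ROI %r: empty mask after rasterisation, record skipped",
            pair.patient_id,
            pair.roi_name,
        )
        return None
    identical = bool(np.array_equal(m_dls.occupancy, m_cs.occupancy))
    if identical:
        v, s, h, a = 1.0, 1.0, 0.0, 0
    else:
        v = vdsc(m_dls, m_cs)
        s = sdsc(m_dls, m_cs, tol_mm=sdsc_tol_mm)
        h = hd95(m_dls, m_cs, percentile=hd_percentile)
        a = apl(m_dls, m_cs, tol_mm=apl_tol_mm)
    return MetricRecord(
        patient_id=pair.patient_id,
        roi_name=pair.roi_name,
        export_time=pair.export_time,
        vdsc=v,
        sdsc3=s,
        hd95=h,
        apl=a,
        awc=identical,
    )


def summarize_roi(records: Sequence[MetricRecord]) -> dict:
    """Cohort summary row for one ROI: N, %AWC, median/IQR/min/max per metric."""
    if not records:
        raise ValueError("summarize_roi requires at least one record")
    out: dict = {
        "roi_name": records[0].roi_name,
        "n": len(records),
        "pct_awc": 100.0 * sum(r.awc for r in records) / len(records),
    }
    for name in ("vdsc", "sdsc3", "hd95", "apl"):
        vals = np.array([getattr(r, name) for r in records], dtype=float)
        q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        out[f"{name}_median"] = float(q50)
        out[f"{name}_iqr"] = float(q75 - q25)
        out[f"{name}_min"] = float(vals.min())
        out[f"{name}_max"] = float(vals.max())
    return out
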