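"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths of the package: containment is a
hand-written even-odd ray crossing, surface distances are all-pairs
``cdist`` minima, percentiles are computed from the sorted sample by the
linear-interpolation formula, and the moving-average window is built by
sorting indices by distance.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def point_in_polygon_evenodd(x: float, y: float, poly_xy: np.ndarray) -> bool:
    """Even-odd ray-crossing test, boundary points counted as outside."""
    inside = False
    n = len(poly_xy)
    for i in range(n):
        x0, y0 = poly_xy[i]
        x1, y1 = poly_xy[(i + 1) % n]
        if (y0 > y) != (y1 > y):
            xc = x0 + (y - y0) * (x1 - x0) / (y1 - y0)
            if x < xc:
                inside = not inside
    return inside


def rasterize_oracle(contours, grid) -> np.ndarray:
    """Loop-based even-odd rasterisation at every voxel centre."""
    occ = np.zeros(grid.shape, dtype=bool)
    xs = grid.axis_centers(0)
    ys = grid.axis_centers(1)
    for z, polys in contours.planes:
        k = grid.z_index(z)
        for ix, x in enumerate(xs):
            for iy, y in enumerate(ys):
                count = sum(
                    point_in_polygon_evenodd(x, y, p[:, :2]) for p in polys
                )
                occ[ix, iy, k] = count % 2 == 1
    return occ


def surface_voxels_oracle(occ: np.ndarray) -> np.ndarray:
    """Boolean surface map by explicit 6-neighbour enumeration."""
    nx, ny, nz = occ.shape
    surf = np.zeros_like(occ)
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not occ[i, j, k]:
                    continue
                for di, dj, dk in offsets:
                    a, b, c = i + di, j + dj, k + dk
                    if not (0 <= a < nx and 0 <= b < ny and 0 <= c < nz) or not occ[a, b, c]:
                        surf[i, j, k] = True
                        break
    return surf


def surface_coords_mm(occ: np.ndarray, grid) -> np.ndarray:
    idx = np.argwhere(surface_voxels_oracle(occ))
    return np.asarray(grid.origin) + idx * np.asarray(grid.spacing)


def sdsc_oracle(occ_a, occ_b, grid, tol: float) -> float:
    """All-pairs distance matrix version of the surface Dice score."""
    sa = surface_coords_mm(occ_a, grid)
    sb = surface_coords_mm(occ_b, grid)
    d = cdist(sa, sb)
    hits = int(np.count_nonzero(d.min(axis=1) <= tol))
    hits += int(np.count_nonzero(d.min(axis=0) <= tol))
    return hits / (len(sa) + len(sb))


def hd95_oracle(occ_a, occ_b, grid, percentile: float = 95.0) -> float:
    sa = surface_coords_mm(occ_a, grid)
    sb = surface_coords_mm(occ_b, grid)
    d = cdist(sa, sb)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(percentile_oracle(pooled, percentile))


def vdsc_oracle(occ_a, occ_b) -> float:
    return 2.0 * np.count_nonzero(occ_a & occ_b) / (
        np.count_nonzero(occ_a) + np.count_nonzero(occ_b)
    )


def boundary_2d_oracle(slice_occ: np.ndarray) -> np.ndarray:
    """4-neighbour in-plane boundary by enumeration."""
    nx, ny = slice_occ.shape
    out = np.zeros_like(slice_occ)
    for i in range(nx):
        for j in range(ny):
            if not slice_occ[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                a, b = i + di, j + dj
                if not (0 <= a < nx and 0 <= b < ny) or not slice_occ[a, b]:
                    out[i, j] = True
                    break
    return out


def apl_oracle(occ_dls: np.ndarray, occ_cs: np.ndarray) -> int:
    """Per-slice set difference of 2-D boundary voxel sets (zero tolerance)."""
    total = 0
    for k in range(occ_cs.shape[2]):
        cs_b = boundary_2d_oracle(occ_cs[:, :, k])
        dls_b = boundary_2d_oracle(occ_dls[:, :, k])
        total += int(np.count_nonzero(cs_b & ~dls_b))
    return total


def percentile_oracle(values, q: float) -> float:
    """Linear-interpolation percentile from the sorted sample."""
    x = np.sort(np.asarray(values, dtype=float))
    if len(x) == 1:
        return float(x[0])
    pos = (len(x) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(x[lo] * (1 - frac) + x[hi] * frac)


def moving_average_oracle(values, k: int) -> np.ndarray:
    """Nearest-k window by sorting indices by (distance, index)."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        order = sorted(range(n), key=lambda j: (abs(j - i), j))
        out[i] = x[order[: min(k, n)]].mean()
    return out
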