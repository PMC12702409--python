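import datetime as dt

import numpy as np
import pytest

from contourqa.geometry import GridSpec, VoxelMask
from contourqa.rtstruct_io import StructurePair
from contourqa.synth import PerturbationSpec, ShapeSpec, make_contours, perturb

EXPORT_T0 = dt.datetime(2024, 8, 28, 12, 0, 0)


def random_mask_pair(rng: np.random.Generator, max_extent: int = 18):
    """Two random non-empty masks (unions of ellipsoids) on one shared grid."""
    shape = tuple(int(rng.integers(8, max_extent + 1)) for _ in range(3))
    grid = GridSpec(origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0), shape=shape)
    idx = np.indices(shape)

    def rand_occ() -> np.ndarray:
        occ = np.zeros(shape, dtype=bool)
        for _ in range(int(rng.integers(1, 4))):
            c = rng.uniform(0, np.array(shape))
            r = rng.uniform(1.5, max(shape) / 2, size=3)
            occ |= (
                ((idx[0] - c[0]) / r[0]) ** 2
                + ((idx[1] - c[1]) / r[1]) ** 2
                + ((idx[2] - c[2]) / r[2]) ** 2
            ) <= 1.0
        if not occ.any():
            occ[shape[0] // 2, shape[1] // 2, shape[2] // 2] = True
        return occ

    return VoxelMask(grid, rand_occ()), VoxelMask(grid, rand_occ())


def cube_mask(grid: GridSpec, lo, hi) -> VoxelMask:
    occ = np.zeros(grid.shape, dtype=bool)
    occ[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return VoxelMask(grid, occ)


def make_pair(dls, cs, patient_id="P0001", roi=None, when=EXPORT_T0) -> StructurePair:
    return StructurePair(
        patient_id=patient_id,
        roi_name=roi or dls.roi_name,
        dls=dls,
        cs=cs,
        export_time=when,
    )


@pytest.fixture
def sphere_contours():
    return make_contours(
        ShapeSpec(kind="sphere", size=(12.0,), z_spacing=2.0), roi_name="Heart"
    )


@pytest.fixture
def identity_pair(sphere_contours):
    cs = perturb(sphere_contours, PerturbationSpec(kind="none"))
    return make_pair(sphere_contours, cs)
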