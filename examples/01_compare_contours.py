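"""Compare an automatic contour with an edited version of itself.

Builds a spherical "heart" contour stack, applies a 2 mm translation as a
stand-in for a clinical edit, and computes the four comparison metrics.
"""

import datetime as dt

from contourqa import (
    PerturbationSpec,
    ShapeSpec,
    StructurePair,
    evaluate_pair,
    make_contours,
    perturb,
)

dls = make_contours(ShapeSpec(kind="sphere", size=(12.0,), z_spacing=2.0), roi_name="Heart")
cs = perturb(dls, PerturbationSpec(kind="translate", magnitude=2.0))
pair = StructurePair("DEMO01", "Heart", dls, cs, dt.datetime(2024, 8, 28, 12, 0))

rec = evaluate_pair(pair)
print(f"VDSC   = {rec.vdsc:.3f}   (volume overlap, 1 = identical)")
print(f"SDSC3  = {rec.sdsc3:.3f}   (surface agreement within 3 mm)")
print(f"HD95   = {rec.hd95:.1f} mm (robust worst-case surface separation)")
print(f"APL    = {rec.apl} voxels (boundary the clinician re-drew)")
print(f"AWC    = {rec.awc}    (accepted without correction?)")

# An untouched contour scores the identity values:
rec0 = evaluate_pair(
    StructurePair("DEMO01", "Heart", dls, perturb(dls, PerturbationSpec(kind="none")),
                  dt.datetime(2024, 8, 28, 12, 0))
)
print(f"\nunchanged copy -> VDSC={rec0.vdsc}, SDSC3={rec0.sdsc3}, "
      f"HD95={rec0.hd95}, APL={rec0.apl}, AWC={rec0.awc}")
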