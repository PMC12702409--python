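"""End-to-end monitoring run on a synthetic DLS/CS cohort.

Writes 16 patients of paired structure-set files, evaluates every pair
into metric records, freezes SPC parameters, screens the ROI history with
the adapted Nelson rules, and emits control-chart CSVs — the same stages
the ``contourqa`` command line exposes as evaluate / fit / monitor /
chart.
"""

import datetime as dt
import tempfile
from pathlib import Path

import numpy as np

from contourqa import (
    PerturbationSpec,
    ShapeSpec,
    evaluate_files,
    fit_parameters,
    freeze_parameters,
    make_contours,
    perturb,
    run_pipeline,
    write_rtstruct_fixture,
)

rng = np.random.default_rng(42)
t0 = dt.datetime(2024, 8, 28, 8, 0)
kinds = ["none", "translate", "dilate", "edit_slices"]

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp)
    (root / "dls").mkdir()
    (root / "cs").mkdir()
    for i in range(16):
        pid = f"SYN{i:04d}"
        dls = make_contours(
            ShapeSpec(kind="sphere", size=(float(rng.uniform(8, 13)),), z_spacing=2.0),
            roi_name="Heart",
        )
        kind = kinds[i % 4]
        cs = perturb(dls, PerturbationSpec(
            kind=kind, magnitude=0.0 if kind == "none" else float(rng.uniform(1, 3)),
            fraction=0.3 if kind == "edit_slices" else 0.0, seed=i))
        when = t0 + dt.timedelta(hours=7 * i)
        write_rtstruct_fixture([dls], root / "dls" / f"{pid}.dcm", pid,
                               export_time=when, label="DLS")
        write_rtstruct_fixture([cs], root / "cs" / f"{pid}.dcm", pid,
                               export_time=when, label="CS")

    pairs = [(str(p), str(root / "cs" / p.name))
             for p in sorted((root / "dls").glob("*.dcm"))]
    out = root / "monitoring"
    out.mkdir()

    records = evaluate_files(pairs, out / "records.csv")
    print(f"evaluated {len(records)} DLS/CS pairs; "
          f"{sum(r.awc for r in records)} accepted without correction")

    params = fit_parameters(records)
    freeze_parameters(params, out / "params.json")
    for p in params:
        print(f"  {p.metric:6s} branch={p.branch:14s} "
              f"target={p.target:8.2f} limits=[{p.lcl:.2f}, {p.ucl:.2f}]")

    result = run_pipeline(pairs, out, params_path=out / "params.json")
    print(f"monitoring: {result['n_alarms']} alarms, "
          f"{len(result['charts'])} control-chart CSVs written")
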