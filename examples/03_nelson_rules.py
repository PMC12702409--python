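"""Detect an outlier, a trend shift and a trend drift in a metric series.

Generates a 60-export series for one ROI with three injected events and
screens it with the adapted Nelson rules: rule 1 needs three of the four
metrics outside their control limits at once, rule 2 needs nine
consecutive points on one side of the target band, rule 3 needs six
consecutive strictly monotone points.
"""

from contourqa import SeriesSpec, fit_parameters, make_metric_series, monitor_records

spec = SeriesSpec(
    roi_name="Heart",
    length=60,
    seed=7,
    outliers={20: {"vdsc": -0.4, "sdsc3": -0.4, "apl": 6000}},  # heavy edit
    shifts={35: {"hd95": 12.0}},                                 # sustained change
    drifts={47: {"apl": (900.0, 7)}},                            # growing edits
)
records = make_metric_series(spec)

# freeze limits on the clean stretch before the first event
params = fit_parameters(records[:20])
alarms = monitor_records(records, params)

for a in alarms:
    print(f"rule {a.rule}: {a.roi_name:6s} {','.join(a.metrics):18s} "
          f"{a.direction:18s} points {a.index_start}-{a.index_end}")
print(f"\n{len(alarms)} alarms; rule 1 = outlier, rule 2 = trend shift, "
      "rule 3 = trend drift")
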