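"""Simulate list-mode alpha detections and recover the activity map.

Builds a small known Ac-225 activity map (tens of mBq per 26.5 um pixel),
simulates a 60-hour list-mode acquisition through the camera's sensitivity
factor f = 1.77, bins the events into pixels, and applies the decay-exact
conversion back to Becquerel at reference time 0.
"""

import numpy as np

from alphaqar import (
    AC225,
    ActivityImage,
    AcquisitionSchedule,
    activity_at_reference,
    bin_events,
    simulate_listmode,
)

rng = np.random.default_rng(0)
truth = ActivityImage(rng.uniform(0.02, 0.08, (16, 16)), pixel_spacing=26.5, isotope=AC225)
schedule = AcquisitionSchedule.from_pairs([(0.0, 60 * 3600.0)])

events = simulate_listmode(truth, f=1.77, schedule=schedule, seed=1)
counts = bin_events(events, pixel_spacing=26.5, grid_shape=truth.activity.shape)
recovered = activity_at_reference(counts, f=1.77, isotope=AC225, schedule=schedule)

rel_err = np.abs(recovered.activity - truth.activity) / truth.activity
print(f"simulated events : {len(events)}")
print(f"true total       : {truth.total_bq:.4f} Bq")
print(f"recovered total  : {recovered.total_bq:.4f} Bq")
print(f"median pixel err : {np.median(rel_err) * 100:.2f} %")
# The per-pixel error is pure Poisson counting noise: with ~10^4 counts per
# pixel the expected relative error is ~1%, and totals agree to ~0.1%.
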