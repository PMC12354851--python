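"""Fit the camera sensitivity factor from a dilution series.

Emulates the device calibration: dried dots of known Ac-225 activity spanning
three orders of magnitude, imaged for 82 hours. The sensitivity factor f
(detected events per primary decay) is fitted by regression through the
origin of measured counts onto primary decays; the detector efficiency
follows as f / (0.5 x 4 alphas).
"""

import numpy as np

from alphaqar import AC225, AcquisitionSchedule, CalibrationSample, fit_sensitivity
from alphaqar.quantify import decay_weight

TRUE_F = 1.77
schedule = AcquisitionSchedule.from_pairs([(0.0, 82 * 3600.0)])
rng = np.random.default_rng(7)

samples = []
for activity_bq in (0.05, 0.2, 1.0, 5.0, 20.0):
    primaries = (activity_bq / AC225.decay_constant) * decay_weight(schedule, AC225)
    counts = rng.poisson(TRUE_F * primaries)  # Poisson counting noise
    samples.append(CalibrationSample(activity_bq, counts, schedule))

result = fit_sensitivity(samples, AC225)
print(f"fitted f            : {result.sensitivity_factor:.4f}  (true {TRUE_F})")
print(f"detector efficiency : {result.detector_efficiency * 100:.1f} %")
print(f"R^2                 : {result.r_squared:.6f}")
# With counts spanning ~10^3..10^6 the fit recovers f to a fraction of a
# percent; efficiency near 88.5% means the scintillator detects almost every
# alpha that reaches it from the 2-pi half-space.
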