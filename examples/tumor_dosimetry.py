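"""3D reconstruction and microscale dosimetry of a synthetic tumor stack.

Generates three serial tumor sections (28 um apart) with known misalignments
and sparse hot-spot activity, stacks them with the anatomy-guided strategy,
convolves the 3D activity with a Monte Carlo Ac-225 dose-voxel kernel, and
summarizes the dose-rate field as a cumulative dose-volume histogram.
"""

import numpy as np

from alphaqar import (
    AC225,
    ActivityVolume,
    TumorStackSpec,
    cumulative_dvh,
    dice,
    dose_rate_map,
    generate_dvk,
    generate_tumor_stack,
    stack_sections,
)
from alphaqar.coreg import Section
from alphaqar.segmentation import largest_component_mask

spec = TumorStackSpec(seed=4, warp_amplitude_um=40.0, image_shape=(128, 128))
raw, _truth = generate_tumor_stack(spec)
sections = [
    Section(s["activity"], s["anatomy"], s["pixel_spacing_um"], s["pixel_spacing_um"],
            s["landmarks"], s["landmarks"])
    for s in raw
]

stack = stack_sections(sections, "anatomy_guided")
masks = [largest_component_mask(a) for a in stack.anatomy]
pair_dice = [dice(masks[i], masks[i + 1]) for i in range(len(masks) - 1)]
print(f"adjacent-section Dice after stacking: {['%.3f' % d for d in pair_dice]}")

kernel = generate_dvk(AC225, voxel_dims_um=(28.0, 26.5, 26.5), n_primaries=100_000, seed=4)
volume = ActivityVolume(np.stack(stack.activity), stack.z_positions, 26.5)
rate = dose_rate_map(volume, kernel)
# dense threshold grid: the strongly non-uniform field concentrates most of
# the DVH's structure far below the peak
dvh = cumulative_dvh(rate, mask=np.stack(masks), n_thresholds=2000)

peak = float(rate.dose_rate[np.stack(masks)].max())
for frac in (0.5, 0.25):
    # largest threshold still covering at least `frac` of the masked volume
    idx = int(np.flatnonzero(dvh.volume_fraction >= frac)[-1])
    print(f"{frac * 100:.0f}% of tissue receives >= {dvh.thresholds[idx] / peak * 100:.2g}% "
          f"of the peak dose rate")
print(f"peak dose rate: {peak:.3g} Gy/h at the synthetic activity scale")
# Sparse hot-spot uptake plus the <100 um alpha range makes the dose-rate
# field highly non-uniform: most of the tissue sits far below the peak.
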