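"""Distance-resolved kidney uptake analysis on a synthetic phantom.

Generates a kidney-like section (elliptical tissue, cortical glomeruli, large
vessels) whose activity is enriched 2x in an annulus 50-100 um around the
glomeruli, segments the compartments from the stain-like anatomy image, and
profiles relative uptake versus distance from the glomeruli with replicate
95% confidence intervals and the per-bin exceedance significance rule.
"""

import numpy as np

from alphaqar import (
    KidneyPhantomSpec,
    aggregate_and_test,
    classify_compartments,
    distance_map,
    generate_kidney_phantom,
    segment_tissue,
    uptake_vs_distance,
)

profiles = {"enriched": [], "flat": []}
for cond, amplitude, base_seed in (("enriched", 2.0, 10), ("flat", 1.0, 20)):
    for rep in range(3):
        spec = KidneyPhantomSpec(
            seed=base_seed + rep, enrichment_amplitude=amplitude, noise_level=0.05
        )
        anatomy, activity, _ = generate_kidney_phantom(spec)
        tissue = segment_tissue(anatomy, spec.pixel_spacing_um)
        comps = classify_compartments(anatomy, tissue, spec.pixel_spacing_um)
        dist = distance_map(comps.glomeruli, spec.pixel_spacing_um)
        profiles[cond].append(
            uptake_vs_distance(
                activity.activity, dist, tissue & ~comps.glomeruli,
                bin_width_um=5.0, max_distance_um=200.0,
            )
        )

ensemble = aggregate_and_test(profiles)
peak_bin = np.nanargmax(ensemble.mean["enriched"])
centers = 0.5 * (ensemble.bin_edges[:-1] + ensemble.bin_edges[1:])
n_sig = int(ensemble.significant_difference.sum())
print(f"enriched profile peak : {ensemble.mean['enriched'][peak_bin]:.2f}x tissue mean "
      f"at {centers[peak_bin]:.0f} um from glomeruli")
print(f"flat profile maximum  : {np.nanmax(ensemble.mean['flat']):.2f}x")
print(f"significant bins      : {n_sig} (mutual CI exceedance, unadjusted)")
# The peak sits at the centre of the constructed 50-100 um annulus; the flat
# condition stays near 1.0 everywhere, and significance concentrates in the
# enriched annulus.
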