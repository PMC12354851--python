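"""Estimate and undo the camera's geometric distortion with a dot phantom.

Generates an ideal dot lattice and a barrel-distorted copy (the distortion
class seen in wide-angle optics, largest in the image corners), estimates the
corrected-to-raw deformation field from matched dot centroids, and applies the
Jacobian-weighted correction that conserves total counts.
"""

import numpy as np

from alphaqar import (
    DistortionSpec,
    PhantomSpec,
    apply_correction,
    displacement_magnitude_map,
    estimate_isotropic_scale,
    estimate_warp_field,
    generate_distorted_phantom,
)

spec = PhantomSpec(
    kind="dots", element_size=80.0, spacing=300.0, grid_rows=7, grid_cols=7,
    image_shape=(256, 256), pixel_spacing=13.25,
)
# stage 1 (circles-phantom role): global isotropic scale, measured on a
# scale-only distortion so the lattice pitch ratio isolates the scale error
circles = PhantomSpec(
    kind="circles", element_size=120.0, spacing=300.0, grid_rows=7, grid_cols=7,
    image_shape=(256, 256), pixel_spacing=13.25,
)
ideal_c, measured_c, _ = generate_distorted_phantom(
    circles, DistortionSpec(isotropic_scale=1.016)
)
scale = estimate_isotropic_scale(measured_c, ideal_c, circles.pixel_spacing)

# stage 2 (dots-phantom role): local warping from the barrel residual
ideal, measured, true_field = generate_distorted_phantom(
    spec, DistortionSpec(k1_per_um2=2e-8)
)
field = estimate_warp_field(measured, ideal, spec.pixel_spacing)
corrected = apply_correction(measured.astype(float), field)

mag = displacement_magnitude_map(field)
print(f"estimated isotropic scale : {scale:.4f}  (true 1.0160)")
print(f"residual fit RMS          : {field.fit_report['residual_rms_um']:.1f} um")
print(f"max displacement          : {mag.max():.0f} um (corners)")
print(f"min Jacobian determinant  : {field.jacobian_det.min():.3f} (fold-free > 0)")
print(f"count conservation error  : {abs(corrected.sum() - measured.sum()) / measured.sum() * 100:.2f} %")
# The recovered field reproduces the injected barrel distortion at the dot
# centroids to well under half a pixel; the Jacobian factor keeps the total
# intensity of the corrected image equal to the raw one.
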