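# alphaqar

Quantitative alpha-particle autoradiography with histological integration and
microscale dosimetry.

Alpha-emitter radiopharmaceutical therapy (αRPT) deposits its entire dose
within < ~100 µm of each decay, so therapeutic effect hinges on *where* in the
tissue the activity sits — yet conventional autoradiography gives activity
maps with no anatomical context, and single 2D sections cannot support
dosimetry for radiation that crosses section boundaries. `alphaqar`
implements the full analysis chain for ex-vivo tissue sections imaged on a
list-mode alpha camera and then stained and scanned on the same slides:

1. **List-mode quantification** — events (x, y, t) are binned into 26.5 µm
   pixels and converted to absolute activity at a reference time via the decay
   relation `Counts(t₁→₂) = f·N₀(e^(−λt₁) − e^(−λt₂))`, summed over arbitrary
   acquisition schedules, so spliced or multi-day recordings need no
   constant-activity approximation. The camera sensitivity factor `f`
   (detected events per primary decay) is fitted from a dilution series by
   regression through the origin; detector efficiency is `f/(0.5·n_α)`.
2. **Warp correction** — lattice phantoms calibrate the camera's geometric
   distortion (global isotropic scale plus a barrel-like residual, largest in
   the corners). Images are resampled through the corrected→raw deformation
   field and multiplied by its Jacobian determinant so counts are conserved.
3. **Histology coregistration** — the same sections are imaged in both
   modalities, with three sections per slide registered as a single rigid
   body (landmark initialization + mutual-information Euler refinement); the
   fixed inter-section layout resolves rotation ambiguities of near-symmetric
   sections.
4. **Compartment analysis** — stained kidney sections are segmented into
   tissue / vessels / glomeruli (Otsu + connected components + shape
   statistics); a Euclidean distance transform yields relative uptake versus
   distance from each compartment, aggregated across replicate sections with
   95% CIs and a per-bin CI-exceedance significance rule.
5. **Microscale dosimetry** — serial sections are stacked into a 3D activity
   volume (activity-only or anatomy-guided strategies, compared by Dice with
   a paired t-test); a Monte Carlo CSDA dose-voxel kernel for the Ac-225
   chain (4 alphas/decay, Bragg–Kleeman range `R = kE^1.75` in water) is
   convolved with the volume into Gy/h dose-rate maps and cumulative
   dose-volume histograms.

A first-class synthetic-data module generates every input with known ground
truth (Poisson list-mode streams, distorted phantoms, kidney-like sections
with annular enrichment, misaligned tumor stacks), which is how the test
suite validates each stage end to end.

## Worked example

```bash
python examples/quantify_events.py
```

```
simulated events : 4685292
true total       : 13.3574 Bq
recovered total  : 13.3564 Bq
median pixel err : 0.45 %
```

A known Ac-225 activity map (tens of mBq per pixel) is pushed through the
forward model — Poisson decay events over a 60-hour acquisition with
`f = 1.77` — then binned and decay-corrected back to Becquerel. Totals agree
to ~0.01%; per-pixel scatter is pure counting noise (~1% at 10⁴ counts).
The other examples cover calibration (`calibrate_sensitivity.py`, which
prints `f = 1.7699` and `88.5 %` efficiency), warp correction
(`warp_correction.py`: isotropic scale 1.0160 recovered exactly,
count conservation error 0.01%), kidney profiling (`kidney_profile.py`:
enrichment peak at 72 µm from glomeruli for a 50–100 µm constructed annulus)
and 3D dosimetry (`tumor_dosimetry.py`: adjacent-section Dice ≈ 0.98–0.99
after anatomy-guided stacking and a strongly non-uniform DVH).

The `amd` command-line tool wraps the same library for shell use
(`amd bin`, `amd calibrate`, `amd warp-calibrate`, `amd segment`,
`amd profile`, `amd dvk`, `amd dose`, `amd dvh`, `amd simulate`, `amd run`).

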