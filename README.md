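# mechanoquant

Quantification pipeline for cell-mechanosensing microscopy assays. It
implements the three measurement chains a mechanobiology lab runs when
asking how cytoskeletal forces regulate YAP signaling, together with the
group statistics and qPCR arithmetic used to compare conditions:

1. **YAP nuclear/cytoplasmic ratio** — nuclei segmented from DAPI by Canny
   edge detection, a 5-px perinuclear cytoplasmic ring built by dilation,
   and the N/C ratio computed as mean nuclear / mean ring stain intensity.
   Cell spread area is measured independently from the F-actin channel.
2. **FRET tension-sensor index** — three-cube (donor / FRET / acceptor)
   imaging of a genetically encoded talin tension sensor. After shade,
   shift, and background correction, bleed-through fractions are calibrated
   as regression slopes on single-fluorophore controls and the pixelwise
   index is

   ```
   FRET index = (I_f − dL·I_d − aL·I_a) / I_a = F_c / I_a
   ```

   averaged over focal adhesions (higher force across the sensor → lower
   FRET).
3. **Traction force microscopy** — substrate displacements from bead image
   pairs (windowed cross-correlation PIV with subpixel peak fitting),
   inverted to traction stresses by regularized Fourier Transform Traction
   Cytometry on the Boussinesq elastic half-space: per wavevector k,
   u(k) = G(k) t(k) with

   ```
   G(k) = 2(1+ν)/(E|k|³) · [ (1−ν)|k|² + ν·k_y²,  −ν·k_x·k_y
                             −ν·k_x·k_y,  (1−ν)|k|² + ν·k_x² ]
   ```

   and Tikhonov-regularized inversion t(k) = (GᵀG + λ_eff²I)⁻¹Gᵀu(k).

Because raw experimental images for this kind of study are rarely deposited,
the package ships a first-class synthetic-scene generator (`synthgen`) that
emulates each assay with complete, seeded ground truth — every claim the
pipeline makes is validated by parameter recovery, not by eyeballing.

## Worked example

```python
from mechanoquant import synthgen, fretindex
from mechanoquant.containers import FretCalibration

illum = synthgen.default_illum_field((256, 256), seed=5)
scene = dict(illum_field=illum, shift_true=(3.0, -2.0), background_true=50.0,
             noise_sd=12.0, shape=(256, 256))

donor_ctrl, _ = synthgen.make_donor_only_control(0.6, seed=1, **scene)
acceptor_ctrl, _ = synthgen.make_acceptor_only_control(0.12, seed=2, **scene)
cal = FretCalibration.merge(
    fretindex.calibrate_bleedthrough(
        fretindex.correct_channels(donor_ctrl, illum_ref=illum), "donor-only"),
    fretindex.calibrate_bleedthrough(
        fretindex.correct_channels(acceptor_ctrl, illum_ref=illum), "acceptor-only"),
)
print(f"dL = {cal.dL:.4f} +/- {cal.dL_se:.4f}")
print(f"aL = {cal.aL:.4f} +/- {cal.aL_se:.4f}")

triplet, _ = synthgen.make_fret_triplet(0.30, 0.6, 0.12, seed=3, **scene)
corrected = fretindex.correct_channels(triplet, illum_ref=illum)
result = fretindex.compute_fret_index(corrected, cal)
mean_fret, adhesions = fretindex.adhesion_mean_fret(result, corrected.acceptor)
print(f"adhesions: {adhesions.n_labels}, mean FRET index = {mean_fret:.4f}")
```

prints

```
dL = 0.5997 +/- 0.0004
aL = 0.1199 +/- 0.0003
adhesions: 19, mean FRET index = 0.3007
```

The scene was synthesized with true leakage fractions dL = 0.6, aL = 0.12, a
uniform true FRET index of 0.30, an illumination gradient, a (3, −2) px
inter-channel shift, background 50, and Gaussian noise at 2% of the signal
scale: the calibration recovers both slopes within their standard errors and
the adhesion-averaged index is within 0.001 of truth. The same pattern holds
for traction microscopy — a 400 Pa contractile patch pair on a 10 kPa,
ν = 0.5 substrate run through bead synthesis → PIV → FTTC (λ = 1e-4,
relative mode) → cell-mask averaging returns 79.9 Pa against a ground-truth
node average of 83.7 Pa (≈5%).

Everything is also scriptable from the shell:

```
mechanoquant synth --kind nc --seed 3 --out runs/demo
mechanoquant ncquant --dapi runs/demo/scene_nc/dapi.tif \
    --stain runs/demo/scene_nc/stain.tif --actin runs/demo/scene_nc/actin.tif \
    --out runs/demo
mechanoquant tfm --deformed d.tif --relaxed r.tif --mask m.tif -E 10000 --nu 0.5 --lam 1e-4 --out runs/tfm
mechanoquant run --config run.yaml --seed 7 --out runs/full
```

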