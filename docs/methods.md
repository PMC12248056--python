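# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Nuclear/cytoplasmic ratio (`imgquant`)

Nuclei are detected in the DAPI channel with a Canny edge detector
(Gaussian σ = 2 px; hysteresis thresholds as gradient-magnitude quantiles
0.90/0.98 by default, with absolute thresholds available). Edge contours
are closed with a disk of radius 3, filled, and refined to the intensity
half-level between foreground and background: the filled contour includes
the edge-pixel layer itself, a systematic ~half-pixel radial bias that the
intensity criterion removes (a clean r = 20 px disk is then recovered to
within 0.1% of πr² instead of ~5%). Components under 50 px² are dropped and
labeling is 8-connected.

The cytoplasmic ring of each nucleus is the disk-dilation of its mask
(width 5 px by default) minus all nuclear pixels. A pixel reachable from
two nuclei is assigned to the nearer nucleus via the Euclidean distance
transform — a deterministic tie-break that prevents double counting.
Nuclei touching the frame border stay in the mask but their records are
flagged excluded: their rings are clipped and would bias the ratio. The
ratio itself is the mean stain intensity over the nucleus divided by the
mean over the ring; a zero-signal ring yields an excluded record, never a
division error. The ring is a proxy for perinuclear cytoplasm, not an
average over the whole cytoplasm; it deliberately samples a band of
comparable cell thickness.

Cell spread area is an independent measurement from the F-actin channel:
Otsu threshold by default (or a fixed value), 8-connected components,
areas in µm² as pixel count × pixel_size². No attempt is made to assign
nuclei to cell footprints.

## FRET index (`fretindex`)

Model: the FRET-channel image is I_f = F_c + dL·I_d + aL·I_a, where F_c is
sensitized emission, dL the donor emission leaking through the FRET
emission filter, and aL the directly excited acceptor contribution. The
index F_c/I_a is a ratiometric proxy for FRET efficiency; for a talin
tension sensor, force across the sensor separates the fluorophore pair and
lowers the index.

Correction cascade (in order): division by the mean-normalized illumination
reference (one flat-field per channel or one shared field); co-registration
of donor and acceptor to the FRET channel by phase cross-correlation with
20× subpixel upsampling (blank channels in single-fluorophore controls are
detected — no structured content 10 SD above the border background — and
passed through); subtraction of the scalar background estimated as the mean
over a 20-px frame border band; "three-point" smoothing, read here as a 3×3
uniform mean with a separable [1,2,1]/4 alternative. Negatives are clipped
to zero only after smoothing — truncating noisy dim pixels first would bias
every downstream intensity statistic upward.

Bleed-through calibration is an ordinary least-squares slope of I_f against
the present fluorophore's channel over foreground pixels (predictor above
border-background mean + 3 SD). Two refinements keep the estimate honest at
realistic noise: (1) the regression runs on non-overlapping 6×6-px block
means — additive noise on the predictor attenuates a raw-pixel OLS slope
(errors-in-variables), and block averaging suppresses that bias
quadratically while costing only linearly in standard error; (2) the
reported SE carries a closed-form (1 + 2ρ) inflation for the correlation
the smoothing filter induces between neighboring blocks (ρ from the
composed box kernel; ≈1.17 for 3-px smoothing and 6-px blocks, matching the
1.1–1.2 underestimate observed in repeated-seed simulations). Negative
fitted slopes are clamped to zero, and a constant predictor or fewer than
100 foreground pixels is an error, not a silent zero.

The index map is computed only where the acceptor exceeds a validity floor
(background mean + 3 SD by default) — below it the ratio is dominated by
noise — and NaN elsewhere; raw values are retained unclipped. The per-cell
value is the pixel mean of the index over focal adhesions segmented from
the acceptor channel (the sensor itself marks adhesions): Otsu threshold,
minimum adhesion 10 px². This pixel mean is exactly the adhesion-area-
weighted average (sum of index over adhesion pixels / adhesion area);
per-adhesion means are also reported so an equal-weight average can be
formed if preferred. An optional division by the mean of a control-sensor
population gives the normalized index. Exposure and illumination are
assumed identical between calibration and measurement images.

## Traction force microscopy (`tfm`)

The substrate is a linear-elastic half-space. In Fourier space the
tangential surface displacement responds to tangential traction through the
2×2 Boussinesq Green tensor G(k) (see README); ν = 0.5 (incompressible
PDMS/polyacrylamide) makes the off-diagonal coupling vanish, but ν is kept
general and validated against the closed-form point-force solution at
ν = 0.3 as well. G diverges at k = 0, so the zero-frequency (rigid-motion)
mode is set to zero in both directions: displacements are zero-mean and
recovered tractions integrate to ~zero net force, the physically correct
convention for a cell in mechanical equilibrium. Displacement fields are
therefore compared modulo this DC mode wherever the free-space analytic
solution (which has no such convention) serves as the oracle.

Forward operator: traction is zero-padded (factor 2 by default) so a
localized patch approximately sees free space instead of periodic images;
factor 1 gives the strictly periodic operator whose λ = 0 inverse is exact
to machine precision on band-limited fields — the algebraic round-trip
identity the tests assert.

Inverse: per wavevector, t(k) = (GᵀG + λ_eff²I)⁻¹Gᵀu(k). The bare
regularization number λ is meaningless without a normalization convention,
so two modes are provided: `relative` (default), where λ_eff = λ·σ_max with
σ_max the largest singular value of G over the grid, making λ a
dimensionless fraction transferable across grid sizes and stiffnesses; and
`absolute`, taking λ_eff = λ in native units for literal reproduction of
legacy conventions. λ = 1e-4 (relative) is the default. For non-periodic
data the field is expanded 2× with cosine-tapered, edge-replicated margins
before the transform to suppress wrap-around; `pad=False` disables this for
exact round trips.

PIV: 32-px interrogation windows at 50% overlap, mean-subtracted FFT
cross-correlation, three-point Gaussian subpixel peak fit (parabolic
fallback), per-node quality = normalized correlation coefficient at the
peak. Nodes below quality 0.3 or with edge-of-search peaks are filled from
the median of valid neighbors and flagged. Stage drift is removed by
subtracting the median displacement of the border band of nodes (assumed
far-field). The vector field is finally conditioned with a Gaussian
smoother of σ = 0.7 nodes — the standard step that averages out
discontinuity errors in PIV fields before inversion; it is exact on uniform
fields and, in recovery simulations, the dominant contributor to keeping
the inverted stress field free of high-frequency noise inflation.
Displacements convert px → µm via the pixel size before inversion;
tractions are reported in Pa. Per-cell stress is the mean traction
magnitude over the grid nodes covered by the cell mask (sampled at node
centers); a mask covering no node yields an excluded record.

## Group statistics and qPCR (`stats_qpcr`)

Every group is Shapiro-Wilk tested at α = 0.05. If all pass: one-way ANOVA
with Tukey's HSD post hoc (scipy). Otherwise: Kruskal-Wallis with Dunn's
rank-based pairwise test — implemented here with the tie-corrected rank
variance and Bonferroni family correction by default (Holm available),
since no package in the scientific Python stack ships Dunn's test. A
zero-variance group forces the nonparametric branch with a warning
(Shapiro-Wilk is undefined there). The dispatcher's omnibus type-I error
stays at the nominal 5% because both branches are valid level-α tests under
the null; this is verified by Monte-Carlo in the tests.

ΔΔCT: duplicate wells are averaged on the CT scale (matching duplicate-well
protocols; wells disagreeing wildly are the user's responsibility to
exclude upstream). ΔCT = CT_target − CT_reference per sample, ΔΔCT
subtracts the control-group mean ΔCT, fold change = 2^(−ΔΔCT). By
construction the control group's geometric-mean fold change is 1. Samples
missing either CT are returned excluded with a reason.

## Synthetic scenes (`synthgen`)

All generators are pure functions of their parameters and seed
(bit-reproducible). Defaults describe a 512×512 frame at 0.1 µm/px
(63×-class sampling); the N/C scenes use 20×-style disk nuclei of radius
15–25 px.

* **N/C scenes** are piecewise constant: disk nuclei (stain 200) inside a
  painted perinuclear annulus (stain 100) wider than the measurement ring,
  within a larger actin footprint. The true ratio is exactly
  nuclear/ring intensity, which is what makes exactness assertions
  possible.
* **FRET triplets** share one cell/adhesion structure across channels
  (elliptical footprint, ~30 elongated peripheral adhesions at 2–3.5× the
  body intensity, smooth multiplicative texture). I_f is synthesized from
  the index model above and then corrupted in this order: acceptor-channel
  shift, additive background, multiplicative illumination gain, additive
  Gaussian noise. Background is applied before the gain (stray light
  traversing the same optics) precisely so that the correction cascade —
  divide gain, register, subtract scalar background — is its exact inverse
  in the noiseless limit; the generator and the correction are exact
  inverses by construction, which the round-trip tests exploit.
* **TFM pairs** render beads as 2-D Gaussians (σ = 1 px; 0.1 µm beads are
  sub-resolution point emitters) at 4 beads/µm² — a dense speckle giving
  ~40 particles per 32-px window, the regime PIV accuracy guidance
  recommends — and warp the relaxed image by the forward-operator
  displacement field (inverse mapping, bilinear interpolation).
  Displacements exceeding half the PIV window are rejected as
  unrecoverable. `traction_dipole` builds equal-and-opposite contractile
  Gaussian patches (zero net force, as equilibrium requires); the returned
  cell mask covers the dilated traction support, standing in for a
  phase-contrast outline.

Noise is additive Gaussian on noise-free signal (a Poisson component is not
modeled); camera characteristics of the emulated instruments are not
published, so noise levels are free parameters recorded in the ground
truth. The generator does not emulate PSF blur beyond the bead kernel,
vignetting beyond a smooth multiplicative field, sensor-expression
variability between cells, or segmentation-adversarial morphologies
(touching nuclei, apoptotic fragments). Passing recovery tests therefore
demonstrates correctness of the estimators under the stated image model,
not robustness to every pathology of real micrographs.

## Validation problem sizes

The recovery suite uses 256×256 FRET frames (5 seeds × 3 index levels),
512×512 bead pairs (5 seeds), 64×64 operator-equivalence grids, 128×128
round-trip grids, and 1000 + 200 Monte-Carlo draws for the statistics
dispatcher — sizes at which every quantity of interest is estimated well
while the whole suite runs in about a minute on one core.

## Known limitations

* The Boussinesq model assumes an infinitely thick substrate; finite-gel
  corrections and 3-D tractions are out of scope.
* PIV is correlation-based only; particle-tracking for very sparse beads is
  not provided.
* The FRET index is not converted to force units; that requires the
  sensor's published single-molecule calibration curve.
* Adhesion segmentation uses the sensor channel itself; with very low
  expression the Otsu threshold degrades before the index does.
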