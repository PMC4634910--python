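# Methods

This note documents the models, numerical choices and known limitations of
`cinedense`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The deforming-ventricle phantom

The phantom is a short-axis annulus (end-diastolic endocardial radius
R_endo = 25 mm, epicardial radius R_epi = 35 mm by default) on a 128 × 128
grid with 2.8 × 2.8 mm² pixels, 30 frames at 17 ms, end-systole at frame 20 —
the geometry of a typical mid-ventricular spiral cine DENSE protocol. Its
deformation is the incompressible polar mapping

    (R, Θ) → ( r(R,t), Θ + α(R,t) ),    r² = R² + c(t),

which preserves area exactly for any c(t), so radial thickening is the
kinematic consequence of circumferential shortening, as in a
volume-conserving wall. The twist profile is
α(R,t) = a(t) · (peak_twist + grad · (R − R_mid)) with a transmural gradient
of zero by default.

**Strain parameterization.** Ground truth is parameterized directly in terms
of the Lagrangian strain (the quantity reported clinically), via
λ = √(2E + 1). c(t) is chosen so that the *area-averaged* circumferential
Lagrangian strain over the wall equals a(t) · peak_ecc: the prescribed
stretch acts at the effective mid-wall radius
R_eff² = (R_epi² − R_endo²) / (2 ln(R_epi/R_endo)), the inverse of the area
mean of 1/R². Per material point,

    Ecc(R,t) = (r²/R² − 1)/2,
    Err(R,t) = ((R/r)² + r² α′(R,t)² − 1)/2,
    twist(R,t) = α(R,t),

all closed form, aggregated exactly like the pipeline output (six 60°
segments from the +x axis, global = mean of segments). With the defaults
(peak Ecc −20 %, twist 8°), peak displacement is ≈ 8.8 mm — under the 10 mm
bound used in the wrap-fraction experiments — and endocardial Err reaches
≈ 67 % while epicardial Err is ≈ 20 %: 2D incompressibility concentrates
thickening subendocardially.

**Activation.** a(t) is a raised-cosine rise from 0 (end-diastole) to 1
(end-systole) followed by a raised-cosine partial relaxation to a diastolic
residual of 0.3 at the last frame (the acquired window rarely spans complete
relaxation). The curve is C¹, so a 10th-order polynomial represents it
accurately over 30 frames.

**Eversion guard.** Shortening with R_endo² + c(t) ≤ 0 would evert the
annulus; `build_phantom` rejects such configurations with a diagnostic.

**Regional heterogeneity** is deliberately not modelled: an azimuthal strain
perturbation would destroy the closed-form oracle that makes the phantom
useful. Between-subject variability is instead created at the cohort level
(uniform jitter of peak strain, twist and radii in `ExperimentConfig`).

## The encoder

Per axis, noise-free phase is wrap(2π k_e u) inside the myocardium, with the
wrap convention (−π, π] (both ±π map to +π — one unambiguous boundary).
The complex signal A·exp(iφ) receives i.i.d. zero-mean Gaussian noise on the
real and imaginary channels, so magnitudes are Rician — the model the
σ = 1.526 σ_M background correction assumes.

* **Noise scale.** σ is set from the *unattenuated* myocardial amplitude as
  σ = A₀/target_snr. Measured SNR therefore equals the target on a
  stationary phantom and falls below it in deforming tissue by exactly the
  intra-voxel dephasing loss — reproducing the SNR-versus-k_e tradeoff at a
  fixed acquisition noise level, which is what changing only the encoding
  gradient does on a scanner.
* **Intra-voxel dephasing.** The within-voxel displacement spread per axis is
  the range of the Eulerian displacement sampled on a 3 × 3 intra-voxel
  subgrid (bilinear interpolation); the magnitude is attenuated by
  |sinc(k_e · spread_x)| · |sinc(k_e · spread_y)|, the first-order model for
  linear phase dispersion across a voxel. A fixed through-plane factor
  |sinc(k_d · slice · f_thru)| with f_thru = 0.05 (a ~5 % through-plane
  displacement spread across the 8 mm slice) applies to all frames; it is
  constant across k_e and so never affects comparisons between encoding
  frequencies.
* **Blood pool.** Blood magnitude decays as exp(−(b₀ + b₁ k_e)·t) with
  b₀ = 0.25/frame, b₁ = 1.5 frame⁻¹·(cycles/mm)⁻¹. These rates were chosen
  once so that the frame-5 residual signal spans roughly a third to a fifth
  of the initial value across the 0.02–0.10 cycles/mm sweep, the range
  typical of in vivo blood-pool dephasing; only the direction (faster decay
  at higher k_e, driven by b₁ > 0) is asserted anywhere.
* **CSPAMM** is modelled as echo-suppression logic (the T1 echo is
  suppressed by subtraction; through-plane dephasing of ≥ ½ cycle across the
  slice suppresses both off-centre echoes). Whether the two-acquisition
  subtraction contributes a √2 noise factor to the reconstructed images
  depends on reconstruction details that are not settled, so it is an
  explicit flag (`cspamm_subtraction_noise`, off by default) rather than an
  assumption.
* **Quantization** (e.g. 12-bit storage) rounds phase to 2π/2^bits steps
  after noise, mirroring fixed-point storage of reconstructed phase.

## Unwrapping

Quality-guided region growing within the segmentation, per frame and axis:
quality is the negative mean wrapped phase-gradient magnitude to masked
4-neighbours; growth order is a max-heap with lexicographic (row, column)
tie-breaking, so the result is deterministic. Each frame's solution is
re-referenced to the previous frame's by an integer multiple of 2π (median
matching over the mask overlap); frame 1 assumes near-zero early-systolic
motion (|u| < 1/(2 k_e)). Disconnected mask components are unwrapped
independently (with a warning); empty-mask frames are flagged and skipped.
The output is congruent with the wrapped input modulo 2π at every masked
pixel by construction. On noise-free phantoms the recovered displacement
matches ground truth to ~1e−15 mm for any k_e in the study range, and the
solution agrees with scikit-image's masked unwrapper up to the global 2π
offset (both checked in the test suite).

## Mechanics

1. **Spatial smoothing**: mask-normalized Gaussian convolution of the
   Eulerian maps (default SD 1 pixel). Outside the mask, values are linearly
   extrapolated from the nearest valid pixel using masked finite-difference
   gradients, keeping interpolation near the wall boundary first-order
   accurate.
2. **Trajectories**: for each material point (pixel centres in the
   end-diastolic mask), the current position solves the Eulerian consistency
   condition x(t) = X + u(x(t), t) by fixed-point iteration (bilinear
   interpolation, 50 iterations, 1e−9 mm tolerance; non-converged points are
   flagged invalid and excluded). The iteration contracts whenever
   ‖∇u‖ < 1, which holds for physiological strain.
3. **Temporal fitting**: unconstrained least squares per displacement
   component in a Legendre basis on time scaled to [−1, 1] (equivalent to a
   raw 10th-order polynomial fit, far better conditioned). Fitted first-frame
   positions can differ from the material points by the fit residual, so all
   strain and twist computations use the fitted frame-1 configuration as the
   material reference — which also makes every curve exactly zero at frame 1.
4. **Strain**: the deformation gradient F per point and frame is the least
   squares fit over the material neighbourhood (default radius 1.5 pixels =
   4.2 mm, the 8-connected pixel neighbourhood); E = ½(FᵀF − I), projected on
   the end-diastolic radial direction (centroid → point) and its 90° CCW
   rotation. Points with degenerate (rank < 2) neighbourhoods are excluded.
   The estimator is exact for affine motions (verified against rotations and
   scalings).
5. **Twist**: signed angle from (X − c) to (x(t) − c) about the end-diastolic
   endocardial centroid, counterclockwise positive (apex-to-base view).

### Known accuracy limits

* Trajectory reconstruction from exact Eulerian maps is interpolation
  limited: bilinear interpolation of the curved displacement field at 2.8 mm
  pixels leaves position errors up to ≈ 0.2 mm near the endocardium (tested
  at < 0.25 mm).
* Peak global Ecc and twist are recovered to ≲ 0.3 % strain and ≲ 0.05°
  noise-free, and within a few tenths of a percent at SNR 20.
* Peak global **Err is biased low** (≈ 21 % recovered vs ≈ 34.5 % truth with
  the default 1-pixel smoothing; ≈ 33 % with smoothing off): the pixel-scale
  neighbourhood of the F estimate and any spatial smoothing average the
  steep, 1/R²-shaped transmural strain profile across a wall only ~3.5
  pixels thick. This mirrors the well-known unreliability of DENSE radial
  strain at clinical resolution and is documented rather than hidden: tests
  assert tight recovery for Ecc/twist and only a coarse bound for Err. For
  noise-free accuracy checks the smoothing is disabled (there is no noise to
  regularize); noisy runs use the defaults.

## Metrics and statistics

* Rician correction: σ = √(2/(4−π))·σ_M ≈ 1.526 σ_M (background magnitude is
  Rayleigh), S = √(M² − σ²) clamped at zero, SNR = S/σ. The background ROI
  is four 16 × 16 corner squares, guaranteed signal-free in the phantom
  geometry.
* Wrap fraction: per axis, the maximum over frames of the percentage of
  wrapped pixels inside the segmentation; the reported value is the mean of
  the x and y maxima (which may occur at different frames).
* Blood curve: mean blood-mask magnitude per frame as a percent of frame 1
  (1-based frames; frame 5 ≈ 85 ms is the early-systole summary).
* Stationary phase RMSE: root-mean-square phase about zero truth (a
  stationary phantom has zero mean phase by construction), per axis;
  2D displacement RMSE = vector sum of the per-axis RMSEs divided by
  2π k_e. Encoding different k_e with the same seed reuses the identical
  noise realization, so radian RMSEs match exactly and the mm-RMSE ratio
  between two k_e equals their inverse ratio exactly.
* Agreement: Bland–Altman bias and 1.96·SD(d) limits (sample SD), the
  modified CoV with the two-value n−1 SD (|x−y|/√2) and the ratio-of-means
  denominator as printed in the reproducibility literature, and two-sided
  paired t-tests. Degenerate difference vectors use documented conventions
  (all-zero → p = 1; zero variance, nonzero mean → p = 0).

## Problem sizes

Unit tests run mostly on a 64 × 64, 24-frame phantom; full-scale checks
(parameter recovery, noise law, wrap fraction) use the 128 × 128, 30-frame
geometry. The acceptance script uses the full-scale phantom throughout; a
single encode–unwrap–mechanics pass takes ~1 s, and the whole suite runs in
well under a minute on one core. Monte-Carlo calibrations use 10⁴ replicates
(t-test size) and 2 × 10⁴ pairs (Bland–Altman/CoV convergence).

## What passing tests do and do not show

The phantom is axisymmetric, noise is spatially white, the segmentation is
exact, and there are no reconstruction artifacts (spiral gridding,
off-resonance, view sharing are all out of scope). Passing tests therefore
validate the *computational pipeline* — encoding model, unwrapping, strain
algebra, statistics — not robustness to real-data confounds such as
segmentation error, regional dysfunction, through-plane motion, or stripe
artifacts from incompletely suppressed echoes.
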