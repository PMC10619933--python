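# Methods

This note documents the models, algorithms, numerical choices, and
known limitations of the package. Everything quantitative stated here
is computed by the test suite or the acceptance script; nothing is
quoted from elsewhere.

## Problem setting

Multicomponent T2 relaxometry acquires a train of T2-weighted images
(here 3D multi-echo spin echo, MESE) and decomposes each voxel's decay
into a nonnegative spectrum over T2. The myelin water fraction (MWF)
is the spectrum fraction with T2 strictly below 40 ms; the
intra/extracellular T2 (IET2) is the amplitude-weighted geometric mean
over the open 40–200 ms window. Because a fully sampled 3D MESE brain
acquisition takes on the order of three hours, the acquisition is
undersampled heavily (up to ~24x) and the reconstruction must recover
the echo images from a few percent of k-space.

The framework has three cooperating parts:

1. **Acquisition** — a different pseudo-random variable-density
   k-space pattern at every echo time, so undersampling artifacts are
   incoherent along the echo dimension while true signal evolutions
   remain strongly correlated.
2. **Reconstruction** — a two-stage compressed-sensing scheme: a
   conventional CS pass, a data-driven SVD of the resulting voxel
   signals truncated to K temporal components, and a second CS pass
   constrained to that subspace (solving for K coefficient images).
3. **Analysis** — flip-angle refinement plus regularized nonnegative
   least squares (NNLS) against an extended-phase-graph (EPG)
   dictionary, with an optional spatially regularized variant.

All of it is exercised on digital phantoms whose MWF/IET2 are known by
construction, so every stage is testable without scanner data.

## Sampling schemes

A scheme is a boolean mask per echo on the phase x slice encode grid
plus an ordered encode list. Properties:

* **Exact budget.** The total sample count is
  `round(n_echoes * n_phase * n_slice / R)` exactly, so the retained
  fraction is a deterministic function of the grid and R (4.2% at
  R=23.9 on the 118x59 x 56-echo brain grid; 6.8% at 14.6; 76.9% at
  1.3). Calibration samples count toward the budget; the denominator
  is the full rectangular grid.
* **Blue-noise placement.** Points are drawn by density-weighted
  best-candidate sampling: each new point is the candidate (drawn from
  the radial density `(1-r)^d`, d = 3 by default, r normalized to the
  inscribed ellipse) farthest from the points already chosen. This
  approximates variable-density Poisson-disc sampling. We initially
  used independent Bernoulli draws; realizations occasionally left
  large k-space holes that doubled reconstruction error, which is why
  the generator enforces spacing.
* **Calibration block.** A fully sampled central region (default
  12x12) at the first two echoes anchors coil-map estimation and the
  early-echo data that characterize stimulated echoes. It is exempt
  from the elliptical shutter and the uniform phase grid (every 2nd
  phase line outside the block).
* **Determinism.** One independent seeded generator per echo; the
  seeds are stored in the scheme and serialized with it. Changing the
  seed of echo k changes only mask k.
* **Encode order** within an echo is center-out by radius, ties broken
  by angle.

Feasibility: with shutter and phase-grid factor 2 the eligible set is
roughly `pi/8` of the grid (~39%), so accelerations below ~2.6 require
disabling those options; the generator raises a descriptive error
otherwise.

## EPG simulation

Echo amplitudes are `|F_0|` of the extended-phase-graph recursion:
ideal 90° excitation about y, refocusing about x (CPMG), one unit of
crusher dephasing per half echo spacing, T2 on transverse states, T1
with regrowth of Z0 (default T1 = 1000 ms; repetition-time saturation
is ignored under a long-TR assumption). States are truncated at
`n_echoes + 2` dephasing orders, which is lossless for CPMG. At 180°
the recursion reduces to `exp(-TE/T2)` exactly; the general case is
verified against an independent isochromat-ensemble Bloch simulation
to 1e-10 (the ensemble over equally spaced crusher phases equals the
continuous integral exactly once more isochromats than occupied
dephasing orders are used).

## Reconstruction

Forward model `y = M F S x`, with mask M, centered orthonormal 2D FFT
F, coil sensitivities S; in the subspace-constrained stage `x = Phi_K
alpha` with an orthonormal temporal basis (n_echoes x K). The solver
is monotone FISTA with per-image wavelet soft-thresholding
(Daubechies-4, 3 periodized levels, clamped to the image size; all
bands thresholded), step `1/(1.01 L)` with L from 30 power iterations,
stopping at 100–150 iterations or relative change < 1e-5. k-space is
normalized so the coil-combined zero-filled first-echo image has unit
99th-percentile magnitude; the regularization weights are quoted on
that scale (brain protocol 0.004, cord 0.001, digital phantom 0.002 —
see below).

Coil handling: SVD coil compression fitted on the echo-1 calibration
block (8 virtual channels by default, retained energy reported), then
sensitivity estimation from the apodized (Hann) zero-filled
calibration block normalized to root-sum-of-squares 1 on a support
thresholded at 10% of the peak RSS. On the smooth synthetic coil
profiles this estimator is accurate to a few percent; an
eigen-decomposition (ESPIRiT-style) estimator would slot behind the
same interface but is not needed at phantom scale.

Subspace: voxels whose first-echo magnitude exceeds 10% of the
99th-percentile form a (voxels x echoes) matrix; its first K right
singular vectors are the basis. K = 12 by default — deliberately
larger than the ~4–6 components the phantom needs, erring toward
retaining noise rather than biasing signal.

Two numerical findings shaped the defaults, both visible in the test
suite:

* **Step-1 shrinkage propagates into the basis.** The L1 penalty in
  the calibration pass systematically distorts echo-train shapes
  (late echoes are shrunk hardest), and a basis computed from the
  distorted signals cannot represent the true ones — the projection of
  noise-free truth onto such a basis loses most of the myelin water
  signal. `ReconConfig.lam_step1` therefore allows a lighter weight
  for step 1 only (the phantom protocol uses 2e-4 against 2e-3 for the
  constrained pass); with `lam_step1=None` both steps use the same
  weight, which is the conventional configuration.
* **MWF is far more fragile than image error.** An echo-image NRMSE of
  ~0.1 is visually good yet enough to bias per-voxel MWF by a factor
  of two if it is structured; the parameter-recovery tests therefore
  check MWF directly rather than only image error.

## T2 analysis

The dictionary has 40 log-spaced T2 values from 8 ms to 2 s (a
standard grid compatible with 6–10 ms echo spacings). Per voxel:

1. **Flip refinement.** Candidate refocusing angles 90°–180° in 1°
   steps; the candidate minimizing the unregularized NNLS misfit wins.
   Dictionaries are cached per angle, and `scipy.optimize.nnls` is
   fast enough (~0.1 ms/solve) that the full scan is the default.
2. **Temporal regularization.** `min ||As-d||^2 + mu^2 ||s||^2, s>=0`
   as a stacked system, with mu bisected so the misfit is 1.02x the
   unregularized minimum (the usual multicomponent-T2 convention). If
   the signal is fit exactly without regularization the unregularized
   solution is returned.
3. **Spatial variant.** An unregularized seeding pass produces spectra
   that are noisy but mean-unbiased; each subsequent pass (2 by
   default) refits every voxel with the Tikhonov pull-to-zero
   *replaced* by a pull toward the kernel-weighted (1-2-1 binomial,
   3x3) average of its neighbors' spectra, with weight
   `nu = spatial_weight * mean column norm` (spatial_weight 0.3). The
   reference takes over the stabilizing role of the temporal term.
   This choice is deliberate: on a two-pool phantom at realistic SNR,
   the identity-Tikhonov term at the 1.02 target merges the 20 ms and
   80 ms peaks and roughly halves MWF even on noise-free images, while
   the reference-anchored refit keeps the class means unbiased to a
   few thousandths with strongly reduced voxel noise. With
   spatial_weight 0 the function reduces exactly to the temporal-only
   fit.

Magnitude data are fitted; the Rician floor is ignored at the SNRs
simulated (it inflates low-MWF classes slightly at SNR 50, visible in
the edge-preservation test). MWF uses a strict `T2 < 40 ms` cutoff;
IET2 uses the open interval (40, 200) ms; voxels with no amplitude in
a window are flagged undefined (NaN plus a boolean map), never
zero-filled.

## The phantom (what it emulates, what it does not)

Concentric shapes on a 2D phase x slice plane: a white-matter-like
annulus (components 20 ms/0.088 and 80 ms/0.912, so MWF = 0.088 —
a typical healthy-WM value), a gray-matter-like disk (MWF 0.039), and
a CSF-like core (single 2000 ms pool, IET2 undefined). The refocusing
flip field is a smooth radial bowl (165° center to 180° edge,
quantized to 1°). Coil sensitivities are Gaussian lobes on a fixed,
evenly spaced ring around the field of view with per-coil linear
phase, RSS-normalized; the seed rotates the ring and perturbs lobe
widths a few percent only, so no draw produces a degenerate
(near-coincident) coil pair — real arrays have fixed geometry. Complex
Gaussian noise is added in k-space with SD quoted relative to the peak
first-echo magnitude (SNR 100 means sigma = 1% of peak). The readout
dimension is fully sampled in the acquisition and decouples by FFT,
so 2D phase x slice is the native scale; 3D is a stack of such planes.

What passing phantom tests do **not** show: robustness to motion, B0
inhomogeneity, slice-profile effects, non-Gaussian coil noise,
anatomically realistic spatial texture, or partial-volume mixtures
beyond piecewise-constant classes. Conclusions about in vivo accuracy
require scanner data.

Default in-silico experiment conditions ("phantom protocol"): 32
echoes at 10 ms spacing, 4 coils, 12x12 calibration, SNR 100,
K = 12, lam = 0.002 with lam_step1 = 2e-4, 150 FISTA iterations.
Problem sizes in the tests (32x32 to 64x64 grids) were chosen so the
full suite runs on a single CPU in minutes.

## Reproducibility statistics

ROI values are medians over defined voxels (metric distributions
within ROIs are skewed). For exam pairs: Bland-Altman bias and
`bias ± 1.96 SD` limits of agreement (sample SD); within-subject SD
`sigma_w = sqrt(sum d_i^2 / 2n)`; repeatability coefficient
`RC = 1.96 sqrt(2) sigma_w`; `COV = 100 sigma_w / grand mean`;
ICC(2,1) — two-way random effects, absolute agreement, single
measurement — from the ANOVA mean squares; and a two-sided one-sample
t-test of the differences. The choice of the sigma_w-based COV and of
the ICC flavor is a convention decision (the field phrase "as in
recent studies" underdetermines them); per-ROI published values are
therefore not claimed reproducible, while the mean-row aggregation
(unweighted arithmetic mean across ROIs) is, and is tested. No
multiple-comparison correction is applied; nominal significances are
simply counted.

## Known limitations

* The ESPIRiT eigen-estimator for coil maps is not implemented; the
  apodized low-resolution estimator is accurate for smooth synthetic
  maps but would be the first thing to upgrade for real data.
* The spatial analysis is a simplification of published adaptive
  spatial-regularization schemes: fixed kernel, fixed weight, two
  iterations, flip map frozen after the first pass.
* The per-voxel flip search cannot exceed 180°, so estimates near 180°
  are biased slightly downward under noise.
* MWF recovery under combined undersampling and noise varies by a few
  thousandths across noise realizations; single-seed results should be
  read with that spread in mind (the suite calibrates it explicitly).
* GRASE acquisition, non-Cartesian trajectories, GPU execution, and
  registration/segmentation of real anatomies are out of scope.
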