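# calipr

Highly accelerated myelin water imaging, end to end and entirely in
silico: incoherent per-echo k-space sampling, two-stage
subspace-constrained compressed-sensing reconstruction, and regularized
multicomponent-T2 analysis, exercised on digital phantoms with known
ground truth.

The package is for researchers in quantitative MRI who want a complete,
testable reference implementation of the CALIPR-style acquisition /
reconstruction / analysis chain — to study its behavior, prototype
changes, or validate analysis code — without needing scanner data.

## The method

A 3D multi-echo spin-echo acquisition samples a different pseudo-random
variable-density pattern of phase–slice encodes at every echo time TE,
with fully sampled central calibration blocks at the first two echoes.
Undersampling artifacts are then incoherent along the echo dimension
while true signal evolutions are strongly correlated, and reconstruction
proceeds in four steps:

1. conventional CS over the whole echo train,
   `min_x ½‖y − MFSx‖² + λ‖T(x)‖₁`
   (mask M, Fourier transform F, coil maps S, wavelet transform T);
2. SVD of the above-threshold voxel signals; the first K right singular
   vectors form a data-driven temporal subspace Φ_K (K = 12 default);
3. a second reconstruction constrained to that subspace,
   `min_α ½‖y − MFSΦ_Kα‖² + λ‖T(α)‖₁`, solving for K coefficient
   images α;
4. echo-image synthesis `x = Φ_K α`.

Echo images are then fitted per voxel: refocusing flip angle by
scanning an extended-phase-graph (EPG) dictionary for the lowest NNLS
misfit, then a regularized nonnegative T2 spectrum
`min ‖As − d‖² + μ²‖s‖², s ≥ 0` with μ chosen so the misfit is 1.02×
the unregularized minimum (an optional spatially regularized variant
anchors each spectrum to its 3×3 neighborhood instead). The myelin
water fraction is the spectrum fraction with T2 < 40 ms; IET2 is the
amplitude-weighted geometric mean over 40–200 ms. Scan–rescan
reproducibility of ROI medians is summarized with Bland–Altman limits
of agreement, repeatability coefficient, coefficient of variation, and
ICC(2,1).

See `docs/methods.md` for assumptions, parameter defaults, and the
reasoning behind the numerical choices.

## Worked example

`examples/03_validation_experiment.py` simulates a fully sampled noisy
phantom acquisition, retrospectively undersamples it at acceleration
14.6, and reconstructs three ways with identical coil maps and
regularization:

```
retained fraction: 6.8%
echo-image NRMSE  reference: 0.0527
echo-image NRMSE  CS:        0.1456
echo-image NRMSE  subspace:  0.0974
MWF error-map RMSE  CS:       0.0686
MWF error-map RMSE  subspace: 0.0460
```

Reading the numbers: the reference reconstruction (all samples) sets
the noise floor; from the same 6.8% of data, the subspace-constrained
reconstruction recovers echo images with two-thirds of the error of
conventional CS, and the resulting myelin water fraction maps are
correspondingly closer to the phantom truth.

`examples/04_parameter_recovery.py` runs the full pipeline at
acceleration 8 and SNR 100:

```
retained fraction: 12.5%
WM-class MWF: 0.0970 (truth 0.088, bias +0.0090)
voxelwise MWF mean absolute error: 0.0272
```

A white-matter bias below 0.01 at 12.5% sampling shows the subspace
reconstruction preserves the small short-T2 myelin signal the metric
depends on. The other examples cover the sampling-scheme generator
(`01`, printing the 4.2% brain-protocol budget), EPG stimulated-echo
behavior (`02`), and the reproducibility statistics (`05`).

A thin CLI wraps the same library calls
(`calipr mask|phantom|simulate|recon|fit|stats|validate`); every
command is deterministic given `--config`/`--seed` and writes a
provenance sidecar.

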