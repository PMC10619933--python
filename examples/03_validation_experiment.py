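"""Retrospective validation: reference vs CS vs subspace reconstruction.

Simulates a fully sampled noisy acquisition of the digital phantom,
retrospectively undersamples it at acceleration 14.6, and reconstructs
three ways with identical coil maps and regularization: using all
samples (reference), conventional CS on the undersampled data, and the
subspace-constrained reconstruction on the same data.  Runtime is a
couple of minutes on one CPU.
"""

from calipr.pipeline import phantom_protocol_config, retrospective_validation

cfg = phantom_protocol_config(seed=1, target_acceleration=14.6,
                              lam=0.002, lam_step1=None)
result = retrospective_validation(cfg, grid_shape=(64, 64),
                                  noise_sigma=0.01, fit_maps=True)

print(f"retained fraction: {100 * result['achieved_fraction']:.1f}%")
print(f"echo-image NRMSE  reference: {result['nrmse_reference']:.4f}")
print(f"echo-image NRMSE  CS:        {result['nrmse_cs']:.4f}")
print(f"echo-image NRMSE  subspace:  {result['nrmse_calipr']:.4f}")
print(f"MWF error-map RMSE  CS:       {result['mwf_rmse_cs']:.4f}")
print(f"MWF error-map RMSE  subspace: {result['mwf_rmse_calipr']:.4f}")
# The subspace constraint shares information across the echo train, so
# at 6.8% sampling its images and MWF maps sit much closer to the
# reference than conventional CS from the same data.
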