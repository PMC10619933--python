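"""Reconstruction chain: coil handling, subspace, and the full pipeline."""

import numpy as np
import pytest

from calipr.phantom import make_coil_maps, simulate_kspace
from calipr.recon import (CoefficientImages, EchoImageSeries, KSpaceData,
                          ReconConfig, SubspaceBasis, build_subspace,
                          coil_compress, cs_reconstruct, estimate_coil_maps,
                          nrmse, run_calipr, subspace_reconstruct,
                          synthesize_echo_images)
from calipr.sampling import generate_sampling_scheme, retrospective_undersample


@pytest.fixture(scope="module")
def full_kspace(small_truth, small_maps):
    return simulate_kspace(small_truth, small_maps)


def test_estimated_coil_maps_match_truth(full_kspace, small_maps, small_truth):
    """Apodized low-res maps agree with the smooth truth on the support."""
    est = estimate_coil_maps(full_kspace, (12, 12))
    rss = np.sqrt(np.sum(np.abs(est.maps) ** 2, axis=0))
    np.testing.assert_allclose(rss[est.support], 1.0, atol=1e-10)
    sup = est.support & small_truth.support
    mag_err = np.abs(np.abs(est.maps[:, sup]) - np.abs(small_maps.maps[:, sup]))
    assert mag_err.max() < 0.05


def test_single_uniform_coil_map_is_unity(small_truth):
    maps1 = make_coil_maps(1, (32, 32))
    ksp = simulate_kspace(small_truth, maps1)
    est = estimate_coil_maps(ksp, (12, 12))
    np.testing.assert_allclose(np.abs(est.maps[0, est.support]), 1.0,
                               atol=1e-10)


def test_estimate_coil_maps_requires_calibration(full_kspace):
    with pytest.raises(ValueError):
        estimate_coil_maps(full_kspace, (0, 0))


def test_coil_compress_unitary_when_keeping_all(full_kspace):
    comp, energy = coil_compress(full_kspace, full_kspace.n_coils, (12, 12))
    assert energy == pytest.approx(1.0, abs=1e-12)
    assert np.sum(np.abs(comp.data) ** 2) == pytest.approx(
        np.sum(np.abs(full_kspace.data) ** 2), rel=1e-10)


def test_coil_compress_exact_for_low_rank(rng):
    """Data spanned by r < n_virtual coil modes compresses losslessly."""
    modes = rng.standard_normal((2, 8)) + 1j * rng.standard_normal((2, 8))
    base = rng.standard_normal((2, 2, 16, 16)) + 1j * rng.standard_normal(
        (2, 2, 16, 16))
    data = np.einsum("rc,rexy->cexy", modes, base)  # 8 coils, rank 2
    mask = np.ones((2, 16, 16), dtype=bool)
    ksp = KSpaceData(data=data, mask=mask, echo_times=np.array([10.0, 20.0]))
    comp, energy = coil_compress(ksp, 4, (6, 6))
    # energy of the discarded modes is zero -> perfect retention
    assert energy == pytest.approx(1.0, abs=1e-10)


def test_coil_compress_error_equals_discarded_singular_values(rng):
    data = rng.standard_normal((16, 1, 12, 12)) + 1j * rng.standard_normal(
        (16, 1, 12, 12))
    mask = np.ones((1, 12, 12), dtype=bool)
    ksp = KSpaceData(data=data, mask=mask, echo_times=np.array([10.0]))
    n_virtual = 8
    comp, energy = coil_compress(ksp, n_virtual, (12, 12))
    s = np.linalg.svd(data.reshape(16, -1), compute_uv=False)
    expected = np.sum(s[:n_virtual] ** 2) / np.sum(s**2)
    assert energy == pytest.approx(expected, rel=1e-10)
    lost = np.sum(np.abs(ksp.data) ** 2) - np.sum(np.abs(comp.data) ** 2)
    assert lost == pytest.approx(np.sum(s[n_virtual:] ** 2), rel=1e-8)


def test_invalid_compression_requests(full_kspace):
    with pytest.raises(ValueError):
        coil_compress(full_kspace, 0)
    with pytest.raises(ValueError):
        coil_compress(full_kspace, 99)


def test_cs_reconstruct_noiseless_fully_sampled(full_kspace, small_maps,
                                                small_truth):
    cfg = ReconConfig(lam=0.0, max_iters=60, rel_tol=1e-12)
    est = cs_reconstruct(full_kspace, small_maps, cfg)
    assert nrmse(est.images, small_truth.echo_images) < 1e-3


def test_subspace_rank_one_data():
    """Mono-exponential voxels are captured exactly by K=1."""
    decay = np.exp(-np.arange(1, 9) * 10.0 / 80.0)
    amp = np.linspace(0.5, 2.0, 36).reshape(6, 6)
    series = EchoImageSeries(images=decay[:, None, None] * amp[None])
    basis = build_subspace(series, K=1)
    sig = np.moveaxis(series.images, 0, -1)
    proj = basis.project_signals(sig)
    assert np.abs(proj - sig).max() < 1e-10


def test_subspace_projection_residual_nonincreasing_in_k(small_truth):
    series = EchoImageSeries(images=small_truth.echo_images)
    sig = np.moveaxis(series.images, 0, -1)[small_truth.support]
    resid = []
    for K in (1, 2, 3, 5, 8, 32):
        basis = build_subspace(series, K=K)
        proj = basis.project_signals(sig)
        resid.append(np.linalg.norm(proj - sig))
    assert all(b <= a + 1e-12 for a, b in zip(resid, resid[1:]))
    # K = n_echoes is the identity
    assert resid[-1] < 1e-8


def test_subspace_exact_for_three_tissue_curves(seq32):
    """With a uniform flip field the phantom holds exactly 3 signal shapes,
    so the K=3 subspace captures them to numerical precision."""
    from calipr.phantom import default_phantom_spec, make_phantom

    truth = make_phantom(default_phantom_spec((32, 32), seq=seq32, seed=0,
                                              flip_center=180.0,
                                              flip_edge=180.0))
    series = EchoImageSeries(images=truth.echo_images)
    sig = np.moveaxis(series.images, 0, -1)[truth.support]
    basis = build_subspace(series, K=3)
    proj = basis.project_signals(sig)
    assert np.linalg.norm(proj - sig) < 1e-8 * np.linalg.norm(sig)


def test_subspace_requires_voxels_above_threshold():
    series = EchoImageSeries(images=np.zeros((4, 8, 8), dtype=complex))
    with pytest.raises(ValueError):
        build_subspace(series, K=2)


def test_synthesize_identity_basis_and_isometry(rng):
    alpha = CoefficientImages(coeffs=rng.standard_normal((4, 8, 8))
                              + 1j * rng.standard_normal((4, 8, 8)))
    identity = SubspaceBasis(basis=np.eye(4))
    out = synthesize_echo_images(alpha, identity)
    np.testing.assert_array_equal(out.images, alpha.coeffs)
    # orthonormal extension preserves per-voxel norms
    m = rng.standard_normal((8, 4)) + 1j * rng.standard_normal((8, 4))
    q, _ = np.linalg.qr(m)
    basis = SubspaceBasis(basis=q)
    ext = synthesize_echo_images(alpha, basis)
    np.testing.assert_allclose(
        np.linalg.norm(ext.images, axis=0),
        np.linalg.norm(alpha.coeffs, axis=0), atol=1e-10)


def test_subspace_recon_exact_for_in_span_data(small_truth, small_maps):
    """Noiseless fully sampled data in the basis span is recovered exactly."""
    from calipr.phantom import default_phantom_spec, make_phantom

    truth = make_phantom(default_phantom_spec((32, 32), seed=0,
                                              flip_center=180.0,
                                              flip_edge=180.0))
    ksp = simulate_kspace(truth, small_maps)
    series = EchoImageSeries(images=truth.echo_images)
    basis = build_subspace(series, K=3)
    cfg = ReconConfig(lam=0.0, max_iters=80, rel_tol=1e-12, K=3)
    alpha = subspace_reconstruct(ksp, small_maps, basis, cfg)
    echoes = synthesize_echo_images(alpha, basis)
    assert nrmse(echoes.images, truth.echo_images) < 1e-6


def test_run_calipr_deterministic_and_k_default(small_truth, small_maps):
    scheme = generate_sampling_scheme((32, 32), 32, 6.0, calib_shape=(10, 10),
                                      seeds=list(range(32)))
    ksp = simulate_kspace(small_truth, small_maps, scheme, 0.005, seed=3)
    cfg = ReconConfig(lam=0.001, max_iters=30, calib_shape=(10, 10))
    assert cfg.K == 12
    a = run_calipr(ksp, cfg)
    b = run_calipr(ksp, cfg)
    np.testing.assert_array_equal(a.echo_images.images, b.echo_images.images)
    assert a.basis.K == 12
    assert a.diagnostics["achieved_fraction"] == pytest.approx(
        scheme.achieved_fraction)
    # step-3 final objective no worse than its initialization
    trace3 = a.diagnostics["step3_objective"]
    assert trace3[-1] <= trace3[0] + 1e-12


def test_subspace_benefit_over_cs(small_truth, small_maps):
    """At acceleration 6 with noise, the subspace recon beats plain CS."""
    scheme = generate_sampling_scheme((32, 32), 32, 6.0, calib_shape=(10, 10),
                                      seeds=list(range(100, 132)))
    full = simulate_kspace(small_truth, small_maps, None, 0.01, seed=4)
    under = retrospective_undersample(full, scheme)
    cfg = ReconConfig(lam=0.002, lam_step1=2e-4, max_iters=60)
    maps = estimate_coil_maps(under, (10, 10))
    cs = cs_reconstruct(under, maps, cfg)
    calipr = run_calipr(under, ReconConfig(lam=0.002, lam_step1=2e-4,
                                           max_iters=60, calib_shape=(10, 10)))
    ref = np.abs(small_truth.echo_images)
    assert nrmse(np.abs(calipr.echo_images.images), ref) < nrmse(
        np.abs(cs.images), ref)


def test_denoising_at_full_sampling(small_truth, small_maps):
    """Subspace projection lowers NRMSE vs noiseless truth for K in 6-12."""
    noisy = simulate_kspace(small_truth, small_maps, None, 0.02, seed=6)
    maps = estimate_coil_maps(noisy, (12, 12))
    cfg = ReconConfig(lam=0.0, max_iters=40)
    plain = cs_reconstruct(noisy, maps, cfg)
    ref = np.abs(small_truth.echo_images)
    base_err = nrmse(np.abs(plain.images), ref)
    for K in (6, 8, 12):
        basis = build_subspace(plain, K=K)
        sig = np.moveaxis(plain.images, 0, -1)
        proj = np.moveaxis(basis.project_signals(sig), -1, 0)
        assert nrmse(np.abs(proj), ref) < base_err
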