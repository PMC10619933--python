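"""Two-stage subspace-constrained compressed-sensing reconstruction.

The chain mirrors how accelerated multi-echo spin-echo data are
recovered in practice:

1. conventional CS: ``min_x 0.5||y - M F S x||^2 + lambda ||T(x)||_1``
   jointly over the echo train (wavelet thresholding applied per echo
   image);
2. a data-driven temporal subspace: SVD of the above-threshold voxel
   signals, truncated to K components;
3. subspace-constrained CS:
   ``min_a 0.5||y - M F S Phi_K a||^2 + lambda ||T(a)||_1``;
4. echo-image synthesis ``x = Phi_K a``.

Because undersampling artifacts are incoherent along the echo
dimension while true signal evolutions are strongly correlated, the
truncated subspace separates them: step 3 recovers what step 1 cannot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .operators import SenseOperator, fft2c, ifft2c, fista

__all__ = [
    "KSpaceData", "CoilMaps", "EchoImageSeries", "SubspaceBasis",
    "CoefficientImages", "ReconConfig", "estimate_coil_maps",
    "coil_compress", "cs_reconstruct", "build_subspace",
    "subspace_reconstruct", "synthesize_echo_images", "run_calipr",
    "nrmse",
]

log = logging.getLogger(__name__)


@dataclass
class KSpaceData:
    """Complex multi-coil multi-echo Cartesian samples.

    data: (coil, echo, phase, slice); zero wherever ``mask`` is false.
    """

    data: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    echo_times: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.shape[1:] != self.mask.shape:
            raise ValueError(
                f"data {self.data.shape} and mask {self.mask.shape} disagree"
            )
        if self.echo_times.size != self.mask.shape[0]:
            raise ValueError("echo_times length must equal the echo count")
        if np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo_times must be strictly increasing")
        if np.any(self.data[:, ~self.mask] != 0):
            raise ValueError("data must be zero at unsampled locations")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[2:]


@dataclass
class CoilMaps:
    """Coil sensitivity profiles, root-sum-of-squares 1 on the support."""

    maps: np.ndarray = field(repr=False)  # (coil, P, S)
    support: np.ndarray = field(repr=False)  # (P, S) boolean

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=complex)
        self.support = np.asarray(self.support, dtype=bool)
        if self.maps.shape[1:] != self.support.shape:
            raise ValueError("maps and support shapes disagree")


@dataclass
class EchoImageSeries:
    """Complex images at each echo time, (echo, phase, slice)."""

    images: np.ndarray = field(repr=False)
    echo_times: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=complex)
        if not np.all(np.isfinite(self.images)):
            raise ValueError("echo images contain non-finite values")


@dataclass
class SubspaceBasis:
    """Truncated orthonormal temporal basis Phi_K, (n_echoes, K)."""

    basis: np.ndarray = field(repr=False)
    singular_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=complex)
        gram = self.basis.conj().T @ self.basis
        if not np.allclose(gram, np.eye(self.K), atol=1e-10):
            raise ValueError("basis columns are not orthonormal")

    @property
    def K(self) -> int:
        return self.basis.shape[1]

    @property
    def n_echoes(self) -> int:
        return self.basis.shape[0]

    def project_signals(self, signals: np.ndarray) -> np.ndarray:
        """Project echo-train signals (..., n_echoes) onto the span."""
        coeff = signals @ self.basis.conj()
        return coeff @ self.basis.T


@dataclass
class CoefficientImages:
    """Subspace coefficient images alpha, (K, phase, slice)."""

    coeffs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=complex)
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coefficient images contain non-finite values")


@dataclass
class ReconConfig:
    """Reconstruction hyperparameters.

    lam
        L1 wavelet weight on the normalized k-space scale; 0.004 is the
        brain default, 0.001 the spinal-cord default.
    lam_step1
        Optional lighter weight for the step-1 calibration
        reconstruction whose images seed the subspace (``None`` uses
        ``lam`` for both steps).  Heavy step-1 shrinkage distorts echo
        shapes, which propagates into the learned basis.
    wavelet, wavelet_levels
        Spatial sparsifying transform (Daubechies-4, 3 levels,
        periodized).
    K
        Subspace size (12 by default: conservative, errs toward
        retaining noise rather than biasing signal).
    intensity_threshold_fraction
        First-echo magnitude threshold (fraction of the 99th
        percentile) used to pick voxels for subspace estimation and the
        coil-map support.
    n_virtual_coils
        Channels kept by SVD coil compression.
    """

    lam: float = 0.004
    lam_step1: float | None = None
    wavelet: str = "db4"
    wavelet_levels: int = 3
    max_iters: int = 100
    rel_tol: float = 1e-5
    K: int = 12
    intensity_threshold_fraction: float = 0.1
    n_virtual_coils: int = 8
    calib_shape: tuple[int, int] = (12, 12)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.K < 1:
            raise ValueError("K must be >= 1")


def nrmse(estimate: np.ndarray, reference: np.ndarray) -> float:
    """Normalized RMSE ``||est - ref|| / ||ref||``."""
    ref = np.asarray(reference)
    return float(np.linalg.norm(estimate - ref) / np.linalg.norm(ref))


def _calib_block(grid_shape: tuple[int, int],
                 calib_shape: tuple[int, int]) -> tuple[slice, slice]:
    p0 = (grid_shape[0] - calib_shape[0]) // 2
    s0 = (grid_shape[1] - calib_shape[1]) // 2
    return slice(p0, p0 + calib_shape[0]), slice(s0, s0 + calib_shape[1])


def estimate_coil_maps(kspace: KSpaceData,
                       calib_shape: tuple[int, int] = (12, 12),
                       threshold_fraction: float = 0.1) -> CoilMaps:
    """Estimate sensitivities from the fully sampled echo-1 calibration block.

    The block is apodized with a Hann window, zero-filled, and inverse
    transformed; per-coil low-resolution images are normalized by their
    root-sum-of-squares so the maps satisfy RSS = 1.  The support is
    where the RSS magnitude exceeds ``threshold_fraction`` of its peak;
    maps are zeroed outside it.
    """
    cp, cs = calib_shape
    if cp <= 0 or cs <= 0:
        raise ValueError("empty calibration region")
    ps, ss = _calib_block(kspace.grid_shape, calib_shape)
    if not kspace.mask[0, ps, ss].all():
        raise ValueError("echo-1 calibration region is not fully sampled")
    low = np.zeros((kspace.n_coils, *kspace.grid_shape), dtype=complex)
    window = np.outer(np.hanning(cp + 2)[1:-1], np.hanning(cs + 2)[1:-1])
    low[:, ps, ss] = kspace.data[:, 0, ps, ss] * window
    imgs = ifft2c(low)
    rss = np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0))
    support = rss > threshold_fraction * rss.max()
    maps = np.where(support, imgs / np.maximum(rss, 1e-30), 0)
    return CoilMaps(maps=maps, support=support)


def coil_compress(kspace: KSpaceData, n_virtual: int,
                  calib_shape: tuple[int, int] = (12, 12)) -> tuple[KSpaceData, float]:
    """SVD coil compression to ``n_virtual`` channels.

    The compression matrix is fitted on the fully sampled echo-1
    calibration samples (falling back to all sampled points if there is
    no calibration block) and applied to the complete dataset.

    Returns the compressed data and the retained energy fraction of the
    calibration matrix.
    """
    if n_virtual <= 0:
        raise ValueError("n_virtual must be positive")
    if n_virtual > kspace.n_coils:
        raise ValueError("n_virtual exceeds the number of physical coils")
    cp, cs = calib_shape
    if cp > 0 and cs > 0 and kspace.mask[0][_calib_block(kspace.grid_shape,
                                                         calib_shape)].all():
        ps, ss = _calib_block(kspace.grid_shape, calib_shape)
        calib = kspace.data[:, 0, ps, ss].reshape(kspace.n_coils, -1)
    else:
        calib = kspace.data[:, kspace.mask].reshape(kspace.n_coils, -1)
    u, s, _ = np.linalg.svd(calib, full_matrices=False)
    energy = float(np.sum(s[:n_virtual] ** 2) / max(np.sum(s**2), 1e-30))
    comp = u[:, :n_virtual].conj().T  # (n_virtual, n_coils)
    data = np.einsum("vc,ce...->ve...", comp, kspace.data)
    data = np.where(kspace.mask[None], data, 0)
    return KSpaceData(data=data, mask=kspace.mask.copy(),
                      echo_times=kspace.echo_times.copy()), energy


def _normalization_scale(kspace: KSpaceData, maps: CoilMaps) -> float:
    """99th-percentile magnitude of the coil-combined zero-filled echo-1 image."""
    imgs = ifft2c(kspace.data[:, 0])
    combined = np.abs(np.sum(maps.maps.conj() * imgs, axis=0))
    scale = float(np.percentile(combined, 99))
    return scale if scale > 0 else 1.0


def cs_reconstruct(kspace: KSpaceData, maps: CoilMaps,
                   config: ReconConfig | None = None,
                   return_trace: bool = False):
    """Step 1: conventional CS reconstruction of the whole echo train.

    Solves ``min_x 0.5||y - MFSx||^2 + lambda||T(x)||_1`` jointly over
    echoes with per-echo-image wavelet thresholding; k-space is
    normalized so the configured lambda scale is data independent.
    """
    config = config or ReconConfig()
    scale = _normalization_scale(kspace, maps)
    op = SenseOperator(maps=maps.maps, mask=kspace.mask)
    res = fista(op, kspace.data / scale, config.lam,
                x0=op.adjoint(kspace.data / scale),
                wavelet=config.wavelet, level=config.wavelet_levels,
                max_iters=config.max_iters, rel_tol=config.rel_tol)
    series = EchoImageSeries(images=res.x * scale, echo_times=kspace.echo_times)
    return (series, res) if return_trace else series


def build_subspace(series: EchoImageSeries,
                   K: int = 12,
                   intensity_threshold_fraction: float = 0.1) -> SubspaceBasis:
    """Step 2: data-driven temporal subspace by SVD of voxel signals.

    Voxels whose first-echo magnitude exceeds the threshold (fraction
    of the 99th percentile) form a (voxels x echoes) matrix; the first
    K right singular vectors span the retained signal-evolution
    subspace.
    """
    x = series.images
    n_echoes = x.shape[0]
    if K > n_echoes:
        raise ValueError(f"K={K} exceeds the echo count {n_echoes}")
    first = np.abs(x[0])
    thresh = intensity_threshold_fraction * np.percentile(first, 99)
    sel = first > thresh
    if not sel.any():
        raise ValueError("no voxels above the intensity threshold")
    signals = x[:, sel].T  # (voxels, echoes)
    _, s, vh = np.linalg.svd(signals, full_matrices=False)
    basis = vh[:K].conj().T  # (echoes, K)
    return SubspaceBasis(basis=basis, singular_values=s)


def subspace_reconstruct(kspace: KSpaceData, maps: CoilMaps,
                         basis: SubspaceBasis,
                         config: ReconConfig | None = None,
                         init: EchoImageSeries | None = None,
                         return_trace: bool = False):
    """Step 3: CS reconstruction constrained to the temporal subspace.

    Identical to step 1 except the unknowns are the K coefficient
    images; initialized from the subspace projection of ``init`` when
    provided.
    """
    config = config or ReconConfig()
    scale = _normalization_scale(kspace, maps)
    op = SenseOperator(maps=maps.maps, mask=kspace.mask, basis=basis.basis)
    if init is not None:
        a0 = op.contract(init.images / scale)
    else:
        a0 = op.adjoint(kspace.data / scale)
    res = fista(op, kspace.data / scale, config.lam, x0=a0,
                wavelet=config.wavelet, level=config.wavelet_levels,
                max_iters=config.max_iters, rel_tol=config.rel_tol)
    coeffs = CoefficientImages(coeffs=res.x * scale)
    return (coeffs, res) if return_trace else coeffs


def synthesize_echo_images(alpha: CoefficientImages,
                           basis: SubspaceBasis,
                           echo_times: np.ndarray | None = None) -> EchoImageSeries:
    """Step 4: expand coefficient images back to echo images, x = Phi_K a."""
    imgs = np.einsum("ek,k...->e...", basis.basis, alpha.coeffs)
    return EchoImageSeries(images=imgs, echo_times=echo_times)


@dataclass
class CaliprResult:
    """Full pipeline output with intermediates and diagnostics."""

    echo_images: EchoImageSeries
    coefficients: CoefficientImages
    basis: SubspaceBasis
    maps: CoilMaps
    step1_images: EchoImageSeries
    diagnostics: dict = field(default_factory=dict)


def run_calipr(kspace: KSpaceData, config: ReconConfig | None = None) -> CaliprResult:
    """Orchestrate coil handling and reconstruction steps 1-4.

    Deterministic: no randomness beyond the (seeded) power iteration,
    so repeated runs bit-compare.
    """
    config = config or ReconConfig()
    diagnostics: dict = {
        "achieved_fraction": float(kspace.mask.mean()),
        "n_coils_in": kspace.n_coils,
    }
    if kspace.n_coils > config.n_virtual_coils:
        kspace, energy = coil_compress(kspace, config.n_virtual_coils,
                                       config.calib_shape)
        diagnostics["coil_compression_energy"] = energy
    maps = estimate_coil_maps(kspace, config.calib_shape,
                              config.intensity_threshold_fraction)
    cfg1 = config if config.lam_step1 is None else replace(
        config, lam=config.lam_step1)
    step1, trace1 = cs_reconstruct(kspace, maps, cfg1, return_trace=True)
    basis = build_subspace(step1, config.K, config.intensity_threshold_fraction)
    alpha, trace3 = subspace_reconstruct(kspace, maps, basis, config,
                                         init=step1, return_trace=True)
    echo_images = synthesize_echo_images(alpha, basis, kspace.echo_times)
    diagnostics["step1_objective"] = trace1.objective
    diagnostics["step3_objective"] = trace3.objective
    diagnostics["singular_values"] = basis.singular_values
    return CaliprResult(echo_images=echo_images, coefficients=alpha,
                        basis=basis, maps=maps, step1_images=step1,
                        diagnostics=diagnostics)
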