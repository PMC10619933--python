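"""Linear operators and the FISTA solver used by the reconstructions.

The forward model is ``y = M F S x`` (mask, centered orthonormal 2D
FFT, coil sensitivity multiply), optionally lifted through a temporal
subspace ``x = Phi alpha`` so the unknowns are coefficient images.  The
adjoint is the exact conjugate transpose of each factor, which is what
makes proximal-gradient iterations and power-iteration step sizes
valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = ["fft2c", "ifft2c", "SenseOperator", "power_iteration",
           "soft_threshold_wavelet", "wavelet_l1_norm", "fista", "FistaResult"]


def fft2c(img: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D inverse FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


@dataclass
class SenseOperator:
    """Masked multi-coil Fourier operator, optionally subspace-lifted.

    forward: image tensor (echo, P, S) or coefficients (K, P, S) ->
    k-space (coil, echo, P, S).  With ``basis`` (n_echoes x K) the
    input is expanded along the echo axis first.
    """

    maps: np.ndarray  # (coil, P, S)
    mask: np.ndarray  # (echo, P, S) boolean
    basis: np.ndarray | None = None  # (n_echoes, K)

    @property
    def image_shape(self) -> tuple[int, ...]:
        n_img = self.basis.shape[1] if self.basis is not None else self.mask.shape[0]
        return (n_img, *self.mask.shape[1:])

    def expand(self, x: np.ndarray) -> np.ndarray:
        """Coefficient images -> echo images (identity without a basis)."""
        if self.basis is None:
            return x
        return np.einsum("ek,k...->e...", self.basis, x)

    def contract(self, x: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`expand`."""
        if self.basis is None:
            return x
        return np.einsum("ek,e...->k...", self.basis.conj(), x)

    def forward(self, x: np.ndarray) -> np.ndarray:
        imgs = self.expand(x)  # (echo, P, S)
        coil_imgs = self.maps[:, None] * imgs[None]  # (coil, echo, P, S)
        return np.where(self.mask[None], fft2c(coil_imgs), 0)

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        imgs = ifft2c(np.where(self.mask[None], y, 0))
        combined = np.sum(self.maps.conj()[:, None] * imgs, axis=0)
        return self.contract(combined)


def power_iteration(op: SenseOperator, n_iters: int = 30,
                    seed: int = 0) -> float:
    """Largest eigenvalue of ``A^H A`` (i.e. the squared operator norm)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(op.image_shape) + 1j * rng.standard_normal(op.image_shape)
    lam = 1.0
    for _ in range(n_iters):
        x = op.adjoint(op.forward(x))
        lam = np.linalg.norm(x)
        if lam == 0:
            return 0.0
        x /= lam
    return float(lam)


def _effective_level(shape: tuple[int, ...], wavelet: str, level: int) -> int:
    max_level = pywt.dwtn_max_level(shape, wavelet)
    return max(1, min(level, max_level))


def _wavelet_coeffs(img: np.ndarray, wavelet: str, level: int):
    level = _effective_level(img.shape, wavelet, level)
    return pywt.wavedec2(img, wavelet, mode="periodization", level=level)


def soft_threshold_wavelet(x: np.ndarray, thresh: float,
                           wavelet: str = "db4", level: int = 3) -> np.ndarray:
    """Proximal operator of ``thresh * ||T(.)||_1`` applied per 2D image.

    Complex coefficients are shrunk in magnitude; every wavelet band
    (including the approximation) is thresholded.
    """
    if thresh <= 0:
        return x
    out = np.empty_like(x)
    flat = x.reshape(-1, *x.shape[-2:])
    oflat = out.reshape(-1, *x.shape[-2:])
    for i in range(flat.shape[0]):
        coeffs = _wavelet_coeffs(flat[i], wavelet, level)
        shrunk = [_shrink(coeffs[0], thresh)]
        shrunk += [tuple(_shrink(b, thresh) for b in bands) for bands in coeffs[1:]]
        oflat[i] = pywt.waverec2(shrunk, wavelet, mode="periodization")[
            : flat.shape[-2], : flat.shape[-1]
        ]
    return out


def _shrink(w: np.ndarray, t: float) -> np.ndarray:
    mag = np.abs(w)
    return np.where(mag > t, w * (1 - t / np.maximum(mag, 1e-30)), 0)


def wavelet_l1_norm(x: np.ndarray, wavelet: str = "db4", level: int = 3) -> float:
    """Sum of absolute wavelet coefficients over all 2D images in ``x``."""
    total = 0.0
    flat = x.reshape(-1, *x.shape[-2:])
    for i in range(flat.shape[0]):
        coeffs = _wavelet_coeffs(flat[i], wavelet, level)
        total += float(np.abs(coeffs[0]).sum())
        total += float(sum(np.abs(b).sum() for bands in coeffs[1:] for b in bands))
    return total


@dataclass
class FistaResult:
    x: np.ndarray = field(repr=False)
    objective: list[float] = field(default_factory=list)
    n_iters: int = 0
    converged: bool = False
    step: float = 0.0


def fista(
    op: SenseOperator,
    y: np.ndarray,
    lam: float,
    x0: np.ndarray | None = None,
    wavelet: str = "db4",
    level: int = 3,
    max_iters: int = 100,
    rel_tol: float = 1e-5,
    monotone: bool = True,
) -> FistaResult:
    """FISTA for ``min 0.5||A x - y||^2 + lam ||T(x)||_1``.

    Step size is ``1 / L`` with ``L`` from power iteration on ``A^H A``.
    With ``monotone`` the momentum is restarted whenever a candidate
    step would increase the objective, so the trace is non-increasing.

    Raises
    ------
    FloatingPointError
        If the objective becomes non-finite (divergence), with the
        iteration number in the message.
    """
    L = power_iteration(op)
    if L <= 0:
        raise ValueError("operator has zero norm; nothing to reconstruct")
    step = 1.0 / (1.01 * L)  # small margin: power iteration underestimates L

    x = np.zeros(op.image_shape, dtype=complex) if x0 is None else x0.astype(complex)
    z = x.copy()
    t = 1.0

    def objective(v: np.ndarray) -> float:
        resid = op.forward(v) - y
        obj = 0.5 * float(np.vdot(resid, resid).real)
        if lam > 0:
            obj += lam * wavelet_l1_norm(v, wavelet, level)
        return obj

    def prox_grad(v: np.ndarray) -> np.ndarray:
        g = op.adjoint(op.forward(v) - y)
        return soft_threshold_wavelet(v - step * g, lam * step, wavelet, level)

    trace = [objective(x)]
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        cand = prox_grad(z)
        f_cand = objective(cand)
        if not np.isfinite(f_cand):
            raise FloatingPointError(
                f"FISTA diverged at iteration {it}: objective={f_cand!r}, "
                f"step={step:.3e}, lambda={lam:.3e}"
            )
        if monotone and f_cand > trace[-1]:
            # restart momentum from the current best iterate
            z = x.copy()
            t = 1.0
            cand = prox_grad(z)
            f_cand = objective(cand)
            if f_cand > trace[-1]:
                # a prox-gradient step from x cannot increase the objective
                # (descent lemma), so we are at the numerical floor: stop
                trace.append(trace[-1])
                converged = True
                break
        x_prev, x = x, cand
        trace.append(f_cand)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = x + ((t - 1.0) / t_next) * (x - x_prev)
        t = t_next
        denom = np.linalg.norm(x)
        if denom > 0 and np.linalg.norm(x - x_prev) / denom < rel_tol:
            converged = True
            break
    return FistaResult(x=x, objective=trace, n_iters=it, converged=converged,
                       step=step)
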