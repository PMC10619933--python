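"""Independent reference implementations used only as test oracles.

Each oracle takes a deliberately different route from the library code
it checks: Bloch isochromat ensemble vs EPG state recursion,
projected-gradient vs active-set NNLS, explicit ANOVA mean squares vs
the closed-form ICC, long-run ISTA vs FISTA.
"""

from __future__ import annotations

import numpy as np

from calipr.epg import SequenceParams


def bloch_mese(t2: float, seq: SequenceParams) -> np.ndarray:
    """Echo amplitudes from an isochromat-ensemble Bloch simulation.

    Simulates L equally spaced crusher phase angles with explicit 3x3
    rotation matrices (90deg excitation about y, refocusing about x),
    relaxation with T1 regrowth, and averages the transverse
    magnetization at each echo.  With L > 2*n_echoes+2 the discrete
    average equals the continuous isochromat integral exactly, so this
    matches the EPG recursion to machine precision while sharing none
    of its code.
    """
    n = seq.n_echoes
    L = 4 * n + 9
    theta = 2 * np.pi * np.arange(L) / L
    M = np.zeros((L, 3))
    M[:, 2] = 1.0

    def rot_y(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])

    def rot_x(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

    c, s = np.cos(theta), np.sin(theta)
    crush = np.zeros((L, 3, 3))
    crush[:, 0, 0] = c
    crush[:, 0, 1] = -s
    crush[:, 1, 0] = s
    crush[:, 1, 1] = c
    crush[:, 2, 2] = 1.0

    tau = seq.delta_te / 2.0
    e2, e1 = np.exp(-tau / t2), np.exp(-tau / seq.t1)

    def relax(M):
        M[:, 0] *= e2
        M[:, 1] *= e2
        M[:, 2] = M[:, 2] * e1 + (1 - e1)
        return M

    M = M @ rot_y(np.pi / 2).T
    refocus = rot_x(np.deg2rad(seq.refocus_flip))
    out = np.empty(n)
    for e in range(n):
        M = relax(M)
        M = np.einsum("lij,lj->li", crush, M)
        M = M @ refocus.T
        M = relax(M)
        M = np.einsum("lij,lj->li", crush, M)
        out[e] = abs((M[:, 0] + 1j * M[:, 1]).mean())
    return out


def projected_gradient_nnls(A: np.ndarray, d: np.ndarray,
                            n_iters: int = 200_000,
                            tol: float = 1e-14) -> np.ndarray:
    """Brute-force NNLS by projected gradient descent with fixed step."""
    L = np.linalg.norm(A, 2) ** 2
    s = np.zeros(A.shape[1])
    AtA = A.T @ A
    Atd = A.T @ d
    for _ in range(n_iters):
        s_new = np.maximum(s - (AtA @ s - Atd) / L, 0.0)
        if np.max(np.abs(s_new - s)) < tol:
            s = s_new
            break
        s = s_new
    return s


def ista_l1_wavelet(op, y, lam, wavelet, level, n_iters=3000):
    """Long-run ISTA (no momentum) for the L1-wavelet problem."""
    from calipr.operators import power_iteration, soft_threshold_wavelet

    step = 1.0 / power_iteration(op)
    x = np.zeros(op.image_shape, dtype=complex)
    for _ in range(n_iters):
        g = op.adjoint(op.forward(x) - y)
        x = soft_threshold_wavelet(x - step * g, lam * step, wavelet, level)
    return x


def anova_icc21(pairs: np.ndarray) -> float:
    """ICC(2,1) from an explicit two-way ANOVA table, cell by cell."""
    arr = np.asarray(pairs, dtype=float)
    n, k = arr.shape
    grand = arr.mean()
    ss_subj = sum(k * (arr[i].mean() - grand) ** 2 for i in range(n))
    ss_exam = sum(n * (arr[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((arr[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_subj - ss_exam
    msr = ss_subj / (n - 1)
    msc = ss_exam / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
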