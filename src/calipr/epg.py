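"""Extended phase graph (EPG) simulation of multi-echo spin-echo decay.

The EPG formalism tracks configuration states :math:`F^+_k, F^-_k, Z_k`
(transverse and longitudinal magnetization at integer dephasing orders
``k``) through the pulse train.  At refocusing flip angles below 180°,
magnetization is shuttled through longitudinal states and returns as
stimulated echoes, so the measured echo amplitudes deviate from a pure
:math:`\\exp(-TE/T_2)` decay.  Capturing this contamination is what makes
joint flip-angle / T2-spectrum estimation possible.

Conventions: ideal 90° excitation about y, refocusing pulses about x
(the CPMG condition: refocusing axis orthogonal to the excitation
axis), one unit of crusher dephasing per half echo spacing.  T1
relaxation (with regrowth of :math:`Z_0`) is included;
repetition-time saturation is not (long-TR assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SequenceParams", "DecayCurve", "epg_mese", "epg_mese_matrix"]


@dataclass(frozen=True)
class SequenceParams:
    """Multi-echo spin-echo timing and pulse parameters.

    Parameters
    ----------
    n_echoes : int
        Number of refocusing pulses / echoes (>= 1).
    delta_te : float
        Echo spacing in ms (> 0).  Echo ``i`` (1-based) occurs at
        ``i * delta_te``.
    refocus_flip : float
        Refocusing flip angle in degrees, in (0, 180].
    excite_flip : float
        Excitation flip angle in degrees; fixed at 90 in this model.
    t1 : float
        Longitudinal relaxation time in ms (> 0).  Default 1000 ms.
    """

    n_echoes: int = 56
    delta_te: float = 6.0
    refocus_flip: float = 180.0
    excite_flip: float = 90.0
    t1: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_echoes < 1:
            raise ValueError("n_echoes must be >= 1")
        if self.delta_te <= 0:
            raise ValueError(f"delta_te must be positive, got {self.delta_te}")
        if not (0 < self.refocus_flip <= 180):
            raise ValueError(
                f"refocus_flip must be in (0, 180], got {self.refocus_flip}"
            )
        if self.t1 <= 0:
            raise ValueError(f"t1 must be positive, got {self.t1}")

    @property
    def echo_times(self) -> np.ndarray:
        """Echo times in ms, ``delta_te .. n_echoes*delta_te``."""
        return self.delta_te * np.arange(1, self.n_echoes + 1)


@dataclass(frozen=True)
class DecayCurve:
    """Echo-train amplitudes for unit initial magnetization."""

    amplitudes: np.ndarray = field(repr=False)
    t2: float = 0.0
    seq: SequenceParams | None = None

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "amplitudes", amps)


def _refocus_matrix(flip_deg: float) -> np.ndarray:
    """Complex 3x3 mixing matrix for a refocusing pulse about x.

    Acts on stacked (F+, F-, Z) states at each dephasing order.
    """
    a = np.deg2rad(flip_deg)
    c2, s2, sa, ca = (
        np.cos(a / 2) ** 2,
        np.sin(a / 2) ** 2,
        np.sin(a),
        np.cos(a),
    )
    return np.array(
        [
            [c2, s2, -1j * sa],
            [s2, c2, 1j * sa],
            [-0.5j * sa, 0.5j * sa, ca],
        ]
    )


def epg_mese_matrix(t2_values: np.ndarray, seq: SequenceParams) -> np.ndarray:
    """Echo amplitudes for many T2 values at once.

    Parameters
    ----------
    t2_values : array of float
        T2 relaxation times in ms, all > 0.
    seq : SequenceParams

    Returns
    -------
    ndarray, shape (n_echoes, len(t2_values))
        ``|F_0|`` after each refocusing period; column ``j`` is the decay
        curve for ``t2_values[j]``.
    """
    t2 = np.atleast_1d(np.asarray(t2_values, dtype=float))
    if np.any(t2 <= 0):
        raise ValueError("all T2 values must be positive")
    n = seq.n_echoes
    tau = seq.delta_te / 2.0
    e2 = np.exp(-tau / t2)  # (m,)
    e1 = np.exp(-tau / seq.t1)
    rot = _refocus_matrix(seq.refocus_flip)

    n_orders = n + 2  # k = 0 .. n+1; lossless truncation for CPMG
    m = t2.size
    fp = np.zeros((n_orders, m), dtype=complex)
    fm = np.zeros((n_orders, m), dtype=complex)
    z = np.zeros((n_orders, m), dtype=complex)
    # ideal 90° excitation about y: all magnetization transverse at order 0
    fp[0] = 1.0
    fm[0] = 1.0  # F-_0 is the conjugate partner of F+_0 (real here)

    out = np.empty((n, m))
    for e in range(n):
        _relax_shift(fp, fm, z, e2, e1)
        # refocusing pulse mixes (F+, F-, Z) at every order
        fp, fm, z = (
            rot[0, 0] * fp + rot[0, 1] * fm + rot[0, 2] * z,
            rot[1, 0] * fp + rot[1, 1] * fm + rot[1, 2] * z,
            rot[2, 0] * fp + rot[2, 1] * fm + rot[2, 2] * z,
        )
        _relax_shift(fp, fm, z, e2, e1)
        out[e] = np.abs(fp[0])
    return out


def _relax_shift(fp: np.ndarray, fm: np.ndarray, z: np.ndarray,
                 e2: np.ndarray, e1: float) -> None:
    """In-place relaxation over half an echo spacing plus one dephasing shift."""
    fp *= e2
    fm *= e2
    z *= e1
    z[0] += 1.0 - e1  # T1 regrowth feeds the k=0 longitudinal state
    # crusher: F(k) <- F(k-1); across k=0, F+_0 picks up the conjugate branch
    fp[1:] = fp[:-1]
    fp[0] = np.conj(fm[1])
    fm[:-1] = fm[1:]
    fm[-1] = 0.0


def epg_mese(t2: float, seq: SequenceParams) -> DecayCurve:
    """Simulate one multi-echo spin-echo decay curve.

    At ``refocus_flip=180`` this reduces to ``exp(-TE_i / t2)`` exactly;
    at lower flips stimulated-echo pathways raise the late-echo
    amplitudes above the pure exponential.

    Parameters
    ----------
    t2 : float
        Transverse relaxation time in ms (> 0).
    seq : SequenceParams

    Returns
    -------
    DecayCurve
        Amplitudes in [0, 1] for unit initial magnetization.
    """
    if t2 <= 0:
        raise ValueError(f"t2 must be positive, got {t2}")
    amps = epg_mese_matrix(np.array([t2]), seq)[:, 0]
    return DecayCurve(amplitudes=amps, t2=float(t2), seq=seq)
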