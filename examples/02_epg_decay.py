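"""Simulate multi-echo spin-echo decay with stimulated-echo contamination.

Compares the echo train of a 100 ms T2 pool under ideal 180-degree
refocusing with the same pool at 150 degrees, where stimulated echoes
raise the late-echo amplitudes above the pure exponential.
"""

import numpy as np

from calipr.epg import SequenceParams, epg_mese

seq_ideal = SequenceParams(n_echoes=10, delta_te=10.0, refocus_flip=180.0)
seq_low = SequenceParams(n_echoes=10, delta_te=10.0, refocus_flip=150.0)

ideal = epg_mese(100.0, seq_ideal).amplitudes
low = epg_mese(100.0, seq_low).amplitudes
pure = np.exp(-seq_ideal.echo_times / 100.0)

print("TE (ms) | 180 deg  | 150 deg  | exp(-TE/T2)")
for te, a, b, p in zip(seq_ideal.echo_times, ideal, low, pure):
    print(f"{te:7.0f} | {a:.6f} | {b:.6f} | {p:.6f}")
print(f"\nmax |180 deg - exponential| = {np.abs(ideal - pure).max():.2e}")
print(f"first-echo attenuation at 150 deg: "
      f"{(1 - low[0] / pure[0]) * 100:.1f}%")
print(f"max |150 deg - exponential| across the train: "
      f"{np.abs(low - pure).max():.4f}")
# At 180 degrees the train is exactly exponential. At 150 degrees part
# of the magnetization is stored longitudinally and returns as
# stimulated echoes: the first echo is attenuated and an even/odd
# modulation appears. The T2 fit must model this to avoid flip-angle
# bias leaking into the spectrum.
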