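"""Vocode a synthetic AM tone and show where the output energy lands.

A 1 kHz tone, 100% amplitude-modulated at 10 Hz, is passed through an
8-channel noise vocoder (equal-octave bands over 200-7900 Hz). Because all
the input energy sits in one analysis band, nearly all vocoded energy
should re-emerge from that band's noise carrier.
"""

import numpy as np
from scipy.signal import periodogram

from vocsim import AudioSignal, VocoderParams, vocode

fs = 16000.0
t = np.arange(int(fs)) / fs
signal = AudioSignal((1 + np.sin(2 * np.pi * 10 * t)) * np.sin(2 * np.pi * 1000 * t), fs)

params = VocoderParams(n_channels=8, carrier_seed=7)
out = vocode(signal, params)

edges = params.band_edges()
freq, pxx = periodogram(out.samples, fs)
print("band (Hz)            energy fraction")
for k in range(edges.n_bands):
    lo, hi = edges.band(k)
    frac = pxx[(freq >= lo) & (freq < hi)].sum() / pxx.sum()
    mark = "  <- contains 1 kHz" if lo <= 1000 < hi else ""
    print(f"{lo:7.1f} - {hi:7.1f}   {frac:7.1%}{mark}")
print(f"\noutput duration {out.duration:.2f} s, RMS preserved: "
      f"{out.rms() / signal.rms():.6f}x input")
# The band containing 1 kHz should hold the large majority of the energy;
# neighbours get only filter-skirt leakage.
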