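"""Dynamic-range limiting and dB quantization acting on an envelope.

A toy single-channel envelope spanning 60 dB is first limited to a 40 dB
dynamic range (everything more than 40 dB below the maximum is zeroed, the
floor here being 0.01), then quantized to 3 levels equally spaced in dB
(0, -20 and -40 dB re max). Implant users have a limited electric dynamic
range and a limited number of discriminable loudness steps; these two
stages simulate exactly that.
"""

import numpy as np

from vocsim import EnvelopeMatrix, limit_dynamic_range, quantize_envelopes
from vocsim.vocoder import quantization_levels

env = EnvelopeMatrix(np.array([[1.0, 0.30, 0.05, 0.011, 0.009, 0.001]]), 16000.0)
print("input envelope:  ", env.values[0])

limited = limit_dynamic_range(env, 40.0)
print("after 40 dB limit:", limited.values[0], "  (values < 0.01 zeroed)")

quantized = quantize_envelopes(limited, 3, 40.0)
print("after 3-step quant:", quantized.values[0])
print("level set:         ", quantization_levels(env.global_max(), 40.0, 3))
# Each retained value snaps to the nearest level in dB; zeros stay zero.
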