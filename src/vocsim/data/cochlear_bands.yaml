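# Default frequency-allocation boundaries (Hz) for the Cochlear Ltd.
# standard 22-channel map (188-7938 Hz), as published in device
# documentation. Keys are channel counts; values are the N+1 band edges.
# Override or extend with a user YAML of the same shape.
22: [188, 313, 438, 563, 688, 813, 938, 1063, 1188, 1313, 1563, 1813,
     2063, 2313, 2688, 3063, 3563, 4063, 4688, 5313, 6063, 6938, 7938]
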