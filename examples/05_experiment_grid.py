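"""A small end-to-end experiment: condition grid, vocoding, scoring.

Three synthetic stimuli are run through a 2 x 2 grid (4 vs 8 channels,
quiet vs 5 dB speech-shaped noise) with 3 repetitions each. The recognizer
is the scripted mock with a mild error model, so scores fall below 100%
and vary across repetitions — the spread the repetition design exists to
measure. A real evaluation would swap in an ASR adapter
(vocsim.adapters.WhisperRecognizer) behind the same contract.
"""

from vocsim import (
    ErrorModel,
    Stimulus,
    SynthSpec,
    build_condition_grid,
    mock_recognizer,
    run_experiment,
    summarize,
    synth_stimulus,
)

stimuli = []
for i in range(3):
    sig, _ = synth_stimulus(SynthSpec(f0=150.0 + 40.0 * i, am_rate=4.0 + i,
                                      duration=0.4, seed=i))
    stimuli.append(Stimulus(f"s{i}", sig, f"now hear token number {i}"))

grid = build_condition_grid({
    "sweep": {"n_channels": [4, 8]},
    "noise": {"snrs": ["quiet", 5]},
})

recognizer = mock_recognizer(
    {s.id: s.transcript for s in stimuli},
    errors=ErrorModel(p_sub=0.1, p_del=0.1, seed=2),
)
result = run_experiment(stimuli, grid, recognizer, reps=3, base_seed=11)
table = summarize(result)
print(table[["label", "snr", "mean_percent", "sd_percent", "n_reps"]]
      .to_string(index=False))
# One row per condition: mean percent correct over repetitions and the
# sample SD capturing recognizer variability.
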