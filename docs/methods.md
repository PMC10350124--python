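# Methods

This note records the signal-processing and scoring model implemented by
`vocsim`, the choices made where the design was genuinely open, and what
the synthetic test material does and does not demonstrate.

## Vocoder chain

**Filterbank.** Analysis and synthesis use the same N non-overlapping
Butterworth band-passes, realized as second-order-section cascades for
numerical stability in narrow, near-Nyquist bands. "6th-order band-pass" is
read as 6 poles total (a 3rd-order prototype doubled by the band
transformation), the common convention in vocoder implementations;
`FilterSpec(prototype_doubling=True)` selects the 12-pole reading.
Filtering is causal (forward-only), mirroring real-time implant
processing; `FilterSpec(zero_phase=True)` switches to zero-phase
filtering for users who prefer delay-free envelopes.

Equal-octave edges follow f_k = f_low·(f_high/f_low)^(k/N). The
Cochlear-standard mode ships the published 22-channel frequency-allocation
boundaries (188–7938 Hz) as editable YAML package data; the interior
boundaries for other channel counts are not standardized, so other counts
require a user-supplied table rather than a silent guess.

Sampling-rate policy: band edges must lie strictly below Nyquist, and
full-bandwidth settings (top edge ≥ 7900 Hz) require fs ≥ 16 kHz; lower
rates are rejected rather than resampled, so a mistake in stimulus
preparation surfaces as an error, not a silently narrowed simulation.

**Envelopes.** Half-wave rectification followed by a 4-pole Butterworth
low-pass (default cutoff 100 Hz, tunable 5–400 Hz in standard practice).
Small negative post-filter ripple is clamped to zero so envelopes are
valid modulators. Causal smoothing delays the envelope by the filter group
delay (≈15–20 ms at a 50 Hz cutoff); envelope-recovery checks therefore
correlate at the best non-negative lag (`delay_compensated_correlation`)
instead of sample-aligned.

**Dynamic-range limiting.** Envelope level is amplitude dB (20·log₁₀). The
range top M is the maximum envelope value over *all* channels and samples
of the stimulus, computed after extraction and before any degradation;
values strictly below M·10^(−DR/20) are zeroed, values exactly at the
floor are retained. Any positive DR is accepted (standard practice sweeps
roughly 10–150 dB; the grid builder warns outside that range, or raises in
strict mode).

**Quantization.** S levels equally spaced in dB over [M_dB − DR, M_dB],
endpoints included for S ≥ 2; S = 1 collapses every retained value to M.
This reads "dividing the dynamic range into equal dB steps" as levels
including both endpoints with step DR/(S−1); the alternative (levels as
bin centers, S counting intervals) is a one-line change to
`quantization_levels` if ever needed. Rounding is nearest-in-dB with exact
midpoints going to the louder level (a deterministic tie-break). Zeros
stay zero. Quantizing with an unbounded ("full") dynamic range is an
invalid combination — equal dB steps are undefined over an infinite span —
so a finite DR must accompany finite steps. Degradation order is fixed:
limiting, then quantization. Note that the final synthesis band-pass
slightly smears the stepwise envelopes, so the vocoded waveform is not
exactly piecewise-level.

**Synthesis and level.** Each channel's carrier is an independent
white-noise stream derived from the carrier seed via `SeedSequence`
spawning, so a fixed seed gives bit-identical output while channels remain
mutually uncorrelated. The carrier is band-passed before and after
envelope multiplication, confining modulation sidebands to the channel.
The summed output is rescaled to the input RMS so presentation level is
comparable across conditions.

## Speech-shaped noise and SNR

The noise generator measures the reference long-term average spectrum by
Welch's method (averaging over multiple reference signals, resampling them
to the output rate when needed), designs a linear-phase FIR via the
frequency-sampling method (`firwin2`, default 1025 taps — ≈16 Hz spectral
resolution at 16 kHz), and filters seeded white noise, trimming the filter
warm-up so the requested duration is exact and steady-state. SNR mixing
solves the noise gain in closed form from full-extent RMS values, so the
realized SNR equals the request to numerical precision; "quiet" bypasses
mixing entirely. The harness mixes noise *before* vocoding by default
(the mixture is what the simulated processor hears), with
`mix_before_vocoding=False` available for the post-vocoder alternative.
RMS is computed over the full file, not speech-active segments — the
simplest reproducible definition.

## Scoring

Text cleaning removes every punctuation character (apostrophes and hyphens
included, so "don't" → "dont"), lower-cases, and splits on whitespace.

Sentence scoring counts common words per sentence as a **multiset**
intersection (a repeated word credits only up to its transcript count) and
pools counts over the sentence set; word order is ignored.

Word-list scoring is positional after list-length equalization. While the
recognizer result and transcript differ in length, each single word of the
longer list is trial-deleted, the positional-match similarity of the
remainder is computed, and the deletion with the highest similarity is
made permanent, leftmost winning ties; deletions always come from the
longer list since only it can shrink to equality. The similarity used
inside the search is the same positional-match count as the final score —
the most self-consistent choice. The greedy search is exact on the
overwhelming majority of small instances but not all: an exhaustive sweep
over every pair with both lists ≤ 6 tokens, length difference ≤ 2, over a
3-token alphabet (1,129,296 pairs) finds it matches the brute-force
optimum on >99% of pairs and never exceeds it; the shortfall cases are
enumerated by the test suite. `brute_force_alignment_score` is the exact
reference, exponential in the surplus and guarded by a size limit.

Homophone matching compares phoneme sequences after stripping lexical
stress digits. The default backend is a compact hand-curated pronouncing
lexicon (~90 words covering common homophone sets) bundled with the
package; out-of-lexicon words fall back to spelling comparison, and a
backend exception falls back likewise with a warning. Users can plug in a
full grapheme-to-phoneme model through the same one-callable interface
(`vocsim.adapters.G2pEnBackend`).

## Experiment harness

A condition grid is the Cartesian product of swept vocoder parameters and
noise conditions, in a canonical parameter order so grids are
deterministic. Unswept parameters take the standard defaults: equal-octave
bands over 200–7900 Hz, 100 Hz envelope cutoff, full dynamic range,
continuous envelopes, and 8 channels (the plateau region of
channel-number sweeps) when channel count itself is not swept.

Each condition × repetition derives its carrier seed deterministically
from the base seed, so a rerun with a deterministic recognizer reproduces
the results table bit-for-bit. By default each repetition regenerates the
carriers *and* re-queries the recognizer — repetition spread then reflects
both carrier and recognizer variability; `fixed_stimuli=True` freezes
carriers so only recognizer stochasticity remains. A recognizer failure on
a stimulus is logged and scored as an empty transcription rather than
aborting a long run. Summaries report mean, sample SD (0 for a single
repetition) and SEM per condition, since either spread measure may be
wanted.

## Synthetic test material

The fixtures generate amplitude-modulated harmonic complexes with
analytically known modulators, fixed-length word-list audio (clips plus
gaps zero-padded to 30 s, matching recognizers that consume fixed
30-second windows), and a scripted deterministic mock recognizer with an
optional seeded substitution/deletion/insertion error model. These verify
envelope recovery, spectral confinement, SNR accuracy, scoring and
harness plumbing end to end without any licensed speech corpus or model
download. They do **not** demonstrate recognition accuracy on real speech:
absolute percent-correct values with real materials depend on the corpus,
the recognizer and its decoding settings, and must be measured with a real
adapter (e.g. `WhisperRecognizer`).

Default problem sizes in tests and examples are desk-scale (seconds of
16 kHz audio, grids of a handful of conditions, 1,092 exhaustive
word-list transcripts); the library itself has no scale limits beyond
memory.

## Known limitations

- No tone-vocoder carriers, FFT-bin (ACE-style) filterbanks, gammatone
  filterbanks, or channel-interaction (current-spread) simulation.
- No compressive amplitude mapping at synthesis; dynamic-range limiting
  removes low-level envelope content rather than compressing it.
- The bundled pronunciation lexicon is intentionally small; large-scale
  homophone scoring should use a full g2p backend.
- Babble and other non-stationary maskers are supported only as
  user-supplied noise files, not generated.
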