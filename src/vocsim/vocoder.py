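"""Noise-vocoder core: envelope extraction, envelope degradations, synthesis.

The processing chain simulates implant sound coding acoustically:

1. split the input into N band-pass channels (:mod:`vocsim.filterbank`);
2. half-wave rectify and low-pass filter each channel to get its envelope;
3. optionally degrade the envelopes — zero values more than ``dr_db`` below
   the stimulus-global maximum (dynamic-range limiting), then round retained
   values to a grid of levels equally spaced in dB (quantization, simulating
   a limited number of discriminable loudness steps);
4. multiply band-limited white-noise carriers by the envelopes, band-pass
   again, and sum.

Envelope level is amplitude dB throughout (20·log10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

from .audio import AudioSignal
from .filterbank import (
    BandEdges,
    FilterSpec,
    _apply,
    _bandpass_sos,
    check_edges_against_fs,
    cochlear_edges,
    equal_octave_edges,
)

FULL_RANGE = "full"
INFINITE_STEPS = "infinite"

#: Channel counts exercised in auditory-implant practice (4–22 electrodes).
STANDARD_CHANNEL_COUNTS = (4, 6, 8, 10, 12, 16, 22)


@dataclass(frozen=True)
class EnvelopeMatrix:
    """N × T matrix of non-negative channel envelopes at sample rate ``fs``."""

    values: np.ndarray = field(repr=False)
    fs: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"envelope matrix must be 2-D; got shape {arr.shape}")
        if arr.size == 0:
            raise ValueError("envelope matrix must be non-empty")
        if np.any(arr < 0):
            raise ValueError("envelope values must be non-negative")
        object.__setattr__(self, "values", arr)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def global_max(self) -> float:
        """Maximum envelope value across all channels and samples."""
        return float(self.values.max())


@dataclass(frozen=True)
class VocoderParams:
    """Full parameter record for one vocoder condition.

    Defaults follow the standard simulation configuration: equal-octave
    bands over 200–7900 Hz, 100 Hz envelope cutoff, full dynamic range and
    continuous (non-quantized) envelopes — i.e. the classic noise vocoder.
    """

    n_channels: int
    edge_mode: Literal["equal_octave", "cochlear_standard"] = "equal_octave"
    f_low: float = 200.0
    f_high: float = 7900.0
    env_cutoff: float = 100.0
    dynamic_range_db: float | str = FULL_RANGE
    quant_steps: int | str = INFINITE_STEPS
    carrier_seed: int = 0
    filter_spec: FilterSpec = field(default_factory=FilterSpec)

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.env_cutoff <= 0:
            raise ValueError("env_cutoff must be positive")
        if self.dynamic_range_db != FULL_RANGE and not (
            isinstance(self.dynamic_range_db, (int, float)) and self.dynamic_range_db > 0
        ):
            raise ValueError(
                f"dynamic_range_db must be positive or {FULL_RANGE!r}; "
                f"got {self.dynamic_range_db!r}"
            )
        if self.quant_steps != INFINITE_STEPS and not (
            isinstance(self.quant_steps, int) and self.quant_steps >= 1
        ):
            raise ValueError(
                f"quant_steps must be an integer >= 1 or {INFINITE_STEPS!r}; "
                f"got {self.quant_steps!r}"
            )

    def band_edges(self) -> BandEdges:
        if self.edge_mode == "equal_octave":
            return equal_octave_edges(self.f_low, self.f_high, self.n_channels)
        if self.edge_mode == "cochlear_standard":
            return cochlear_edges(self.n_channels)
        raise ValueError(f"unknown edge_mode: {self.edge_mode!r}")

    def with_seed(self, seed: int) -> "VocoderParams":
        return replace(self, carrier_seed=int(seed))


def extract_envelopes(
    channels: Sequence[AudioSignal], env_cutoff: float, spec: FilterSpec | None = None
) -> EnvelopeMatrix:
    """Half-wave rectify and low-pass filter each channel.

    The smoother is a causal Butterworth low-pass (``spec.lowpass_order``
    poles, default 4) at ``env_cutoff`` Hz. Residual negative filter ripple
    is clamped to zero so the result is a valid envelope.
    """
    spec = spec or FilterSpec()
    if not channels:
        raise ValueError("need at least one channel signal")
    fs = channels[0].fs
    if any(c.fs != fs for c in channels):
        raise ValueError("all channels must share one sampling rate")
    if env_cutoff >= fs / 2.0:
        raise ValueError(
            f"envelope cutoff {env_cutoff} Hz must lie below Nyquist ({fs / 2:.0f} Hz)"
        )
    sos = sps.butter(spec.lowpass_order, env_cutoff, btype="low", fs=fs, output="sos")
    rows = []
    for ch in channels:
        rect = np.maximum(ch.samples, 0.0)
        env = _apply(sos, rect, spec.zero_phase)
        rows.append(np.maximum(env, 0.0))
    return EnvelopeMatrix(np.vstack(rows), fs)


def limit_dynamic_range(env: EnvelopeMatrix, dr_db: float | str) -> EnvelopeMatrix:
    """Zero envelope values more than ``dr_db`` below the global maximum.

    The top of the dynamic range is the maximum envelope value across ALL
    channels of the stimulus; any value whose level relative to that maximum
    falls below ``-dr_db`` is set to zero. ``dr_db="full"`` is the identity.
    """
    if dr_db == FULL_RANGE:
        return env
    dr = float(dr_db)
    if dr <= 0:
        raise ValueError(f"dynamic range must be positive dB; got {dr}")
    m = env.global_max()
    if m == 0.0:
        return env
    floor = m * 10.0 ** (-dr / 20.0)
    out = np.where(env.values < floor, 0.0, env.values)
    return EnvelopeMatrix(out, env.fs)


def quantization_levels(global_max: float, dr_db: float, n_steps: int) -> np.ndarray:
    """Quantized envelope levels: ``n_steps`` values equally spaced in dB
    over ``[max_dB - dr_db, max_dB]`` (both endpoints included for
    ``n_steps >= 2``; a single step sits at the maximum)."""
    if n_steps < 1:
        raise ValueError(f"number of quantization steps must be >= 1; got {n_steps}")
    if dr_db <= 0:
        raise ValueError(f"dynamic range must be positive dB; got {dr_db}")
    max_db = 20.0 * math.log10(global_max)
    if n_steps == 1:
        levels_db = np.array([max_db])
    else:
        levels_db = max_db - dr_db + np.arange(n_steps) * (dr_db / (n_steps - 1))
    return 10.0 ** (levels_db / 20.0)


def quantize_envelopes(
    env: EnvelopeMatrix, n_steps: int | str, dr_db: float | str
) -> EnvelopeMatrix:
    """Round nonzero envelope values to the nearest quantized level.

    Levels divide the envelope dynamic range into equal dB steps (see
    :func:`quantization_levels`); rounding is nearest-in-dB with midpoints
    going to the louder level. Zeros (values already removed by the
    dynamic-range floor) stay zero. ``n_steps="infinite"`` is the identity.
    """
    if n_steps == INFINITE_STEPS:
        return env
    if not isinstance(n_steps, int) or n_steps < 1:
        raise ValueError(f"quantization steps must be an integer >= 1; got {n_steps!r}")
    if dr_db == FULL_RANGE:
        raise ValueError(
            "quantization requires a finite dynamic range: equal dB steps are "
            "undefined over an unbounded range"
        )
    m = env.global_max()
    if m == 0.0:
        return env
    levels = quantization_levels(m, float(dr_db), n_steps)
    levels_db = 20.0 * np.log10(levels)
    nz = env.values > 0
    out = np.zeros_like(env.values)
    if nz.any():
        v_db = 20.0 * np.log10(env.values[nz])
        mids = (levels_db[:-1] + levels_db[1:]) / 2.0
        # side="right": an exact midpoint rounds to the louder level
        idx = np.searchsorted(mids, v_db, side="right")
        out[nz] = levels[idx]
    return EnvelopeMatrix(out, env.fs)


def synthesize(
    env: EnvelopeMatrix,
    edges: BandEdges,
    spec: FilterSpec | None = None,
    seed: int = 0,
) -> AudioSignal:
    """Impose channel envelopes on band-limited noise carriers and sum.

    Each channel gets an independent white-noise carrier (deterministically
    derived from ``seed``), band-passed to the channel range, multiplied
    sample-wise by the channel envelope, band-passed again to confine
    modulation sidebands, then all channels are summed.
    """
    spec = spec or FilterSpec()
    if env.n_channels != edges.n_bands:
        raise ValueError(
            f"envelope has {env.n_channels} channels but the filterbank has "
            f"{edges.n_bands} bands"
        )
    check_edges_against_fs(edges, env.fs)
    streams = np.random.SeedSequence(seed).spawn(env.n_channels)
    total = np.zeros(env.n_samples)
    for k in range(env.n_channels):
        rng = np.random.default_rng(streams[k])
        carrier = rng.standard_normal(env.n_samples)
        lo, hi = edges.band(k)
        sos = _bandpass_sos(lo, hi, env.fs, spec)
        carrier = _apply(sos, carrier, spec.zero_phase)
        modulated = carrier * env.values[k]
        total += _apply(sos, modulated, spec.zero_phase)
    return AudioSignal(total, env.fs)


def degrade_envelopes(env: EnvelopeMatrix, params: VocoderParams) -> EnvelopeMatrix:
    """Apply the two envelope degradations in their fixed order:
    dynamic-range limiting first, then quantization."""
    env = limit_dynamic_range(env, params.dynamic_range_db)
    return quantize_envelopes(env, params.quant_steps, params.dynamic_range_db)


def vocode(signal: AudioSignal, params: VocoderParams) -> AudioSignal:
    """Run the full vocoder chain on a mono signal.

    split → envelope extraction → dynamic-range limiting → quantization →
    noise synthesis. The output has the input's length and is rescaled to
    the input's RMS so presentation level is comparable across conditions.
    With ``dynamic_range_db="full"`` and ``quant_steps="infinite"`` the
    degradation stages are identities and this is the classic noise vocoder.
    """
    from .filterbank import split_bands  # local to avoid cycle at import time

    edges = params.band_edges()
    channels = split_bands(signal, edges, params.filter_spec)
    env = extract_envelopes(channels, params.env_cutoff, params.filter_spec)
    env = degrade_envelopes(env, params)
    out = synthesize(env, edges, params.filter_spec, params.carrier_seed)
    in_rms, out_rms = signal.rms(), out.rms()
    if in_rms > 0 and out_rms > 0:
        out = out.scaled(in_rms / out_rms)
    return out
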