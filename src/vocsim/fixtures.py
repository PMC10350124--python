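"""Synthetic test signals and a scriptable mock recognizer.

Clinical sentence and word corpora (AzBio, CNC, IEEE) are licensed and
cannot ship with a package, and a real speech-recognition model is a heavy
optional dependency. This module provides substitutes sufficient to
exercise and verify every pipeline stage: amplitude-modulated harmonic
complexes with analytically known envelopes, concatenated "word-list"
clips, and a deterministic recognizer whose output is scripted (optionally
corrupted by a seeded substitution/deletion/insertion error model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .audio import AudioSignal
from .scoring import WordSequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of an amplitude-modulated harmonic complex.

    ``f0`` and ``n_harmonics`` set the spectral content (all harmonics must
    stay below Nyquist); ``am_rate``/``am_depth`` set the sinusoidal
    modulator, which doubles as the analytically known envelope for
    envelope-recovery tests.
    """

    f0: float = 200.0
    n_harmonics: int = 10
    am_rate: float = 8.0
    am_depth: float = 1.0
    duration: float = 1.0
    fs: float = 16000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.n_harmonics < 1:
            raise ValueError("need f0 > 0 and n_harmonics >= 1")
        if not 0.0 <= self.am_depth <= 1.0:
            raise ValueError(f"am_depth must lie in [0, 1]; got {self.am_depth}")
        if self.f0 * self.n_harmonics >= self.fs / 2.0:
            raise ValueError(
                f"highest harmonic {self.f0 * self.n_harmonics:.0f} Hz aliases "
                f"at fs={self.fs:.0f} Hz"
            )
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")


def synth_stimulus(spec: SynthSpec) -> tuple[AudioSignal, np.ndarray]:
    """Synthesize an AM harmonic complex and return (signal, ideal envelope).

    The waveform is ``m(t) * sum_k sin(2π k f0 t + φ_k)`` with random
    harmonic phases (seeded) and modulator
    ``m(t) = 1 + am_depth · sin(2π am_rate t)``; the returned envelope is
    ``m(t)`` itself.
    """
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    phases = rng.uniform(0, 2 * np.pi, size=spec.n_harmonics)
    carrier = np.zeros(n)
    for k in range(1, spec.n_harmonics + 1):
        carrier += np.sin(2 * np.pi * k * spec.f0 * t + phases[k - 1])
    carrier /= spec.n_harmonics
    modulator = 1.0 + spec.am_depth * np.sin(2 * np.pi * spec.am_rate * t)
    return AudioSignal(modulator * carrier, spec.fs), modulator


def build_word_list_audio(
    clips: Sequence[tuple[AudioSignal, str]],
    gap: float = 0.2,
    total: float = 30.0,
) -> tuple[AudioSignal, WordSequence]:
    """Concatenate word clips with silent gaps into one fixed-length list.

    Word recognizers typically process fixed 30-second windows, so word
    tests present lists per clip rather than single words; shorter content
    is zero-padded to exactly ``total`` seconds. Returns the audio and the
    transcript in presentation order.
    """
    if not clips:
        raise ValueError("need at least one clip")
    fs = clips[0][0].fs
    if any(c.fs != fs for c, _ in clips):
        raise ValueError("all clips must share one sampling rate")
    gap_n = int(round(gap * fs))
    total_n = int(round(total * fs))
    pieces, tokens = [], []
    for i, (clip, token) in enumerate(clips):
        if i:
            pieces.append(np.zeros(gap_n))
        pieces.append(clip.samples)
        tokens.append(token)
    body = np.concatenate(pieces)
    if body.size > total_n:
        raise ValueError(
            f"clips + gaps span {body.size / fs:.2f} s, exceeding the "
            f"{total:.2f} s list duration"
        )
    out = np.zeros(total_n)
    out[: body.size] = body
    return AudioSignal(out, fs), WordSequence(tokens)


def delay_compensated_correlation(
    x: np.ndarray, y: np.ndarray, max_lag_samples: int
) -> float:
    """Maximum Pearson correlation between ``x`` and ``y`` over non-negative
    integer lags of ``x``.

    Causal filtering delays a recovered envelope relative to the true
    modulator by the filter group delay; envelope-recovery checks therefore
    compare at the best lag rather than sample-aligned.
    """
    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
        return float(np.dot(a, b) / denom) if denom > 0 else 0.0

    n = min(x.size, y.size)
    best = -1.0
    for lag in range(0, max_lag_samples + 1):
        if n - lag < 2:
            break
        best = max(best, _corr(x[lag:n], y[: n - lag]))
    return best


@dataclass(frozen=True)
class ErrorModel:
    """Seeded token-level corruption: substitution, deletion, insertion.

    Emulates recognizer failure modes — missing words, or hearing one word
    as several — with per-token probabilities. Insertions draw from
    ``vocabulary`` and are placed after the affected token.
    """

    p_sub: float = 0.0
    p_del: float = 0.0
    p_ins: float = 0.0
    vocabulary: tuple[str, ...] = ("gah", "bah", "dah")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_del", "p_ins"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability; got {p}")

    def corrupt(self, words: Sequence[str], rng: np.random.Generator) -> list[str]:
        out: list[str] = []
        for w in words:
            if rng.random() < self.p_del:
                continue
            if rng.random() < self.p_sub:
                w = str(rng.choice(self.vocabulary))
            out.append(w)
            if rng.random() < self.p_ins:
                out.append(str(rng.choice(self.vocabulary)))
        return out


class MockRecognizer:
    """Deterministic scripted recognizer conforming to the recognizer
    contract: ``transcribe(audio, stimulus_id) -> raw text``.

    Returns the scripted text for each stimulus id, optionally corrupted by
    an :class:`ErrorModel` (re-seeded per call from the model seed and the
    call count, so repeated runs of a whole experiment are reproducible).
    Unknown stimuli yield an empty transcription and a log message.
    """

    def __init__(
        self,
        script: Mapping[str, str],
        errors: Optional[ErrorModel] = None,
        name: str = "mock",
    ) -> None:
        self.script = dict(script)
        self.errors = errors
        self.name = name
        self.stochastic = False  # fully determined by (stimulus_id, call count)
        self._calls = 0

    def transcribe(self, audio: AudioSignal, stimulus_id: str | None = None) -> str:
        self._calls += 1
        if stimulus_id is None or stimulus_id not in self.script:
            logger.warning("mock recognizer: unknown stimulus %r", stimulus_id)
            return ""
        text = self.script[stimulus_id]
        if self.errors is None:
            return text
        rng = np.random.default_rng(
            np.random.SeedSequence((self.errors.seed, self._calls))
        )
        return " ".join(self.errors.corrupt(text.split(), rng))


def mock_recognizer(
    script: Mapping[str, str], errors: Optional[ErrorModel] = None
) -> MockRecognizer:
    """Build a scripted :class:`MockRecognizer` (identity when ``errors`` is
    None: the experiment scores 100% on a clean pipeline)."""
    return MockRecognizer(script, errors)
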