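"""Optional adapters to external recognizers and g2p backends.

These wrap third-party models behind the package's contracts. None of them
is required by the test suite; each imports its dependency lazily and
raises a clear error when it is missing.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .audio import AudioSignal


class WhisperRecognizer:
    """Adapter for the openai-whisper speech recognizer.

    Requires the ``whisper`` package (``pip install openai-whisper``).
    Whisper decodes probabilistically by default, so repeated calls on the
    same audio may differ — the experiment harness's repetitions exist to
    average over exactly that.
    """

    stochastic = True

    def __init__(self, model_name: str = "base", **decode_options) -> None:
        try:
            import whisper  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the openai-whisper package is not installed; "
                "install it to use WhisperRecognizer"
            ) from exc
        import whisper

        self.name = f"whisper-{model_name}"
        self._model = whisper.load_model(model_name)
        self._options = decode_options

    def transcribe(self, audio: AudioSignal, stimulus_id: str | None = None) -> str:
        import numpy as np

        samples = audio.samples.astype("float32")
        if audio.fs != 16000:
            from scipy.signal import resample_poly

            up, down = 16000, int(round(audio.fs))
            g = np.gcd(up, down)
            samples = resample_poly(samples, up // g, down // g).astype("float32")
        out = self._model.transcribe(samples, **self._options)
        return out["text"]


class G2pEnBackend:
    """Grapheme-to-phoneme backend using the g2p-en package, usable as the
    ``phonetic`` argument of :func:`vocsim.scoring.words_match`."""

    def __init__(self) -> None:
        try:
            from g2p_en import G2p
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the g2p-en package is not installed; install it or use the "
                "built-in lexicon (vocsim.phonetics.builtin_lexicon_g2p)"
            ) from exc
        self._g2p = G2p()

    def __call__(self, word: str) -> Optional[Sequence[str]]:
        phones = [p for p in self._g2p(word) if p.strip() and p != " "]
        return tuple(phones) or None
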