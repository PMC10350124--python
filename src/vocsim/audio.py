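"""Mono audio container and WAV I/O.

All DSP in this package operates on :class:`AudioSignal`: a float64 sample
vector plus a sampling rate in Hz. Files are read and written as mono WAV
(PCM16 or float32) via :mod:`scipy.io.wavfile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile


@dataclass(frozen=True)
class AudioSignal:
    """A mono audio signal.

    Parameters
    ----------
    samples : ndarray
        1-D float array of sample values.
    fs : float
        Sampling rate in Hz.
    """

    samples: np.ndarray = field(repr=False)
    fs: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1:
            raise ValueError(f"audio must be mono (1-D); got shape {arr.shape}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive; got {self.fs}")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.fs

    @property
    def nyquist(self) -> float:
        return self.fs / 2.0

    def rms(self) -> float:
        """Root-mean-square amplitude over the full extent."""
        if self.samples.size == 0:
            return 0.0
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def scaled(self, gain: float) -> "AudioSignal":
        return AudioSignal(self.samples * gain, self.fs)


def read_wav(path: str | Path) -> AudioSignal:
    """Read a mono WAV file (PCM16, PCM32, or float32/64).

    Integer PCM is rescaled to [-1, 1).
    """
    fs, data = wavfile.read(str(path))
    if data.ndim == 2:
        if data.shape[1] != 1:
            raise ValueError(
                f"{path}: expected mono audio, got {data.shape[1]} channels"
            )
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return AudioSignal(data, float(fs))


def write_wav(path: str | Path, signal: AudioSignal, *, subtype: str = "float32") -> None:
    """Write a mono WAV file.

    Parameters
    ----------
    subtype : {"float32", "pcm16"}
        Sample encoding. PCM16 clips to [-1, 1] before scaling.
    """
    if subtype == "float32":
        wavfile.write(str(path), int(round(signal.fs)), signal.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(signal.samples, -1.0, 1.0)
        wavfile.write(
            str(path), int(round(signal.fs)), np.round(clipped * 32767.0).astype(np.int16)
        )
    else:
        raise ValueError(f"unsupported WAV subtype: {subtype!r}")
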