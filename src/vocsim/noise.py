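"""Speech-shaped noise generation and SNR mixing.

Speech-shaped noise (SSN) is noise whose long-term average spectrum (LTAS)
matches that of speech; presenting vocoded speech in SSN at a fixed SNR is
the standard adverse-listening condition in implant simulations. The
generator here filters seeded white noise through a linear-phase FIR filter
designed from the reference LTAS (measured by Welch's method from reference
signals, or supplied directly as a spectrum target).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy import signal as sps

from .audio import AudioSignal

QUIET = "quiet"


@dataclass(frozen=True)
class SpectrumTarget:
    """A long-term average spectrum: frequencies (Hz) and relative levels (dB)."""

    frequencies: np.ndarray = field(repr=False)
    levels_db: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=np.float64)
        l = np.asarray(self.levels_db, dtype=np.float64)
        if f.ndim != 1 or f.size < 2 or f.size != l.size:
            raise ValueError("need matching 1-D frequency and level arrays (>= 2 points)")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(l)):
            raise ValueError("levels must be finite")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "levels_db", l)


def ltas(signal: AudioSignal, nperseg: int = 2048) -> SpectrumTarget:
    """Long-term average spectrum of a signal via Welch's method (amplitude dB)."""
    f, pxx = sps.welch(signal.samples, fs=signal.fs, nperseg=min(nperseg, len(signal)))
    pxx = np.maximum(pxx, np.max(pxx) * 1e-12)
    return SpectrumTarget(f, 10.0 * np.log10(pxx))


def _target_from_reference(
    reference: Union[SpectrumTarget, Sequence[AudioSignal]],
    fs: float,
    nperseg: int,
) -> SpectrumTarget:
    if isinstance(reference, SpectrumTarget):
        return reference
    refs = list(reference)
    if not refs:
        raise ValueError("reference must be a SpectrumTarget or a non-empty "
                         "sequence of audio signals")
    psds = []
    freqs = None
    for sig in refs:
        x = sig.samples
        if sig.fs != fs:
            # bring the reference to the output rate so the PSD grid matches
            up, down = int(round(fs)), int(round(sig.fs))
            g = np.gcd(up, down)
            x = sps.resample_poly(x, up // g, down // g)
        f, pxx = sps.welch(x, fs=fs, nperseg=min(nperseg, x.size))
        freqs = f
        psds.append(pxx)
    mean_psd = np.mean(np.vstack(psds), axis=0)
    mean_psd = np.maximum(mean_psd, np.max(mean_psd) * 1e-12)
    return SpectrumTarget(freqs, 10.0 * np.log10(mean_psd))


def speech_shaped_noise(
    reference: Union[SpectrumTarget, Sequence[AudioSignal]],
    duration: float,
    fs: float,
    seed: int = 0,
    *,
    numtaps: int = 1025,
    nperseg: int = 2048,
) -> AudioSignal:
    """Generate noise whose LTAS matches a reference spectrum.

    Parameters
    ----------
    reference : SpectrumTarget or sequence of AudioSignal
        Target spectrum, or speech signals whose average Welch PSD defines it.
    duration : float
        Output duration in seconds (exact to the sample).
    fs : float
        Output sampling rate in Hz.
    seed : int
        Seed for the white-noise source; fixed seed gives identical samples.
    numtaps : int
        Length of the linear-phase shaping filter (odd; controls spectral
        resolution of the match).
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive; got {duration}")
    target = _target_from_reference(reference, fs, nperseg)
    n = int(round(duration * fs))

    nyq = fs / 2.0
    grid = np.linspace(0.0, nyq, 512)
    levels = np.interp(grid, target.frequencies, target.levels_db,
                       left=target.levels_db[0], right=target.levels_db[-1])
    gains = 10.0 ** (levels / 20.0)  # PSD dB -> amplitude response
    gains /= gains.max()
    if numtaps % 2 == 0:
        numtaps += 1
    fir = sps.firwin2(numtaps, grid, gains, fs=fs)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    white = rng.standard_normal(n + numtaps)
    shaped = sps.fftconvolve(white, fir, mode="full")
    # drop the filter's group delay and warm-up so the extent is steady-state
    start = numtaps - 1
    shaped = shaped[start:start + n]
    shaped /= np.sqrt(np.mean(shaped**2))
    return AudioSignal(shaped, fs)


def mix_at_snr(
    speech: AudioSignal, noise: AudioSignal, snr_db: float | str
) -> AudioSignal:
    """Add noise to speech at a requested SNR.

    The noise is scaled so ``20*log10(rms_speech / rms_noise) = snr_db``,
    with RMS computed over the full stimulus extent, then added sample-wise.
    ``snr_db="quiet"`` returns the speech unchanged. Noise must be at least
    as long as the speech and is trimmed to match.
    """
    if snr_db == QUIET:
        return speech
    if speech.fs != noise.fs:
        raise ValueError(
            f"sampling rates differ: speech {speech.fs} Hz vs noise {noise.fs} Hz"
        )
    if len(noise) < len(speech):
        raise ValueError("noise must be at least as long as the speech")
    snr = float(snr_db)
    noise_seg = noise.samples[: len(speech)]
    s_rms = speech.rms()
    n_rms = float(np.sqrt(np.mean(noise_seg**2)))
    if n_rms == 0:
        raise ValueError("noise signal is silent")
    gain = (s_rms / n_rms) * 10.0 ** (-snr / 20.0)
    return AudioSignal(speech.samples + gain * noise_seg, speech.fs)


def measure_snr(speech: AudioSignal, scaled_noise: AudioSignal) -> float:
    """SNR in dB between two aligned components (full-extent RMS)."""
    n = scaled_noise.samples[: len(speech)]
    return 20.0 * float(
        np.log10(speech.rms() / np.sqrt(np.mean(n**2)))
    )
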