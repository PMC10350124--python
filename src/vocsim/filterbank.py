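"""Channel frequency boundaries and band-pass analysis filtering.

A vocoder channel simulates one implant electrode: a band of the acoustic
spectrum whose envelope will drive a noise carrier. This module computes
channel boundaries two ways — equal-octave spacing over a requested range,
and the standard frequency-allocation table of Cochlear Ltd. devices — and
performs the band-pass analysis split with cascaded Butterworth filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import signal as sps

from .audio import AudioSignal

#: Minimum sampling rate accepted when the top band edge reaches the
#: full-bandwidth settings (7900 / 7938 Hz). Lower-rate inputs are rejected
#: rather than silently resampled.
MIN_FS_FULL_RANGE = 16000.0


@dataclass(frozen=True)
class BandEdges:
    """Strictly increasing boundary frequencies of N non-overlapping bands.

    ``edges`` holds N+1 frequencies in Hz; band ``k`` spans
    ``edges[k]``–``edges[k+1]``.
    """

    edges: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.edges, dtype=np.float64)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("band edges need at least two boundary frequencies")
        if arr[0] <= 0:
            raise ValueError("all band edges must be positive")
        if not np.all(np.diff(arr) > 0):
            raise ValueError("band edges must be strictly increasing")
        object.__setattr__(self, "edges", arr)

    @property
    def n_bands(self) -> int:
        return self.edges.size - 1

    def band(self, k: int) -> tuple[float, float]:
        return float(self.edges[k]), float(self.edges[k + 1])

    def band_containing(self, freq: float) -> int:
        """Index of the band containing ``freq`` (errors if outside range)."""
        if not (self.edges[0] <= freq <= self.edges[-1]):
            raise ValueError(f"{freq} Hz lies outside the filterbank range")
        return int(min(np.searchsorted(self.edges, freq, side="right") - 1,
                       self.n_bands - 1))


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter orders for the analysis/synthesis chain.

    ``bandpass_order`` counts the total poles of each band-pass filter
    (6 poles = a 3rd-order low/high prototype pair); ``lowpass_order`` is the
    pole count of the envelope smoother. ``prototype_doubling`` selects the
    alternative reading where a "6th-order band-pass" means a 6th-order
    prototype (12 poles). ``zero_phase`` switches from causal (forward-only,
    as in real-time implant processing) to zero-phase filtering.
    """

    bandpass_order: int = 6
    lowpass_order: int = 4
    prototype_doubling: bool = False
    zero_phase: bool = False

    def __post_init__(self) -> None:
        for name in ("bandpass_order", "lowpass_order"):
            v = getattr(self, name)
            if v <= 0 or v % 2 != 0:
                raise ValueError(f"{name} must be a positive even integer; got {v}")

    @property
    def bandpass_poles(self) -> int:
        return self.bandpass_order * (2 if self.prototype_doubling else 1)


def equal_octave_edges(f_low: float, f_high: float, n: int) -> BandEdges:
    """Band boundaries with equal width in octaves.

    The overall range ``[f_low, f_high]`` is converted to octaves and split
    into ``n`` equal parts, so ``edges[k] = f_low * (f_high/f_low)**(k/n)``
    and successive edges share a constant ratio.
    """
    if f_low <= 0 or f_high <= f_low:
        raise ValueError(
            f"need 0 < f_low < f_high; got f_low={f_low}, f_high={f_high}"
        )
    if n < 1:
        raise ValueError(f"channel count must be >= 1; got {n}")
    k = np.arange(n + 1, dtype=np.float64)
    edges = f_low * (f_high / f_low) ** (k / n)
    edges[0], edges[-1] = f_low, f_high  # exact endpoints
    return BandEdges(edges)


def _default_band_tables() -> dict[int, list[float]]:
    path = resources.files("vocsim.data").joinpath("cochlear_bands.yaml")
    with path.open("r") as fh:
        raw = yaml.safe_load(fh)
    return {int(k): [float(v) for v in vals] for k, vals in raw.items()}


def load_band_table(path: str | Path) -> dict[int, list[float]]:
    """Load a user band-table config: ``{n_channels: [edge list in Hz]}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {int(k): [float(v) for v in vals] for k, vals in raw.items()}


def cochlear_edges(n: int, tables: dict[int, Sequence[float]] | None = None) -> BandEdges:
    """Device-standard channel boundaries (Cochlear Ltd. allocation).

    The bundled table covers the full 22-channel allocation (188–7938 Hz);
    other channel counts require a user-supplied table via ``tables`` or
    :func:`load_band_table`.
    """
    table = dict(_default_band_tables())
    if tables:
        table.update({int(k): list(v) for k, v in tables.items()})
    if n not in table:
        raise ValueError(
            f"no device band table for {n} channels; bundled tables cover "
            f"{sorted(table)} — supply one via `tables` or a YAML config"
        )
    edges = np.asarray(table[n], dtype=np.float64)
    if edges.size != n + 1:
        raise ValueError(
            f"band table for {n} channels must list {n + 1} edges; got {edges.size}"
        )
    return BandEdges(edges)


def _bandpass_sos(lo: float, hi: float, fs: float, spec: FilterSpec) -> np.ndarray:
    # scipy's bandpass design doubles the prototype order, so a 6-pole
    # band-pass comes from a 3rd-order prototype.
    order = spec.bandpass_poles // 2
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _apply(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    return sps.sosfiltfilt(sos, x) if zero_phase else sps.sosfilt(sos, x)


def check_edges_against_fs(edges: BandEdges, fs: float) -> None:
    """Validate that a filterbank is realizable at sampling rate ``fs``."""
    nyq = fs / 2.0
    if edges.edges[-1] >= nyq:
        raise ValueError(
            f"top band edge {edges.edges[-1]:.0f} Hz is at or above the "
            f"Nyquist frequency ({nyq:.0f} Hz)"
        )
    if edges.edges[-1] >= 7900.0 and fs < MIN_FS_FULL_RANGE:
        raise ValueError(
            f"full-range filterbanks (top edge >= 7900 Hz) require "
            f"fs >= {MIN_FS_FULL_RANGE:.0f} Hz; got {fs:.0f} Hz"
        )


def split_bands(
    signal: AudioSignal, edges: BandEdges, spec: FilterSpec | None = None
) -> list[AudioSignal]:
    """Pass a signal through N non-overlapping band-pass filters.

    Returns one :class:`AudioSignal` per band, each the same length as the
    input. Filters are Butterworth cascades realized as second-order
    sections for numerical stability in narrow high-frequency bands; by
    default they run causally (forward only).
    """
    spec = spec or FilterSpec()
    if len(signal) == 0:
        raise ValueError("cannot filter an empty signal")
    check_edges_against_fs(edges, signal.fs)
    out = []
    for k in range(edges.n_bands):
        lo, hi = edges.band(k)
        sos = _bandpass_sos(lo, hi, signal.fs, spec)
        out.append(AudioSignal(_apply(sos, signal.samples, spec.zero_phase), signal.fs))
    return out
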