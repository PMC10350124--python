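"""Condition grids and the vocoder → noise → recognizer → scorer harness.

A *condition* is one vocoder parameter set crossed with one listening
condition (quiet or a noise SNR) and a test material (sentences or word
lists). The harness runs every stimulus through noise mixing (optional),
vocoding and a recognizer, scores the output with the material-appropriate
grader, repeats each condition a configurable number of times (repetitions
capture recognizer stochasticity and fresh noise carriers), and aggregates
mean and spread per condition.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .audio import AudioSignal
from .noise import QUIET, mix_at_snr, speech_shaped_noise
from .scoring import (
    Matcher,
    ScoreResult,
    align_and_score_words,
    clean_text,
    homophone_matcher,
    score_sentences,
)
from .vocoder import STANDARD_CHANNEL_COUNTS, VocoderParams, vocode

logger = logging.getLogger(__name__)

SENTENCES = "sentences"
WORD_LISTS = "word_lists"

#: Canonical sweep order so grids are deterministic regardless of dict order.
_SWEEPABLE = (
    "n_channels",
    "edge_mode",
    "f_low",
    "f_high",
    "env_cutoff",
    "dynamic_range_db",
    "quant_steps",
)

# Parameter ranges exercised in standard simulation practice; values outside
# warn (default) or raise (strict).
_RANGES = {
    "n_channels": set(STANDARD_CHANNEL_COUNTS),
    "f_low": (188.0, 2000.0),
    "f_high": (2000.0, 7938.0),
    "env_cutoff": (5.0, 400.0),
    "dynamic_range_db": (10.0, 150.0),
    "quant_steps": (1, 100),
}


@runtime_checkable
class Recognizer(Protocol):
    """Contract any audio→text recognizer adapter must satisfy."""

    name: str
    stochastic: bool

    def transcribe(self, audio: AudioSignal, stimulus_id: str | None = None) -> str:
        ...


@dataclass(frozen=True)
class Stimulus:
    """One test item: audio plus its reference transcript."""

    id: str
    audio: AudioSignal
    transcript: str


@dataclass(frozen=True)
class Condition:
    params: VocoderParams
    snr: float | str = QUIET
    material: str = SENTENCES
    label: str = ""

    def describe(self) -> dict:
        p = self.params
        return {
            "label": self.label,
            "n_channels": p.n_channels,
            "edge_mode": p.edge_mode,
            "f_low": p.f_low,
            "f_high": p.f_high,
            "env_cutoff": p.env_cutoff,
            "dynamic_range_db": p.dynamic_range_db,
            "quant_steps": p.quant_steps,
            "snr": self.snr,
            "material": self.material,
        }


@dataclass
class ExperimentResult:
    """Per-condition repetition scores with consistency-checked aggregates."""

    conditions: list[Condition]
    scores: dict[str, list[ScoreResult]] = field(default_factory=dict)

    def percents(self, label: str) -> np.ndarray:
        return np.array([s.percent for s in self.scores[label]])

    def mean_percent(self, label: str) -> float:
        return float(np.mean(self.percents(label)))

    def sd_percent(self, label: str) -> float:
        p = self.percents(label)
        return float(np.std(p, ddof=1)) if p.size > 1 else 0.0

    def sem_percent(self, label: str) -> float:
        p = self.percents(label)
        return self.sd_percent(label) / math.sqrt(p.size) if p.size else 0.0


def _check_range(name: str, value, strict: bool) -> None:
    rng = _RANGES.get(name)
    if rng is None or isinstance(value, str):  # "full" / "infinite" / modes
        return
    if isinstance(rng, set):
        ok = value in rng
    else:
        ok = rng[0] <= value <= rng[1]
    if not ok:
        msg = f"{name}={value!r} lies outside the standard simulation range {rng}"
        if strict:
            raise ValueError(msg)
        logger.warning(msg)


def build_condition_grid(config: dict) -> list[Condition]:
    """Build the Cartesian product of swept vocoder parameters × noise
    conditions from an experiment config.

    Config keys: ``sweep`` (parameter → list of values; at least one
    parameter required), ``defaults`` (overrides for unswept parameters),
    ``noise.snrs`` (list of dB values and/or ``"quiet"``; default quiet
    only), ``material``, ``strict`` (out-of-range values raise instead of
    warning). Ordering is deterministic: parameters in canonical order,
    values in listed order, noise conditions last.
    """
    sweep = config.get("sweep") or {}
    unknown = set(sweep) - set(_SWEEPABLE)
    if unknown:
        raise ValueError(f"unknown sweep parameters: {sorted(unknown)}")
    if not sweep:
        raise ValueError("experiment config must sweep at least one parameter")
    if any(len(v) == 0 for v in sweep.values()):
        raise ValueError("every swept parameter needs at least one value")
    strict = bool(config.get("strict", False))
    defaults = dict(config.get("defaults") or {})
    material = config.get("material", SENTENCES)
    if material not in (SENTENCES, WORD_LISTS):
        raise ValueError(f"material must be {SENTENCES!r} or {WORD_LISTS!r}")
    snrs = (config.get("noise") or {}).get("snrs", [QUIET])
    if not snrs:
        raise ValueError("noise.snrs must list at least one condition")

    base = {"n_channels": 8}
    base.update(defaults)
    swept = [p for p in _SWEEPABLE if p in sweep]
    combos = itertools.product(*(sweep[p] for p in swept))
    conditions = []
    for values in combos:
        assignment = dict(base)
        assignment.update(dict(zip(swept, values)))
        for name, value in assignment.items():
            _check_range(name, value, strict)
        params = VocoderParams(**assignment)
        for snr in snrs:
            tag = "quiet" if snr == QUIET else f"snr{snr}"
            label = "_".join(
                [f"{p}={assignment[p]}" for p in swept] + [tag]
            )
            conditions.append(
                Condition(params=params, snr=snr, material=material, label=label)
            )
    labels = [c.label for c in conditions]
    if len(set(labels)) != len(labels):
        raise ValueError("condition labels are not unique")
    return conditions


def total_presentations(n_stimuli: int, reps: int, n_conditions: int) -> int:
    """Planned stimulus presentations: stimuli × repetitions × conditions."""
    return n_stimuli * reps * n_conditions


def _derived_seed(base_seed: int, *indices: int) -> int:
    ss = np.random.SeedSequence((int(base_seed),) + tuple(int(i) for i in indices))
    return int(ss.generate_state(1)[0] % (2**31))


def _score_repetition(
    texts: Sequence[str],
    stimuli: Sequence[Stimulus],
    material: str,
    matcher: Optional[Matcher],
) -> ScoreResult:
    results = [clean_text(t) for t in texts]
    refs = [clean_text(s.transcript) for s in stimuli]
    if material == SENTENCES:
        return score_sentences(results, refs, matcher)
    total = ScoreResult(0, 0)
    for res, ref in zip(results, refs):
        total = total + align_and_score_words(res, ref, matcher)
    return total


def run_experiment(
    stimuli: Sequence[Stimulus],
    grid: Sequence[Condition],
    recognizer: Recognizer,
    reps: int = 5,
    base_seed: int = 0,
    *,
    noise: AudioSignal | None = None,
    homophones: bool = True,
    fixed_stimuli: bool = False,
    mix_before_vocoding: bool = True,
) -> ExperimentResult:
    """Run every condition × repetition and collect per-repetition scores.

    Each repetition regenerates the vocoded stimulus with a fresh carrier
    seed derived from ``base_seed`` (frozen across repetitions when
    ``fixed_stimuli`` is set) and re-queries the recognizer, so repetition
    spread reflects both carrier and recognizer variability. Noise defaults
    to speech-shaped noise matched to the stimulus set's own spectrum; pass
    ``noise`` to use other maskers (e.g. babble). By default the
    speech+noise mixture is vocoded; ``mix_before_vocoding=False`` adds
    noise to the vocoded speech instead. A recognizer failure on a stimulus
    is scored as an empty transcription and the run continues.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not stimuli:
        raise ValueError("need at least one stimulus")
    matcher = homophone_matcher() if homophones else None
    needs_noise = any(c.snr != QUIET for c in grid)
    if needs_noise and noise is None:
        max_dur = max(s.audio.duration for s in stimuli)
        fs = stimuli[0].audio.fs
        noise = speech_shaped_noise(
            [s.audio for s in stimuli], max_dur + 0.1, fs,
            seed=_derived_seed(base_seed, 0xA5),
        )

    result = ExperimentResult(conditions=list(grid))
    for ci, cond in enumerate(grid):
        rep_scores = []
        for ri in range(reps):
            carrier_seed = _derived_seed(base_seed, ci, 0 if fixed_stimuli else ri)
            params = cond.params.with_seed(carrier_seed)
            texts = []
            for s in stimuli:
                audio = s.audio
                if cond.snr != QUIET and mix_before_vocoding:
                    audio = mix_at_snr(audio, noise, cond.snr)
                audio = vocode(audio, params)
                if cond.snr != QUIET and not mix_before_vocoding:
                    audio = mix_at_snr(audio, noise, cond.snr)
                try:
                    texts.append(recognizer.transcribe(audio, s.id))
                except Exception:
                    logger.exception(
                        "recognizer %s failed on %s; scoring empty output",
                        getattr(recognizer, "name", "?"), s.id,
                    )
                    texts.append("")
            rep_scores.append(
                _score_repetition(texts, stimuli, cond.material, matcher)
            )
            logger.info(
                "condition %s rep %d/%d: %.1f%%",
                cond.label, ri + 1, reps, rep_scores[-1].percent,
            )
        result.scores[cond.label] = rep_scores
    return result


def summarize(result: ExperimentResult) -> pd.DataFrame:
    """One row per condition: parameters, mean percent correct, sample SD,
    standard error of the mean, and repetition count."""
    if not result.conditions or not result.scores:
        raise ValueError("experiment result is empty")
    rows = []
    for cond in result.conditions:
        reps = result.scores[cond.label]
        if not reps:
            raise ValueError(f"condition {cond.label} has no repetitions")
        row = cond.describe()
        row.update(
            mean_percent=result.mean_percent(cond.label),
            sd_percent=result.sd_percent(cond.label),
            sem_percent=result.sem_percent(cond.label),
            n_reps=len(reps),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def save_results(
    result: ExperimentResult, csv_path: str | Path, json_path: str | Path | None = None
) -> None:
    """Write the per-condition summary as CSV and (optionally) the full
    per-repetition scores as JSON."""
    summarize(result).to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            label: [
                {"n_correct": s.n_correct, "n_total": s.n_total, "percent": s.percent}
                for s in reps
            ]
            for label, reps in result.scores.items()
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
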