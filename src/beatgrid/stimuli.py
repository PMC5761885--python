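"""Stimulus assembly: condition-matched pair concatenation and rendering.

Each experimental trial concatenates two *different* rhythms from the same
condition into a 32-grid rhythm and appends a closing tone, for 33 grid
positions in total; grid isochronicity is preserved across the joins.  Trials
are rendered as onset schedules (time in ms, level in dB relative to the
accented-intensity reference) and optionally as WAV audio.

Levels: intensity rhythms alternate accented tones at the reference level
with unaccented tones 8.5 dB softer; temporal rhythms are equated for overall
loudness by playing every tone 0.8 dB below the reference.  The closing tone
is an isolated (hence accented) tone and is rendered at the accented level of
its trial type.  Each rhythm is preceded by 500 ms of silence, and one of
five inter-onset intervals (140–160 ms) is assigned per trial, centred on
the optimal beat rate of 600 ms (ioi 150 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .grid import EnumeratedSpace

__all__ = [
    "SILENT", "UNACCENTED", "ACCENTED",
    "StimulusTrial", "OnsetSchedule", "ClickSpec", "ExperimentConfig",
    "EXP1_CONFIG", "EXP2_CONFIG",
    "build_experiment_stimuli", "schedule_onsets", "render_wav",
    "trials_to_frame",
]

SILENT, UNACCENTED, ACCENTED = 0, 1, 2

#: trials per used condition (table order) and accent type
EXP1_TRIAL_COUNTS: dict[tuple[int, int], int] = {
    (0, 0): 24, (1, 0): 15, (1, 1): 15, (1, 2): 15, (2, 1): 15,
    (2, 2): 15, (2, 3): 15, (3, 3): 12, (3, 4): 12, (3, 5): 10,
}
EXP2_TRIAL_COUNTS: dict[tuple[int, int], int] = {
    (0, 0): 28, (1, 0): 24, (1, 1): 24, (2, 1): 18,
    (2, 2): 18, (2, 3): 18, (3, 3): 10, (3, 4): 8,
}

TEMPO_SET_MS = (140, 145, 150, 155, 160)
LEAD_SILENCE_MS = 500.0
ACCENT_DELTA_DB = 8.5     # accented minus unaccented, intensity rhythms
TEMPORAL_OFFSET_DB = -0.8  # temporal tones relative to the accented reference


@dataclass(frozen=True)
class ExperimentConfig:
    """Trial counts per condition and accent type, tempo set, dB levels."""

    trial_counts: dict[tuple[int, int], int]
    tempo_set_ms: tuple[int, ...] = TEMPO_SET_MS
    accent_delta_db: float = ACCENT_DELTA_DB
    temporal_offset_db: float = TEMPORAL_OFFSET_DB
    final_tone_accented: bool = True
    min_patterns: int = 6   # conditions below this (either type) are not usable
    seed: int = 0

    @property
    def total_trials(self) -> int:
        return 2 * sum(self.trial_counts.values())


EXP1_CONFIG = ExperimentConfig(EXP1_TRIAL_COUNTS)
EXP2_CONFIG = ExperimentConfig(EXP2_TRIAL_COUNTS)


@dataclass(frozen=True)
class StimulusTrial:
    trial_id: int
    accent_type: str               # "temporal" | "intensity"
    condition: tuple[int, int]     # (missing_beats, off_beat_accents)
    component_ids: tuple[str, str]
    grid: tuple[int, ...]          # 33 symbols from {SILENT, UNACCENTED, ACCENTED}
    ioi_ms: int


@dataclass(frozen=True)
class OnsetSchedule:
    """(time_ms, level_db) pairs; levels are relative to the reference."""

    onsets: tuple[tuple[float, float], ...]
    lead_silence_ms: float = LEAD_SILENCE_MS


class _VarietyPairSampler:
    """Round-robin pair sampling without replacement over a pattern pool.

    The pool is shuffled once (seeded) and consumed two patterns per trial;
    when exhausted it is reshuffled.  Within-trial duplicate pairs are
    rejected, which maximizes the number of distinct patterns heard.
    """

    def __init__(self, pool: list, rng: np.random.Generator):
        if len(pool) < 2:
            raise ValueError("need at least two distinct patterns per condition")
        self._pool = list(pool)
        self._rng = rng
        self._queue: list = []

    def _refill(self) -> None:
        order = self._rng.permutation(len(self._pool))
        self._queue.extend(self._pool[i] for i in order)

    def draw_pair(self) -> tuple:
        if len(self._queue) < 2:
            self._refill()
        a = self._queue.pop(0)
        # skip over an immediate duplicate; pools have >= 2 distinct members
        idx = next(i for i, b in enumerate(self._queue) if b != a)
        b = self._queue.pop(idx)
        return a, b


def _temporal_grid(ev_a, acc_a, ev_b, acc_b) -> tuple[int, ...]:
    sym = []
    for ev, acc in ((ev_a, acc_a), (ev_b, acc_b)):
        for e, a in zip(ev, acc):
            sym.append(ACCENTED if a else (UNACCENTED if e else SILENT))
    sym.append(ACCENTED)  # closing tone
    return tuple(sym)


def _intensity_grid(mask_a, mask_b) -> tuple[int, ...]:
    sym = [ACCENTED if a else UNACCENTED for a in mask_a]
    sym += [ACCENTED if a else UNACCENTED for a in mask_b]
    sym.append(ACCENTED)
    return tuple(sym)


def build_experiment_stimuli(space: EnumeratedSpace,
                             intensity_sets: dict[tuple[int, int], list[tuple[int, ...]]],
                             config: ExperimentConfig) -> list[StimulusTrial]:
    """Build the full trial set for one experiment.

    For each condition in the config and each accent type, the configured
    number of trials is built from two distinct same-condition patterns;
    tempi are drawn uniformly from the tempo set.  Requesting a condition
    outside the space (or one with fewer than two patterns of either type)
    fails loudly.
    """
    rng = np.random.default_rng(config.seed)
    counts = space.counts
    trials: list[StimulusTrial] = []
    trial_id = 1
    for key, n_trials in config.trial_counts.items():
        need = max(2, config.min_patterns)
        if counts.get(key, 0) < need or len(intensity_sets.get(key, ())) < need:
            raise ValueError(
                f"condition {key} is not usable: needs >= {need} temporal and "
                f">= {need} intensity patterns (got {counts.get(key, 0)} "
                f"temporal, {len(intensity_sets.get(key, ()))} intensity)")
        temporal_pool = space.condition_records(key)
        t_sampler = _VarietyPairSampler(temporal_pool, rng)
        for _ in range(n_trials):
            a, b = t_sampler.draw_pair()
            trials.append(StimulusTrial(
                trial_id=trial_id,
                accent_type="temporal",
                condition=key,
                component_ids=(f"T{a.pattern_id}", f"T{b.pattern_id}"),
                grid=_temporal_grid(a.events, a.accents, b.events, b.accents),
                ioi_ms=int(rng.choice(config.tempo_set_ms)),
            ))
            trial_id += 1
        masks = intensity_sets[key]
        i_sampler = _VarietyPairSampler(list(range(len(masks))), rng)
        for _ in range(n_trials):
            ia, ib = i_sampler.draw_pair()
            trials.append(StimulusTrial(
                trial_id=trial_id,
                accent_type="intensity",
                condition=key,
                component_ids=(f"I{key[0]}.{key[1]}.{ia + 1}",
                               f"I{key[0]}.{key[1]}.{ib + 1}"),
                grid=_intensity_grid(masks[ia], masks[ib]),
                ioi_ms=int(rng.choice(config.tempo_set_ms)),
            ))
            trial_id += 1
    return trials


def schedule_onsets(trial: StimulusTrial, ioi_ms: int | None = None,
                    config: ExperimentConfig = EXP1_CONFIG) -> OnsetSchedule:
    """Onset times and dB levels for one trial.

    Grid position k (1-based) sounds at ``500 + (k - 1) * ioi`` ms.  Levels
    are relative to the accented-intensity reference: intensity trials use 0
    (accented) and ``-accent_delta_db`` (unaccented); temporal trials place
    every tone at ``temporal_offset_db``.
    """
    ioi = trial.ioi_ms if ioi_ms is None else ioi_ms
    if ioi not in config.tempo_set_ms:
        raise ValueError(f"ioi {ioi} ms not in the configured tempo set")
    onsets = []
    for k, sym in enumerate(trial.grid, start=1):
        if sym == SILENT:
            continue
        t = LEAD_SILENCE_MS + (k - 1) * ioi
        if trial.accent_type == "temporal":
            level = config.temporal_offset_db
        else:
            level = 0.0 if sym == ACCENTED else -config.accent_delta_db
        onsets.append((t, level))
    return OnsetSchedule(onsets=tuple(onsets))


@dataclass(frozen=True)
class ClickSpec:
    """A short band-limited click: exponentially decaying sine burst."""

    duration_ms: float = 30.0
    frequency_hz: float = 1200.0
    decay_ms: float = 6.0


def _click_samples(spec: ClickSpec, sample_rate: int) -> np.ndarray:
    n = int(round(spec.duration_ms / 1000.0 * sample_rate))
    t = np.arange(n) / sample_rate
    click = np.sin(2 * np.pi * spec.frequency_hz * t) * np.exp(-t / (spec.decay_ms / 1000.0))
    if n:
        click[0] = 0.0
    return click


def render_wav(schedule: OnsetSchedule, path, sample_rate: int = 44100,
               click_spec: ClickSpec = ClickSpec(),
               reference_dbfs: float = -6.0) -> np.ndarray:
    """Render a schedule to 16-bit mono WAV; returns the float waveform.

    The accented reference level sits at ``reference_dbfs`` below full scale.
    Overlapping clicks (click longer than the smallest inter-onset gap) are
    rejected so levels stay exact.
    """
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz")
    times = [t for t, _ in schedule.onsets]
    if len(times) >= 2:
        min_gap = min(b - a for a, b in zip(times, times[1:]))
        if click_spec.duration_ms >= min_gap:
            raise ValueError("click duration exceeds the smallest onset gap")
    click = _click_samples(click_spec, sample_rate)
    total_ms = (times[-1] if times else schedule.lead_silence_ms) + click_spec.duration_ms
    out = np.zeros(int(round(total_ms / 1000.0 * sample_rate)) + 1)
    ref_amp = 10.0 ** (reference_dbfs / 20.0)
    for t_ms, level_db in schedule.onsets:
        amp = ref_amp * 10.0 ** (level_db / 20.0)
        i0 = int(round(t_ms / 1000.0 * sample_rate))
        out[i0:i0 + click.size] += amp * click[: out.size - i0]
    peak = np.abs(out).max()
    if peak > 1.0:  # only possible for pathological click/level settings
        out /= peak
    wavfile.write(path, sample_rate, (out * 32767.0).astype(np.int16))
    return out


def trials_to_frame(trials: list[StimulusTrial]) -> pd.DataFrame:
    """Manifest: one row per trial."""
    return pd.DataFrame([
        {
            "trial_id": t.trial_id,
            "accent_type": t.accent_type,
            "missing_beats": t.condition[0],
            "off_beat_accents": t.condition[1],
            "component_a": t.component_ids[0],
            "component_b": t.component_ids[1],
            "ioi_ms": t.ioi_ms,
            "grid": "".join(map(str, t.grid)),
        }
        for t in trials
    ])
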