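"""Enumeration and classification of 16-position rhythm grids.

A rhythm lives on a grid of 16 isochronous positions (four beats of four
sixteenth-note subdivisions; beats fall on positions 1, 5, 9 and 13).  A
*temporal* rhythm is a binary onset vector — 9 tones, 7 silences, starting
with a tone.  Perceptual (Povel–Essens) accents arise from the grouping of
onsets in time:

* an isolated tone is accented,
* the second of a pair of consecutive tones is accented,
* the first and last of a run of three or more consecutive tones are accented.

An *intensity* rhythm is the projection of such an accent pattern onto a
fully isochronous tone stream: every position carries a tone and the six
accented positions are rendered louder.

Counterevidence against the duple beat is counted two ways: *missing beats*
(silent — or, for intensity rhythms, unaccented — beat positions) and
*off-beat accents* (accents on the even positions 2, 4, …, 16).  Positions
3, 7, 11 and 15 are metrically ambiguous (on the beat under an eight-beat
reading) and contribute to neither count.

Run-delimitation conventions
----------------------------
Patterns were never heard in isolation: each 16-grid pattern is followed
either by a second pattern (which always starts with a tone) or by a closing
tone.  The ``continuation`` convention models this by appending a virtual
onset after position 16 when delimiting runs; an accent assigned to the
virtual position falls outside the grid and is discarded.  This convention
reproduces the published enumeration tables exactly and is the default.
``linear`` (runs end at the grid edge) and ``cyclic`` (runs wrap from 16
back to 1) are available for comparison.

All positions in public interfaces are 1-based.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GRID_LEN",
    "BEAT_POSITIONS",
    "OFFBEAT_POSITIONS",
    "AMBIGUOUS_POSITIONS",
    "RunConvention",
    "ConditionLabel",
    "ConstraintSet",
    "PatternRecord",
    "EnumeratedSpace",
    "EXP1_CONSTRAINTS",
    "EXP2_CONSTRAINTS",
    "CATEGORY_MAP",
    "find_runs",
    "assign_temporal_accents",
    "classify_condition",
    "interval_multiset",
    "enumerate_space",
    "project_to_intensity",
    "tabulate_conditions",
    "experiment_table",
    "space_to_frame",
]

GRID_LEN = 16
#: 1-based positions of the four beats under the intended four-beat reading.
BEAT_POSITIONS = (1, 5, 9, 13)
#: 1-based even positions — off the beat under either duple reading.
OFFBEAT_POSITIONS = (2, 4, 6, 8, 10, 12, 14, 16)
#: 1-based metrically ambiguous positions, excluded from counterevidence.
AMBIGUOUS_POSITIONS = (3, 7, 11, 15)

RunConvention = Literal["linear", "cyclic", "continuation"]

#: Off-beat-accent category per missing-beat count, as used in the analysis:
#: {missing_beats: {off_beat_accents: "few" | "some" | "many"}}.  Any
#: combination absent from this map is never used in an experiment.
CATEGORY_MAP: dict[int, dict[int, str]] = {
    0: {0: "few"},
    1: {0: "few", 1: "some", 2: "many"},
    2: {1: "few", 2: "some", 3: "many"},
    3: {3: "few", 4: "some", 5: "many"},
}


def _as_events(events: Sequence[int] | str) -> np.ndarray:
    if isinstance(events, str):
        events = [int(c) for c in events]
    arr = np.asarray(events, dtype=np.int8)
    if arr.shape != (GRID_LEN,) or not np.isin(arr, (0, 1)).all():
        raise ValueError(f"expected a binary vector of length {GRID_LEN}")
    return arr


def find_runs(events: Sequence[int] | str,
              run_convention: RunConvention = "continuation") -> list[list[int]]:
    """Maximal runs of consecutive onsets, as lists of 1-based positions.

    Under ``continuation`` a virtual onset is appended after position 16, so
    a run touching the grid end extends one position beyond it (position 17
    marks the virtual continuation).  Under ``cyclic`` a run may wrap from 16
    to 1.  All-onset or all-silence inputs have no run structure and are
    rejected.
    """
    ev = _as_events(events)
    if ev.all() or not ev.any():
        raise ValueError("pattern must contain at least one onset and one silence")
    seq = list(ev) + [1] if run_convention == "continuation" else list(ev)
    runs: list[list[int]] = []
    i = 0
    while i < len(seq):
        if seq[i]:
            j = i
            while j < len(seq) and seq[j]:
                j += 1
            runs.append(list(range(i + 1, j + 1)))
            i = j
        else:
            i += 1
    if run_convention == "cyclic" and ev[0] and ev[-1] and len(runs) > 1:
        runs = runs[1:-1] + [runs[-1] + runs[0]]
    return runs


def _max_run(bits: np.ndarray, run_convention: RunConvention, pad: bool) -> int:
    """Longest run of ones; ``pad`` appends the virtual onset (events only)."""
    seq = list(bits)
    if pad and run_convention == "continuation":
        seq = seq + [1]
    if run_convention == "cyclic" and all(seq):
        return len(seq)
    if run_convention == "cyclic":
        seq = seq + seq
    best = cur = 0
    for b in seq:
        cur = cur + 1 if b else 0
        best = max(best, cur)
    return best


def assign_temporal_accents(events: Sequence[int] | str,
                            run_convention: RunConvention = "continuation",
                            ) -> np.ndarray:
    """Binary accent mask (length 16) under the Povel–Essens grouping rules.

    Per maximal run of consecutive onsets: length 1 — that onset; length 2 —
    the second onset; length >= 3 — the first and last onsets.  Under the
    ``continuation`` convention an accent that lands on the virtual position
    17 belongs to the following pattern and is discarded.
    """
    accents = np.zeros(GRID_LEN, dtype=np.int8)
    for run in find_runs(events, run_convention):
        if len(run) == 1:
            marked = [run[0]]
        elif len(run) == 2:
            marked = [run[1]]
        else:
            marked = [run[0], run[-1]]
        for pos in marked:
            if run_convention == "cyclic":
                pos = (pos - 1) % GRID_LEN + 1
            if 1 <= pos <= GRID_LEN:
                accents[pos - 1] = 1
    return accents


@dataclass(frozen=True)
class ConditionLabel:
    """Counterevidence classification of a single 16-grid rhythm."""

    missing_beats: int
    off_beat_accents: int
    category: str  # "few" | "some" | "many" | "not_used"

    @property
    def key(self) -> tuple[int, int]:
        return (self.missing_beats, self.off_beat_accents)


def classify_condition(events: Sequence[int] | str,
                       accents: Sequence[int] | str) -> ConditionLabel:
    """Count missing beats and off-beat accents; map to the analysis category.

    ``missing_beats`` counts silent beat positions, ``off_beat_accents``
    counts accents on even positions; the ambiguous positions 3/7/11/15
    contribute to neither.  An accent on a silent position is rejected.
    """
    ev = _as_events(events)
    acc = _as_events(accents)
    if (acc > ev).any():
        raise ValueError("accent on a silent position")
    return classify_accent_mask(acc, events=ev)


def classify_accent_mask(accents: Sequence[int] | str,
                         events: np.ndarray | None = None) -> ConditionLabel:
    """Classification driven by the accent mask alone.

    For intensity rhythms every position carries a tone, so a missing beat is
    an *unaccented* beat position.  When ``events`` is given (temporal
    rhythms) a missing beat is a *silent* beat position; under the
    no-unaccented-beats selection rule the two coincide.
    """
    acc = _as_events(accents)
    ref = acc if events is None else np.asarray(events)
    missing = sum(1 for p in BEAT_POSITIONS if not ref[p - 1])
    off = int(sum(acc[p - 1] for p in OFFBEAT_POSITIONS))
    category = CATEGORY_MAP.get(missing, {}).get(off, "not_used")
    return ConditionLabel(missing, off, category)


def interval_multiset(events: Sequence[int] | str) -> tuple[int, ...]:
    """Sorted cyclic inter-onset gaps (note durations in grid units).

    Successive onset-to-onset gaps, closing the loop from the last onset back
    to the first across the 16-boundary; the gaps sum to 16 and there is one
    gap per onset.
    """
    ev = _as_events(events)
    onsets = np.flatnonzero(ev)
    if onsets.size == 0:
        raise ValueError("pattern has no onsets")
    gaps = np.diff(np.append(onsets, onsets[0] + GRID_LEN))
    return tuple(sorted(int(g) for g in gaps))


def _interval_sequence(events: np.ndarray) -> tuple[int, ...]:
    onsets = np.flatnonzero(events)
    return tuple(int(g) for g in np.diff(np.append(onsets, onsets[0] + GRID_LEN)))


@dataclass(frozen=True)
class ConstraintSet:
    """Selection rules for the temporal-rhythm space.

    The Experiment-1 preset keeps 9-onset patterns that start with a tone,
    have event runs of at most five and silence runs of at most three, four
    pairwise-distinct beat quarters, exactly six accents, and no unaccented
    beat positions.  Experiment 2 tightens the event-run bound to three,
    fixes the note-duration multiset to five sixteenths, two eighths, one
    dotted eighth and one quarter, and excludes rhythms that open with an
    eighth note followed immediately by the quarter note (an exclusion
    recovered empirically from the published inventory; see the methods
    note).
    """

    max_event_run: int = 5
    max_silence_run: int = 3
    required_accents: int = 6
    distinct_beat_quarters: bool = True
    no_unaccented_beats: bool = True
    required_interval_multiset: tuple[int, ...] | None = None
    exclude_opening_eighth_quarter: bool = False
    run_convention: RunConvention = "continuation"
    n_onsets: int = 9

    def with_convention(self, run_convention: RunConvention) -> "ConstraintSet":
        return replace(self, run_convention=run_convention)


EXP1_CONSTRAINTS = ConstraintSet()
EXP2_CONSTRAINTS = ConstraintSet(
    max_event_run=3,
    required_interval_multiset=(1, 1, 1, 1, 1, 2, 2, 3, 4),
    exclude_opening_eighth_quarter=True,
)


@dataclass(frozen=True)
class PatternRecord:
    """One enumerated temporal rhythm with its accent mask and label."""

    pattern_id: int
    events: tuple[int, ...]
    accents: tuple[int, ...]
    condition: ConditionLabel

    @property
    def event_string(self) -> str:
        return "".join(map(str, self.events))

    @property
    def accent_string(self) -> str:
        return "".join(map(str, self.accents))


@dataclass
class EnumeratedSpace:
    """All temporal rhythms passing a constraint set, grouped by condition."""

    constraints: ConstraintSet
    records: list[PatternRecord]
    #: distinct accent masks per condition key — the intensity inventory
    intensity_masks: dict[tuple[int, int], list[tuple[int, ...]]] = field(
        default_factory=dict)

    @property
    def counts(self) -> dict[tuple[int, int], int]:
        return dict(Counter(r.condition.key for r in self.records))

    @property
    def intensity_counts(self) -> dict[tuple[int, int], int]:
        return {k: len(v) for k, v in self.intensity_masks.items()}

    def condition_records(self, key: tuple[int, int]) -> list[PatternRecord]:
        return [r for r in self.records if r.condition.key == key]


def _candidate_masks(n_onsets: int) -> Iterable[np.ndarray]:
    """All 16-position masks with the given onset count and an onset at 1."""
    for rest in combinations(range(1, GRID_LEN), n_onsets - 1):
        ev = np.zeros(GRID_LEN, dtype=np.int8)
        ev[0] = 1
        ev[list(rest)] = 1
        yield ev


def _passes_structural(ev: np.ndarray, c: ConstraintSet) -> bool:
    """Constraints that do not involve the accent mask."""
    if _max_run(ev, c.run_convention, pad=True) > c.max_event_run:
        return False
    if _max_run(1 - ev, c.run_convention, pad=False) > c.max_silence_run:
        return False
    if c.distinct_beat_quarters:
        quarters = {tuple(ev[i:i + 4]) for i in (0, 4, 8, 12)}
        if len(quarters) < 4:
            return False
    if c.required_interval_multiset is not None:
        if interval_multiset(ev) != tuple(sorted(c.required_interval_multiset)):
            return False
    if c.exclude_opening_eighth_quarter:
        seq = _interval_sequence(ev)
        if seq[:2] == (2, 4):
            return False
    return True


def enumerate_space(constraints: ConstraintSet = EXP1_CONSTRAINTS) -> EnumeratedSpace:
    """Exhaustively enumerate the constrained temporal-rhythm space.

    Iterates every 16-position mask with ``n_onsets`` onsets and an onset at
    position 1, assigns accents, applies the constraint set and labels the
    survivors.  The intensity inventory is built alongside: the distinct
    accent masks of patterns passing the structural and accent-count
    constraints (the no-unaccented-beats rule is temporal-specific — for an
    intensity rhythm an unaccented beat is counterevidence, not grounds for
    exclusion), restricted to masks with an accented downbeat and classified
    by the mask's own counterevidence.
    """
    c = constraints
    records: list[PatternRecord] = []
    intensity: dict[tuple[int, int], dict[tuple[int, ...], None]] = {}
    for ev in _candidate_masks(c.n_onsets):
        if not _passes_structural(ev, c):
            continue
        acc = assign_temporal_accents(ev, c.run_convention)
        if int(acc.sum()) != c.required_accents:
            continue
        mask = tuple(int(a) for a in acc)
        if acc[0]:
            label = classify_accent_mask(acc)
            intensity.setdefault(label.key, {}).setdefault(mask, None)
        if c.no_unaccented_beats:
            if any(ev[p - 1] and not acc[p - 1] for p in BEAT_POSITIONS):
                continue
        label = classify_condition(ev, acc)
        records.append(PatternRecord(
            pattern_id=len(records) + 1,
            events=tuple(int(e) for e in ev),
            accents=mask,
            condition=label,
        ))
    masks = {k: list(v) for k, v in intensity.items()}
    return EnumeratedSpace(constraints=c, records=records, intensity_masks=masks)


def project_to_intensity(space: EnumeratedSpace) -> dict[tuple[int, int], list[tuple[int, ...]]]:
    """Per-condition intensity inventory (distinct accent masks).

    Built during enumeration; returned here keyed by
    ``(missing_beats, off_beat_accents)``.
    """
    if not space.records and not space.intensity_masks:
        raise ValueError("cannot project a degenerate (empty) space")
    return space.intensity_masks


def tabulate_conditions(space: EnumeratedSpace,
                        intensity_sets: dict[tuple[int, int], list[tuple[int, ...]]] | None = None,
                        min_patterns: int = 6) -> pd.DataFrame:
    """Condition table: temporal/intensity counts, category, inclusion flag.

    A condition is *used* when both its temporal and intensity counts reach
    ``min_patterns``.  Rows cover every condition with a nonzero count plus
    every condition named in the category map (so printed zero cells appear).
    """
    if intensity_sets is None:
        intensity_sets = space.intensity_masks
    temporal = Counter(r.condition.key for r in space.records)
    keys = set(temporal) | set(intensity_sets)
    keys |= {(mb, ob) for mb, m in CATEGORY_MAP.items() for ob in m}
    rows = []
    for mb, ob in sorted(keys):
        n_t = temporal.get((mb, ob), 0)
        n_i = len(intensity_sets.get((mb, ob), ()))
        if n_t == 0 and n_i == 0 and ob not in CATEGORY_MAP.get(mb, {}):
            continue
        category = CATEGORY_MAP.get(mb, {}).get(ob, "not_used")
        used = n_t >= min_patterns and n_i >= min_patterns
        rows.append({
            "missing_beats": mb,
            "off_beat_accents": ob,
            "n_temporal": n_t,
            "n_intensity": n_i,
            "category": category,
            "used": used,
        })
    return pd.DataFrame(rows)


def experiment_table(experiment: int, min_patterns: int = 6,
                     run_convention: RunConvention = "continuation",
                     ) -> tuple[EnumeratedSpace, pd.DataFrame]:
    """Enumerate and tabulate an experiment's stimulus inventory.

    Experiment 2 tightens the *temporal* constraints only; its intensity
    rhythms are isochronous tone streams to which the event-density and
    note-duration constraints do not apply, so the intensity inventory is the
    Experiment-1 one (as in the published tables).
    """
    if experiment == 1:
        space = enumerate_space(EXP1_CONSTRAINTS.with_convention(run_convention))
        return space, tabulate_conditions(space, min_patterns=min_patterns)
    if experiment == 2:
        space = enumerate_space(EXP2_CONSTRAINTS.with_convention(run_convention))
        exp1 = enumerate_space(EXP1_CONSTRAINTS.with_convention(run_convention))
        space.intensity_masks = exp1.intensity_masks
        return space, tabulate_conditions(space, min_patterns=min_patterns)
    raise ValueError("experiment must be 1 or 2")


def space_to_frame(space: EnumeratedSpace, preset_name: str = "") -> pd.DataFrame:
    """Flat export: one row per pattern (1-based positions encoded as strings)."""
    return pd.DataFrame([
        {
            "pattern_id": r.pattern_id,
            "events": r.event_string,
            "accents": r.accent_string,
            "missing_beats": r.condition.missing_beats,
            "off_beat_accents": r.condition.off_beat_accents,
            "category": r.condition.category,
            "preset": preset_name,
        }
        for r in space.records
    ])
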