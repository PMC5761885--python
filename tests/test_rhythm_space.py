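"""Accent assignment, classification and enumeration of the rhythm space."""

import re
from itertools import combinations

import numpy as np
import pytest

from beatgrid.grid import (
    EXP1_CONSTRAINTS,
    EXP2_CONSTRAINTS,
    assign_temporal_accents,
    classify_condition,
    enumerate_space,
    find_runs,
    interval_multiset,
    project_to_intensity,
    tabulate_conditions,
)


def mask(positions):
    ev = [0] * 16
    for p in positions:
        ev[p - 1] = 1
    return ev


class TestAccentAssignment:
    @pytest.mark.parametrize("positions, accented", [
        ([5], [5]),                      # isolated tone
        ([1, 2], [2]),                   # pair: second tone
        ([1, 2, 3, 4, 5], [1, 5]),       # run >= 3: first and last
        ([1, 3, 5, 7, 9, 11, 13, 15], [1, 3, 5, 7, 9, 11, 13, 15]),
    ])
    def test_grouping_rules(self, positions, accented):
        acc = assign_temporal_accents(mask(positions), "linear")
        assert sorted(np.flatnonzero(acc) + 1) == sorted(accented)

    def test_continuation_discards_virtual_accent(self):
        # a trailing pair 15-16 continues into the virtual onset: the run has
        # length three and its final accent falls beyond the grid
        acc = assign_temporal_accents(mask([1, 15, 16]), "continuation")
        assert sorted(np.flatnonzero(acc) + 1) == [1, 15]
        # under the linear reading the pair's second tone is accented
        acc_lin = assign_temporal_accents(mask([1, 15, 16]), "linear")
        assert sorted(np.flatnonzero(acc_lin) + 1) == [1, 16]

    def test_cyclic_run_wraps(self):
        acc = assign_temporal_accents(mask([16, 1, 2]), "cyclic")
        # wrapped run 16-1-2: first (16) and last (2) accented
        assert sorted(np.flatnonzero(acc) + 1) == [2, 16]

    @pytest.mark.parametrize("bad", [[1] * 16, [0] * 16])
    def test_degenerate_patterns_rejected(self, bad):
        with pytest.raises(ValueError):
            assign_temporal_accents(bad)

    @pytest.mark.parametrize("convention", ["linear", "continuation"])
    def test_accent_masks_match_regex_oracle_all_masks(self, convention):
        """Against an independent regex run scanner over all 11,440 masks."""
        for onsets in combinations(range(16), 9):
            ev = [0] * 16
            for p in onsets:
                ev[p] = 1
            s = "".join(map(str, ev)) + ("1" if convention == "continuation" else "")
            expected = set()
            for m in re.finditer(r"1+", s):
                i, j = m.start(), m.end() - 1
                marked = [i] if i == j else ([i + 1] if j == i + 1 else [i, j])
                expected.update(k for k in marked if k < 16)
            acc = assign_temporal_accents(ev, convention)
            assert set(np.flatnonzero(acc)) == expected, ev


class TestClassification:
    def test_strictly_metric(self):
        # accents on the four beats plus two ambiguous positions; every beat
        # carries a tone: no missing beats, no off-beat accents
        acc = mask([1, 5, 9, 13, 3, 7])
        ev = mask([1, 5, 9, 13, 3, 7, 2, 10, 14])
        label = classify_condition(ev, acc)
        assert (label.missing_beats, label.off_beat_accents) == (0, 0)
        assert label.category == "few"

    def test_heavily_syncopated(self):
        acc = mask([1, 2, 4, 6, 8, 10])
        ev = mask([1, 2, 3, 4, 6, 7, 8, 10, 11])  # 5, 9, 13 silent
        label = classify_condition(ev, acc)
        assert (label.missing_beats, label.off_beat_accents) == (3, 5)
        assert label.category == "many"

    def test_category_map_two_missing_three_off(self, exp1):
        space, _ = exp1
        recs = space.condition_records((2, 3))
        assert recs and all(r.condition.category == "many" for r in recs)

    def test_accent_on_silence_rejected(self):
        with pytest.raises(ValueError, match="silent"):
            classify_condition(mask([1, 5]), mask([1, 9]))

    def test_ambiguous_positions_count_nowhere(self):
        base_ev = mask([1, 2, 5, 6, 9, 10, 13, 14, 3])
        acc = assign_temporal_accents(base_ev, "linear")
        label = classify_condition(base_ev, acc)
        # adding/removing accents at 3/7/11/15 cannot change either count
        assert label.off_beat_accents == sum(
            acc[p - 1] for p in (2, 4, 6, 8, 10, 12, 14, 16))


class TestIntervals:
    def test_beat_skeleton(self):
        assert interval_multiset(mask([1, 5, 9, 13])) == (4, 4, 4, 4)

    def test_conservation_over_nine_onset_patterns(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            pos = [1] + sorted(rng.choice(range(2, 17), size=8, replace=False).tolist())
            gaps = interval_multiset(mask(pos))
            assert len(gaps) == 9 and sum(gaps) == 16

    def test_experiment2_multiset(self, exp2):
        space, _ = exp2
        for rec in space.records:
            assert interval_multiset(rec.events) == (1, 1, 1, 1, 1, 2, 2, 3, 4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            interval_multiset([0] * 16)


class TestEnumeration:
    def test_contradictory_accent_requirement_gives_empty_space(self):
        import dataclasses
        c = dataclasses.replace(EXP1_CONSTRAINTS, required_accents=10)
        assert enumerate_space(c).records == []

    def test_experiment2_is_subset_of_experiment1(self, exp1, exp2):
        s1, _ = exp1
        s2, _ = exp2
        events1 = {r.events for r in s1.records}
        assert all(r.events in events1 for r in s2.records)
        assert len(s2.records) < len(s1.records)

    def test_no_duplicate_patterns(self, exp1):
        space, _ = exp1
        assert len({r.events for r in space.records}) == len(space.records)

    def test_every_record_satisfies_its_constraints(self, exp1):
        space, _ = exp1
        for rec in space.records:
            assert rec.events[0] == 1
            assert sum(rec.accents) == 6
            assert all(a <= e for a, e in zip(rec.accents, rec.events))
            # beat positions: silent or accented, never an unaccented tone
            for p in (1, 5, 9, 13):
                assert not (rec.events[p - 1] and not rec.accents[p - 1])

    def test_projection_never_exceeds_temporal_counts(self, exp1):
        space, _ = exp1
        proj = project_to_intensity(space)
        counts = space.counts
        for key, masks in proj.items():
            if key in counts:
                assert len(masks) <= counts[key]

    def test_every_temporal_mask_is_in_its_conditions_inventory(self, exp1):
        space, _ = exp1
        proj = project_to_intensity(space)
        for rec in space.records:
            assert rec.accents in set(map(tuple, proj[rec.condition.key]))


class TestTabulation:
    def test_experiment1_has_ten_used_conditions(self, exp1):
        _, table = exp1
        assert int(table["used"].sum()) == 10

    def test_low_intensity_condition_not_used(self, exp1):
        _, table = exp1
        row = table.set_index(["missing_beats", "off_beat_accents"]).loc[(2, 0)]
        assert row["n_temporal"] == 11 and row["n_intensity"] == 3
        assert not row["used"]

    def test_threshold_zero_uses_every_nonempty_condition(self, exp1):
        space, _ = exp1
        table = tabulate_conditions(space, min_patterns=0)
        nonempty = (table["n_temporal"] > 0) & (table["n_intensity"] > 0)
        assert (table.loc[nonempty, "used"]).all()

    def test_counts_invariant_to_record_order(self, exp1):
        space, _ = exp1
        shuffled = type(space)(constraints=space.constraints,
                               records=list(reversed(space.records)),
                               intensity_masks=space.intensity_masks)
        t1 = tabulate_conditions(space).sort_values(
            ["missing_beats", "off_beat_accents"]).reset_index(drop=True)
        t2 = tabulate_conditions(shuffled).sort_values(
            ["missing_beats", "off_beat_accents"]).reset_index(drop=True)
        assert t1.equals(t2)
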