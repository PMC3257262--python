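"""Presence bookkeeping, disappearance events and nucleation inference."""

import pytest

from nmrtitrate.datamodel import (
    Condition,
    PresenceMatrix,
    ProteinSequence,
    SegmentCall,
    ShiftRecord,
    ShiftTable,
)
from nmrtitrate.hierarchy import (
    build_presence,
    consistency_report,
    disappearance_events,
    find_nucleation,
    hierarchy_report,
)


def matrix_from_present(seq, present_by_label, ladder):
    conditions = tuple(Condition(f) for f in ladder)
    states = {}
    for c in conditions:
        present = present_by_label[c.label]
        for p in seq.positions:
            if p in seq.prolines:
                states[(p, c.label)] = "absent"
            else:
                states[(p, c.label)] = "present" if p in present else "absent"
    return PresenceMatrix(conditions, states, seq.prolines)


class TestBuildPresence:
    def test_all_assigned_means_all_present(self):
        seq = ProteinSequence.from_string("ACDEF")
        table = ShiftTable(Condition(1.0), [ShiftRecord(p, "H", 8.0 + p * 0.01)
                                            for p in range(1, 6)])
        m = build_presence([table], seq)
        assert m.present_positions("dmso100") == frozenset(range(1, 6))

    def test_prolines_never_present(self, default_study):
        m = default_study.presence
        for label in m.labels:
            assert not (m.present_positions(label) & m.proline_mask)

    def test_flexible_tail_at_half_dmso(self, default_study, ged_seq):
        """At the lowest DMSO rung exactly the non-proline residues of the
        flexible N-terminal segment [2, 32] remain visible."""
        expected = frozenset(p for p in range(2, 33) if p != 12)
        assert default_study.presence.present_positions("dmso50") == expected

    def test_minor_duplicates_counted_as_present(self, default_study):
        m = default_study.presence
        assert m.state(9, "dmso100") == "minor_duplicate"
        assert m.is_present(9, "dmso100")

    def test_record_outside_sequence_rejected(self):
        seq = ProteinSequence.from_string("ACD")
        table = ShiftTable(Condition(1.0), [ShiftRecord(7, "H", 8.0)])
        with pytest.raises(ValueError):
            build_presence([table], seq)


class TestConsistency:
    def test_monotone_presence_is_clean(self, default_study, ged_seq):
        assert consistency_report(default_study.presence, ged_seq) == []

    def test_reappearing_residue_flagged_not_fixed(self):
        seq = ProteinSequence.from_string("ACDEF")
        m = matrix_from_present(seq, {
            "dmso100": {1, 2, 3, 4, 5},
            "dmso90": {1, 2, 4, 5},   # 3 vanishes...
            "dmso80": {1, 2, 3, 5},   # ...and comes back
        }, (1.0, 0.9, 0.8))
        issues = consistency_report(m, seq)
        assert issues == [{"position": 3, "absent_at": "dmso90",
                           "reappears_at": "dmso80"}]


class TestDisappearanceEvents:
    def test_no_changes_no_events(self):
        seq = ProteinSequence.from_string("ACDEF")
        m = matrix_from_present(seq, {
            "dmso100": {1, 2, 3}, "dmso90": {1, 2, 3},
        }, (1.0, 0.9))
        assert disappearance_events(m, seq) == []

    def test_single_residue_event(self):
        seq = ProteinSequence.from_string("ACDEF")
        m = matrix_from_present(seq, {
            "dmso100": {1, 2, 3, 4, 5}, "dmso90": {1, 2, 4, 5},
        }, (1.0, 0.9))
        events = disappearance_events(m, seq)
        assert [(e.segment.interval, e.condition.label) for e in events] == \
            [((3, 3), "dmso90")]

    def test_prolines_bridge_runs(self):
        # P at 3: residues 2 and 4 vanishing together form one segment [2,4]
        seq = ProteinSequence.from_string("ACPDE")
        m = matrix_from_present(seq, {
            "dmso100": {1, 2, 4, 5}, "dmso90": {1, 5},
        }, (1.0, 0.9))
        events = disappearance_events(m, seq)
        assert [e.segment.interval for e in events] == [(2, 4)]
        assert events[0].newly_absent_positions == (2, 4)

    def test_planted_stage_map_reconstructed(self, default_study, ged_seq):
        """The generator's stage map is the oracle: events per condition must
        reproduce exactly the residues planted to vanish there."""
        truth = default_study.truth
        events = disappearance_events(default_study.presence, ged_seq)
        labels = [c.label for c in default_study.conditions]
        got: dict[int, set] = {}
        for e in events:
            got.setdefault(labels.index(e.condition.label), set()).update(
                e.newly_absent_positions)
        expected: dict[int, set] = {}
        for p, s in truth.stage.items():
            if s is not None and s >= 1 and p not in ged_seq.prolines:
                expected.setdefault(s, set()).add(p)
        assert got == expected

    def test_each_residue_vanishes_at_most_once(self, default_study, ged_seq):
        events = disappearance_events(default_study.presence, ged_seq)
        seen: set[int] = set()
        for e in events:
            overlap = seen & set(e.newly_absent_positions)
            assert not overlap
            seen.update(e.newly_absent_positions)


class TestFindNucleation:
    def exchange(self, *intervals, label="dmso100"):
        return [SegmentCall(a, b, "exchange", label) for a, b in intervals]

    def test_no_absent_runs_no_calls(self):
        seq = ProteinSequence.from_string("ACDEFGH")
        m = matrix_from_present(seq, {"dmso100": set(seq.positions)}, (1.0,))
        assert find_nucleation(m, self.exchange((2, 3)), seq) == []

    def test_flanked_absent_run_is_nucleation(self, default_study, ged_seq):
        calls = find_nucleation(
            default_study.presence,
            self.exchange((97, 108), (117, 120)), ged_seq)
        assert [c.interval for c in calls] == [(109, 116)]
        assert calls[0].left_flank.interval == (97, 108)
        assert calls[0].right_flank.interval == (117, 120)

    def test_one_sided_flank_excluded(self, default_study, ged_seq):
        calls = find_nucleation(default_study.presence,
                                self.exchange((97, 108)), ged_seq)
        assert calls == []

    def test_flank_window_limits_gap(self, default_study, ged_seq):
        # left exchange ends at 104: gap of 5 > default window 3
        far = self.exchange((95, 104), (117, 120))
        assert find_nucleation(default_study.presence, far, ged_seq) == []
        assert [c.interval for c in
                find_nucleation(default_study.presence, far, ged_seq,
                                flank_window=5)] == [(109, 116)]

    def test_terminal_runs_excluded(self):
        seq = ProteinSequence.from_string("ACDEFGHIKL")
        m = matrix_from_present(
            seq, {"dmso100": {3, 4, 5, 6, 7, 8, 9}}, (1.0,))
        # absent runs: [1,2] (terminus) and [10,10] (terminus)
        assert find_nucleation(m, self.exchange((3, 5), (7, 9)), seq) == []

    def test_invariant_to_condition_relabeling(self, default_study, ged_seq):
        m = default_study.presence
        renamed = PresenceMatrix(
            tuple(Condition(c.dmso_fraction, label=f"x{i}")
                  for i, c in enumerate(m.conditions)),
            {(p, f"x{list(m.labels).index(lab)}"): st
             for (p, lab), st in m.states.items()},
            m.proline_mask,
        )
        ex = self.exchange((97, 108), (117, 120))
        assert [c.interval for c in find_nucleation(renamed, ex, ged_seq)] == \
            [c.interval for c in find_nucleation(m, ex, ged_seq)]


class TestHierarchyReport:
    def test_empty_inputs_exit_cleanly(self):
        seq = ProteinSequence.from_string("ACDEF")
        m = matrix_from_present(seq, {"dmso100": set(), "dmso90": set()},
                                (1.0, 0.9))
        report = hierarchy_report(seq, m, [], [])
        assert report["nucleation"] == []
        assert report["incorporation_order"] == []

    def test_full_synthetic_run(self, default_study, ged_seq):
        m = default_study.presence
        events = disappearance_events(m, ged_seq)
        ex = [SegmentCall(97, 108, "exchange", "dmso100"),
              SegmentCall(117, 121, "exchange", "dmso100")]
        nuc = find_nucleation(m, ex, ged_seq)
        report = hierarchy_report(ged_seq, m, events, nuc,
                                  exchange={"dmso100": ex})
        assert report["nucleation"][0]["interval"] == [109, 116]
        # final condition: only the flexible N-terminal segment remains
        final = report["per_condition"][-1]
        assert final["flexible_segments"] == [[2, 32]]
        # C-half packs earlier/tighter than the N-half down the ladder
        for row in report["per_condition"][1:]:
            assert row["packing"]["c_half_incorporated"] >= \
                row["packing"]["n_half_incorporated"]
        assert report["consistency"] == []
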