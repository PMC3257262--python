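"""Secondary-shift baselines, thresholding and propensity-segment calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrtitrate.datamodel import Condition, ProteinSequence, ShiftRecord, ShiftTable
from nmrtitrate.secondary_shifts import (
    RandomCoilTable,
    SecondaryShiftProfile,
    call_propensity_segments,
    delta_ca,
    solvent_weights,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def constant_table(medium: str, value: float) -> RandomCoilTable:
    return RandomCoilTable(medium, {aa: value for aa in AA20}, "test")


def profile(deltas: dict, dmso: float = 0.9, p1: float | None = None):
    p1 = dmso if p1 is None else p1
    return SecondaryShiftProfile(Condition(dmso), deltas, p1, 1.0 - p1)


class TestSolventWeights:
    @pytest.mark.parametrize("frac,expected", [
        (1.0, (1.0, 0.0)),
        (0.0, (0.0, 1.0)),
        (0.9, (0.9, 0.1)),
    ])
    def test_volume_fraction_policy(self, frac, expected):
        p1, p2 = solvent_weights(Condition(frac))
        assert (p1, p2) == pytest.approx(expected)


class TestDeltaCa:
    def test_blended_baseline_arithmetic(self):
        # 55.0 - (0.8*52.0 + 0.2*53.0) = 2.8
        seq = ProteinSequence.from_string("A")
        tab = ShiftTable(Condition(0.8), [ShiftRecord(1, "CA", 55.0)])
        prof = delta_ca(tab, constant_table("dmso", 52.0),
                        constant_table("aqueous", 53.0), seq)
        assert prof.deltas[1] == pytest.approx(2.8)

    def test_pure_dmso_collapses_to_single_baseline(self):
        seq = ProteinSequence.from_string("A")
        tab = ShiftTable(Condition(1.0), [ShiftRecord(1, "CA", 55.0)])
        prof = delta_ca(tab, constant_table("dmso", 52.0),
                        constant_table("aqueous", 99.0), seq)
        assert prof.deltas[1] == pytest.approx(3.0)

    def test_pure_aqueous_collapses_to_single_baseline(self):
        seq = ProteinSequence.from_string("A")
        tab = ShiftTable(Condition(0.0), [ShiftRecord(1, "CA", 55.0)])
        prof = delta_ca(tab, constant_table("dmso", 99.0),
                        constant_table("aqueous", 53.0), seq)
        assert prof.deltas[1] == pytest.approx(2.0)

    def test_observed_equal_to_baseline_gives_zero(self):
        seq = ProteinSequence.from_string("A")
        tab = ShiftTable(Condition(0.8), [ShiftRecord(1, "CA", 52.2)])
        prof = delta_ca(tab, constant_table("dmso", 52.0),
                        constant_table("aqueous", 53.0), seq)
        assert prof.deltas[1] == pytest.approx(0.0)

    @settings(deadline=None, max_examples=20)
    @given(st.floats(0.0, 1.0))
    def test_identical_tables_make_weights_irrelevant(self, frac):
        seq = ProteinSequence.from_string("AC")
        tab = ShiftTable(Condition(frac), [ShiftRecord(1, "CA", 55.0),
                                           ShiftRecord(2, "CA", 60.0)])
        prof = delta_ca(tab, constant_table("dmso", 52.0),
                        constant_table("aqueous", 52.0), seq)
        assert prof.deltas[1] == pytest.approx(3.0)
        assert prof.deltas[2] == pytest.approx(8.0)

    def test_missing_ca_is_absent_not_zero(self):
        seq = ProteinSequence.from_string("ACD")
        tab = ShiftTable(Condition(0.8), [ShiftRecord(1, "CA", 55.0),
                                          ShiftRecord(2, "N", 118.0)])
        prof = delta_ca(tab, constant_table("dmso", 52.0),
                        constant_table("aqueous", 53.0), seq)
        assert set(prof.deltas) == {1}

    def test_minor_state_records_ignored(self):
        seq = ProteinSequence.from_string("A")
        tab = ShiftTable(Condition(1.0), [ShiftRecord(1, "CA", 55.0, "major"),
                                          ShiftRecord(1, "CA", 99.0, "minor")])
        prof = delta_ca(tab, constant_table("dmso", 52.0),
                        constant_table("aqueous", 52.0), seq)
        assert prof.deltas[1] == pytest.approx(3.0)

    def test_incomplete_random_coil_table_rejected(self):
        with pytest.raises(ValueError, match="missing amino acids"):
            RandomCoilTable("dmso", {"A": 52.0})


def brute_force_segments(deltas: dict, threshold: float, min_len: int):
    """Independent oracle: enumerate every maximal qualifying run directly."""
    out = []
    for sign, label in ((+1, "helix-propensity"), (-1, "sheet-propensity")):
        sig = {p for p, d in deltas.items() if sign * d > threshold}
        best = []
        for a in sorted(sig):
            for b in sorted(sig):
                if b < a:
                    continue
                if all(p in sig for p in range(a, b + 1)):
                    best.append((a, b))
        maximal = [(a, b) for (a, b) in best
                   if not any((c <= a and b <= d and (c, d) != (a, b))
                              for (c, d) in best)]
        out.extend((a, b, label) for (a, b) in maximal if b - a + 1 >= min_len)
    return sorted(out)


class TestSegmentCalling:
    def test_all_zero_profile_has_no_segments(self):
        prof = profile({p: 0.0 for p in range(1, 20)})
        assert call_propensity_segments(prof) == []

    def test_example_run(self):
        prof = profile({100: 1.2, 101: 1.5, 102: 0.9, 103: 0.2})
        segs = call_propensity_segments(prof, 0.7, 3)
        assert [(s.start, s.end, s.label) for s in segs] == \
            [(100, 102, "helix-propensity")]

    def test_interrupted_run_splits(self):
        deltas = {p: 1.5 for p in range(10, 20)}
        deltas[15] = 0.1  # one sub-threshold residue breaks the run
        segs = call_propensity_segments(profile(deltas), 0.7, 3)
        assert [(s.start, s.end) for s in segs] == [(10, 14), (16, 19)]
        assert call_propensity_segments(profile(deltas), 0.7, min_len=6) == []

    def test_threshold_is_strict(self):
        prof = profile({p: 0.7 for p in range(1, 10)})
        assert call_propensity_segments(prof, 0.7, 3) == []
        prof = profile({p: 0.7000001 for p in range(1, 10)})
        assert len(call_propensity_segments(prof, 0.7, 3)) == 1

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_propensity_segments(profile({1: 1.0}), -0.1)

    def test_missing_residues_break_runs(self):
        deltas = {p: 2.0 for p in range(1, 11) if p != 5}
        segs = call_propensity_segments(profile(deltas), 0.7, 3)
        assert [(s.start, s.end) for s in segs] == [(1, 4), (6, 10)]

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        deltas = {int(p): float(rng.normal(0, 1.2))
                  for p in rng.choice(np.arange(1, 60), size=n, replace=False)}
        threshold = float(rng.uniform(0.2, 1.5))
        min_len = int(rng.integers(1, 5))
        segs = call_propensity_segments(profile(deltas), threshold, min_len)
        assert sorted((s.start, s.end, s.label) for s in segs) == \
            brute_force_segments(deltas, threshold, min_len)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_raising_threshold_shrinks_segments(self, seed):
        rng = np.random.default_rng(seed)
        deltas = {p: float(rng.normal(0, 1.2)) for p in range(1, 40)}
        lo = call_propensity_segments(profile(deltas), 0.5, 3)
        hi = call_propensity_segments(profile(deltas), 0.9, 3)
        # every high-threshold segment is contained in some low-threshold one
        for seg in hi:
            assert any(s.start <= seg.start and seg.end <= s.end and s.label == seg.label
                       for s in lo)

    def test_planted_helix_recovered_within_one_residue(self):
        rng = np.random.default_rng(7)
        deltas = {p: float(rng.normal(0.0, 0.2)) for p in range(1, 101)}
        for p in range(40, 61):
            deltas[p] = float(rng.normal(2.8, 0.2))
        segs = call_propensity_segments(profile(deltas), 0.7, 3)
        helix = [s for s in segs if s.label == "helix-propensity"
                 and s.overlaps(40, 60)]
        assert len(helix) == 1
        assert abs(helix[0].start - 40) <= 1
        assert abs(helix[0].end - 60) <= 1
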