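"""Hierarchy of segment incorporation from peak disappearance.

As denaturant is diluted, residues that fold and join the (NMR-invisible)
self-assembly drop out of the HSQC. Tracking which residues vanish at which
rung of the condition ladder yields the order in which chain segments are
incorporated; the segment already missing at the *highest* denaturant
concentration, when flanked on both sides by conformational-exchange
stretches, is the candidate nucleation site of folding and association.

Presence is defined by assignment records (a residue is present at a
condition iff it has an assigned major-state amide peak there), not by raw
intensity thresholds. Prolines have no amide peak; they never count as
present and they *bridge* rather than break absent runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .datamodel import (
    Condition,
    PresenceMatrix,
    ProteinSequence,
    SegmentCall,
    ShiftTable,
    contiguous_runs,
)

DEFAULT_FLANK_WINDOW = 3

AMIDE_NUCLEI = ("H", "N")


@dataclass(frozen=True)
class IncorporationEvent:
    """A contiguous segment newly absent at ``condition``.

    The segment's peaks are present at the immediately higher DMSO fraction
    and gone at this one: the segment has entered the assembly here.
    """

    segment: SegmentCall
    condition: Condition
    newly_absent_positions: tuple[int, ...]


@dataclass(frozen=True)
class NucleationCall:
    """An absent run at the highest-denaturant condition with exchange flanks."""

    start: int
    end: int
    left_flank: SegmentCall
    right_flank: SegmentCall
    condition: Condition

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def build_presence(
    tables: Sequence[ShiftTable], seq: ProteinSequence
) -> PresenceMatrix:
    """Presence matrix from per-condition assigned shift tables.

    Tables must be ordered by strictly decreasing ``dmso_fraction``. A
    residue is *present* iff it carries a major-state amide (H or N) record;
    a present residue with an additional minor-state amide record is marked
    ``minor_duplicate``.
    """
    prolines = seq.prolines
    states: dict[tuple[int, str], str] = {}
    for tab in tables:
        tab.validate_against(seq)
        major = set()
        minor = set()
        for nuc in AMIDE_NUCLEI:
            major |= set(tab.shifts(nuc, "major"))
            minor |= set(tab.shifts(nuc, "minor"))
        for pos in seq.positions:
            if pos in prolines:
                states[(pos, tab.condition.label)] = "absent"
            elif pos in major:
                states[(pos, tab.condition.label)] = (
                    "minor_duplicate" if pos in minor else "present"
                )
            else:
                states[(pos, tab.condition.label)] = "absent"
    matrix = PresenceMatrix(tuple(t.condition for t in tables), states, prolines)
    matrix.validate_complete(seq)
    return matrix


def _observable_axis(seq: ProteinSequence) -> list[int]:
    """Non-proline positions in order; the coordinate axis for absent runs."""
    return [p for p in seq.positions if p not in seq.prolines]


def _runs_bridging_prolines(positions: Iterable[int], seq: ProteinSequence) -> list[tuple[int, int]]:
    """Maximal runs of non-proline positions, letting prolines bridge gaps."""
    axis = _observable_axis(seq)
    index = {p: i for i, p in enumerate(axis)}
    idxs = sorted(index[p] for p in positions)
    runs = []
    for i0, i1 in contiguous_runs(idxs):
        runs.append((axis[i0], axis[i1]))
    return runs


def consistency_report(matrix: PresenceMatrix, seq: ProteinSequence) -> list[dict]:
    """Residues that reappear after vanishing (non-monotone presence).

    Real titration lists contain such inconsistencies; they are surfaced for
    inspection, never silently repaired.
    """
    issues = []
    for pos in _observable_axis(seq):
        seen_absent_at = None
        for c in matrix.conditions:
            if not matrix.is_present(pos, c):
                if seen_absent_at is None:
                    seen_absent_at = c.label
            elif seen_absent_at is not None:
                issues.append({
                    "position": pos,
                    "absent_at": seen_absent_at,
                    "reappears_at": c.label,
                })
                seen_absent_at = None
    return issues


def disappearance_events(
    matrix: PresenceMatrix, seq: ProteinSequence
) -> list[IncorporationEvent]:
    """Segments newly absent at each step down the denaturant ladder.

    For every adjacent condition pair the maximal contiguous runs of
    residues present at the higher DMSO fraction but absent at the lower one
    are returned, ordered by condition then start position. Prolines bridge
    runs (they are invisible at every condition, so they carry no
    disappearance information).
    """
    if len(matrix.conditions) < 2:
        raise ValueError("need at least 2 conditions to track disappearance")
    events: list[IncorporationEvent] = []
    for prev, cur in zip(matrix.conditions, matrix.conditions[1:]):
        newly_absent = sorted(
            matrix.present_positions(prev) - matrix.present_positions(cur)
        )
        for start, end in _runs_bridging_prolines(newly_absent, seq):
            members = tuple(p for p in newly_absent if start <= p <= end)
            seg = SegmentCall(
                start, end, "incorporated-at-condition", cur.label,
                evidence={"newly_absent_positions": members},
            )
            events.append(IncorporationEvent(seg, cur, members))
    return events


def find_nucleation(
    matrix: PresenceMatrix,
    exchange: Sequence[SegmentCall],
    seq: ProteinSequence,
    flank_window: int = DEFAULT_FLANK_WINDOW,
) -> list[NucleationCall]:
    """Candidate nucleation sites at the highest-denaturant condition.

    Every maximal absent run at the first (highest ``dmso_fraction``)
    condition that has a detected exchange segment within ``flank_window``
    residues on *both* sides is returned. Runs touching a chain terminus are
    excluded: one flank is geometrically impossible there (this also
    discards the always-missing N-terminal amide).
    """
    top = matrix.conditions[0]
    axis = _observable_axis(seq)
    absent = [p for p in axis if not matrix.is_present(p, top)]
    calls: list[NucleationCall] = []
    for start, end in _runs_bridging_prolines(absent, seq):
        if start <= axis[0] or end >= axis[-1]:
            continue
        left = [s for s in exchange
                if s.end < start and start - s.end <= flank_window]
        right = [s for s in exchange
                 if s.start > end and s.start - end <= flank_window]
        if left and right:
            calls.append(NucleationCall(
                start, end,
                max(left, key=lambda s: s.end),
                min(right, key=lambda s: s.start),
                top,
            ))
    return calls


def hierarchy_report(
    seq: ProteinSequence,
    matrix: PresenceMatrix,
    events: Sequence[IncorporationEvent],
    nucleation: Sequence[NucleationCall],
    propensity: Mapping[str, Sequence[SegmentCall]] | None = None,
    exchange: Mapping[str, Sequence[SegmentCall]] | None = None,
) -> dict:
    """Assemble the full, JSON-serialisable hierarchy report.

    Per condition: newly incorporated segments, remaining flexible (still
    visible) segments, and any propensity / exchange calls. Globally: the
    nucleation call(s), the incorporation order, the consistency audit, and
    an N-half vs C-half packing summary (fraction of each half's observable
    residues already incorporated at each condition).
    """
    propensity = propensity or {}
    exchange = exchange or {}
    axis = _observable_axis(seq)
    mid = (seq.first + seq.last) / 2
    n_half = [p for p in axis if p <= mid]
    c_half = [p for p in axis if p > mid]

    per_condition = []
    for c in matrix.conditions:
        present = matrix.present_positions(c)
        flexible = _runs_bridging_prolines(sorted(present), seq) if present else []
        newly = [list(e.segment.interval) for e in events if e.condition.label == c.label]
        per_condition.append({
            "condition": c.label,
            "dmso_fraction": c.dmso_fraction,
            "n_present": len(present),
            "newly_incorporated": newly,
            "flexible_segments": [list(r) for r in flexible],
            "propensity": [
                {"interval": list(s.interval), "label": s.label}
                for s in propensity.get(c.label, [])
            ],
            "exchange": [list(s.interval) for s in exchange.get(c.label, [])],
            "packing": {
                "n_half_incorporated": (
                    sum(1 for p in n_half if p not in present) / len(n_half)
                    if n_half else 0.0
                ),
                "c_half_incorporated": (
                    sum(1 for p in c_half if p not in present) / len(c_half)
                    if c_half else 0.0
                ),
            },
        })
    return {
        "sequence": {"name": seq.name, "first": seq.first, "last": seq.last,
                     "prolines": sorted(seq.prolines)},
        "conditions": list(matrix.labels),
        "per_condition": per_condition,
        "nucleation": [
            {"interval": list(n.interval),
             "left_flank": list(n.left_flank.interval),
             "right_flank": list(n.right_flank.interval),
             "condition": n.condition.label}
            for n in nucleation
        ],
        "incorporation_order": [
            {"condition": e.condition.label, "interval": list(e.segment.interval)}
            for e in events
        ],
        "consistency": consistency_report(matrix, seq),
    }
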