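"""Core domain types shared by every analysis stage.

The coordinate frame for all per-residue results is a :class:`ProteinSequence`
with 1-based, contiguous residue numbering. Intervals are closed on both ends
(``[start, end]`` includes both residues), matching the convention used when
reporting protein segments such as ``Arg109-Met116``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: nuclei the pipeline understands (backbone plus the proline side-chain pair)
NUCLEI = ("CA", "CB", "CG", "N", "H", "HA", "C")

#: peak states: the dominant conformer and slow-exchange duplicates
STATES = ("major", "minor")

#: residue observability states in a presence matrix
PRESENCE_STATES = ("present", "absent", "minor_duplicate")


class ParseError(ValueError):
    """Raised when an input file violates the documented format."""


@dataclass(frozen=True)
class ProteinSequence:
    """A numbered amino-acid sequence.

    Parameters
    ----------
    residues:
        Ordered ``(position, one_letter_code)`` pairs. Positions must be
        strictly increasing and contiguous.
    name:
        Free-text identifier (e.g. the FASTA header).
    """

    residues: tuple[tuple[int, str], ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("sequence must contain at least one residue")
        prev = None
        for pos, aa in self.residues:
            if aa not in STANDARD_AA:
                raise ParseError(f"non-standard amino acid letter {aa!r} at position {pos}")
            if prev is not None and pos != prev + 1:
                raise ValueError(
                    f"positions must be contiguous and increasing; got {prev} -> {pos}"
                )
            prev = pos

    @classmethod
    def from_string(cls, seq: str, first: int = 1, name: str = "") -> "ProteinSequence":
        seq = seq.strip().upper()
        if not seq:
            raise ParseError("empty sequence")
        return cls(tuple((first + i, aa) for i, aa in enumerate(seq)), name=name)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    @property
    def first(self) -> int:
        return self.residues[0][0]

    @property
    def last(self) -> int:
        return self.residues[-1][0]

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.residues)

    @property
    def prolines(self) -> frozenset[int]:
        return frozenset(p for p, aa in self.residues if aa == "P")

    def amino_acid(self, position: int) -> str:
        if not self.first <= position <= self.last:
            raise KeyError(f"position {position} outside sequence [{self.first}, {self.last}]")
        return self.residues[position - self.first][1]

    def __contains__(self, position: int) -> bool:
        return self.first <= position <= self.last

    def as_str(self) -> str:
        return "".join(aa for _, aa in self.residues)


@dataclass(frozen=True)
class Condition:
    """One point on the denaturant ladder.

    ``dmso_fraction`` is the DMSO volume fraction in [0, 1]; 1.0 is the fully
    denaturing condition, lower fractions approach the aqueous/assembled state.
    """

    dmso_fraction: float
    temperature_c: float = 45.0
    field_mhz: float = 800.0
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.dmso_fraction <= 1.0:
            raise ValueError(f"dmso_fraction must be in [0,1], got {self.dmso_fraction}")
        if self.field_mhz <= 0:
            raise ValueError("field_mhz must be positive")
        if not self.label:
            object.__setattr__(self, "label", f"dmso{round(self.dmso_fraction * 100):d}")


@dataclass(frozen=True)
class ShiftRecord:
    """One assigned chemical shift: residue, nucleus, ppm, conformer state."""

    position: int
    nucleus: str
    shift_ppm: float
    state: str = "major"

    def __post_init__(self) -> None:
        if self.nucleus not in NUCLEI:
            raise ValueError(f"unknown nucleus {self.nucleus!r}; expected one of {NUCLEI}")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if not math.isfinite(self.shift_ppm):
            raise ValueError(f"shift for residue {self.position} {self.nucleus} is not finite")


@dataclass
class ShiftTable:
    """All assigned shifts for one condition.

    ``(position, nucleus, state)`` is unique within a table; slow-exchange
    duplicate peaks are kept as distinct ``state='minor'`` records rather than
    merged into the major set.
    """

    condition: Condition
    records: list[ShiftRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, str, str]] = set()
        for rec in self.records:
            key = (rec.position, rec.nucleus, rec.state)
            if key in seen:
                raise ValueError(f"duplicate shift record for (position={key[0]}, "
                                 f"nucleus={key[1]}, state={key[2]})")
            seen.add(key)

    def get(self, position: int, nucleus: str, state: str = "major") -> Optional[ShiftRecord]:
        for rec in self.records:
            if rec.position == position and rec.nucleus == nucleus and rec.state == state:
                return rec
        return None

    def shifts(self, nucleus: str, state: str = "major") -> dict[int, float]:
        """Map position -> shift for one nucleus/state."""
        return {
            rec.position: rec.shift_ppm
            for rec in self.records
            if rec.nucleus == nucleus and rec.state == state
        }

    def positions(self, state: str = "major") -> frozenset[int]:
        return frozenset(rec.position for rec in self.records if rec.state == state)

    def validate_against(self, seq: ProteinSequence) -> None:
        for rec in self.records:
            if rec.position not in seq:
                raise ValueError(
                    f"shift record references position {rec.position} outside the sequence"
                )


@dataclass(frozen=True)
class DoubletPeak:
    """A resolved amide doublet from a high-resolution HSQC.

    The in-phase splitting of the two proton components carries the
    three-bond HN-HA scalar coupling.
    """

    position: int
    h_ppm_low: float
    h_ppm_high: float
    n_ppm: float

    def __post_init__(self) -> None:
        if self.h_ppm_high < self.h_ppm_low:
            raise ValueError(
                f"doublet at position {self.position}: h_ppm_high < h_ppm_low"
            )

    @property
    def splitting_ppm(self) -> float:
        return self.h_ppm_high - self.h_ppm_low


@dataclass
class RelaxationSeries:
    """Per-residue CPMG intensity decays for one condition.

    ``delays_s`` are the CPMG relaxation delays in seconds (strictly
    increasing, all positive); ``intensities[p]`` is the decay curve of
    residue ``p`` sampled at those delays.
    """

    condition: Condition
    delays_s: tuple[float, ...]
    intensities: dict[int, tuple[float, ...]]
    intensity_errors: dict[int, tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        self.delays_s = tuple(float(d) for d in self.delays_s)
        if len(self.delays_s) < 3:
            raise ValueError("need at least 3 CPMG delays")
        if any(d <= 0 for d in self.delays_s):
            raise ValueError("all delays must be positive")
        if any(b <= a for a, b in zip(self.delays_s, self.delays_s[1:])):
            raise ValueError("delays must be strictly increasing")
        self.intensities = {p: tuple(float(v) for v in vals)
                            for p, vals in self.intensities.items()}
        for p, vals in self.intensities.items():
            if len(vals) != len(self.delays_s):
                raise ValueError(
                    f"residue {p}: {len(vals)} intensities for {len(self.delays_s)} delays"
                )
        if self.intensity_errors is not None:
            self.intensity_errors = {p: tuple(float(v) for v in vals)
                                     for p, vals in self.intensity_errors.items()}
            for p, vals in self.intensity_errors.items():
                if len(vals) != len(self.delays_s):
                    raise ValueError(f"residue {p}: error list length mismatch")


@dataclass
class PresenceMatrix:
    """Residue x condition observability.

    ``states[(position, label)]`` is one of ``present`` / ``absent`` /
    ``minor_duplicate`` (present with a slow-exchange duplicate peak).
    Prolines carry no backbone amide proton and are therefore never
    ``present``; they are tracked by ``proline_mask``.
    """

    conditions: tuple[Condition, ...]
    states: dict[tuple[int, str], str]
    proline_mask: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        fracs = [c.dmso_fraction for c in self.conditions]
        if any(b >= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("conditions must be ordered by strictly decreasing dmso_fraction")
        for (pos, label), st in self.states.items():
            if st not in PRESENCE_STATES:
                raise ValueError(f"unknown presence state {st!r} at ({pos}, {label})")
            if pos in self.proline_mask and st != "absent":
                raise ValueError(f"proline {pos} cannot be {st}: prolines have no amide peak")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.conditions)

    def positions(self) -> tuple[int, ...]:
        return tuple(sorted({p for p, _ in self.states}))

    def state(self, position: int, condition: "Condition | str") -> str:
        label = condition if isinstance(condition, str) else condition.label
        return self.states[(position, label)]

    def is_present(self, position: int, condition: "Condition | str") -> bool:
        """present or present-with-minor-duplicate."""
        return self.state(position, condition) in ("present", "minor_duplicate")

    def present_positions(self, condition: "Condition | str") -> frozenset[int]:
        label = condition if isinstance(condition, str) else condition.label
        return frozenset(
            p for (p, lab), st in self.states.items()
            if lab == label and st in ("present", "minor_duplicate")
        )

    def validate_complete(self, seq: ProteinSequence) -> None:
        """Every non-proline position must carry a state at every condition."""
        for pos in seq.positions:
            if pos in self.proline_mask:
                continue
            for c in self.conditions:
                if (pos, c.label) not in self.states:
                    raise ValueError(f"missing state for residue {pos} at {c.label}")


@dataclass(frozen=True)
class SegmentCall:
    """A contiguous residue interval with a class label and evidence.

    ``label`` is one of the pipeline's segment classes: ``helix-propensity``,
    ``sheet-propensity``, ``exchange``, ``nucleation`` or
    ``incorporated-at-condition``. The interval is closed: ``[start, end]``.
    """

    start: int
    end: int
    label: str
    condition_label: str = ""
    evidence: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"segment end {self.end} before start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


def contiguous_runs(positions: Iterable[int]) -> list[tuple[int, int]]:
    """Collapse a set of integer positions into maximal closed intervals."""
    pts = sorted(set(positions))
    if not pts:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = pts[0]
    for p in pts[1:]:
        if p == prev + 1:
            prev = p
        else:
            runs.append((start, prev))
            start = prev = p
    runs.append((start, prev))
    return runs
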