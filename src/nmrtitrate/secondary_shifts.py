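"""Secondary Calpha chemical shifts in mixed DMSO/water solvents.

In a mixed solvent the random-coil baseline itself moves with composition, so
the secondary shift of residue *i* is computed against a blended baseline:

    dCA(i) = CA_obs(i) - (p1 * CA_rc_dmso(aa_i) + p2 * CA_rc_aq(aa_i))

where ``p1 + p2 = 1`` weight the DMSO and aqueous random-coil reference
tables. Contiguous runs of residues whose dCA clears an uncertainty
threshold (default 0.7 ppm, the typical spread of Calpha shifts) are called
as helix- (positive) or sheet- (negative) propensity segments.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Mapping

from .datamodel import Condition, ProteinSequence, SegmentCall, ShiftTable, contiguous_runs
from .io import read_random_coil

DEFAULT_THRESHOLD_PPM = 0.7
DEFAULT_MIN_LEN = 3


@dataclass(frozen=True)
class RandomCoilTable:
    """Random-coil Calpha reference shifts for one solvent medium."""

    medium: str  # "dmso" or "aqueous"
    values: Mapping[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.values)
        if missing:
            raise ValueError(f"random-coil table missing amino acids: {sorted(missing)}")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]


def _load_packaged(filename: str, medium: str, source: str) -> RandomCoilTable:
    ref = importlib.resources.files("nmrtitrate.data").joinpath(filename)
    with importlib.resources.as_file(ref) as path:
        return RandomCoilTable(medium, read_random_coil(path, medium=medium), source)


def default_random_coil_dmso() -> RandomCoilTable:
    """Packaged DMSO Calpha random-coil defaults.

    These are synthetic defaults: aqueous reference values carried over with
    a uniform solvent correction, standing in for peptide-calibrated DMSO
    tables (Grathwohl & Wuthrich). Replace with calibrated values for
    quantitative work on real spectra; all pipeline logic is independent of
    the numbers.
    """
    return _load_packaged(
        "random_coil_ca_dmso_synthetic_default.tsv", "dmso",
        "synthetic default (uniform offset from aqueous)",
    )


def default_random_coil_aqueous() -> RandomCoilTable:
    """Packaged aqueous Calpha random-coil defaults (Richarz/Wishart-style)."""
    return _load_packaged(
        "random_coil_ca_aqueous_default.tsv", "aqueous",
        "standard aqueous random-coil compilation",
    )


@dataclass
class SecondaryShiftProfile:
    """Per-residue dCA for one condition, with the solvent weights used."""

    condition: Condition
    deltas: dict[int, float]
    p1: float
    p2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p1 <= 1.0 and 0.0 <= self.p2 <= 1.0):
            raise ValueError("solvent weights must lie in [0, 1]")
        if abs(self.p1 + self.p2 - 1.0) > 1e-9:
            raise ValueError(f"solvent weights must sum to 1, got {self.p1 + self.p2}")


WeightPolicy = Callable[[Condition], tuple[float, float]]


def solvent_weights(condition: Condition) -> tuple[float, float]:
    """Default solvent-weight policy: the DMSO volume fraction.

    The weights represent the relative exposure of the chain to the two
    solvents; absent a direct measurement, the volume fraction is the
    declared default. Any ``Condition -> (p1, p2)`` callable can replace it.
    """
    p1 = condition.dmso_fraction
    return (p1, 1.0 - p1)


def delta_ca(
    obs: ShiftTable,
    rc_dmso: RandomCoilTable,
    rc_aq: RandomCoilTable,
    seq: ProteinSequence,
    weight_policy: WeightPolicy = solvent_weights,
) -> SecondaryShiftProfile:
    """Secondary Calpha shifts against the composition-blended baseline.

    Only major-state CA records contribute. Residues with no CA record are
    simply absent from the result (never zero-filled), so downstream segment
    calling treats them as run breakers.
    """
    p1, p2 = weight_policy(obs.condition)
    deltas: dict[int, float] = {}
    for pos, ca_obs in sorted(obs.shifts("CA", state="major").items()):
        aa = seq.amino_acid(pos)
        try:
            baseline = p1 * rc_dmso[aa] + p2 * rc_aq[aa]
        except KeyError:
            raise KeyError(
                f"residue {aa}{pos} missing from a random-coil table"
            ) from None
        deltas[pos] = ca_obs - baseline
    return SecondaryShiftProfile(obs.condition, deltas, p1, p2)


def call_propensity_segments(
    profile: SecondaryShiftProfile,
    threshold_ppm: float = DEFAULT_THRESHOLD_PPM,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[SegmentCall]:
    """Maximal contiguous runs of significant secondary shifts.

    A residue is helix-significant when ``dCA > threshold`` and
    sheet-significant when ``dCA < -threshold``; the inequalities are strict,
    so a residue sitting exactly at the uncertainty line is not significant.
    Sub-threshold and missing residues break runs; only runs of at least
    ``min_len`` residues are reported.
    """
    if threshold_ppm < 0:
        raise ValueError("threshold_ppm must be non-negative")
    calls: list[SegmentCall] = []
    for sign, label in ((+1, "helix-propensity"), (-1, "sheet-propensity")):
        qualifying = [p for p, d in profile.deltas.items() if sign * d > threshold_ppm]
        for start, end in contiguous_runs(qualifying):
            if end - start + 1 >= min_len:
                seg_deltas = {p: profile.deltas[p] for p in range(start, end + 1)}
                calls.append(SegmentCall(
                    start, end, label, profile.condition.label,
                    evidence={"deltas_ppm": seg_deltas,
                              "threshold_ppm": threshold_ppm},
                ))
    calls.sort(key=lambda s: (s.start, s.label))
    return calls
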