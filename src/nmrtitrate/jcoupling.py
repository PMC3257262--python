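"""Three-bond HN-HA scalar couplings from HSQC doublet splittings.

3J(HN-HA) reports on the backbone phi torsion and, unlike chemical shifts,
is largely solvent-independent. Typical values: 3-5 Hz in an alpha helix,
6-8 Hz in a random coil, 8-11 Hz in beta sheet. An *unresolved* doublet
(no measurable splitting) is evidence of helix, not a 0 Hz coupling, and is
kept as an explicit state throughout.

Random-coil reference couplings are corrected for an aromatic preceding
residue (ring-current and phi-distribution effects shift the coil value);
the correction magnitude is a configurable parameter.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .datamodel import Condition, DoubletPeak, ProteinSequence

AROMATIC = frozenset("FYWH")

#: classification band edges in Hz (inclusive as documented in classify_band)
HELIX_BAND = (3.0, 5.0)
COIL_BAND = (6.0, 8.0)
SHEET_BAND = (8.0, 11.0)

DEFAULT_AROMATIC_CORRECTION_HZ = -0.5


def default_j_random_base() -> dict[str, float]:
    """Packaged per-residue random-coil 3J(HN-HA) base values in Hz.

    Synthetic defaults near the coil mid-band (~7 Hz); editable data meant to
    be replaced by peptide-calibrated values (Penkett-style) for real work.
    """
    ref = importlib.resources.files("nmrtitrate.data").joinpath(
        "j_random_base_synthetic_default.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["aa"], df["j_hz"].astype(float)))


def j_from_doublet(peak: DoubletPeak, field_mhz: float) -> float:
    """Coupling in Hz from the doublet splitting in ppm.

    J = (h_ppm_high - h_ppm_low) * field_mhz; linear in the proton frequency.
    """
    if field_mhz <= 0:
        raise ValueError("field_mhz must be positive")
    return peak.splitting_ppm * field_mhz


def j_random_for(
    seq: ProteinSequence,
    position: int,
    base: Mapping[str, float] | None = None,
    aromatic_correction_hz: float = DEFAULT_AROMATIC_CORRECTION_HZ,
) -> float | None:
    """Random-coil 3J for a residue, corrected for an aromatic predecessor.

    Returns ``None`` for the first residue in the chain (no preceding
    residue, so the correction is undefined and the coupling is treated as
    unresolved downstream).
    """
    if base is None:
        base = default_j_random_base()
    if position == seq.first:
        return None
    aa = seq.amino_acid(position)
    j = base[aa]
    if seq.amino_acid(position - 1) in AROMATIC:
        j += aromatic_correction_hz
    return j


def classify_band(j_obs: float) -> str:
    """Assign a coupling to the helix / coil / sheet band.

    Bands: helix [3, 5], coil [6, 8], sheet (8, 11]. The shared edge at 8 Hz
    goes to coil so that the classification is total and deterministic.
    Values in the gaps (below 3, between 5 and 6, above 11) are unresolved.
    """
    if j_obs < 0:
        raise ValueError("coupling must be non-negative")
    if HELIX_BAND[0] <= j_obs <= HELIX_BAND[1]:
        return "helix"
    if COIL_BAND[0] <= j_obs <= COIL_BAND[1]:
        return "coil"
    if SHEET_BAND[0] < j_obs <= SHEET_BAND[1]:
        return "sheet"
    return "unresolved"


@dataclass
class JCouplingProfile:
    """Per-residue observed / reference couplings and their deviations.

    ``deviation[p] = j_obs[p] - j_random[p]``; negative deviations flag
    helical propensity (PPII structures deviate the same way — recorded in
    ``notes``), positive deviations flag sheet propensity. Residues present
    in ``unresolved`` had no measurable splitting, which in a titration
    toward the folded state is itself evidence of helical structure.
    """

    condition: Condition
    j_obs: dict[int, float]
    j_random: dict[int, float]
    deviation: dict[int, float]
    band: dict[int, str]
    unresolved: frozenset[int] = frozenset()
    notes: dict[str, str] = field(default_factory=dict)

    def deviation_range(self) -> tuple[float, float]:
        """(min, max) of the observed deviations in Hz."""
        vals = list(self.deviation.values())
        if not vals:
            raise ValueError("profile has no resolved deviations")
        return (min(vals), max(vals))


def deviation_profile(
    doublets: Iterable[DoubletPeak],
    seq: ProteinSequence,
    condition: Condition,
    base: Mapping[str, float] | None = None,
    aromatic_correction_hz: float = DEFAULT_AROMATIC_CORRECTION_HZ,
    unresolved_positions: Iterable[int] = (),
) -> JCouplingProfile:
    """Build the full coupling-deviation profile for one condition.

    ``unresolved_positions`` lists residues whose peaks were observed but
    showed no measurable splitting; they carry no ``j_obs`` and are flagged
    explicitly.
    """
    if base is None:
        base = default_j_random_base()
    j_obs: dict[int, float] = {}
    j_random: dict[int, float] = {}
    deviation: dict[int, float] = {}
    band: dict[int, str] = {}
    unresolved = set(unresolved_positions)
    for peak in doublets:
        j = j_from_doublet(peak, condition.field_mhz)
        jr = j_random_for(seq, peak.position, base, aromatic_correction_hz)
        if jr is None:
            unresolved.add(peak.position)
            continue
        j_obs[peak.position] = j
        j_random[peak.position] = jr
        deviation[peak.position] = j - jr
        band[peak.position] = classify_band(j)
    return JCouplingProfile(
        condition, j_obs, j_random, deviation, band, frozenset(unresolved),
        notes={"negative_deviation": "helical propensity (includes PPII)",
               "positive_deviation": "sheet propensity",
               "unresolved": "no measurable splitting; consistent with helix"},
    )
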