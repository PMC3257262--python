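"""Cis/trans assignment of X-Pro peptide bonds from proline 13C shifts.

The chemical-shift difference between the proline Cbeta and Cgamma nuclei is
a clean isomer reporter: around 5 ppm for a trans peptide bond and around
9-10 ppm for cis. Classification uses a configurable decision boundary
(default 7 ppm) with a symmetric ambiguity band (default +/- 1 ppm): below
the band is trans, above is cis, inside is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datamodel import ProteinSequence, ShiftTable

DEFAULT_BOUNDARY_PPM = 7.0
DEFAULT_MARGIN_PPM = 1.0


@dataclass(frozen=True)
class ProlineCall:
    position: int
    delta_bg_ppm: float
    isomer: str  # cis / trans / ambiguous
    state: str = "major"


def classify_proline(
    cb_ppm: float,
    cg_ppm: float,
    position: int = 0,
    state: str = "major",
    boundary_ppm: float = DEFAULT_BOUNDARY_PPM,
    margin_ppm: float = DEFAULT_MARGIN_PPM,
) -> ProlineCall:
    """Classify one X-Pro bond from the Cbeta and Cgamma shifts.

    delta = cb - cg. trans when delta < boundary - margin; cis when
    delta > boundary + margin; ambiguous inside the closed band
    [boundary - margin, boundary + margin]. The zones are disjoint and
    monotone in delta.
    """
    if margin_ppm < 0:
        raise ValueError("margin_ppm must be non-negative")
    delta = cb_ppm - cg_ppm
    if delta < boundary_ppm - margin_ppm:
        isomer = "trans"
    elif delta > boundary_ppm + margin_ppm:
        isomer = "cis"
    else:
        isomer = "ambiguous"
    return ProlineCall(position, delta, isomer, state)


def classify_prolines(
    table: ShiftTable,
    seq: ProteinSequence,
    boundary_ppm: float = DEFAULT_BOUNDARY_PPM,
    margin_ppm: float = DEFAULT_MARGIN_PPM,
) -> list[ProlineCall]:
    """Classify every proline with both CB and CG assigned (major and minor).

    A proline with one of the two nuclei missing raises, naming the position
    and nucleus, since a silent skip would understate the isomer evidence.
    """
    calls: list[ProlineCall] = []
    for state in ("major", "minor"):
        cbs = table.shifts("CB", state)
        cgs = table.shifts("CG", state)
        for pos in sorted(seq.prolines):
            has_cb, has_cg = pos in cbs, pos in cgs
            if not has_cb and not has_cg:
                continue  # this proline/state simply not recorded
            if not has_cb or not has_cg:
                missing = "CB" if not has_cb else "CG"
                raise ValueError(f"proline {pos} ({state}): missing {missing} shift")
            calls.append(classify_proline(
                cbs[pos], cgs[pos], pos, state, boundary_ppm, margin_ppm))
    return calls
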