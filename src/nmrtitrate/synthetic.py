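"""Self-consistent synthetic titration study with a planted ground truth.

The generator plants a folding-and-association model on a synthetic chain —
a nucleation segment that is already assembly-bound (hence NMR-invisible) at
the highest denaturant concentration, incorporation stages that radiate
outward from it in both directions as denaturant is diluted, and a flexible
N-terminal tail that never joins the core — and emits every observable the
pipeline consumes: per-condition chemical-shift tables (with slow-exchange
minor duplicates and trans-proline CB/CG pairs), HSQC doublet lists, CPMG
decay series, and the presence matrix. The planted model is returned
alongside, so every analysis stage can be scored against the truth.

The default geometry mirrors a 137-residue coiled-coil construct with
prolines at 12/38/67, nucleation at [109, 116] and a flexible tail [2, 32];
the sequence itself is synthetic (drawn from the seed) since only the
landmarks matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .datamodel import (
    Condition,
    DoubletPeak,
    PresenceMatrix,
    ProteinSequence,
    RelaxationSeries,
    ShiftRecord,
    ShiftTable,
)
from .relaxation import DEFAULT_CPMG_DELAYS_S
from .secondary_shifts import (
    RandomCoilTable,
    default_random_coil_aqueous,
    default_random_coil_dmso,
    solvent_weights,
)

#: the denaturant ladder the study conditions follow (DMSO volume fractions)
DEFAULT_DMSO_LADDER = (1.00, 0.90, 0.85, 0.80, 0.70, 0.50)


def default_conditions() -> tuple[Condition, ...]:
    return tuple(Condition(dmso_fraction=f) for f in DEFAULT_DMSO_LADDER)


#: incorporation stages of the default fixture: condition index at which each
#: band becomes absent, radiating outward from the nucleation segment
DEFAULT_STAGE_BANDS: dict[int, tuple[tuple[int, int], ...]] = {
    0: ((109, 116),),
    1: ((97, 108), (117, 121)),
    2: ((69, 96), (122, 125)),
    3: ((126, 137),),
    4: ((39, 68),),
    5: ((33, 38),),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Declarative description of the planted study.

    Emission parameters: ``helix_offset_ppm`` is the full-folding secondary
    Calpha shift (+2.8 ppm, a typical helical magnitude); couplings shrink
    from ``j_coil_hz`` toward ``j_helix_hz`` with folding and are omitted
    (unresolved) below ``j_floor_hz``; exchange-broadened residues carry
    ``r2_base + r2_exchange_boost``. Noise levels are the study-typical
    defaults: 0.2 ppm shift scatter, 2% intensity scatter, 0.2 Hz coupling
    scatter.
    """

    n_residues: int = 137
    first: int = 1
    proline_positions: tuple[int, ...] = (12, 38, 67)
    nucleation: tuple[int, int] = (109, 116)
    flexible: tuple[int, int] = (2, 32)
    dmso_ladder: tuple[float, ...] = DEFAULT_DMSO_LADDER
    stage_bands: Mapping[int, tuple[tuple[int, int], ...]] | None = None
    helix_offset_ppm: float = 2.8
    shift_sigma_ppm: float = 0.2
    intensity_sigma_frac: float = 0.02
    j_sigma_hz: float = 0.2
    j_coil_hz: float = 7.0
    j_helix_hz: float = 4.0
    j_floor_hz: float = 3.0
    r2_base: float = 3.0
    r2_exchange_boost: float = 12.0
    boost_window: int = 1
    trans_pro_delta_ppm: float = 5.0
    minor_positions: tuple[int, ...] = (9, 10, 13, 14, 70, 71, 72)
    minor_proline_positions: tuple[int, ...] = (12,)
    i0: float = 100.0
    delays_s: tuple[float, ...] = DEFAULT_CPMG_DELAYS_S


DEFAULT_CONFIG = SyntheticConfig()


@dataclass(frozen=True)
class GroundTruth:
    """The planted model: who folds when, and with what propensity.

    ``stage[p]`` is the condition index at which residue *p* becomes absent
    (``None`` = stays flexible forever). ``always_absent`` holds the
    N-terminal residue, whose amide proton exchanges too fast to observe at
    any condition.
    """

    seq: ProteinSequence
    helix_propensity: Mapping[int, float]
    stage: Mapping[int, int | None]
    nucleation_segment: tuple[int, int]
    flexible_segment: tuple[int, int]
    always_absent: frozenset[int]
    amide_h_ppm: Mapping[int, float]
    amide_n_ppm: Mapping[int, float]
    config: SyntheticConfig
    seed: int

    def __post_init__(self) -> None:
        n0, n1 = self.nucleation_segment
        for p in range(n0, n1 + 1):
            if self.stage.get(p) != 0:
                raise ValueError("nucleation residues must carry the earliest stage (0)")
        self._check_radiating()

    def _check_radiating(self) -> None:
        """Stages never decrease with distance from the nucleation segment."""
        n0, n1 = self.nucleation_segment
        inf = math.inf
        for arm in (range(n1 + 1, self.seq.last + 1),
                    range(n0 - 1, self.seq.first - 1, -1)):
            prev = 0.0
            for p in arm:
                if p in self.always_absent or p in self.seq.prolines:
                    continue
                s = self.stage.get(p)
                val = inf if s is None else float(s)
                if val < prev:
                    raise ValueError(
                        f"stage decreases with distance from nucleation at residue {p}"
                    )
                prev = val
        return None

    def fold_fraction(self, position: int, condition_index: int) -> float:
        """Degree of folding of a residue at a condition (0 = coil, 1 = full).

        Residues ramp up linearly toward their incorporation stage, reaching
        full folding at the last condition where they are still visible;
        flexible residues stay at 0. Monotone non-decreasing down the ladder
        (hence non-increasing in ``dmso_fraction``).
        """
        s = self.stage.get(position)
        if s is None:
            return 0.0
        if s == 0:
            return 1.0
        return min(1.0, (condition_index + 1) / s)

    def is_present(self, position: int, condition_index: int) -> bool:
        if position in self.always_absent or position in self.seq.prolines:
            return False
        s = self.stage.get(position)
        return s is None or s > condition_index


@dataclass
class SyntheticStudy:
    """Everything the generator emits, keyed by condition label."""

    truth: GroundTruth
    conditions: tuple[Condition, ...]
    shift_tables: dict[str, ShiftTable]
    doublets: dict[str, list[DoubletPeak]]
    relaxation: dict[str, RelaxationSeries]
    presence: PresenceMatrix


def _random_sequence(rng: np.random.Generator, config: SyntheticConfig) -> ProteinSequence:
    letters = list("ACDEFGHIKLMNQRSTVWY")  # no proline; prolines are planted
    seq = [letters[i] for i in rng.integers(0, len(letters), size=config.n_residues)]
    for p in config.proline_positions:
        seq[p - config.first] = "P"
    return ProteinSequence.from_string("".join(seq), first=config.first, name="synthetic")


def _radiating_stage_bands(
    config: SyntheticConfig,
) -> dict[int, tuple[tuple[int, int], ...]]:
    """Generic radiating stage map for non-default geometries.

    Residues outside the nucleation and flexible segments are assigned
    stages 1..C-1 proportional to their distance from the nucleation
    segment, per arm, so that stages never decrease outward.
    """
    n0, n1 = config.nucleation
    f0, f1 = config.flexible
    last = config.first + config.n_residues - 1
    n_cond = len(config.dmso_ladder)
    bands: dict[int, list[int]] = {s: [] for s in range(n_cond)}
    bands[0] = list(range(n0, n1 + 1))
    for p in range(config.first, last + 1):
        if n0 <= p <= n1 or f0 <= p <= f1 or p == config.first:
            continue
        if p < n0:
            dist, arm_len = n0 - p, n0 - max(config.first + 1, f1 + 1)
        else:
            dist, arm_len = p - n1, last - n1
        frac = dist / max(arm_len, 1)
        stage = min(n_cond - 1, 1 + int(frac * (n_cond - 2)))
        bands[stage].append(p)
    from .datamodel import contiguous_runs
    return {s: tuple(contiguous_runs(ps)) for s, ps in bands.items() if ps}


def make_ground_truth(config: SyntheticConfig | None = None, seed: int = 0) -> GroundTruth:
    """Plant the model. Deterministic for a fixed (config, seed)."""
    config = config or DEFAULT_CONFIG
    n0, n1 = config.nucleation
    last = config.first + config.n_residues - 1
    if n0 <= config.first or n1 >= last:
        raise ValueError("nucleation segment must not touch a chain terminus")
    rng = np.random.default_rng(seed)
    seq = _random_sequence(rng, config)

    if config.stage_bands is not None:
        stage_bands = dict(config.stage_bands)
    elif (config.nucleation == DEFAULT_CONFIG.nucleation
          and config.flexible == DEFAULT_CONFIG.flexible
          and config.n_residues == DEFAULT_CONFIG.n_residues
          and config.dmso_ladder == DEFAULT_CONFIG.dmso_ladder):
        stage_bands = dict(DEFAULT_STAGE_BANDS)
    else:
        stage_bands = _radiating_stage_bands(config)

    stage: dict[int, int | None] = {}
    for s, intervals in stage_bands.items():
        for a, b in intervals:
            for p in range(a, b + 1):
                stage[p] = s
    f0, f1 = config.flexible
    for p in range(f0, f1 + 1):
        stage[p] = None
    propensity = {
        p: (1.0 if stage.get(p) is not None else 0.0) for p in seq.positions
    }
    amide_h = {p: float(7.7 + 1.0 * rng.random()) for p in seq.positions}
    amide_n = {p: float(112.0 + 14.0 * rng.random()) for p in seq.positions}
    return GroundTruth(
        seq=seq,
        helix_propensity=propensity,
        stage=stage,
        nucleation_segment=config.nucleation,
        flexible_segment=config.flexible,
        always_absent=frozenset({config.first}),
        amide_h_ppm=amide_h,
        amide_n_ppm=amide_n,
        config=config,
        seed=seed,
    )


def emit_observables(
    truth: GroundTruth,
    conditions: Sequence[Condition] | None = None,
    rc_dmso: RandomCoilTable | None = None,
    rc_aq: RandomCoilTable | None = None,
) -> SyntheticStudy:
    """Emit every observable of the planted study.

    Deterministic for a fixed ground truth: the emission stream is seeded
    from ``truth.seed``.
    """
    cfg = truth.config
    conditions = tuple(conditions) if conditions is not None else tuple(
        Condition(dmso_fraction=f) for f in cfg.dmso_ladder
    )
    rc_dmso = rc_dmso or default_random_coil_dmso()
    rc_aq = rc_aq or default_random_coil_aqueous()
    rng = np.random.default_rng(truth.seed + 1)
    seq = truth.seq
    prolines = seq.prolines

    shift_tables: dict[str, ShiftTable] = {}
    doublets: dict[str, list[DoubletPeak]] = {}
    relaxation: dict[str, RelaxationSeries] = {}
    presence_states: dict[tuple[int, str], str] = {}
    delays = np.asarray(cfg.delays_s)

    for ci, cond in enumerate(conditions):
        p1, p2 = solvent_weights(cond)
        records: list[ShiftRecord] = []
        dlist: list[DoubletPeak] = []
        intens: dict[int, tuple[float, ...]] = {}
        errs: dict[int, tuple[float, ...]] = {}

        # proline CB/CG pairs (from 3D carbon experiments; isomer reporters).
        # Emitted noiselessly: their uncertainty is far below the ppm-scale
        # separation between the trans and cis bands.
        for p in sorted(prolines):
            cb = 31.0
            records.append(ShiftRecord(p, "CB", cb, "major"))
            records.append(ShiftRecord(p, "CG", cb - cfg.trans_pro_delta_ppm, "major"))
            if p in cfg.minor_proline_positions:
                records.append(ShiftRecord(p, "CB", cb + 0.3, "minor"))
                records.append(ShiftRecord(
                    p, "CG", cb + 0.3 - cfg.trans_pro_delta_ppm, "minor"))

        for p, aa in seq:
            if p in prolines:
                continue
            if not truth.is_present(p, ci):
                presence_states[(p, cond.label)] = "absent"
                continue
            f = truth.fold_fraction(p, ci)
            prop = truth.helix_propensity[p]

            # chemical shifts: blended random-coil baseline + helical offset
            baseline = p1 * rc_dmso[aa] + p2 * rc_aq[aa]
            ca = baseline + cfg.helix_offset_ppm * prop * f \
                + rng.normal(0.0, cfg.shift_sigma_ppm)
            h = truth.amide_h_ppm[p] + rng.normal(0.0, 0.01)
            n = truth.amide_n_ppm[p] + rng.normal(0.0, 0.05)
            records.append(ShiftRecord(p, "CA", float(ca), "major"))
            records.append(ShiftRecord(p, "H", float(h), "major"))
            records.append(ShiftRecord(p, "N", float(n), "major"))

            is_minor = p in cfg.minor_positions
            if is_minor:
                records.append(ShiftRecord(p, "H", float(h) + 0.05, "minor"))
                records.append(ShiftRecord(p, "N", float(n) + 0.3, "minor"))
            presence_states[(p, cond.label)] = "minor_duplicate" if is_minor else "present"

            # doublet: splitting shrinks from coil toward helix with folding
            j_pred = cfg.j_coil_hz + (cfg.j_helix_hz - cfg.j_coil_hz) * prop * f
            if j_pred >= cfg.j_floor_hz:
                j = max(0.0, j_pred + rng.normal(0.0, cfg.j_sigma_hz))
                half = 0.5 * j / cond.field_mhz
                dlist.append(DoubletPeak(p, float(h - half), float(h + half), float(n)))

            # CPMG decay: exchange boost for residues about to be incorporated
            s = truth.stage.get(p)
            boosted = s is not None and ci < s <= ci + cfg.boost_window
            r2 = cfg.r2_base + (cfg.r2_exchange_boost if boosted else 0.0)
            clean = cfg.i0 * np.exp(-r2 * delays)
            noisy = clean * (1.0 + rng.normal(0.0, cfg.intensity_sigma_frac,
                                              size=delays.size))
            intens[p] = tuple(float(v) for v in np.maximum(noisy, 1e-6))
            errs[p] = tuple(float(v) for v in cfg.intensity_sigma_frac * clean)

        for p in sorted(prolines):
            presence_states[(p, cond.label)] = "absent"

        shift_tables[cond.label] = ShiftTable(cond, records)
        doublets[cond.label] = dlist
        relaxation[cond.label] = RelaxationSeries(cond, cfg.delays_s, intens, errs)

    presence = PresenceMatrix(conditions, presence_states, prolines)
    return SyntheticStudy(truth, conditions, shift_tables, doublets, relaxation, presence)


def simulate(
    config: SyntheticConfig | None = None, seed: int = 0
) -> SyntheticStudy:
    """One-call convenience: plant a ground truth and emit its observables."""
    truth = make_ground_truth(config, seed)
    return emit_observables(truth)
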