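"""End-to-end analysis: wire every stage into one hierarchy report.

Given a sequence, per-condition shift tables, doublet lists and CPMG series,
this runs secondary-shift propensity calling, coupling deviations, R2
fitting with exchange-segment detection, proline isomer calls, presence
bookkeeping and nucleation inference, and returns the structured report.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from . import hierarchy, jcoupling, proline, relaxation, secondary_shifts
from .config import RunConfig
from .datamodel import Condition, DoubletPeak, ProteinSequence, RelaxationSeries, ShiftTable


def analyse(
    seq: ProteinSequence,
    shift_tables: Mapping[str, ShiftTable],
    conditions: Sequence[Condition],
    doublets: Mapping[str, Sequence[DoubletPeak]] | None = None,
    relaxation_series: Mapping[str, RelaxationSeries] | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Run every stage and assemble the hierarchy report.

    ``conditions`` must be ordered by decreasing ``dmso_fraction`` and every
    mapping is keyed by condition label. Doublets and relaxation series are
    optional per condition; stages that lack input are simply omitted from
    the report for that condition.
    """
    config = config or RunConfig()
    rc_dmso = secondary_shifts.default_random_coil_dmso()
    rc_aq = secondary_shifts.default_random_coil_aqueous()

    ordered_tables = [shift_tables[c.label] for c in conditions]
    matrix = hierarchy.build_presence(ordered_tables, seq)
    events = hierarchy.disappearance_events(matrix, seq)

    propensity: dict[str, list] = {}
    exchange: dict[str, list] = {}
    couplings: dict[str, dict] = {}
    r2_summaries: dict[str, dict] = {}
    proline_calls: dict[str, list] = {}

    for cond in conditions:
        table = shift_tables[cond.label]
        profile = secondary_shifts.delta_ca(table, rc_dmso, rc_aq, seq)
        propensity[cond.label] = secondary_shifts.call_propensity_segments(
            profile, config.threshold_ppm, config.min_len)

        if doublets and cond.label in doublets:
            jprof = jcoupling.deviation_profile(
                doublets[cond.label], seq, cond,
                aromatic_correction_hz=config.aromatic_correction_hz)
            couplings[cond.label] = {
                "n_resolved": len(jprof.j_obs),
                "n_unresolved": len(jprof.unresolved),
                "deviation_range_hz": (list(jprof.deviation_range())
                                       if jprof.deviation else None),
            }

        if relaxation_series and cond.label in relaxation_series:
            r2prof = relaxation.fit_profile(relaxation_series[cond.label])
            if len(r2prof.r2) >= 5:
                exchange[cond.label] = relaxation.detect_exchange_segments(
                    r2prof, config.k_sigma, config.exchange_min_len)
                r2_summaries[cond.label] = r2prof.summary()

        calls = proline.classify_prolines(
            table, seq, config.boundary_ppm, config.margin_ppm)
        proline_calls[cond.label] = [
            {"position": c.position, "delta_bg_ppm": c.delta_bg_ppm,
             "isomer": c.isomer, "state": c.state}
            for c in calls
        ]

    top = conditions[0]
    nucleation = hierarchy.find_nucleation(
        matrix, exchange.get(top.label, []), seq, config.flank_window)

    report = hierarchy.hierarchy_report(
        seq, matrix, events, nucleation, propensity, exchange)
    report["parameters"] = config.to_dict()
    report["couplings"] = couplings
    report["r2_summary"] = r2_summaries
    report["prolines"] = proline_calls
    return report
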