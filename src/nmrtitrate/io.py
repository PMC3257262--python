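"""Readers and writers for the pipeline's plain-text formats.

Sequences are FASTA. Everything else is tab-separated text with a header row:

===============  =============================================================
shift table      condition_label, position, aa, nucleus, shift_ppm, state
doublet list     condition_label, position, h_ppm_low, h_ppm_high, n_ppm
relaxation       condition_label, position, delay_s, intensity, intensity_err
presence         condition_label, position, state
random coil      aa, shift_ppm, medium
===============  =============================================================

All writers sort rows deterministically so that write -> read -> write is
byte-stable. Floats are written with :func:`repr` precision, so a round trip
reproduces the exact values.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import pandas as pd
from Bio import SeqIO

from .datamodel import (
    Condition,
    DoubletPeak,
    ParseError,
    PresenceMatrix,
    ProteinSequence,
    RelaxationSeries,
    ShiftRecord,
    ShiftTable,
    contiguous_runs,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_sequence(source: Union[PathLike, TextIO, str], first: int = 1) -> ProteinSequence:
    """Read a single-record FASTA into a numbered :class:`ProteinSequence`.

    ``source`` may be a path, an open handle, or FASTA text itself. Numbering
    starts at ``first`` (default 1).
    """
    if isinstance(source, str) and source.lstrip().startswith(">"):
        handle: TextIO = _io.StringIO(source)
    elif hasattr(source, "read"):
        handle = source  # type: ignore[assignment]
    else:
        handle = open(source)  # noqa: SIM115 - closed by SeqIO iteration below
    records = list(SeqIO.parse(handle, "fasta"))
    if hasattr(handle, "close") and handle is not source:
        handle.close()
    if len(records) == 0:
        raise ParseError("no FASTA record found")
    if len(records) > 1:
        raise ParseError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return ProteinSequence.from_string(str(rec.seq), first=first, name=rec.id)


def write_sequence(seq: ProteinSequence, path: PathLike) -> None:
    Path(path).write_text(f">{seq.name or 'seq'}\n{seq.as_str()}\n")


def count_observable(seq: ProteinSequence) -> int:
    """Number of residues expected to give an amide cross peak in an HSQC.

    Prolines lack the backbone amide proton, so the expected peak count of a
    fully observable chain is the non-proline residue count.
    """
    return len(seq) - len(seq.prolines)


def residues_in_segment(
    seq: ProteinSequence, start: int, end: int, exclude_proline: bool = False
) -> int:
    """Count residues in the closed interval ``[start, end]``.

    With ``exclude_proline=True`` this is the expected amide peak count of
    the segment.
    """
    if start > end:
        raise ValueError(f"start {start} after end {end}")
    if start not in seq or end not in seq:
        raise ValueError(
            f"interval [{start}, {end}] not inside sequence [{seq.first}, {seq.last}]"
        )
    n = end - start + 1
    if exclude_proline:
        n -= sum(1 for p in seq.prolines if start <= p <= end)
    return n


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def _read_tsv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def _numeric(df: pd.DataFrame, column: str, path: PathLike) -> pd.Series:
    # python's float() is correctly rounded, so repr-written values
    # round-trip exactly (pandas' fast parser can be off by one ulp)
    def parse(value: str) -> float:
        try:
            return float(value) if value != "" else float("nan")
        except ValueError:
            return float("nan")

    out = df[column].map(parse)
    bad = out.isna() & (df[column] != "")
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}: non-numeric value {df[column][bad.idxmax()]!r} "
                         f"in column {column!r} at line {row}")
    return out


def _write_tsv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _condition_for(label: str, conditions: Mapping[str, Condition] | None) -> Condition:
    if conditions and label in conditions:
        return conditions[label]
    # fall back to parsing labels of the form "dmso90"
    if label.startswith("dmso"):
        try:
            return Condition(dmso_fraction=float(label[4:]) / 100.0, label=label)
        except ValueError:
            pass
    raise ParseError(f"unknown condition label {label!r}; pass a condition mapping")


# ---------------------------------------------------------------------------
# shift tables
# ---------------------------------------------------------------------------

SHIFT_COLUMNS = ["condition_label", "position", "aa", "nucleus", "shift_ppm", "state"]


def read_shift_tables(
    path: PathLike, conditions: Mapping[str, Condition] | None = None
) -> dict[str, ShiftTable]:
    """Read a shift TSV; returns one :class:`ShiftTable` per condition label."""
    df = _read_tsv(path, SHIFT_COLUMNS)
    df = df.assign(
        position=_numeric(df, "position", path).astype(int),
        shift_ppm=_numeric(df, "shift_ppm", path),
    )
    tables: dict[str, ShiftTable] = {}
    for label, grp in df.groupby("condition_label", sort=True):
        records = [
            ShiftRecord(int(r.position), r.nucleus, float(r.shift_ppm), r.state)
            for r in grp.itertuples()
        ]
        tables[str(label)] = ShiftTable(_condition_for(str(label), conditions), records)
    return tables


def write_shift_tables(
    tables: Iterable[ShiftTable], path: PathLike, seq: ProteinSequence | None = None
) -> None:
    rows = []
    for tab in tables:
        for rec in tab.records:
            aa = seq.amino_acid(rec.position) if seq and rec.position in seq else "X"
            rows.append((tab.condition.label, rec.position, aa, rec.nucleus,
                         repr(rec.shift_ppm), rec.state))
    rows.sort(key=lambda r: (r[0], r[1], r[3], r[5]))
    _write_tsv(pd.DataFrame(rows, columns=SHIFT_COLUMNS), path)


# ---------------------------------------------------------------------------
# doublet lists
# ---------------------------------------------------------------------------

DOUBLET_COLUMNS = ["condition_label", "position", "h_ppm_low", "h_ppm_high", "n_ppm"]


def read_doublets(path: PathLike) -> dict[str, list[DoubletPeak]]:
    df = _read_tsv(path, DOUBLET_COLUMNS)
    df = df.assign(
        position=_numeric(df, "position", path).astype(int),
        h_ppm_low=_numeric(df, "h_ppm_low", path),
        h_ppm_high=_numeric(df, "h_ppm_high", path),
        n_ppm=_numeric(df, "n_ppm", path),
    )
    out: dict[str, list[DoubletPeak]] = {}
    for label, grp in df.groupby("condition_label", sort=True):
        out[str(label)] = [
            DoubletPeak(int(r.position), float(r.h_ppm_low), float(r.h_ppm_high),
                        float(r.n_ppm))
            for r in grp.itertuples()
        ]
    return out


def write_doublets(doublets: Mapping[str, Sequence[DoubletPeak]], path: PathLike) -> None:
    rows = [
        (label, d.position, repr(d.h_ppm_low), repr(d.h_ppm_high), repr(d.n_ppm))
        for label in sorted(doublets)
        for d in sorted(doublets[label], key=lambda d: d.position)
    ]
    _write_tsv(pd.DataFrame(rows, columns=DOUBLET_COLUMNS), path)


# ---------------------------------------------------------------------------
# relaxation series
# ---------------------------------------------------------------------------

RELAX_COLUMNS = ["condition_label", "position", "delay_s", "intensity", "intensity_err"]


def read_relaxation(
    path: PathLike, conditions: Mapping[str, Condition] | None = None
) -> dict[str, RelaxationSeries]:
    df = _read_tsv(path, RELAX_COLUMNS)
    df = df.assign(
        position=_numeric(df, "position", path).astype(int),
        delay_s=_numeric(df, "delay_s", path),
        intensity=_numeric(df, "intensity", path),
        intensity_err=_numeric(df, "intensity_err", path),
    )
    out: dict[str, RelaxationSeries] = {}
    for label, grp in df.groupby("condition_label", sort=True):
        delays = tuple(sorted(grp["delay_s"].unique()))
        intens: dict[int, tuple[float, ...]] = {}
        errs: dict[int, tuple[float, ...]] = {}
        has_err = False
        for pos, sub in grp.groupby("position"):
            sub = sub.sort_values("delay_s")
            if tuple(sub["delay_s"]) != delays:
                raise ParseError(
                    f"{path}: residue {pos} at {label} does not cover the full delay set"
                )
            intens[int(pos)] = tuple(sub["intensity"])
            if sub["intensity_err"].notna().all():
                errs[int(pos)] = tuple(sub["intensity_err"])
                has_err = True
        out[str(label)] = RelaxationSeries(
            _condition_for(str(label), conditions), delays, intens,
            errs if has_err else None,
        )
    return out


def write_relaxation(series: Iterable[RelaxationSeries], path: PathLike) -> None:
    rows = []
    for s in series:
        for pos in sorted(s.intensities):
            errs = (s.intensity_errors or {}).get(pos)
            for k, (d, inten) in enumerate(zip(s.delays_s, s.intensities[pos])):
                e = repr(errs[k]) if errs is not None else ""
                rows.append((s.condition.label, pos, d, repr(inten), e))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    _write_tsv(
        pd.DataFrame(
            [(a, b, repr(c), d, e) for a, b, c, d, e in rows],
            columns=RELAX_COLUMNS,
        ),
        path,
    )


# ---------------------------------------------------------------------------
# presence matrices
# ---------------------------------------------------------------------------

PRESENCE_COLUMNS = ["condition_label", "position", "state"]


def read_presence(
    path: PathLike,
    conditions: Sequence[Condition],
    proline_mask: Iterable[int] = (),
) -> PresenceMatrix:
    df = _read_tsv(path, PRESENCE_COLUMNS)
    df = df.assign(position=_numeric(df, "position", path).astype(int))
    known = {c.label for c in conditions}
    states: dict[tuple[int, str], str] = {}
    for r in df.itertuples():
        if r.condition_label not in known:
            raise ParseError(f"{path}: unknown condition label {r.condition_label!r}")
        states[(int(r.position), r.condition_label)] = r.state
    return PresenceMatrix(tuple(conditions), states, frozenset(proline_mask))


def write_presence(matrix: PresenceMatrix, path: PathLike) -> None:
    order = {c.label: i for i, c in enumerate(matrix.conditions)}
    rows = sorted(
        ((label, pos, st) for (pos, label), st in matrix.states.items()),
        key=lambda r: (order[r[0]], r[1]),
    )
    _write_tsv(pd.DataFrame(rows, columns=PRESENCE_COLUMNS), path)


# ---------------------------------------------------------------------------
# random-coil reference tables
# ---------------------------------------------------------------------------

RC_COLUMNS = ["aa", "shift_ppm", "medium"]


def read_random_coil(path: PathLike, medium: str | None = None) -> dict[str, float]:
    """Read a random-coil reference TSV into an ``aa -> ppm`` map.

    If the file contains more than one medium, ``medium`` selects which to
    load.
    """
    df = _read_tsv(path, RC_COLUMNS)
    if medium is not None:
        df = df[df["medium"] == medium]
        if df.empty:
            raise ParseError(f"{path}: no rows for medium {medium!r}")
    df = df.assign(shift_ppm=_numeric(df, "shift_ppm", path))
    return {r.aa: float(r.shift_ppm) for r in df.itertuples()}


def write_random_coil(values: Mapping[str, float], medium: str, path: PathLike) -> None:
    rows = [(aa, repr(float(values[aa])), medium) for aa in sorted(values)]
    _write_tsv(pd.DataFrame(rows, columns=RC_COLUMNS), path)
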