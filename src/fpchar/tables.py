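"""Schema-validated CSV readers and writers for every table kind.

One table kind per file, tidy layout, UTF-8, comma-separated with a header
row.  Floats are serialized with Python's shortest round-trip repr, so
``read_table(write_table(x)) == x`` exactly.  Output is byte-identical
across repeated calls (no timestamps, fixed column order).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BleachTrace,
    CellRecord,
    DecayFit,
    ExposureEvent,
    ExposureSchedule,
    HillFit,
    OserRecord,
    TitrationSeries,
)

__all__ = [
    "SchemaError",
    "ParseError",
    "EmptyInputError",
    "read_table",
    "write_table",
    "TABLE_KINDS",
]


class SchemaError(ValueError):
    """The file's header does not match the declared table kind."""


class ParseError(ValueError):
    """A cell could not be parsed as the declared type."""


class EmptyInputError(ValueError):
    """The file is empty (no header, no rows)."""


# kind -> (ordered columns, numeric columns)
_SCHEMAS: dict[str, tuple[list[str], set[str]]] = {
    "cells": (
        ["cell_id", "fp_name", "day", "channel", "intensity", "exposure_ms"],
        {"day", "intensity", "exposure_ms"},
    ),
    "schedule": (
        ["start_s", "channel", "duration_s"],
        {"start_s", "duration_s"},
    ),
    "trace": (
        ["frame", "time_s", "channel", "value"],
        {"frame", "time_s", "value"},
    ),
    "titration": (
        ["fp_name", "replicate", "pH", "fluorescence", "normalized"],
        {"replicate", "pH", "fluorescence"},
    ),
    "oser": (
        ["cell_id", "fp_name", "whorl_count"],
        {"whorl_count"},
    ),
    "decayfit": (
        [
            "fp_name", "order", "a", "b", "r", "s", "sse", "bic",
            "half_time_1_s", "half_time_2_s", "halftime_unreliable",
        ],
        {"order", "a", "b", "r", "s", "sse", "bic", "half_time_1_s", "half_time_2_s"},
    ),
    "hillfit": (
        ["fp_name", "pKa", "hill", "offset", "ph50", "rss"],
        {"pKa", "hill", "offset", "ph50", "rss"},
    ),
}

TABLE_KINDS = tuple(_SCHEMAS)


def _load_frame(path: str | Path, kind: str) -> pd.DataFrame:
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    columns, numeric = _SCHEMAS[kind]
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r} for kind {kind!r}")
    for col in numeric:
        vals = df[col].to_numpy()
        out = np.empty(len(vals), dtype=float)
        for i, v in enumerate(vals):
            if v == "":
                out[i] = math.nan
                continue
            try:
                out[i] = float(v)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {v!r} in column {col!r}, row {i}"
                ) from None
        df[col] = out
    return df[columns]


def _opt(x: float) -> float | None:
    return None if (x is None or (isinstance(x, float) and math.isnan(x))) else float(x)


def read_table(path: str | Path, kind: str):
    """Read and validate a CSV of the given kind, returning typed records.

    ``cells`` -> list[CellRecord]; ``schedule`` -> ExposureSchedule;
    ``trace`` -> BleachTrace (no schedule attached); ``titration`` ->
    list[TitrationSeries]; ``oser`` -> list[OserRecord]; ``decayfit`` ->
    list[(fp_name, DecayFit)]; ``hillfit`` -> list[(fp_name, HillFit)].
    """
    df = _load_frame(path, kind)
    if kind == "cells":
        records: list[CellRecord] = []
        for (cell_id, fp_name, day), grp in df.groupby(
            ["cell_id", "fp_name", "day"], sort=False
        ):
            records.append(
                CellRecord(
                    cell_id=str(cell_id),
                    fp_name=str(fp_name),
                    day=int(day),
                    intensity=dict(zip(grp["channel"], grp["intensity"])),
                    exposure_ms=dict(zip(grp["channel"], grp["exposure_ms"])),
                )
            )
        return records
    if kind == "schedule":
        events = [
            ExposureEvent(row.start_s, row.channel, row.duration_s)
            for row in df.itertuples()
        ]
        return ExposureSchedule(events)
    if kind == "trace":
        if len(df) == 0:
            raise EmptyInputError(f"{path}: trace has no frames")
        return BleachTrace(
            fp_name="",
            own_channel=str(df["channel"].iloc[0]),
            frame_times_s=df["time_s"].to_numpy(),
            raw=df["value"].to_numpy(),
        )
    if kind == "titration":
        series = []
        for (fp_name,), grp in df.groupby(["fp_name"], sort=False):
            wide = grp.pivot_table(
                index="replicate", columns="pH", values="fluorescence", sort=True
            )
            series.append(
                TitrationSeries(
                    fp_name=str(fp_name),
                    pH=wide.columns.to_numpy(dtype=float),
                    fluorescence=wide.to_numpy(dtype=float),
                    normalized=bool(grp["normalized"].iloc[0] == "True"),
                )
            )
        return series
    if kind == "oser":
        return [
            OserRecord(str(r.cell_id), str(r.fp_name), int(r.whorl_count))
            for r in df.itertuples()
        ]
    if kind == "decayfit":
        out = []
        for r in df.itertuples():
            half = [h for h in (_opt(r.half_time_1_s), _opt(r.half_time_2_s)) if h is not None]
            out.append(
                (
                    str(r.fp_name),
                    DecayFit(
                        order=int(r.order),
                        a=float(r.a),
                        b=_opt(r.b),
                        r=float(r.r),
                        s=_opt(r.s),
                        sse=float(r.sse),
                        bic=float(r.bic),
                        half_times_s=half,
                        halftime_unreliable=(r.halftime_unreliable == "True"),
                    ),
                )
            )
        return out
    if kind == "hillfit":
        return [
            (
                str(r.fp_name),
                HillFit(
                    pKa=float(r.pKa),
                    hill=float(r.hill),
                    offset=float(r.offset),
                    ph50=_opt(r.ph50),
                    rss=float(r.rss),
                ),
            )
            for r in df.itertuples()
        ]
    raise ValueError(f"unknown table kind {kind!r}")  # pragma: no cover


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, (bool, str)):
        return str(x)
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return repr(float(x))


def write_table(records, path: str | Path, kind: str) -> Path:
    """Write typed records as a deterministic CSV of the given kind."""
    columns, _ = _SCHEMAS[kind]
    rows: list[list] = []
    if kind == "cells":
        for rec in records:
            for ch in sorted(rec.intensity):
                rows.append(
                    [rec.cell_id, rec.fp_name, rec.day, ch,
                     rec.intensity[ch], rec.exposure_ms[ch]]
                )
    elif kind == "schedule":
        sched = records if isinstance(records, ExposureSchedule) else ExposureSchedule(list(records))
        for e in sched.events:
            rows.append([e.start_s, e.channel, e.duration_s])
    elif kind == "trace":
        tr: BleachTrace = records
        for i, (t, v) in enumerate(zip(tr.frame_times_s, tr.raw), start=1):
            rows.append([i, t, tr.own_channel, v])
    elif kind == "titration":
        for ser in records:
            for rep in range(ser.n_replicates):
                for j, ph in enumerate(ser.pH):
                    rows.append(
                        [ser.fp_name, rep + 1, ph, ser.fluorescence[rep, j], ser.normalized]
                    )
    elif kind == "oser":
        for rec in records:
            rows.append([rec.cell_id, rec.fp_name, rec.whorl_count])
    elif kind == "decayfit":
        for fp_name, fit in records:
            half = list(fit.half_times_s) + [None, None]
            rows.append(
                [fp_name, fit.order, fit.a, fit.b, fit.r, fit.s, fit.sse, fit.bic,
                 half[0], half[1], fit.halftime_unreliable]
            )
    elif kind == "hillfit":
        for fp_name, fit in records:
            rows.append([fp_name, fit.pKa, fit.hill, fit.offset, fit.ph50, fit.rss])
    else:
        raise ValueError(f"unknown table kind {kind!r}")

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [",".join(columns)]
    for row in rows:
        lines.append(",".join(_fmt(x) for x in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
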