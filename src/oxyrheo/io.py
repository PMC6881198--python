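"""CSV/JSON readers and writers for traces, rheograms and reports.

All CSV dialects are UTF-8 with a header row and '.' decimal separator.
Floats round-trip at full precision (shortest-repr serialization).
Unknown extra columns in a trace are preserved untouched.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Union

import numpy as np
import pandas as pd

from .rheofit import PowerLawFit
from .viscometry import Rheogram, RheogramPoint, RheologyTrace, TRACE_COLUMNS

__all__ = [
    "TraceParseError",
    "read_trace",
    "write_trace",
    "read_rheogram",
    "write_rheogram",
    "write_fit_report",
    "write_json",
]

PathLike = Union[str, Path]


def _FLOAT_FMT(x) -> str:
    """Shortest round-trip float serialization (plain Python repr)."""
    return repr(float(x))


class TraceParseError(ValueError):
    """Malformed trace file; the message names the file, column and row."""


def read_trace(path: PathLike, sample_id: str | None = None) -> RheologyTrace:
    """Read a velocity trace CSV into a :class:`RheologyTrace`.

    Required columns: time_s, pressure_pa, po2_mmhg, umax_um_s, replicate.
    Extra columns pass through unchanged.  Non-numeric cells are reported
    with their (1-based, header-inclusive) line number.
    """
    p = Path(path)
    if not p.exists():
        raise TraceParseError(f"trace file not found: {p}")
    df = pd.read_csv(p, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"{p}: missing required column(s) {missing}")
    for col in TRACE_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            line = int(bad[0]) + 2  # header + 1-based
            raise TraceParseError(
                f"{p}: non-numeric value {df[col].iloc[bad[0]]!r} in column {col!r} at line {line}"
            )
        if coerced.isna().any():
            line = int(df.index[coerced.isna()][0]) + 2
            raise TraceParseError(f"{p}: empty value in column {col!r} at line {line}")
        df[col] = coerced
    return RheologyTrace(records=df, sample_id=sample_id or p.stem)


def write_trace(trace: RheologyTrace, path: PathLike) -> None:
    trace.records.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_rheogram(rheograms: Union[Rheogram, Iterable[Rheogram]], path: PathLike) -> None:
    """Write one or several rheograms (stacked) as the documented CSV dialect."""
    if isinstance(rheograms, Rheogram):
        rheograms = [rheograms]
    frames = [r.to_dataframe() for r in rheograms]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_rheogram(path: PathLike) -> List[Rheogram]:
    """Read a rheogram CSV back into one Rheogram per oxygen tension."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["po2_mmhg", "shear_rate_per_s", "viscosity_pa_s", "shear_stress_pa", "sd_pa_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing required column(s) {missing}")
    out = []
    for po2, grp in df.groupby("po2_mmhg"):
        grp = grp.sort_values("shear_rate_per_s")
        points = tuple(
            RheogramPoint(
                shear_rate_per_s=row.shear_rate_per_s,
                viscosity_pa_s=row.viscosity_pa_s,
                shear_stress_pa=row.shear_stress_pa,
                po2_mmhg=row.po2_mmhg,
                sd_pa_s=row.sd_pa_s,
            )
            for row in grp.itertuples()
        )
        out.append(Rheogram(points=points, po2_mmhg=float(po2)))
    return out


def write_fit_report(fits: Sequence[PowerLawFit], path: PathLike) -> None:
    """JSON fit report: a list of {po2_mmhg, n, K_pa_sn, r2, n_points}."""
    write_json([f.to_dict() for f in fits], path)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(data, path: PathLike) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_jsonable) + "\n")
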