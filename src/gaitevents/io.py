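"""CSV readers and writers for traces and event lists.

The trace dialect is fixed (comma delimiter, header row, '.' decimal): columns
``time_s, ax_g, ay_g, az_g`` with optional ``fsr_heel, fsr_toe``.  Event files
carry ``kind, n, t_s, amplitude, latency_ms``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventKind, GaitEvent
from .fsr import FsrTrace
from .preprocess import AccelTrace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_events_csv",
    "write_events_csv",
    "events_to_frame",
]

TRACE_COLUMNS = ["time_s", "ax_g", "ay_g", "az_g"]
FSR_COLUMNS = ["fsr_heel", "fsr_toe"]


def read_trace_csv(
    path: str | Path, fs: float | None = None
) -> tuple[AccelTrace, FsrTrace | None]:
    """Read a trace CSV; the sampling rate is inferred from the time column.

    When ``fs`` is given, the inferred rate must agree within 0.1%.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed trace CSV {path}: {exc}") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV {path} lacks required columns {missing}")
    if df[TRACE_COLUMNS].isna().any().any():
        bad = int(df[TRACE_COLUMNS].isna().any(axis=1).idxmax()) + 2  # header is line 1
        raise ValueError(f"trace CSV {path}: non-numeric or missing value at line {bad}")
    t = df["time_s"].to_numpy(float)
    dt = np.diff(t)
    fs_inferred = 1.0 / float(np.median(dt))
    if fs is not None and abs(fs_inferred - fs) > 1e-3 * fs:
        raise ValueError(
            f"trace CSV {path}: inferred sampling rate {fs_inferred:.4f} Hz "
            f"disagrees with configured {fs:.4f} Hz"
        )
    accel = AccelTrace(
        fs=fs_inferred,
        t=t,
        ax=df["ax_g"].to_numpy(float),
        ay=df["ay_g"].to_numpy(float),
        az=df["az_g"].to_numpy(float),
    )
    fsr = None
    if all(c in df.columns for c in FSR_COLUMNS):
        fsr = FsrTrace(
            fs=fs_inferred,
            heel=df["fsr_heel"].to_numpy(float),
            toe=df["fsr_toe"].to_numpy(float),
        )
    return accel, fsr


def write_trace_csv(path: str | Path, accel: AccelTrace, fsr: FsrTrace | None = None) -> None:
    data = {
        "time_s": accel.t,
        "ax_g": accel.ax,
        "ay_g": accel.ay,
        "az_g": accel.az,
    }
    if fsr is not None:
        data["fsr_heel"] = fsr.heel
        data["fsr_toe"] = fsr.toe
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.8g")


def events_to_frame(events: list[GaitEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "kind": [e.kind.value for e in events],
            "n": [e.n for e in events],
            "t_s": [e.t for e in events],
            "amplitude": [e.amplitude for e in events],
            "latency_ms": [e.latency_s * 1000.0 for e in events],
        }
    )


def write_events_csv(path: str | Path, events: list[GaitEvent]) -> None:
    events_to_frame(events).to_csv(path, index=False, float_format="%.10g")


def read_events_csv(path: str | Path) -> list[GaitEvent]:
    df = pd.read_csv(path)
    return [
        GaitEvent(
            kind=EventKind(row.kind),
            n=int(row.n),
            t=float(row.t_s),
            amplitude=float(row.amplitude),
            latency_s=float(row.latency_ms) / 1000.0,
        )
        for row in df.itertuples()
    ]
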