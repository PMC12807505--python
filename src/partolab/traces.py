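"""Telemetry containers and I/O: pressure traces, delivery records,
zeitgeber-time alignment, and 1 Hz resampling.

All internal times are seconds since the recording's lights-on reference
(ZT0); delivery timestamps are ZT-referenced whole minutes. Conversion from
wall-clock time happens only at the edges via :func:`to_zt`.

Telemetry dialect
-----------------
Pressure traces are delimited text with a header line::

    timestamp_s,pressure_mmHg
    0.000,5.213
    ...

Delivery events::

    animal_id,group,event_type,timestamp_min

with ``event_type`` currently always ``pup_delivery``. A cohort manifest
lists one animal per row: ``animal_id,group,d_drg,d_uterus,trace_path,
events_path`` (paths relative to the manifest).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PressureTrace",
    "DeliveryRecord",
    "TelemetryFormatError",
    "TelemetryDataError",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "read_manifest",
    "resample_1hz",
    "to_zt",
]


class TelemetryFormatError(ValueError):
    """Raised when a telemetry file does not parse as the documented dialect."""


class TelemetryDataError(ValueError):
    """Raised when a telemetry file parses but violates a data invariant."""


@dataclass
class PressureTrace:
    """One animal's intrauterine-pressure time series.

    Parameters
    ----------
    timestamps : seconds since lights-on (ZT0), strictly increasing.
    pressure : mmHg, aligned with ``timestamps``.
    sample_rate : nominal sampling rate in Hz.
    interpolated : optional boolean mask marking samples reconstructed by
        linear interpolation across telemetry dropouts; such spans are
        excluded from peak statistics downstream.
    ground_truth_events : populated only by the synthetic generator — a
        DataFrame of true transient (time_s, amplitude_mmHg), used for
        detector-recovery checks. Never read from disk.
    """

    animal_id: str
    group: str
    timestamps: np.ndarray
    pressure: np.ndarray
    sample_rate: float
    interpolated: np.ndarray | None = None
    ground_truth_events: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.timestamps.ndim != 1 or self.pressure.ndim != 1:
            raise TelemetryDataError("timestamps and pressure must be 1-D")
        if len(self.timestamps) != len(self.pressure):
            raise TelemetryDataError("timestamps and pressure must have equal length")
        if len(self.timestamps) == 0:
            raise TelemetryDataError("empty trace")
        if not np.all(np.isfinite(self.pressure)):
            raise TelemetryDataError("pressure contains non-finite values")
        diffs = np.diff(self.timestamps)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0))
            raise TelemetryDataError(
                f"timestamps not strictly increasing at sample {i + 1} "
                f"(t={self.timestamps[i + 1]!r} after t={self.timestamps[i]!r})"
            )
        if self.sample_rate <= 0 or not np.isfinite(self.sample_rate):
            raise TelemetryDataError("sample_rate must be finite and positive")
        if self.interpolated is not None:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)
            if len(self.interpolated) != len(self.pressure):
                raise TelemetryDataError("interpolated mask length mismatch")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class DeliveryRecord:
    """Per-animal pup-delivery annotations at whole-minute accuracy.

    ``delivery_times`` are ZT-referenced minutes; labor onset is the first
    delivery ("marked by appearance of the first pup").
    """

    animal_id: str
    group: str
    delivery_times: np.ndarray  # minutes, sorted ascending, whole minutes
    completed_by_gd20: bool = True
    d_drg: int | None = None
    d_uterus: int | None = None

    def __post_init__(self) -> None:
        self.delivery_times = np.asarray(self.delivery_times, dtype=float)
        if self.delivery_times.ndim != 1:
            raise TelemetryDataError("delivery_times must be 1-D")
        if np.any(np.diff(self.delivery_times) < 0):
            raise TelemetryDataError("delivery_times must be sorted ascending")
        if len(self.delivery_times) and not np.allclose(
            self.delivery_times, np.round(self.delivery_times)
        ):
            raise TelemetryDataError("delivery_times must be whole minutes")

    @property
    def n_pups(self) -> int:
        return len(self.delivery_times)

    @property
    def first_pup_time(self) -> float | None:
        """Labor onset in ZT minutes, or None if no deliveries."""
        return float(self.delivery_times[0]) if len(self.delivery_times) else None

    @property
    def onset_zt(self) -> float | None:
        """Labor onset in ZT hours."""
        t = self.first_pup_time
        return None if t is None else t / 60.0

    @property
    def interpup_intervals(self) -> np.ndarray:
        """Successive inter-pup gaps in minutes (empty with < 2 pups)."""
        return np.diff(self.delivery_times)


# ---------------------------------------------------------------------------
# readers / writers


def write_trace(trace: PressureTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {"timestamp_s": trace.timestamps, "pressure_mmHg": trace.pressure}
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_trace(
    path: str | Path, animal_id: str = "", group: str = "", sample_rate: float | None = None
) -> PressureTrace:
    """Read a pressure trace from the delimited dialect.

    Unparseable rows are reported with 1-based file line numbers; the first
    non-monotone timestamp is likewise named.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TelemetryFormatError(f"{path}: cannot parse as delimited text: {exc}") from exc
    missing = {"timestamp_s", "pressure_mmHg"} - set(df.columns)
    if missing:
        raise TelemetryFormatError(f"{path}: missing column(s) {sorted(missing)}")
    ts = pd.to_numeric(df["timestamp_s"], errors="coerce")
    pr = pd.to_numeric(df["pressure_mmHg"], errors="coerce")
    bad = ts.isna() | pr.isna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +1 header, +1 one-based
        raise TelemetryFormatError(f"{path}: unparseable row(s) at line(s) {lines[:10]}")
    ts = ts.to_numpy()
    diffs = np.diff(ts)
    if np.any(diffs <= 0):
        line = int(np.argmax(diffs <= 0)) + 3  # offending sample, 1-based with header
        raise TelemetryDataError(f"{path}: non-monotone timestamp at line {line}")
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(diffs)) if len(diffs) else 1.0
    return PressureTrace(
        animal_id=animal_id or path.stem,
        group=group,
        timestamps=ts,
        pressure=pr.to_numpy(),
        sample_rate=sample_rate,
    )


def write_events(records: list[DeliveryRecord], path: str | Path) -> None:
    rows = [
        {
            "animal_id": r.animal_id,
            "group": r.group,
            "event_type": "pup_delivery",
            "timestamp_min": int(t),
        }
        for r in records
        for t in r.delivery_times
    ]
    pd.DataFrame(rows, columns=["animal_id", "group", "event_type", "timestamp_min"]).to_csv(
        path, index=False
    )


def read_events(path: str | Path) -> dict[str, DeliveryRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"animal_id", "group", "event_type", "timestamp_min"} - set(df.columns)
    if missing:
        raise TelemetryFormatError(f"{path}: missing column(s) {sorted(missing)}")
    out: dict[str, DeliveryRecord] = {}
    for (animal, group), sub in df[df["event_type"] == "pup_delivery"].groupby(
        ["animal_id", "group"], sort=False
    ):
        out[str(animal)] = DeliveryRecord(
            animal_id=str(animal),
            group=str(group),
            delivery_times=np.sort(sub["timestamp_min"].to_numpy(dtype=float)),
        )
    return out


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest; relative paths are resolved against it."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"animal_id", "group", "d_drg", "d_uterus", "trace_path", "events_path"}
    missing = required - set(df.columns)
    if missing:
        raise TelemetryFormatError(f"{path}: manifest missing column(s) {sorted(missing)}")
    base = path.parent
    for col in ("trace_path", "events_path"):
        df[col] = [str((base / p)) if not Path(p).is_absolute() else p for p in df[col]]
    return df


# ---------------------------------------------------------------------------
# resampling and ZT conversion


def resample_1hz(trace: PressureTrace) -> PressureTrace:
    """Resample a trace to exactly 1 Hz by bin-averaging.

    Each output sample at integer second ``t`` is the mean of input samples
    with timestamps in the half-open bin ``[t, t+1)``. Bins containing no
    samples (telemetry dropouts) are filled by linear interpolation between
    the neighboring non-empty bins and flagged in ``interpolated``.
    """
    if trace.sample_rate < 1.0:
        raise TelemetryDataError("resample_1hz requires sample_rate >= 1 Hz")
    t0 = float(np.floor(trace.timestamps[0]))
    idx = np.floor(trace.timestamps - t0).astype(np.int64)
    n_bins = int(idx[-1]) + 1
    sums = np.bincount(idx, weights=trace.pressure, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    empty = counts == 0
    with np.errstate(invalid="ignore"):
        means = sums / np.where(empty, 1, counts)
    if empty.any():
        filled = np.flatnonzero(~empty)
        means[empty] = np.interp(np.flatnonzero(empty), filled, means[filled])
    return PressureTrace(
        animal_id=trace.animal_id,
        group=trace.group,
        timestamps=t0 + np.arange(n_bins, dtype=float),
        pressure=means,
        sample_rate=1.0,
        interpolated=empty,
        ground_truth_events=trace.ground_truth_events,
    )


def _time_of_day_seconds(t) -> float:
    if isinstance(t, _dt.datetime):
        t = t.time()
    if isinstance(t, _dt.time):
        return t.hour * 3600 + t.minute * 60 + t.second + t.microsecond / 1e6
    if isinstance(t, str):
        parts = t.split(":")
        if len(parts) not in (2, 3):
            raise ValueError(f"cannot parse time of day {t!r}; expected HH:MM[:SS]")
        h, m = int(parts[0]), int(parts[1])
        s = float(parts[2]) if len(parts) == 3 else 0.0
        return h * 3600 + m * 60 + s
    if isinstance(t, (int, float)):
        return float(t) % 86400.0
    raise TypeError(f"unsupported time-of-day type {type(t)!r}")


def to_zt(clock_time, lights_on) -> float:
    """Convert a wall-clock time to zeitgeber time in hours.

    ZT0 is lights-on; the result is in [0, 24), wrapping across midnight.
    Accepts ``datetime``/``time`` objects, ``"HH:MM[:SS]"`` strings, or
    seconds-of-day numbers for both arguments.
    """
    delta = (_time_of_day_seconds(clock_time) - _time_of_day_seconds(lights_on)) % 86400.0
    if delta >= 86400.0:  # float modulo can round -tiny up to the period
        delta = 0.0
    return delta / 3600.0
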