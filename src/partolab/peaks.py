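"""Contraction-peak detection and labor-referenced windowing.

A contraction peak is a strict local maximum of the 1 Hz pressure trace
whose sample value ("height", absolute mmHg, not baseline-subtracted) is at
least ``min_height`` and whose topographic prominence is at least
``min_prominence``. Prominence follows the standard definition: the height
of the peak above the higher of the two base minima, where each base is the
minimum sample between the peak and the nearest strictly higher sample on
that side (or the trace edge if there is none). Plateaus collapse to a
single peak at the plateau midpoint (floor division); edge samples cannot
be peaks. The study's detection settings are height >= 40 mmHg and
prominence >= 20 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal
from sklearn.base import BaseEstimator, TransformerMixin

from .traces import DeliveryRecord, PressureTrace

__all__ = [
    "Peak",
    "PeakSet",
    "AnimalSummary",
    "ContractionPeakDetector",
    "find_peaks",
    "window_peaks",
    "summarize_animal",
]

WINDOW_LABELS = ("pre_labor", "post_onset_2h", "beyond_2h", "custom")
POST_ONSET_WINDOW_S = 2 * 3600.0


@dataclass(frozen=True)
class Peak:
    """One detected contraction peak (times in seconds, ZT-referenced)."""

    time: float
    height: float  # mmHg, absolute sample value at the apex
    prominence: float  # mmHg


@dataclass
class PeakSet:
    """Peaks of one animal restricted to an analysis window.

    ``window_bounds`` is half-open ``[start, end)`` in seconds.
    """

    animal_id: str
    window_label: str
    peaks: list[Peak]
    window_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        if self.window_label not in WINDOW_LABELS:
            raise ValueError(f"window_label must be one of {WINDOW_LABELS}")
        self.peaks = sorted(self.peaks, key=lambda p: p.time)
        lo, hi = self.window_bounds
        for p in self.peaks:
            if not (lo <= p.time < hi):
                raise ValueError(f"peak at t={p.time} outside window [{lo}, {hi})")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def heights(self) -> np.ndarray:
        return np.asarray([p.height for p in self.peaks])


@dataclass
class AnimalSummary:
    """Per-animal outcomes feeding the group-level statistics and the GLS
    contrast model.

    ``mean_peak_pressure`` is Pi — the arithmetic mean of peak heights in
    the designated analysis window (NaN when no peaks were detected there).
    ``onset_after_zt3`` uses the strict rule onset_zt > boundary.
    """

    animal_id: str
    group: str
    d_drg: int
    d_uterus: int
    mean_peak_pressure: float  # mmHg; NaN when undefined
    n_peaks: int
    mean_interpup_interval: float  # minutes; NaN when < 2 pups
    onset_zt: float  # hours; NaN when no deliveries
    onset_after_zt3: bool | None

    def to_row(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "group": self.group,
            "d_drg": self.d_drg,
            "d_uterus": self.d_uterus,
            "mean_peak_pressure": self.mean_peak_pressure,
            "n_peaks": self.n_peaks,
            "mean_interpup_interval": self.mean_interpup_interval,
            "onset_zt": self.onset_zt,
            "onset_after_zt3": self.onset_after_zt3,
        }


class ContractionPeakDetector(BaseEstimator, TransformerMixin):
    """Detector for contraction peaks in 1 Hz pressure traces.

    Parameters
    ----------
    min_height : float, default 40.0
        Minimum absolute sample value at the apex, mmHg.
    min_prominence : float, default 20.0
        Minimum topographic prominence, mmHg.
    exclude_interpolated : bool, default True
        Drop peaks whose apex lies in a flagged telemetry-dropout span.

    The estimator is stateless; ``fit`` only validates parameters so the
    detector composes with scikit-learn pipelines.
    """

    def __init__(
        self,
        min_height: float = 40.0,
        min_prominence: float = 20.0,
        exclude_interpolated: bool = True,
    ):
        self.min_height = min_height
        self.min_prominence = min_prominence
        self.exclude_interpolated = exclude_interpolated

    def fit(self, X=None, y=None):
        if not (np.isfinite(self.min_height) and np.isfinite(self.min_prominence)):
            raise ValueError("thresholds must be finite")
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> list[Peak]:
        """Detect peaks in a :class:`PressureTrace` (or bare 1 Hz array)."""
        return self.fit().detect(X)

    def detect(self, trace) -> list[Peak]:
        if isinstance(trace, PressureTrace):
            if trace.sample_rate != 1.0:
                raise ValueError(
                    f"peak detection requires a 1 Hz trace (got {trace.sample_rate} Hz); "
                    "resample first"
                )
            x = trace.pressure
            times = trace.timestamps
            interp = trace.interpolated
        else:
            x = np.asarray(trace, dtype=float)
            times = np.arange(len(x), dtype=float)
            interp = None
        if len(x) < 3:
            raise ValueError("trace shorter than 3 samples has no interior local maxima")
        idx, props = _signal.find_peaks(
            x, height=self.min_height, prominence=self.min_prominence
        )
        if interp is not None and self.exclude_interpolated and len(idx):
            keep = ~interp[idx]
            idx, heights, proms = idx[keep], props["peak_heights"][keep], props["prominences"][keep]
        else:
            heights, proms = props["peak_heights"], props["prominences"]
        return [
            Peak(time=float(times[i]), height=float(h), prominence=float(p))
            for i, h, p in zip(idx, heights, proms)
        ]


def find_peaks(
    trace, min_height: float = 40.0, min_prominence: float = 20.0,
    exclude_interpolated: bool = True,
) -> list[Peak]:
    """Functional wrapper over :class:`ContractionPeakDetector`."""
    return ContractionPeakDetector(
        min_height=min_height,
        min_prominence=min_prominence,
        exclude_interpolated=exclude_interpolated,
    ).detect(trace)


def window_peaks(
    peaks: list[Peak],
    record: DeliveryRecord,
    window_label: str,
    recording_bounds: tuple[float, float],
    animal_id: str | None = None,
) -> PeakSet:
    """Restrict peaks to a labor-referenced analysis window.

    Windows are half-open so the three labels partition the recording:
    ``pre_labor`` = [start, onset), ``post_onset_2h`` = [onset, onset+2h),
    ``beyond_2h`` = [onset+2h, end). Onset is the first pup's delivery time.
    """
    start, end = recording_bounds
    if window_label == "custom":
        raise ValueError("custom windows: construct a PeakSet directly")
    if window_label not in WINDOW_LABELS:
        raise ValueError(f"unknown window label {window_label!r}")
    onset_min = record.first_pup_time
    if onset_min is None:
        raise ValueError(
            f"{record.animal_id}: onset-referenced window {window_label!r} requested "
            "but the record has no deliveries"
        )
    onset = onset_min * 60.0
    if window_label == "pre_labor":
        bounds = (start, onset)
    elif window_label == "post_onset_2h":
        bounds = (onset, min(onset + POST_ONSET_WINDOW_S, end))
    else:  # beyond_2h
        bounds = (min(onset + POST_ONSET_WINDOW_S, end), end)
    lo, hi = bounds
    selected = [p for p in peaks if lo <= p.time < hi]
    return PeakSet(
        animal_id=animal_id or record.animal_id,
        window_label=window_label,
        peaks=selected,
        window_bounds=bounds,
    )


def summarize_animal(
    peakset: PeakSet,
    record: DeliveryRecord,
    d_drg: int | None = None,
    d_uterus: int | None = None,
    zt_boundary: float = 3.0,
) -> AnimalSummary:
    """Collapse one animal's windowed peaks and delivery record into the
    outcomes used downstream.

    Undefined statistics (no peaks, single pup, no deliveries) are carried
    as NaN / None rather than raised.
    """
    heights = peakset.heights
    mean_peak = float(np.mean(heights)) if len(heights) else float("nan")
    gaps = record.interpup_intervals
    mean_gap = float(np.mean(gaps)) if len(gaps) else float("nan")
    onset = record.onset_zt
    onset_zt = float("nan") if onset is None else float(onset)
    after = None if onset is None else bool(onset > zt_boundary)
    return AnimalSummary(
        animal_id=record.animal_id,
        group=record.group,
        d_drg=int(d_drg if d_drg is not None else (record.d_drg or 0)),
        d_uterus=int(d_uterus if d_uterus is not None else (record.d_uterus or 0)),
        mean_peak_pressure=mean_peak,
        n_peaks=len(peakset),
        mean_interpup_interval=mean_gap,
        onset_zt=onset_zt,
        onset_after_zt3=after,
    )


def summaries_to_frame(summaries: list[AnimalSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])
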