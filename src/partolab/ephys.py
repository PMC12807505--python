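"""Mechanically activated current classification for patch-clamp sweeps.

Sweeps are low-pass filtered at 500 Hz (-3 dB) with an 8-pole Bessel
filter before analysis. The baseline is the mean current in the window
from 35 ms to 5 ms before stimulus onset; a sweep is a mechanoresponse
only if the peak baseline-subtracted amplitude during stimulation strictly
exceeds five times the baseline standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "SweepRecord",
    "MechResponse",
    "bessel_lowpass",
    "baseline_stats",
    "classify_response",
    "MechanoresponseClassifier",
]

BASELINE_WINDOW_MS = (35.0, 5.0)  # before stimulus onset, closed-open


@dataclass
class SweepRecord:
    """One patch-clamp sweep on a uniform time grid (ms / pA)."""

    time_ms: np.ndarray
    current_pA: np.ndarray
    stimulus_onset_ms: float
    hold_duration_ms: float
    depth_um: float
    sample_rate_hz: float
    ramp_speed_um_per_ms: float = 1.0

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if self.time_ms.shape != self.current_pA.shape or self.time_ms.ndim != 1:
            raise ValueError("time and current must be 1-D and aligned")
        if len(self.time_ms) < 2:
            raise ValueError("sweep too short")
        dt = np.diff(self.time_ms)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
            raise ValueError("time must be a uniform ascending grid")
        stim_end = (
            self.stimulus_onset_ms
            + self.depth_um / self.ramp_speed_um_per_ms
            + self.hold_duration_ms
        )
        if self.stimulus_onset_ms < self.time_ms[0] or stim_end > self.time_ms[-1]:
            raise ValueError("stimulus window not inside the record")

    @property
    def stimulus_end_ms(self) -> float:
        return (
            self.stimulus_onset_ms
            + self.depth_um / self.ramp_speed_um_per_ms
            + self.hold_duration_ms
        )

    def copy_with(self, current: np.ndarray) -> "SweepRecord":
        return SweepRecord(
            time_ms=self.time_ms.copy(),
            current_pA=current,
            stimulus_onset_ms=self.stimulus_onset_ms,
            hold_duration_ms=self.hold_duration_ms,
            depth_um=self.depth_um,
            sample_rate_hz=self.sample_rate_hz,
            ramp_speed_um_per_ms=self.ramp_speed_um_per_ms,
        )


@dataclass(frozen=True)
class MechResponse:
    """Verdict for one sweep under the 5x baseline-SD rule."""

    baseline_mean: float  # pA
    baseline_sd: float  # pA
    peak_amplitude: float  # pA, |extreme - baseline| during stimulation
    signed_peak: float  # pA, baseline-subtracted extreme (inward negative)
    threshold: float  # pA, 5 * baseline_sd
    is_response: bool
    depth_um: float


def bessel_lowpass(sweep: SweepRecord, cutoff_hz: float = 500.0, poles: int = 8) -> SweepRecord:
    """Low-pass the sweep with an n-pole Bessel filter, -3 dB at ``cutoff_hz``.

    The digital filter is derived from the analog Bessel prototype via the
    bilinear transform with cutoff pre-warping (scipy's ``norm="mag"``
    places the half-power point exactly at the requested cutoff). Initial
    conditions are matched to the first sample so a constant trace passes
    through unchanged.
    """
    nyquist = sweep.sample_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {nyquist} Hz")
    b, a = _signal.bessel(poles, cutoff_hz, btype="low", norm="mag", fs=sweep.sample_rate_hz)
    zi = _signal.lfilter_zi(b, a) * sweep.current_pA[0]
    filtered, _ = _signal.lfilter(b, a, sweep.current_pA, zi=zi)
    return sweep.copy_with(filtered)


def _baseline_slice(sweep: SweepRecord) -> slice:
    lo_ms = sweep.stimulus_onset_ms - BASELINE_WINDOW_MS[0]
    hi_ms = sweep.stimulus_onset_ms - BASELINE_WINDOW_MS[1]
    if lo_ms < sweep.time_ms[0]:
        raise ValueError("baseline window truncated: record starts too late")
    i0 = int(np.searchsorted(sweep.time_ms, lo_ms, side="left"))
    i1 = int(np.searchsorted(sweep.time_ms, hi_ms, side="left"))
    if i1 - i0 < 2:
        raise ValueError("baseline window contains fewer than 2 samples")
    return slice(i0, i1)


def baseline_stats(sweep: SweepRecord) -> tuple[float, float]:
    """Mean and sample SD (n-1) of the pre-stimulus baseline window
    [onset - 35 ms, onset - 5 ms)."""
    seg = sweep.current_pA[_baseline_slice(sweep)]
    return float(np.mean(seg)), float(np.std(seg, ddof=1))


def classify_response(
    sweep: SweepRecord,
    sd_multiple: float = 5.0,
    cutoff_hz: float = 500.0,
    poles: int = 8,
    filter_first: bool = True,
) -> MechResponse:
    """Apply the mechanoresponse rule to one sweep.

    The sweep is filtered (unless ``filter_first=False``), the baseline
    mean/SD are taken from the filtered pre-stimulus window, and the peak
    amplitude is the largest |current - baseline_mean| over the stimulation
    window [onset, onset + ramp + hold]. A response requires the amplitude
    to strictly exceed ``sd_multiple`` times the baseline SD.
    """
    work = bessel_lowpass(sweep, cutoff_hz, poles) if filter_first else sweep
    mean, sd = baseline_stats(work)
    in_stim = (work.time_ms >= work.stimulus_onset_ms) & (
        work.time_ms <= work.stimulus_end_ms
    )
    dev = work.current_pA[in_stim] - mean
    signed_peak = float(dev[np.argmax(np.abs(dev))]) if in_stim.any() else 0.0
    amplitude = abs(signed_peak)
    threshold = sd_multiple * sd
    return MechResponse(
        baseline_mean=mean,
        baseline_sd=sd,
        peak_amplitude=amplitude,
        signed_peak=signed_peak,
        threshold=threshold,
        is_response=bool(amplitude > threshold),
        depth_um=sweep.depth_um,
    )


class MechanoresponseClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based classifier for mechanically activated currents.

    Parameters mirror :func:`classify_response`. The classifier is
    stateless (``fit`` validates parameters only); ``predict`` maps a
    sequence of :class:`SweepRecord` to booleans and ``decision_function``
    returns the margin ``peak_amplitude - threshold`` in pA.
    """

    def __init__(
        self,
        sd_multiple: float = 5.0,
        cutoff_hz: float = 500.0,
        poles: int = 8,
        filter_first: bool = True,
    ):
        self.sd_multiple = sd_multiple
        self.cutoff_hz = cutoff_hz
        self.poles = poles
        self.filter_first = filter_first

    def fit(self, X=None, y=None):
        if self.sd_multiple <= 0 or self.cutoff_hz <= 0 or self.poles < 1:
            raise ValueError("invalid classifier parameters")
        self.classes_ = np.array([False, True])
        return self

    def _responses(self, sweeps) -> list[MechResponse]:
        return [
            classify_response(
                s,
                sd_multiple=self.sd_multiple,
                cutoff_hz=self.cutoff_hz,
                poles=self.poles,
                filter_first=self.filter_first,
            )
            for s in sweeps
        ]

    def predict(self, X) -> np.ndarray:
        self.fit()
        return np.array([r.is_response for r in self._responses(X)])

    def decision_function(self, X) -> np.ndarray:
        self.fit()
        return np.array([r.peak_amplitude - r.threshold for r in self._responses(X)])

    def describe(self, X) -> "pd.DataFrame":
        """Full per-sweep MechResponse table."""
        import pandas as pd

        self.fit()
        return pd.DataFrame([r.__dict__ for r in self._responses(X)])
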