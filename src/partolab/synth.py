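"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes:
multi-hour intrauterine-pressure traces with a low noisy baseline and
Gaussian-bump contraction transients whose event times follow a two-rate
Poisson process (sparse before labor onset, group-dependent rate after),
per-animal delivery records at whole-minute accuracy, and patch-clamp
sweeps with optional inward mechanoresponses.

Determinism: every animal draws from `numpy.random.SeedSequence(seed,
spawn_key=(animal_index,))`, so output is byte-identical for identical
seed + config and independent of generation order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig, GroupSpec, SweepConfig
from .ephys import SweepRecord
from .traces import DeliveryRecord, PressureTrace, write_events, write_trace

__all__ = [
    "generate_pressure_trace",
    "generate_delivery_events",
    "generate_sweep",
    "generate_cohort",
    "write_cohort",
]

# transient centers are kept at least this many widths apart so that peaks
# stay resolvable on the 1 Hz grid and the ground-truth count is well defined
MIN_SEPARATION_WIDTHS = 3.0


def _animal_rngs(config: CohortConfig, animal_index: int):
    """Three independent, reproducible streams per animal: labor onset,
    delivery gaps, and trace noise/events. Onset uses its own stream so the
    trace and the delivery record agree on it."""
    ss = np.random.SeedSequence(entropy=int(config.seed), spawn_key=(int(animal_index),))
    onset_ss, delivery_ss, trace_ss = ss.spawn(3)
    return (
        np.random.default_rng(onset_ss),
        np.random.default_rng(delivery_ss),
        np.random.default_rng(trace_ss),
    )


def _draw_onset_seconds(group: GroupSpec, rng_onset: np.random.Generator) -> float:
    onset_h = rng_onset.normal(group.onset_zt_mean, group.onset_zt_sd)
    return max(onset_h, 0.0) * 3600.0


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int, lower: float = 0.0
) -> np.ndarray:
    """Normal(mean, sd) truncated below at ``lower``, by rejection."""
    if sd == 0:
        return np.full(size, max(mean, lower))
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = out < lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    out[out < lower] = lower
    return out


def _poisson_times(rng: np.random.Generator, rate_per_hour: float, t0: float, t1: float):
    """Homogeneous Poisson event times on [t0, t1) seconds."""
    span = max(t1 - t0, 0.0)
    n = rng.poisson(rate_per_hour * span / 3600.0)
    return np.sort(t0 + rng.uniform(0.0, span, n)) if n else np.empty(0)


def _thin_min_separation(times: np.ndarray, min_sep: float) -> np.ndarray:
    """Greedily drop events closer than ``min_sep`` to the last kept one."""
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= min_sep:
            kept.append(float(t))
    return np.asarray(kept)


def render_transients(
    t: np.ndarray, events: np.ndarray, amplitudes: np.ndarray, width_s: float
) -> np.ndarray:
    """Sum of Gaussian contraction bumps amp * exp(-(t-tc)^2 / (2 width^2)),
    evaluated on the time grid ``t`` (seconds). Each bump is rendered only
    within +-4 widths of its center."""
    out = np.zeros_like(t, dtype=float)
    if len(t) < 2:
        dt = 1.0
    else:
        dt = t[1] - t[0]
    half = int(np.ceil(4.0 * width_s / dt))
    for tc, amp in zip(events, amplitudes):
        ic = int(round((tc - t[0]) / dt))
        lo, hi = max(ic - half, 0), min(ic + half + 1, len(t))
        if lo < hi:
            out[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - tc) / width_s) ** 2)
    return out


def generate_pressure_trace(config: CohortConfig, animal_index: int) -> PressureTrace:
    """Simulate one animal's intrauterine-pressure trace.

    baseline + Gaussian noise + sum of Gaussian contraction transients;
    event times from a Poisson process whose rate switches from
    ``prelabor_event_rate`` to the group's ``postonset_event_rate`` at the
    animal's labor onset. Amplitudes are hierarchical: the animal draws a
    mean level ~ Normal(peak_amp_mean, peak_amp_sd) — peak_amp_sd is the
    between-animal spread that generates the group-dependent variance the
    GLS contrast model estimates — and individual transients scatter
    around that level with SD ``within_animal_amp_sd``. Both draws are
    truncated below at 0. Ground-truth event times/amplitudes are attached
    for detector-recovery checks.
    """
    group, _ = config.animal_group(animal_index)
    rng_onset, _, rng_trace = _animal_rngs(config, animal_index)
    onset_s = _draw_onset_seconds(group, rng_onset)

    duration_s = config.duration * 3600.0
    fs = config.raw_sample_rate
    n = int(round(duration_s * fs))
    t = np.arange(n, dtype=float) / fs

    pressure = np.full(n, config.baseline_pressure)
    if config.baseline_noise_sd > 0:
        pressure += rng_trace.normal(0.0, config.baseline_noise_sd, n)

    switch = min(onset_s, duration_s)
    events = np.concatenate(
        [
            _poisson_times(rng_trace, config.prelabor_event_rate, 0.0, switch),
            _poisson_times(rng_trace, group.postonset_event_rate, switch, duration_s),
        ]
    )
    events = _thin_min_separation(events, MIN_SEPARATION_WIDTHS * config.peak_width_sd)
    level = _truncated_normal(rng_trace, group.peak_amp_mean, group.peak_amp_sd, 1)[0]
    amps = _truncated_normal(rng_trace, level, config.within_animal_amp_sd, len(events))

    pressure += render_transients(t, events, amps, config.peak_width_sd)

    return PressureTrace(
        animal_id=config.animal_id(animal_index),
        group=group.label,
        timestamps=t,
        pressure=pressure,
        sample_rate=fs,
        ground_truth_events=pd.DataFrame(
            {"time_s": events, "amplitude_mmHg": amps, "post_onset": events >= switch}
        ),
    )


def generate_delivery_events(config: CohortConfig, animal_index: int) -> DeliveryRecord:
    """Simulate one animal's pup-delivery record.

    Labor onset from the group's onset distribution; successive inter-pup
    gaps Normal(interpup_interval_mean, interpup_interval_sd) truncated at
    1 minute; all timestamps rounded to whole minutes.
    """
    group, _ = config.animal_group(animal_index)
    rng_onset, rng_delivery, _ = _animal_rngs(config, animal_index)
    onset_min = _draw_onset_seconds(group, rng_onset) / 60.0

    lo, hi = config.n_pups_range
    n_pups = int(rng_delivery.integers(lo, hi + 1))
    gaps = _truncated_normal(
        rng_delivery, group.interpup_interval_mean, config.interpup_interval_sd,
        n_pups - 1, lower=1.0,
    )
    times = np.round(onset_min + np.concatenate([[0.0], np.cumsum(gaps)]))
    duration_min = config.duration * 60.0
    return DeliveryRecord(
        animal_id=config.animal_id(animal_index),
        group=group.label,
        delivery_times=times,
        completed_by_gd20=bool(times[-1] <= duration_min),
        d_drg=group.d_drg,
        d_uterus=group.d_uterus,
    )


def generate_sweep(
    config: SweepConfig, depth: float, responsive: bool, index: int = 0
) -> SweepRecord:
    """Simulate one mechanical-indentation sweep.

    Gaussian baseline noise throughout; if ``responsive``, an inward
    (negative) deflection of the configured amplitude rises linearly during
    the probe ramp and persists through the hold window.
    """
    amplitude = config.amplitude_for_depth(depth)
    ss = np.random.SeedSequence(entropy=int(config.seed), spawn_key=(int(index),))
    rng = np.random.default_rng(ss)

    fs_ms = config.sample_rate / 1000.0  # samples per ms
    ramp_ms = depth / config.ramp_speed_um_per_ms
    total_ms = config.stimulus_onset + ramp_ms + config.hold_duration + config.pre_sweep
    n = int(round(total_ms * fs_ms))
    t_ms = np.arange(n, dtype=float) / fs_ms

    current = rng.normal(0.0, config.baseline_current_sd, n)
    if responsive and amplitude > 0:
        onset, hold_end = config.stimulus_onset, config.stimulus_onset + ramp_ms + config.hold_duration
        envelope = np.zeros(n)
        if ramp_ms > 0:
            ramping = (t_ms >= onset) & (t_ms < onset + ramp_ms)
            envelope[ramping] = (t_ms[ramping] - onset) / ramp_ms
        envelope[(t_ms >= onset + ramp_ms) & (t_ms < hold_end)] = 1.0
        current -= amplitude * envelope

    return SweepRecord(
        time_ms=t_ms,
        current_pA=current,
        stimulus_onset_ms=config.stimulus_onset,
        hold_duration_ms=config.hold_duration,
        depth_um=depth,
        sample_rate_hz=config.sample_rate,
        ramp_speed_um_per_ms=config.ramp_speed_um_per_ms,
    )


def generate_cohort(config: CohortConfig):
    """Generate all traces and delivery records of a cohort, in memory."""
    traces = [generate_pressure_trace(config, i) for i in range(config.n_animals)]
    records = [generate_delivery_events(config, i) for i in range(config.n_animals)]
    return traces, records


def write_cohort(config: CohortConfig, outdir: str | Path) -> Path:
    """Generate a cohort and write it as delimited text with a manifest.

    Returns the manifest path. Output is byte-identical for identical
    seed + config.
    """
    outdir = Path(outdir)
    (outdir / "traces").mkdir(parents=True, exist_ok=True)
    traces, records = generate_cohort(config)

    rows = []
    for i, (trace, record) in enumerate(zip(traces, records)):
        group, _ = config.animal_group(i)
        trace_path = Path("traces") / f"{trace.animal_id}.csv"
        write_trace(trace, outdir / trace_path)
        rows.append(
            {
                "animal_id": trace.animal_id,
                "group": group.label,
                "d_drg": group.d_drg,
                "d_uterus": group.d_uterus,
                "trace_path": str(trace_path),
                "events_path": "events.csv",
            }
        )
    write_events(records, outdir / "events.csv")
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    config.to_yaml(outdir / "cohort_config.yaml")
    return manifest


def write_sweep(sweep: SweepRecord, path: str | Path) -> None:
    """Write a sweep as ``time_ms,current_pA`` with a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"time_ms": sweep.time_ms, "current_pA": sweep.current_pA}).to_csv(
        path, index=False, float_format="%.6f"
    )
    meta = {
        "stimulus_onset_ms": sweep.stimulus_onset_ms,
        "hold_duration_ms": sweep.hold_duration_ms,
        "depth_um": sweep.depth_um,
        "sample_rate_hz": sweep.sample_rate_hz,
        "ramp_speed_um_per_ms": sweep.ramp_speed_um_per_ms,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_sweep(path: str | Path) -> SweepRecord:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return SweepRecord(
        time_ms=df["time_ms"].to_numpy(),
        current_pA=df["current_pA"].to_numpy(),
        stimulus_onset_ms=meta["stimulus_onset_ms"],
        hold_duration_ms=meta["hold_duration_ms"],
        depth_um=meta["depth_um"],
        sample_rate_hz=meta["sample_rate_hz"],
        ramp_speed_um_per_ms=meta.get("ramp_speed_um_per_ms", 1.0),
    )
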