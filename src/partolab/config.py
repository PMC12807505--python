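"""Configuration objects for synthetic cohorts, sweeps, and pipeline runs.

All configs are plain dataclasses with eager validation and YAML round-trip
support, so that a run can be reproduced exactly from the config file it
serialized.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "GroupSpec",
    "CohortConfig",
    "SweepConfig",
    "RunConfig",
    "default_cohort_config",
    "config_hash",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _finite_positive(name: str, value: float) -> None:
    _require(math.isfinite(value) and value > 0, f"{name} must be finite and > 0, got {value!r}")


def _finite_nonneg(name: str, value: float) -> None:
    _require(math.isfinite(value) and value >= 0, f"{name} must be finite and >= 0, got {value!r}")


@dataclass
class GroupSpec:
    """One treatment group of the cohort.

    ``d_drg`` / ``d_uterus`` are the knockout indicator codes for the group
    (1 = PIEZO1/2 deleted in that compartment), matching the two dummy
    predictors of the GLS contrast model.
    """

    label: str
    d_drg: int
    d_uterus: int
    postonset_event_rate: float  # contraction events per hour after labor onset
    peak_amp_mean: float  # mmHg, group mean contraction amplitude
    peak_amp_sd: float  # mmHg, BETWEEN-animal SD of the per-animal mean
    # amplitude level — the generative counterpart of the group-dependent
    # error variance sigma_g^2 in the GLS contrast model
    interpup_interval_mean: float  # minutes
    onset_zt_mean: float  # hours after lights-on
    onset_zt_sd: float  # hours

    def __post_init__(self) -> None:
        _require(self.d_drg in (0, 1), f"d_drg must be 0 or 1, got {self.d_drg}")
        _require(self.d_uterus in (0, 1), f"d_uterus must be 0 or 1, got {self.d_uterus}")
        _finite_positive("postonset_event_rate", self.postonset_event_rate)
        _finite_positive("peak_amp_mean", self.peak_amp_mean)
        _finite_nonneg("peak_amp_sd", self.peak_amp_sd)
        _finite_positive("interpup_interval_mean", self.interpup_interval_mean)
        _finite_nonneg("onset_zt_mean", self.onset_zt_mean)
        _finite_nonneg("onset_zt_sd", self.onset_zt_sd)


@dataclass
class CohortConfig:
    """Generative settings for a synthetic telemetry cohort.

    A cohort is a set of animals, each with a multi-hour intrauterine-pressure
    trace (baseline + Gaussian noise + bell-shaped contraction transients,
    event times from a two-rate Poisson process switching at labor onset) and
    a delivery record (onset time plus successive inter-pup gaps, rounded to
    whole minutes).
    """

    groups: list[GroupSpec]
    n_per_group: list[int]
    baseline_pressure: float = 5.0  # mmHg
    baseline_noise_sd: float = 1.5  # mmHg
    prelabor_event_rate: float = 2.0  # events/hour before onset
    peak_width_sd: float = 15.0  # seconds, Gaussian transient width
    within_animal_amp_sd: float = 5.0  # mmHg, transient-to-transient jitter
    interpup_interval_sd: float = 3.0  # minutes
    n_pups_range: tuple[int, int] = (6, 9)
    raw_sample_rate: float = 4.0  # Hz
    duration: float = 8.0  # hours of recording, starting at ZT0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_group, int):
            self.n_per_group = [self.n_per_group] * len(self.groups)
        self.n_per_group = list(self.n_per_group)
        self.n_pups_range = tuple(self.n_pups_range)
        self.groups = [g if isinstance(g, GroupSpec) else GroupSpec(**g) for g in self.groups]
        _require(len(self.groups) >= 1, "at least one group required")
        _require(
            len(self.n_per_group) == len(self.groups),
            "n_per_group must have one entry per group",
        )
        _require(all(n >= 1 for n in self.n_per_group), "group sizes must be >= 1")
        labels = [g.label for g in self.groups]
        _require(len(set(labels)) == len(labels), "group labels must be unique")
        _finite_nonneg("baseline_pressure", self.baseline_pressure)
        _finite_nonneg("baseline_noise_sd", self.baseline_noise_sd)
        _finite_positive("prelabor_event_rate", self.prelabor_event_rate)
        _finite_positive("peak_width_sd", self.peak_width_sd)
        _finite_nonneg("within_animal_amp_sd", self.within_animal_amp_sd)
        _finite_nonneg("interpup_interval_sd", self.interpup_interval_sd)
        lo, hi = self.n_pups_range
        _require(1 <= lo <= hi, f"invalid n_pups_range {self.n_pups_range}")
        _finite_positive("raw_sample_rate", self.raw_sample_rate)
        _require(self.raw_sample_rate >= 1.0, "raw_sample_rate must be >= 1 Hz")
        _finite_positive("duration", self.duration)
        _require(int(self.seed) == self.seed, "seed must be an integer")

    @property
    def n_animals(self) -> int:
        return int(sum(self.n_per_group))

    def animal_group(self, animal_index: int) -> tuple[GroupSpec, int]:
        """Map a flat animal index to its (group, within-group index)."""
        if not 0 <= animal_index < self.n_animals:
            raise ValueError(
                f"animal_index {animal_index} out of range for cohort of {self.n_animals}"
            )
        offset = 0
        for g, n in zip(self.groups, self.n_per_group):
            if animal_index < offset + n:
                return g, animal_index - offset
            offset += n
        raise AssertionError("unreachable")

    def animal_id(self, animal_index: int) -> str:
        group, k = self.animal_group(animal_index)
        return f"{group.label}_{k:02d}"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_pups_range"] = list(self.n_pups_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["groups"] = [GroupSpec(**g) if not isinstance(g, GroupSpec) else g for g in d["groups"]]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SweepConfig:
    """Generative settings for synthetic mechanical-indentation sweeps.

    The probe protocol mirrors whole-cell mechanostimulation: a ramp at
    ``ramp_speed_um_per_ms`` to the target indentation, held for
    ``hold_duration`` ms. Responsive sweeps carry an inward (negative)
    current deflection whose amplitude is configured per indentation depth.
    """

    sample_rate: float = 20000.0  # Hz
    stimulus_onset: float = 150.0  # ms
    hold_duration: float = 125.0  # ms, probe held at target indentation
    baseline_current_sd: float = 1.0  # pA
    depths: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0)  # micrometers
    response_amplitude: tuple[float, ...] = (20.0, 80.0, 200.0, 400.0)  # pA per depth
    ramp_speed_um_per_ms: float = 1.0
    pre_sweep: float = 50.0  # ms recorded after stimulus window ends
    seed: int = 0

    def __post_init__(self) -> None:
        self.depths = tuple(float(d) for d in self.depths)
        self.response_amplitude = tuple(float(a) for a in self.response_amplitude)
        _finite_positive("sample_rate", self.sample_rate)
        _finite_positive("stimulus_onset", self.stimulus_onset)
        _finite_positive("hold_duration", self.hold_duration)
        _finite_nonneg("baseline_current_sd", self.baseline_current_sd)
        _finite_positive("ramp_speed_um_per_ms", self.ramp_speed_um_per_ms)
        _require(len(self.depths) >= 1, "at least one depth required")
        _require(
            all(d >= 0 for d in self.depths)
            and all(a <= b for a, b in zip(self.depths, self.depths[1:])),
            "depths must be non-negative and ascending",
        )
        _require(
            len(self.response_amplitude) == len(self.depths),
            "response_amplitude must have one entry per depth",
        )
        _require(all(a >= 0 for a in self.response_amplitude), "amplitudes must be >= 0")
        _require(self.stimulus_onset >= 40.0, "need >= 40 ms of pre-stimulus baseline")

    def amplitude_for_depth(self, depth: float) -> float:
        for d, a in zip(self.depths, self.response_amplitude):
            if d == depth:
                return a
        raise ValueError(f"depth {depth} not in configured depths {self.depths}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["depths"] = list(self.depths)
        d["response_amplitude"] = list(self.response_amplitude)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SweepConfig":
        return cls(**d)


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """The default four-group study design: control, uterus-specific,
    DRG-specific and combined knockouts, with additive amplitude effects.

    Absolute per-group contraction amplitudes are not canonical; the defaults
    place the control mean at 100 mmHg and apply the additive knockout
    effects -16.01 mmHg (uterus) and -47.11 mmHg (DRG).
    """
    beta0, b_ut, b_drg = 100.0, -16.01, -47.11
    groups = [
        GroupSpec("control", 0, 0, 30.0, beta0, 10.0, 6.0, 1.5, 0.8),
        GroupSpec("uterus_ko", 0, 1, 25.0, beta0 + b_ut, 12.0, 8.0, 1.8, 0.8),
        GroupSpec("drg_ko", 1, 0, 15.0, beta0 + b_drg, 14.0, 7.0, 2.8, 1.2),
        GroupSpec("combined_ko", 1, 1, 8.0, beta0 + b_ut + b_drg, 16.0, 15.0, 3.0, 1.5),
    ]
    return CohortConfig(groups=groups, n_per_group=[8, 7, 6, 8], seed=seed)


@dataclass
class RunConfig:
    """End-to-end pipeline settings. Defaults reproduce the study's stated
    analysis: 1 Hz resampling, peaks with minimum height 40 mmHg and
    prominence 20 mmHg, the 2-hour post-onset window, the ZT3 onset
    dichotomy, and the one-sided heteroscedastic GLS contrasts."""

    outdir: str
    cohort: CohortConfig | None = None
    manifest: str | None = None  # ingest an existing cohort instead of generating
    min_height: float = 40.0  # mmHg
    min_prominence: float = 20.0  # mmHg
    window: str = "post_onset_2h"
    zt_boundary: float = 3.0  # hours; onset strictly later counts as "after"
    gls_tol: float = 1e-8
    gls_max_iter: int = 100
    gls_one_step: bool = False
    gls_alternative: str = "less"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig.from_dict(self.cohort)
        _require(
            (self.cohort is None) != (self.manifest is None),
            "exactly one of cohort / manifest must be set",
        )
        _finite_positive("min_height", self.min_height)
        _finite_positive("min_prominence", self.min_prominence)
        _require(
            self.window in ("pre_labor", "post_onset_2h", "beyond_2h"),
            f"unknown window {self.window!r}",
        )
        _finite_positive("zt_boundary", self.zt_boundary)
        _finite_positive("gls_tol", self.gls_tol)
        _require(self.gls_max_iter >= 1, "gls_max_iter must be >= 1")
        _require(self.gls_alternative in ("less", "two-sided"), "alternative must be less/two-sided")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"] = self.cohort.to_dict()
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def config_hash(cfg) -> str:
    """Stable short hash of a config, for provenance in run logs."""
    payload = yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
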