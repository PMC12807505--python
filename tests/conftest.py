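import numpy as np
import pytest

import partolab as pl


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_cohort_config():
    """A fast two-animal-per-group four-group cohort for structural tests.

    Amplitude means are lifted above the 40 mmHg detection threshold for
    every group (under the defaults the combined knockout's contractions
    are mostly undetectable, by design) and onsets pulled early so the
    2-hour window fits inside the short recording.
    """
    cfg = pl.default_cohort_config(seed=11)
    cfg.n_per_group = [2, 2, 2, 2]
    cfg.duration = 3.0
    cfg.raw_sample_rate = 2.0
    for g, mean in zip(cfg.groups, (120.0, 104.0, 73.0, 57.0)):
        g.peak_amp_mean = mean
        g.peak_amp_sd = 6.0
        g.onset_zt_mean, g.onset_zt_sd = 0.4, 0.1
        g.postonset_event_rate = max(g.postonset_event_rate, 15.0)
    return cfg


def recovery_cohort_config(seed: int) -> pl.CohortConfig:
    """Four-group cohort with the study's group sizes and the estimated
    knockout effects embedded additively in the amplitude means.

    The control level is placed at 140 mmHg so that every group's
    amplitude distribution stays well above the 40 mmHg detection
    threshold (no censoring), keeping the embedded effects identifiable.
    """
    b0, b_ut, b_drg = 140.0, -16.01, -47.11

    def mk(label, d_drg, d_ut, mean):
        return pl.GroupSpec(
            label=label, d_drg=d_drg, d_uterus=d_ut,
            postonset_event_rate=30.0, peak_amp_mean=mean, peak_amp_sd=8.0,
            interpup_interval_mean=6.0, onset_zt_mean=0.4, onset_zt_sd=0.1,
        )

    return pl.CohortConfig(
        groups=[
            mk("control", 0, 0, b0),
            mk("uterus_ko", 0, 1, b0 + b_ut),
            mk("drg_ko", 1, 0, b0 + b_drg),
            mk("combined_ko", 1, 1, b0 + b_ut + b_drg),
        ],
        n_per_group=[8, 7, 6, 8],
        baseline_pressure=0.5,
        baseline_noise_sd=1.0,
        within_animal_amp_sd=5.0,
        raw_sample_rate=4.0,
        duration=3.0,
        seed=seed,
    )


def run_cohort_through_pipeline(cfg: pl.CohortConfig):
    """Generator -> resample -> peaks -> window -> summaries, in memory."""
    summaries = []
    for i in range(cfg.n_animals):
        trace = pl.resample_1hz(pl.generate_pressure_trace(cfg, i))
        record = pl.generate_delivery_events(cfg, i)
        detected = pl.find_peaks(trace)
        bounds = (float(trace.timestamps[0]), float(trace.timestamps[-1]) + 1.0)
        ps = pl.window_peaks(detected, record, "post_onset_2h", bounds)
        group, _ = cfg.animal_group(i)
        summaries.append(
            pl.summarize_animal(ps, record, group.d_drg, group.d_uterus)
        )
    return summaries
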