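import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import stepmetrics as sm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_series(n_epochs: int, counts=0.0, steps=0.0,
                 axis_means=(0.090, 0.095, 0.985),
                 axis_sds=(0.020, 0.020, 0.020),
                 start="2015-01-05 00:00:00",
                 subject_id="T01") -> sm.EpochSeries:
    """Hand-built series with constant (or per-epoch array) channels."""
    index = pd.date_range(start, periods=n_epochs, freq="15s")
    steps60 = np.full(n_epochs, np.nan)
    steps_arr = np.broadcast_to(np.asarray(steps, float), (n_epochs // 4,))
    steps60[:: 4][: len(steps_arr)] = steps_arr
    data = pd.DataFrame({
        "counts15": np.broadcast_to(np.asarray(counts, float), (n_epochs,)).copy(),
        "steps60": steps60,
        "ax_mean": np.broadcast_to(np.asarray(axis_means[0], float), (n_epochs,)).copy(),
        "ay_mean": np.broadcast_to(np.asarray(axis_means[1], float), (n_epochs,)).copy(),
        "az_mean": np.broadcast_to(np.asarray(axis_means[2], float), (n_epochs,)).copy(),
        "ax_sd": np.broadcast_to(np.asarray(axis_sds[0], float), (n_epochs,)).copy(),
        "ay_sd": np.broadcast_to(np.asarray(axis_sds[1], float), (n_epochs,)).copy(),
        "az_sd": np.broadcast_to(np.asarray(axis_sds[2], float), (n_epochs,)).copy(),
    }, index=index)
    return sm.EpochSeries.from_frame(subject_id, data)


def run_cohort(cohort: sm.synthetic.SyntheticCohort):
    """Standard pipeline on an in-memory synthetic cohort."""
    frames = []
    for series in cohort.series:
        cleaned = sm.preprocess_series(series, cohort.diary)
        frames.append(sm.day_metrics_frame(cleaned))
    daydata = pd.concat(frames, ignore_index=True)
    daydata, included = sm.screen_validity(daydata)
    summary = sm.summarize_subjects(daydata, included,
                                    subjects_meta=cohort.truth.subjects)
    return daydata, included, summary


@pytest.fixture(scope="session")
def cohort105():
    """Default study-scale cohort (n=105, 7 days, seed 1) plus pipeline output."""
    cohort = sm.generate_cohort(sm.SyntheticConfig(n_subjects=105, seed=1))
    daydata, included, summary = run_cohort(cohort)
    return cohort, daydata, included, summary


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort with frequent planted nonwear, for recovery tests."""
    cfg = sm.SyntheticConfig(n_subjects=6, seed=3, nonwear_episodes_per_day=0.6)
    cohort = sm.generate_cohort(cfg)
    return cohort


@pytest.fixture()
def week_series():
    """Quiet 7-day hand-built series (all wear, zero activity)."""
    return build_series(7 * 5760)


def make_day_df(rows):
    """Day-metrics frame stub for screening tests."""
    frame = pd.DataFrame(rows)
    frame["date"] = [dt.date(2015, 1, 5) + dt.timedelta(days=i)
                     for i in range(len(frame))] if "date" not in frame else frame["date"]
    return frame
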