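import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import stepmetrics as sm
from stepmetrics.io_epoch import ConfigError, DiaryEntry
from stepmetrics.preprocess import TooShortError, ValidityRules

from conftest import build_series
from oracles import naive_nonwear_mask


def _random_stats_series(rng, hours=4):
    """Series with random axis statistics spanning wear-like and still regimes."""
    n = hours * 240
    regimes = rng.integers(0, 3, size=n // 60)  # per-15-min regime
    means = np.empty((n, 3))
    sds = np.empty((n, 3))
    for i, reg in enumerate(np.repeat(regimes, 60)):
        if reg == 0:   # still, off-body-like
            means[i] = [0.01, 0.015, 1.0]
            sds[i] = 0.002
        elif reg == 1:  # worn, quiet
            means[i] = [0.09, 0.095, 0.98]
            sds[i] = 0.02
        else:           # worn, moving
            means[i] = rng.normal([0.09, 0.095, 0.95], 0.03)
            sds[i] = rng.uniform(0.05, 0.2, 3)
    means += rng.normal(0, 0.002, (n, 3))
    return build_series(n, axis_means=(means[:, 0], means[:, 1], means[:, 2]),
                        axis_sds=(sds[:, 0], sds[:, 1], sds[:, 2]))


def test_zero_variance_recording_is_all_nonwear():
    series = build_series(2 * 240, axis_means=(0.0, 0.0, 1.0),
                          axis_sds=(0.0, 0.0, 0.0))
    out = sm.detect_nonwear(series)
    assert out.mask_nonwear.all()


def test_moving_worn_recording_is_never_nonwear():
    # per-epoch SDs of 25 mg and axis means (200, 300, 900) mg fail both rules
    series = build_series(2 * 240, axis_means=(0.2, 0.3, 0.9),
                          axis_sds=(0.025, 0.025, 0.025))
    out = sm.detect_nonwear(series)
    assert not out.mask_nonwear.any()


def test_sustained_high_acceleration_flags_malfunction_block():
    series = build_series(4 * 240, axis_means=(0.2, 0.3, 0.9),
                          axis_sds=(0.025, 0.025, 0.025))
    block = slice(240, 300)  # one 15-min block
    series.data.iloc[block, series.data.columns.get_loc("ax_mean")] = 6.0
    out = sm.detect_nonwear(series)
    assert out.mask_nonwear[block].all()
    assert out.mask_nonwear.sum() == 60


def test_recording_shorter_than_one_block_errors():
    with pytest.raises(TooShortError):
        sm.detect_nonwear(build_series(40))


def test_detection_matches_brute_force_oracle():
    rng = np.random.default_rng(17)
    for _ in range(12):
        series = _random_stats_series(rng)
        got = sm.detect_nonwear(series).mask_nonwear
        want = naive_nonwear_mask(
            series.data[["ax_mean", "ay_mean", "az_mean"]].to_numpy(),
            series.data[["ax_sd", "ay_sd", "az_sd"]].to_numpy())
        assert (got == want).all()


def test_detection_is_translation_invariant():
    rng = np.random.default_rng(23)
    series = _random_stats_series(rng)
    shifted = series.copy()
    shifted.data.index = series.data.index + pd.Timedelta(minutes=45)
    a = sm.detect_nonwear(series).mask_nonwear
    b = sm.detect_nonwear(shifted).mask_nonwear
    assert (a == b).all()


def test_planted_nonwear_recovery_rates(small_cohort):
    """>=95% of planted nonwear minutes flagged; <=2% of true wear flagged."""
    cohort = small_cohort
    tp = fn = fp = tn = 0
    for series in cohort.series:
        detected = sm.detect_nonwear(series)
        planted = cohort.truth.nonwear_intervals
        planted = planted[planted.subject_id == series.subject_id]
        truth = np.zeros(len(series), bool)
        idx = series.data.index
        for row in planted.itertuples():
            truth |= np.asarray((idx >= row.start) & (idx < row.end))
        mask = detected.mask_nonwear
        tp += (mask & truth).sum()
        fn += (~mask & truth).sum()
        fp += (mask & ~truth).sum()
        tn += (~mask & ~truth).sum()
    assert tp / (tp + fn) >= 0.95
    assert fp / (fp + tn) <= 0.02


# ---------------------------------------------------------------------------
# Imputation


def _week_with_nonwear_at(slot, days_nonwear, counts_by_day):
    series = build_series(7 * 5760)
    col = series.data.columns.get_loc("counts15")
    for day, value in counts_by_day.items():
        series.data.iloc[day * 5760 + slot, col] = value
    for day in days_nonwear:
        series.mask_nonwear[day * 5760 + slot] = True
    return series


def test_imputation_is_the_donor_mean_at_the_same_clock_time():
    slot = 10 * 240  # 10:00:00
    counts = {0: 0, 1: 0, 2: 999, 3: 60, 4: 0, 5: 0, 6: 0}
    series = _week_with_nonwear_at(slot, [2], counts)
    out = sm.impute_nonwear(series)
    assert out.data["counts15"].iloc[2 * 5760 + slot] == pytest.approx(10.0)
    assert out.mask_imputed[2 * 5760 + slot]
    # wear epochs unchanged
    untouched = ~series.mask_nonwear
    assert (out.data["counts15"].to_numpy()[untouched]
            == series.data["counts15"].to_numpy()[untouched]).all()


def test_epoch_without_donors_stays_missing():
    slot = 10 * 240
    series = _week_with_nonwear_at(slot, range(7), {d: 50 for d in range(7)})
    out = sm.impute_nonwear(series)
    for day in range(7):
        assert np.isnan(out.data["counts15"].iloc[day * 5760 + slot])
        assert not out.mask_imputed[day * 5760 + slot]


def test_step_minutes_imputed_from_fully_worn_donor_minutes():
    series = build_series(7 * 5760, steps=0.0)
    minute = 10 * 60  # 10:00
    scol = series.data.columns.get_loc("steps60")
    for day, value in enumerate([30, 30, 0, 60, 30, 30, 30]):
        series.data.iloc[day * 5760 + minute * 4, scol] = value
    # day 2, 10:00: one epoch of the minute is nonwear
    series.mask_nonwear[2 * 5760 + minute * 4 + 1] = True
    out = sm.impute_nonwear(series)
    donors = [30, 30, 60, 30, 30, 30]
    assert out.data["steps60"].iloc[2 * 5760 + minute * 4] == pytest.approx(
        np.mean(donors))


def test_imputation_beats_zero_filling_for_steps(small_cohort):
    cohort = small_cohort
    err_imputed = err_zeroed = 0.0
    truth = cohort.truth.day_truth.set_index(["subject_id", "date"])["steps"]
    for series in cohort.series:
        detected = sm.detect_nonwear(series)
        imputed = sm.exclude_sleep(sm.impute_nonwear(detected), cohort.diary)
        zeroed = sm.exclude_sleep(detected, cohort.diary)
        zeroed.mask_nonwear[:] = False  # keep the zeros, pretend it is wear
        for frame, acc in ((sm.day_metrics_frame(imputed), "imp"),
                           (sm.day_metrics_frame(zeroed), "zero")):
            for row in frame.itertuples():
                true_steps = truth.get((row.subject_id, row.date))
                if true_steps is None or np.isnan(row.steps):
                    continue
                err = abs(row.steps - true_steps)
                if acc == "imp":
                    err_imputed += err
                else:
                    err_zeroed += err
    assert err_imputed < err_zeroed


# ---------------------------------------------------------------------------
# Sleep exclusion


def test_diary_window_masks_sleep_minutes(week_series):
    diary = [DiaryEntry("T01", dt.date(2015, 1, 5) + dt.timedelta(days=d),
                        dt.time(22, 0), dt.time(8, 0)) for d in range(-1, 7)]
    out = sm.exclude_sleep(week_series, diary)
    # a full interior night masks 600 minutes = 2400 epochs
    day = out.data.index.date == dt.date(2015, 1, 7)
    assert out.mask_sleep[day].sum() == (8 * 60 + 2 * 60) * 4  # 00-08 and 22-24
    awake_min = (day & ~out.mask_sleep).sum() / 4
    assert awake_min == 840


def test_missing_night_falls_back_to_mean_times(week_series):
    diary = [DiaryEntry("T01", dt.date(2015, 1, 5) + dt.timedelta(days=d),
                        dt.time(22, 0), dt.time(8, 0)) for d in range(-1, 7)]
    full = sm.exclude_sleep(week_series, diary)
    missing = [e for e in diary if e.date != dt.date(2015, 1, 8)]
    partial = sm.exclude_sleep(week_series, missing)
    assert (full.mask_sleep == partial.mask_sleep).all()


def test_subject_without_diary_is_a_config_error(week_series):
    with pytest.raises(ConfigError, match="T01"):
        sm.exclude_sleep(week_series, [DiaryEntry("OTHER", dt.date(2015, 1, 5),
                                                  dt.time(22, 0), dt.time(8, 0))])


def test_sleep_mask_equals_ground_truth_with_exact_diary(small_cohort):
    cohort = small_cohort
    windows = cohort.truth.sleep_windows
    for series in cohort.series[:2]:
        out = sm.exclude_sleep(series, cohort.diary)
        own = windows[windows.subject_id == series.subject_id]
        truth = np.zeros(len(series), bool)
        idx = series.data.index
        for row in own.itertuples():
            truth |= np.asarray((idx >= row.bed) & (idx < row.wake))
        assert (out.mask_sleep == truth).all()


# ---------------------------------------------------------------------------
# Validity screening


def _days(subject, specs):
    rows = []
    for date, wear_min in specs:
        rows.append({"subject_id": subject, "date": date,
                     "is_weekend": date.weekday() >= 5,
                     "wear_total_min": wear_min})
    return pd.DataFrame(rows)


def test_weekend_day_required_for_inclusion():
    monday = dt.date(2015, 1, 5)
    weekdays = [(monday + dt.timedelta(days=i), 1200) for i in range(5)]
    day_df = _days("A", weekdays)
    _, included = sm.screen_validity(day_df)
    assert not included["A"]

    with_sunday = weekdays[:3] + [(dt.date(2015, 1, 11), 1200)]
    _, included = sm.screen_validity(_days("B", with_sunday))
    assert included["B"]


def test_sixteen_hour_boundary_is_strict():
    monday = dt.date(2015, 1, 5)
    specs = [(monday + dt.timedelta(days=i), 15.9 * 60) for i in range(7)]
    flagged, included = sm.screen_validity(_days("A", specs))
    assert not flagged["valid"].any()
    assert not included["A"]
    specs = [(monday + dt.timedelta(days=i), 16 * 60) for i in range(7)]
    flagged, included = sm.screen_validity(_days("A", specs))
    assert flagged["valid"].all()
    assert included["A"]


@given(st.integers(0, 6), st.integers(1, 8))
def test_translation_invariance_under_whole_block_shifts(offset_blocks, seed):
    rng = np.random.default_rng(seed)
    series = _random_stats_series(rng, hours=3)
    shifted = series.copy()
    shifted.data.index = (series.data.index
                          + pd.Timedelta(minutes=15 * offset_blocks))
    assert (sm.detect_nonwear(series).mask_nonwear
            == sm.detect_nonwear(shifted).mask_nonwear).all()
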