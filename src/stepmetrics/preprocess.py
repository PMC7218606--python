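"""Nonwear detection, imputation, sleep exclusion and validity screening.

The cleaning stages mirror a standard 24-h wear protocol reduction:

1. **Nonwear detection** — each consecutive 15-min block is flagged as
   nonwear when, over the surrounding 60-min window (centered on the block,
   truncated at the recording edges), at least 2 of the 3 axes show an
   acceleration SD below 13 mg, or at least 2 of 3 show a mean below 50 mg.
   Sustained abnormal accelerations (axis mean above 5.5 g through a whole
   block) are treated as device malfunction and likewise flagged nonwear.
2. **Imputation** — flagged epochs are imputed with the mean value observed
   at the same clock time on the subject's other (worn) days; epochs with no
   donor day stay missing.  Counts are imputed per 15-s epoch and steps per
   60-s minute (donor minutes must be fully worn).
3. **Sleep exclusion** — diary bed→wake windows are masked as sleep; nights
   without a diary entry fall back to the subject's mean bed/wake clock
   times over the reported nights.
4. **Validity screening** — a day is valid with >=16 h of wear over the
   24-h day; a subject is included with >=4 valid days of which >=1 falls
   on a weekend.

Window statistics are pooled from the epoch-level per-axis mean/SD channels
(pooled variance = mean within-epoch variance + between-epoch variance of
means); raw-sample statistics are not available at epoch resolution.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd

from .io_epoch import (
    AXIS_MEAN_COLUMNS,
    AXIS_SD_COLUMNS,
    ConfigError,
    DiaryEntry,
    EpochSeries,
    StepmetricsError,
)

EPOCHS_PER_MIN = 4
MINUTES_PER_DAY = 1440
SLOTS_PER_DAY = MINUTES_PER_DAY * EPOCHS_PER_MIN


class TooShortError(StepmetricsError):
    """Recording shorter than one nonwear block."""


@dataclasses.dataclass(frozen=True)
class NonwearParams:
    """Thresholds of the nonwear/malfunction rule (units in field names)."""

    block_min: int = 15
    window_min: int = 60
    sd_threshold_mg: float = 13.0
    mean_threshold_mg: float = 50.0
    axes_required: int = 2
    malfunction_g: float = 5.5

    def __post_init__(self) -> None:
        if min(self.block_min, self.window_min, self.sd_threshold_mg,
               self.mean_threshold_mg, self.malfunction_g) <= 0:
            raise ConfigError("nonwear thresholds must be positive")
        if self.window_min < self.block_min or self.window_min % self.block_min:
            raise ConfigError("window_min must be a multiple of block_min")


@dataclasses.dataclass(frozen=True)
class ValidityRules:
    min_days: int = 4
    min_weekend_days: int = 1
    min_wear_hours: float = 16.0

    def __post_init__(self) -> None:
        if min(self.min_days, self.min_weekend_days, self.min_wear_hours) <= 0:
            raise ConfigError("validity rules must be positive")


# ---------------------------------------------------------------------------
# Nonwear detection


def detect_nonwear(series: EpochSeries,
                   params: NonwearParams = NonwearParams()) -> EpochSeries:
    """Return a copy of *series* with ``mask_nonwear`` set per 15-s epoch.

    Blocks are anchored at the recording start, so shifting a recording by a
    whole number of blocks shifts the mask identically.
    """
    out = series.copy()
    n = len(out)
    epb = params.block_min * 60 // 15          # epochs per block
    half = (params.window_min - params.block_min) * 60 // 15 // 2
    if n < epb:
        raise TooShortError(
            f"{series.subject_id}: {n} epochs < one {params.block_min}-min block"
        )
    means = out.data[AXIS_MEAN_COLUMNS].to_numpy(float)
    sds = out.data[AXIS_SD_COLUMNS].to_numpy(float)
    if np.isnan(means).any() or np.isnan(sds).any():
        raise ConfigError(f"{series.subject_id}: acceleration channels contain NaN")

    sd_thr = params.sd_threshold_mg / 1000.0
    mean_thr = params.mean_threshold_mg / 1000.0
    mask = np.zeros(n, dtype=bool)
    n_blocks = (n + epb - 1) // epb
    for b in range(n_blocks):
        b0, b1 = b * epb, min((b + 1) * epb, n)
        w0, w1 = max(0, b0 - half), min(n, b1 + half)
        m = means[w0:w1]
        s = sds[w0:w1]
        win_mean = m.mean(axis=0)
        win_var = (s ** 2).mean(axis=0) + m.var(axis=0)
        win_sd = np.sqrt(win_var)
        low_sd = int((win_sd < sd_thr).sum())
        low_mean = int((np.abs(win_mean) < mean_thr).sum())
        malfunction = bool(
            (np.abs(means[b0:b1]).max(axis=1) > params.malfunction_g).all()
        )
        if (low_sd >= params.axes_required
                or low_mean >= params.axes_required
                or malfunction):
            mask[b0:b1] = True
    out.mask_nonwear = mask
    out.mask_imputed = np.zeros(n, dtype=bool)
    return out


# ---------------------------------------------------------------------------
# Time-matched imputation


def _day_slot_layout(series: EpochSeries):
    idx = series.data.index
    dates = idx.normalize()
    day0 = dates[0]
    day_idx = ((dates - day0).days).to_numpy()
    slot = ((idx - dates).total_seconds().to_numpy() / 15).astype(int)
    n_days = int(day_idx.max()) + 1
    return day_idx, slot, n_days, day0


def impute_nonwear(series: EpochSeries) -> EpochSeries:
    """Impute counts/steps over nonwear epochs from the same clock time on
    the subject's other worn days; epochs with no donor day stay missing.

    Wear epochs are never altered.  ``mask_imputed`` marks nonwear epochs
    whose counts were recovered; a minute's steps are recovered only from
    donor minutes whose four epochs are all worn.
    """
    out = series.copy()
    n = len(out)
    day_idx, slot, n_days, _ = _day_slot_layout(out)
    nonwear = out.mask_nonwear
    counts = out.data["counts15"].to_numpy(float)

    counts_mat = np.full((n_days, SLOTS_PER_DAY), np.nan)
    wear_mat = np.zeros((n_days, SLOTS_PER_DAY), dtype=bool)
    present = np.zeros((n_days, SLOTS_PER_DAY), dtype=bool)
    counts_mat[day_idx, slot] = counts
    wear_mat[day_idx, slot] = ~nonwear
    present[day_idx, slot] = True

    donor = wear_mat & ~np.isnan(counts_mat)
    with np.errstate(invalid="ignore"):
        donor_n = donor.sum(axis=0)
        donor_sum = np.where(donor, counts_mat, 0.0).sum(axis=0)
        donor_mean = np.where(donor_n > 0, donor_sum / np.maximum(donor_n, 1), np.nan)

    new_counts = counts.copy()
    has_donor = donor_n[slot] > 0
    target = nonwear
    new_counts[target & has_donor] = donor_mean[slot[target & has_donor]]
    new_counts[target & ~has_donor] = np.nan
    out.data["counts15"] = new_counts
    out.mask_imputed = target & has_donor

    # Steps at minute resolution ------------------------------------------
    steps = out.data["steps60"].to_numpy(float)
    steps_mat = np.full((n_days, MINUTES_PER_DAY), np.nan)
    minute_start = slot % EPOCHS_PER_MIN == 0
    steps_mat[day_idx[minute_start], slot[minute_start] // EPOCHS_PER_MIN] = (
        steps[minute_start]
    )
    wear4 = wear_mat.reshape(n_days, MINUTES_PER_DAY, EPOCHS_PER_MIN)
    present4 = present.reshape(n_days, MINUTES_PER_DAY, EPOCHS_PER_MIN)
    minute_worn = wear4.all(axis=2) & present4.all(axis=2)
    minute_present = present4.all(axis=2)
    minute_touched = (~wear4 & present4).any(axis=2)  # any nonwear epoch

    donor_min = minute_worn & ~np.isnan(steps_mat)
    dn = donor_min.sum(axis=0)
    dsum = np.where(donor_min, steps_mat, 0.0).sum(axis=0)
    dmean = np.where(dn > 0, dsum / np.maximum(dn, 1), np.nan)

    new_steps = steps.copy()
    min_of_day = slot // EPOCHS_PER_MIN
    is_target_min = minute_touched[day_idx, min_of_day] & minute_present[day_idx, min_of_day]
    sel = minute_start & is_target_min
    new_steps[sel] = dmean[min_of_day[sel]]
    out.data["steps60"] = new_steps
    return out


# ---------------------------------------------------------------------------
# Sleep exclusion


def _mean_clock_times(entries: list[DiaryEntry]) -> tuple[dt.time, dt.time]:
    # Bed times are averaged on a noon-anchored scale so windows crossing
    # midnight average sensibly (22:00 and 02:00 -> 00:00, not 12:00).
    bed = np.mean([((e.bed_time.hour * 60 + e.bed_time.minute) - 720) % 1440
                   for e in entries])
    wake = np.mean([e.wake_time.hour * 60 + e.wake_time.minute for e in entries])
    bed_min = int(round(720 + bed)) % 1440
    wake_min = int(round(wake)) % 1440
    return dt.time(bed_min // 60, bed_min % 60), dt.time(wake_min // 60, wake_min % 60)


def exclude_sleep(series: EpochSeries,
                  diary: list[DiaryEntry]) -> EpochSeries:
    """Mask diary bed→wake windows as sleep (``mask_sleep``).

    Nights without an entry use the subject's mean bed/wake clock times over
    the available nights.  A subject with no diary entries at all is a
    configuration error.
    """
    own = [e for e in diary if e.subject_id == series.subject_id]
    if not own:
        raise ConfigError(f"no diary entries for subject {series.subject_id}")
    out = series.copy()
    by_date = {e.date: e for e in own}
    fb_bed, fb_wake = _mean_clock_times(own)

    idx = out.data.index
    first = idx[0].date() - dt.timedelta(days=1)
    last = idx[-1].date()
    mask = np.zeros(len(idx), dtype=bool)
    d = first
    while d <= last:
        entry = by_date.get(d)
        if entry is None:
            entry = DiaryEntry(series.subject_id, d, fb_bed, fb_wake)
        start, end = entry.window()
        if end > idx[0].to_pydatetime() and start <= idx[-1].to_pydatetime():
            mask |= (idx >= start) & (idx < end)
        d += dt.timedelta(days=1)
    out.mask_sleep = np.asarray(mask)
    return out


# ---------------------------------------------------------------------------
# Validity screening


def screen_validity(daydata: pd.DataFrame,
                    rules: ValidityRules = ValidityRules()
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Flag valid days and included subjects.

    *daydata* needs columns ``subject_id``, ``date``, ``is_weekend`` and
    ``wear_total_min`` (wear over the full 24-h day; the protocol is 24-h
    wear, so wear during sleep counts toward the threshold).
    """
    out = daydata.copy()
    out["valid"] = out["wear_total_min"] >= rules.min_wear_hours * 60.0
    valid = out[out["valid"]]
    n_valid = valid.groupby("subject_id").size()
    n_weekend = valid[valid["is_weekend"]].groupby("subject_id").size()
    subjects = out["subject_id"].unique()
    included = pd.Series(
        [
            (n_valid.get(s, 0) >= rules.min_days
             and n_weekend.get(s, 0) >= rules.min_weekend_days)
            for s in subjects
        ],
        index=pd.Index(subjects, name="subject_id"),
        name="included",
    )
    return out, included


def preprocess_series(series: EpochSeries, diary: list[DiaryEntry],
                      params: NonwearParams = NonwearParams()) -> EpochSeries:
    """Full cleaning chain: detect nonwear → impute → mask sleep."""
    return exclude_sleep(impute_nonwear(detect_nonwear(series, params)), diary)
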