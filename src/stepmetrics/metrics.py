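"""Daily and weekly physical-activity metrics.

Counts-based intensity uses pediatric activity-count cut points on 15-s
epochs: sedentary <=25, light 26-573, moderate 574-1002, vigorous >=1003
counts/15 s; LMVPA is everything above sedentary and MVPA everything above
light.  Step-based metrics use 60-s cadence (steps/min) organized into
~20 steps/min bands with behavioral labels (incidental 1-19, sporadic
20-39, purposeful 40-59, slow walking 60-79, medium walking 80-99, brisk
walking 100-119, faster walking >=120), time at zero cadence (TZC), and
peak 1-/30-/60-min cadences (mean of the N highest, not necessarily
consecutive, minutes of the day).

Weekly subject-level values weight weekday and weekend means as
``(weekday mean x 5 + weekend mean x 2) / 7``; the >=60 min/day MVPA
guideline flag is evaluated on the weekly-weighted MVPA.

A minute enters the step-based metrics only when all four of its 15-s
epochs are awake wear (imputed epochs count as wear); counts-based minutes
are accumulated per 15-s epoch (1 epoch = 0.25 min).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io_epoch import ConfigError, EpochSeries

EPOCHS_PER_MIN = 4


@dataclasses.dataclass(frozen=True)
class CutPoints:
    """Activity-count intensity thresholds (counts per 15-s epoch)."""

    sedentary_max: float = 25.0
    moderate_min: float = 574.0
    vigorous_min: float = 1003.0

    def __post_init__(self) -> None:
        if not 0 <= self.sedentary_max < self.moderate_min < self.vigorous_min:
            raise ConfigError("cut points must be increasing and nonnegative")


INTENSITY_LABELS = ["sedentary", "light", "moderate", "vigorous"]


@dataclasses.dataclass(frozen=True)
class CadenceBands:
    """Cadence-band lower edges (steps/min); zero cadence is its own bin."""

    lower_edges: tuple[float, ...] = (1, 20, 40, 60, 80, 100, 120)
    labels: tuple[str, ...] = (
        "incidental", "sporadic", "purposeful", "slow_walking",
        "medium_walking", "brisk_walking", "faster_walking",
    )

    def __post_init__(self) -> None:
        edges = self.lower_edges
        if len(edges) != len(self.labels):
            raise ConfigError("one label per band required")
        if list(edges) != sorted(edges) or edges[0] <= 0:
            raise ConfigError("band edges must be increasing and positive")

    @property
    def columns(self) -> list[str]:
        cols = []
        for i, lo in enumerate(self.lower_edges):
            if i + 1 < len(self.lower_edges):
                hi = self.lower_edges[i + 1] - 1
                cols.append(f"band_{int(lo)}_{int(hi)}")
            else:
                cols.append(f"band_{int(lo)}_plus")
        return cols


DEFAULT_BANDS = CadenceBands()
BAND_COLUMNS = DEFAULT_BANDS.columns
GUIDELINE_MVPA_MIN = 60.0

DAY_METRIC_COLUMNS = [
    "subject_id", "date", "is_weekend",
    "awake_min", "wear_total_min", "wear_awake_min",
    "sedentary_min", "light_min", "moderate_min", "vigorous_min",
    "lmvpa_min", "mvpa_min", "mean_counts15",
    "steps", "tzc_min", *BAND_COLUMNS,
    "peak1", "peak30", "peak60", "n_step_minutes", "peak_short", "valid",
]


def classify_intensity(counts15: float, cuts: CutPoints = CutPoints()) -> str:
    """Classify one 15-s epoch's counts into an intensity category."""
    if counts15 < 0:
        raise ValueError(f"negative counts: {counts15}")
    return INTENSITY_LABELS[int(_intensity_codes(np.asarray([counts15]), cuts)[0])]


def _intensity_codes(counts: np.ndarray, cuts: CutPoints) -> np.ndarray:
    codes = np.zeros(counts.shape, dtype=int)
    codes[counts > cuts.sedentary_max] = 1
    codes[counts >= cuts.moderate_min] = 2
    codes[counts >= cuts.vigorous_min] = 3
    return codes


class PeakCadence(NamedTuple):
    value: float
    short: bool  # fewer than n minutes were available


def peak_cadence(minute_steps: Sequence[float], n: int) -> PeakCadence:
    """Mean of the ``min(n, available)`` highest steps/min values.

    Returns NaN for an empty day; flags days offering fewer than *n*
    minutes (the mean then uses everything available).
    """
    arr = np.asarray(minute_steps, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return PeakCadence(float("nan"), False)
    top = np.sort(arr)[::-1][: int(n)]
    return PeakCadence(float(top.mean()), arr.size < n)


def _band_minutes(steps: np.ndarray, bands: CadenceBands) -> dict[str, float]:
    # The first band opens at zero (exclusive) so fractional imputed
    # cadences below its integer lower edge still count as incidental
    # movement; together with TZC the bins partition [0, inf).
    out = {"tzc_min": float((steps == 0).sum())}
    edges = [0.0] + list(bands.lower_edges[1:]) + [np.inf]
    for col, lo, hi in zip(bands.columns, edges[:-1], edges[1:]):
        out[col] = float(((steps > lo) & (steps < hi)).sum()
                         if lo == 0.0 else
                         ((steps >= lo) & (steps < hi)).sum())
    return out


def day_metrics(series: EpochSeries, date: dt.date,
                cuts: CutPoints = CutPoints(),
                bands: CadenceBands = DEFAULT_BANDS) -> dict:
    """Compute one subject-day's metric row (masks must be set already)."""
    idx = series.data.index
    sel = np.asarray(idx.date == date)
    if not sel.any():
        raise ValueError(f"{series.subject_id}: {date} outside recording")
    awake = sel & ~series.mask_sleep
    usable = series.usable & awake
    worn = sel & ~series.mask_nonwear

    row: dict = {
        "subject_id": series.subject_id,
        "date": date,
        "is_weekend": date.weekday() >= 5,
        "awake_min": awake.sum() / EPOCHS_PER_MIN,
        "wear_total_min": worn.sum() / EPOCHS_PER_MIN,
        "wear_awake_min": usable.sum() / EPOCHS_PER_MIN,
        "valid": False,
    }
    if not usable.any():
        for col in DAY_METRIC_COLUMNS:
            row.setdefault(col, np.nan)
        row["peak_short"] = True
        row["n_step_minutes"] = 0
        return row

    counts = series.data["counts15"].to_numpy(float)[usable]
    codes = _intensity_codes(counts, cuts)
    for code, label in enumerate(INTENSITY_LABELS):
        row[f"{label}_min"] = float((codes == code).sum()) / EPOCHS_PER_MIN
    row["lmvpa_min"] = row["light_min"] + row["moderate_min"] + row["vigorous_min"]
    row["mvpa_min"] = row["moderate_min"] + row["vigorous_min"]
    row["mean_counts15"] = float(counts.mean())

    # Whole minutes: all four epochs awake wear and a steps value present.
    day_pos = np.flatnonzero(sel)
    secs = idx[sel].second.values + idx[sel].minute.values * 60 + idx[sel].hour.values * 3600
    minute_id = secs // 60
    usable_day = usable[day_pos]
    steps_day = series.data["steps60"].to_numpy(float)[day_pos]
    frame = pd.DataFrame({"minute": minute_id, "usable": usable_day, "steps": steps_day})
    grouped = frame.groupby("minute")
    full = grouped["usable"].all() & (grouped.size() == EPOCHS_PER_MIN)
    minute_steps = grouped["steps"].first()
    ok = full & minute_steps.notna()
    steps_vals = minute_steps[ok].to_numpy(float)

    row["n_step_minutes"] = int(steps_vals.size)
    row["steps"] = float(steps_vals.sum()) if steps_vals.size else np.nan
    row.update(_band_minutes(steps_vals, bands) if steps_vals.size
               else {c: np.nan for c in ["tzc_min", *bands.columns]})
    p1 = peak_cadence(steps_vals, 1)
    p30 = peak_cadence(steps_vals, 30)
    p60 = peak_cadence(steps_vals, 60)
    row["peak1"], row["peak30"], row["peak60"] = p1.value, p30.value, p60.value
    row["peak_short"] = p60.short
    return row


def day_metrics_frame(series: EpochSeries,
                      cuts: CutPoints = CutPoints(),
                      bands: CadenceBands = DEFAULT_BANDS) -> pd.DataFrame:
    """Metric rows for every calendar date the recording touches."""
    dates = sorted(set(series.data.index.date))
    rows = [day_metrics(series, d, cuts, bands) for d in dates]
    return pd.DataFrame(rows)[DAY_METRIC_COLUMNS]


# ---------------------------------------------------------------------------
# Weekly weighting

WEEKLY_METRICS = [
    "awake_min", "wear_total_min", "wear_awake_min",
    "sedentary_min", "light_min", "moderate_min", "vigorous_min",
    "lmvpa_min", "mvpa_min", "mean_counts15",
    "steps", "tzc_min", *BAND_COLUMNS, "peak1", "peak30", "peak60",
]

SUBJECT_SUMMARY_COLUMNS = [
    "subject_id", "n_valid_days", "n_weekend_days",
    *["steps_per_day" if m == "steps" else m for m in WEEKLY_METRICS],
    "meets_guideline",
]


def weekly_summary(days: pd.DataFrame,
                   guideline_mvpa_min: float = GUIDELINE_MVPA_MIN) -> dict:
    """Weekly-weighted summary of one subject's *valid* day rows.

    weekly value = (mean over valid weekdays x 5 + mean over valid weekend
    days x 2) / 7.  Requires at least one valid day in each stratum
    (guaranteed by the screening rules).
    """
    if days.empty:
        raise ConfigError("weekly_summary needs at least one valid day")
    subject = days["subject_id"].iloc[0]
    wd = days[~days["is_weekend"]]
    we = days[days["is_weekend"]]
    if wd.empty or we.empty:
        raise ConfigError(
            f"{subject}: weekly weighting needs >=1 valid weekday and weekend day"
        )
    out: dict = {
        "subject_id": subject,
        "n_valid_days": int(len(days)),
        "n_weekend_days": int(len(we)),
    }
    for metric in WEEKLY_METRICS:
        weekly = (wd[metric].mean() * 5 + we[metric].mean() * 2) / 7
        name = "steps_per_day" if metric == "steps" else metric
        out[name] = float(weekly)
    out["meets_guideline"] = bool(out["mvpa_min"] >= guideline_mvpa_min)
    return out


def summarize_subjects(daydata: pd.DataFrame, included: pd.Series,
                       guideline_mvpa_min: float = GUIDELINE_MVPA_MIN,
                       subjects_meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Weekly summaries for every included subject (the cohort table).

    *daydata* must carry the ``valid`` flag from
    :func:`stepmetrics.preprocess.screen_validity`; *subjects_meta* may add
    passthrough labels (``sex``, ``weight_status``) keyed by ``subject_id``.
    """
    rows = []
    for subject, flag in included.items():
        if not flag:
            continue
        days = daydata[(daydata["subject_id"] == subject) & daydata["valid"]]
        rows.append(weekly_summary(days, guideline_mvpa_min))
    cohort = pd.DataFrame(rows, columns=SUBJECT_SUMMARY_COLUMNS)
    if subjects_meta is not None and not cohort.empty:
        cohort = cohort.merge(subjects_meta, on="subject_id", how="left")
    return cohort
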