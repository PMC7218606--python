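"""Reference descriptive statistics for the motivating cohort.

The package was built around a 7-day, 24-h hip-worn accelerometry protocol in
105 children with overweight or obesity (mean age 10.1 y).  The published
cohort-level descriptive statistics below (mean and between-subject SD of each
daily metric, weekly-weighted) serve two purposes:

* they are the default calibration targets of the synthetic cohort generator
  (:mod:`stepmetrics.synthetic`), so that simulated cohorts are summarized by
  realistic step and cadence distributions; and
* they support the desk-scale composite summaries below (hours of active time,
  ambulatory time, zero-cadence time, ...), which are pure arithmetic on the
  published values.

All times are min/day unless noted; cadences are steps/min.
"""

from __future__ import annotations

N_COHORT = 105
N_MEETING_GUIDELINE = 20  # subjects with weekly-weighted MVPA >= 60 min/day

# (mean, between-subject SD), weekly-weighted daily values
COHORT_DESCRIPTIVES: dict[str, tuple[float, float]] = {
    "awake_min": (919.6, 31.5),
    "wear_awake_min": (903.1, 35.3),
    "sedentary_min": (600.8, 69.6),
    "light_min": (273.2, 51.7),
    "moderate_min": (34.0, 11.6),
    "vigorous_min": (10.7, 6.7),
    "mvpa_min": (44.7, 16.8),
    "steps_per_day": (8676.8, 2202.9),
    "peak60": (63.7, 13.6),
    "peak30": (78.0, 14.5),
    "peak1": (111.5, 13.3),
    "tzc_min": (346.6, 78.1),
    "band_1_19": (439.0, 63.4),
    "band_20_39": (71.9, 18.2),
    "band_40_59": (27.5, 9.2),
    "band_60_79": (15.9, 7.9),
    "band_80_99": (10.2, 6.2),
    "band_100_119": (6.6, 6.0),
    "band_120_plus": (1.6, 2.6),
}

#: Cadence-band columns in ascending order (excluding zero cadence).
BAND_COLUMNS = [
    "band_1_19",
    "band_20_39",
    "band_40_59",
    "band_60_79",
    "band_80_99",
    "band_100_119",
    "band_120_plus",
]

#: Bands at >= 20 steps/min, i.e. sporadic movement through faster walking.
AMBULATORY_BANDS = BAND_COLUMNS[1:]


def mean(metric: str) -> float:
    return COHORT_DESCRIPTIVES[metric][0]


def sd(metric: str) -> float:
    return COHORT_DESCRIPTIVES[metric][1]


def guideline_prevalence_pct(n_meeting: int = N_MEETING_GUIDELINE,
                             n_total: int = N_COHORT) -> float:
    """Percentage of the cohort meeting the >=60 min/day MVPA guideline."""
    if n_total <= 0 or not 0 <= n_meeting <= n_total:
        raise ValueError("need 0 <= n_meeting <= n_total")
    return round(100.0 * n_meeting / n_total, 1)


def active_hours_per_day() -> float:
    """Mean h/day at light or higher intensity (LMVPA = light + MVPA)."""
    return round((mean("light_min") + mean("mvpa_min")) / 60.0, 1)


def ambulatory_hours_per_day() -> float:
    """Mean h/day in cadence bands >= 20 steps/min."""
    return round(sum(mean(b) for b in AMBULATORY_BANDS) / 60.0, 1)


def zero_cadence_hours_per_day() -> float:
    """Mean h/day at zero cadence (TZC)."""
    return round(mean("tzc_min") / 60.0, 1)


def incidental_hours_per_day() -> float:
    """Mean h/day of incidental movement (1-19 steps/min)."""
    return round(mean("band_1_19") / 60.0, 1)


def sedentary_hours_per_day() -> float:
    """Mean h/day of count-defined sedentary time."""
    return round(mean("sedentary_min") / 60.0, 1)
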