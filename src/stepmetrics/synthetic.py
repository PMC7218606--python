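"""Synthetic 7-day accelerometry cohorts with known ground truth.

The generator emulates the study conditions the package targets: ~105
children wearing a hip accelerometer 24 h/day for 7 days, with diary-logged
sleep windows, occasional nonwear episodes and rare device-malfunction
spikes.  Awake time is tiled with alternating rest and activity bouts
(exponential bout durations); each active bout carries a nominal cadence
drawn within one of the behavioral cadence bands, and per-band expected
daily minutes default to the reference cohort descriptives
(:mod:`stepmetrics.reference`), so a default cohort reproduces realistic
steps/day and cadence-band distributions.

Counts are derived from cadence through a linear map with multiplicative
lognormal noise, calibrated so that walking at 115 steps/min lands just
above the moderate-intensity threshold of 574 counts/15 s.  Because much of
children's vigorous activity is non-ambulatory play, a configurable
fraction of awake zero-cadence minutes receives high-count activity bursts
with no steps.

Ground truth (sleep windows, planted nonwear/malfunction intervals, and
per-day band/intensity/step totals realized in the activity stream before
nonwear overwriting) is returned alongside the emitted streams, enabling
recovery tests for every downstream stage.

Determinism: one root seed; per-subject RNG streams are spawned from a
``numpy`` ``SeedSequence``, so identical ``(config, seed)`` produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from . import reference
from .io_epoch import (
    AXIS_MEAN_COLUMNS,
    AXIS_SD_COLUMNS,
    ConfigError,
    DiaryEntry,
    EpochSeries,
    write_diary,
    write_epoch_file,
)
from .metrics import (
    BAND_COLUMNS,
    DEFAULT_BANDS,
    CutPoints,
    _band_minutes,
    _intensity_codes,
)

SLOTS_PER_DAY = 5760
MINUTES_PER_DAY = 1440

_DEFAULT_BAND_MEANS = {b: reference.mean(b) for b in BAND_COLUMNS}
_DEFAULT_BAND_SDS = {b: reference.sd(b) for b in BAND_COLUMNS}

# Nominal in-band cadence ranges stay two steps/min clear of the band edges
# so per-minute cadence jitter cannot leak minutes across bands.
_BAND_CADENCE_RANGES = {
    "band_1_19": (2, 17),
    "band_20_39": (22, 37),
    "band_40_59": (42, 57),
    "band_60_79": (62, 77),
    "band_80_99": (82, 97),
    "band_100_119": (102, 117),
    "band_120_plus": (122, 145),
}


@dataclasses.dataclass
class SyntheticConfig:
    """Cohort-level simulation settings (defaults = the study conditions)."""

    n_subjects: int = 105
    days: int = 7
    seed: int = 1
    start_date: dt.date = dt.date(2015, 1, 5)  # a Monday: 5 weekdays + weekend

    # Sleep protocol (clock minutes); expected awake time ~920 min/day.
    bed_time_mean_min: int = 1340          # 22:20
    wake_time_mean_min: int = 420          # 07:00
    sleep_subject_sd_min: float = 15.0
    sleep_night_sd_min: float = 12.0
    diary_jitter_sd_min: float = 0.0

    # Nonwear / malfunction
    nonwear_episodes_per_day: float = 0.15
    nonwear_durations_min: tuple[int, ...] = (60, 75, 90, 105, 120)
    malfunction_per_week: float = 0.2

    # Activity structure
    band_minutes_mean: dict = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_BAND_MEANS))
    band_minutes_sd: dict = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_BAND_SDS))
    bout_mean_min: float = 3.0
    day_jitter_sigma: float = 0.12         # lognormal day-to-day variation
    weekend_multiplier: float = 1.0
    cadence_jitter_sd: float = 0.5
    incidental_mean_cadence: float = 5.103  # sets expected steps/day ~8677

    # Cadence→counts map and non-ambulatory activity
    counts_slope: float = 5.0              # counts/15 s per steps/min
    counts_intercept: float = 0.0
    counts_noise_sigma: float = 0.45       # lognormal sigma, mean-one noise
    nonambulatory_fraction: float = 0.07   # awake minutes with stepless bursts
    nonambulatory_subject_sigma: float = 0.30  # residual between-subject spread
    nonambulatory_coupling: float = 2.5    # burst propensity ~ (rel. volume)^c
    subject_activity_sigma: float = 0.12   # shared activity factor across bands
    burst_counts_scale: float = 700.0

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.days <= 0:
            raise ConfigError("n_subjects and days must be positive")
        if any(v < 0 for v in self.band_minutes_mean.values()):
            raise ConfigError("band minutes must be nonnegative")
        if any(v < 0 for v in self.band_minutes_sd.values()):
            raise ConfigError("band minute SDs must be nonnegative")
        for rate in (self.nonwear_episodes_per_day, self.malfunction_per_week,
                     self.nonambulatory_fraction, self.cadence_jitter_sd):
            if rate < 0:
                raise ConfigError("rates must be nonnegative")
        expected_awake = MINUTES_PER_DAY - (
            MINUTES_PER_DAY - self.bed_time_mean_min + self.wake_time_mean_min)
        total = sum(self.band_minutes_mean.values())
        if total >= expected_awake - 30:
            raise ConfigError(
                f"infeasible bout mix: {total:.0f} active min/day vs "
                f"{expected_awake:.0f} expected awake min/day"
            )
        if total >= MINUTES_PER_DAY:
            raise ConfigError("band minutes exceed the day")


@dataclasses.dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    subjects: pd.DataFrame          # subject_id, sex, weight_status
    sleep_windows: pd.DataFrame     # subject_id, date, bed, wake
    nonwear_intervals: pd.DataFrame  # subject_id, start, end, kind
    day_truth: pd.DataFrame         # per subject-day realized activity


@dataclasses.dataclass
class SyntheticCohort:
    series: list[EpochSeries]
    diary: list[DiaryEntry]
    truth: GroundTruth
    epoch_paths: list[Path] | None = None
    diary_path: Path | None = None


# ---------------------------------------------------------------------------
# Calibration helpers


def _truncation_adjusted_mu(target: float, sd: float) -> float:
    """Location m with E[max(N(m, sd), 0)] == target (censored-normal mean)."""
    if sd == 0 or target == 0:
        return target

    def censored_mean(m: float) -> float:
        z = m / sd
        return m * norm.cdf(z) + sd * norm.pdf(z)

    lo, hi = target - 6 * sd, target + sd
    return brentq(lambda m: censored_mean(m) - target, lo, hi, xtol=1e-9)


def _incidental_cadence_pmf(mean_target: float) -> tuple[np.ndarray, np.ndarray]:
    """Geometric-shaped cadence pmf on 2..17 steps/min with a given mean.

    Incidental movement is dominated by very low cadences, so the in-band
    distribution decays from the low edge rather than being uniform.
    """
    support = np.arange(2, 18)

    def mean_at(theta: float) -> float:
        w = np.exp(-(support - 2) / theta)
        return float((support * w).sum() / w.sum())

    theta = brentq(lambda t: mean_at(t) - mean_target, 0.3, 50.0, xtol=1e-9)
    weights = np.exp(-(support - 2) / theta)
    return support, weights / weights.sum()


def cadence_to_counts_map(cadence, config: SyntheticConfig,
                          rng: np.random.Generator):
    """Counts per 15-s epoch for a given cadence (steps/min).

    Expected value is ``intercept + slope * cadence`` (monotone in cadence);
    realizations carry mean-one multiplicative lognormal noise.
    """
    cad = np.asarray(cadence, dtype=float)
    if (cad < 0).any():
        raise ValueError("cadence must be nonnegative")
    base = config.counts_intercept + config.counts_slope * cad
    sig = config.counts_noise_sigma
    noise = rng.lognormal(-0.5 * sig * sig, sig, size=cad.shape)
    return base * noise


# ---------------------------------------------------------------------------
# Per-subject simulation


def _draw_band_targets(cfg: SyntheticConfig, rng: np.random.Generator) -> dict:
    out = {}
    for band in BAND_COLUMNS:
        mu, sd = cfg.band_minutes_mean[band], cfg.band_minutes_sd[band]
        if mu == 0:
            out[band] = 0.0
            continue
        m = _truncation_adjusted_mu(mu, sd)
        out[band] = max(0.0, rng.normal(m, sd))
    return out


def _sleep_schedule(cfg: SyntheticConfig, rng: np.random.Generator):
    """Bed/wake clock minutes for nights -1 .. days-1 (wake of night j is
    the morning of day j+1)."""
    bed_off = rng.normal(0, cfg.sleep_subject_sd_min)
    wake_off = rng.normal(0, cfg.sleep_subject_sd_min)
    beds, wakes = [], []
    for _ in range(cfg.days + 1):
        bed = cfg.bed_time_mean_min + bed_off + rng.normal(0, cfg.sleep_night_sd_min)
        wake = cfg.wake_time_mean_min + wake_off + rng.normal(0, cfg.sleep_night_sd_min)
        beds.append(int(np.clip(round(bed), 1260, 1435)))
        wakes.append(int(np.clip(round(wake), 330, 560)))
    return beds, wakes


def _build_day_cadence(cfg: SyntheticConfig, rng: np.random.Generator,
                       awake_len: int, band_minutes: dict,
                       pmf) -> np.ndarray:
    """Minute-level cadence over one day's awake period (length awake_len)."""
    targets = {b: int(round(m)) for b, m in band_minutes.items()}
    total = sum(targets.values())
    if total > awake_len - 5:
        scale = (awake_len - 5) / max(total, 1)
        targets = {b: int(math.floor(m * scale)) for b, m in targets.items()}
        total = sum(targets.values())
    bouts: list[tuple[int, int]] = []
    support, probs = pmf
    for band in BAND_COLUMNS:
        remaining = targets[band]
        lo, hi = _BAND_CADENCE_RANGES[band]
        while remaining > 0:
            length = max(1, int(round(rng.exponential(cfg.bout_mean_min))))
            length = min(length, remaining)
            if band == "band_1_19":
                cad = int(rng.choice(support, p=probs))
            else:
                cad = int(rng.integers(lo, hi + 1))
            bouts.append((length, cad))
            remaining -= length
    order = rng.permutation(len(bouts))
    bouts = [bouts[i] for i in order]
    rest_total = awake_len - total
    gaps = rng.multinomial(rest_total, np.full(len(bouts) + 1, 1.0 / (len(bouts) + 1)))
    cadence = np.zeros(awake_len, dtype=float)
    pos = int(gaps[0])
    for (length, cad), gap in zip(bouts, gaps[1:]):
        cadence[pos:pos + length] = cad
        pos += length + int(gap)
    # per-minute jitter on active minutes
    active = cadence > 0
    if cfg.cadence_jitter_sd > 0 and active.any():
        jitter = rng.normal(0, cfg.cadence_jitter_sd, size=int(active.sum()))
        cadence[active] = np.clip(np.round(cadence[active] + jitter), 0, 240)
    return cadence


def simulate_subject(subject_id: str, cfg: SyntheticConfig,
                     seed_seq: np.random.SeedSequence):
    """One subject's emitted epoch stream, diary entries and ground truth."""
    rng = np.random.Generator(np.random.PCG64(seed_seq))
    days, start = cfg.days, cfg.start_date
    n_epochs = days * SLOTS_PER_DAY

    # --- traits -----------------------------------------------------------
    sex = "boy" if rng.random() < 62 / 105 else "girl"
    weight_status = str(rng.choice(
        ["overweight", "mild obesity", "severe obesity", "morbid obesity"],
        p=[0.42, 0.33, 0.18, 0.07]))
    base_x = float(np.clip(rng.normal(0.090, 0.002), 0.085, 0.095))
    base_y = float(np.clip(rng.normal(0.095, 0.002), 0.090, 0.100))
    base_z = math.sqrt(max(0.05, 1.0 - base_x ** 2 - base_y ** 2))

    beds, wakes = _sleep_schedule(cfg, rng)
    band_targets = _draw_band_targets(cfg, rng)
    # mean-one general activity factor: children differ in overall volume,
    # not just band-by-band, which also drives non-ambulatory play below
    sig_a = cfg.subject_activity_sigma
    activity = rng.lognormal(-0.5 * sig_a * sig_a, sig_a)
    band_targets = {b: v * activity for b, v in band_targets.items()}
    mean_cad = {b: (cfg.incidental_mean_cadence if b == "band_1_19"
                    else 0.5 * sum(_BAND_CADENCE_RANGES[b]))
                for b in BAND_COLUMNS}
    exp_steps = sum(band_targets[b] * mean_cad[b] for b in BAND_COLUMNS)
    ref_steps = sum(cfg.band_minutes_mean[b] * mean_cad[b] for b in BAND_COLUMNS)
    rel_volume = exp_steps / ref_steps if ref_steps > 0 else 1.0
    pmf = _incidental_cadence_pmf(cfg.incidental_mean_cadence)

    steps_min = np.zeros(days * MINUTES_PER_DAY, dtype=float)  # per minute
    sleep_minute = np.zeros(days * MINUTES_PER_DAY, dtype=bool)

    diary, sleep_rows = [], []
    for night in range(days + 1):
        night_date = start + dt.timedelta(days=night - 1)
        bed_min, wake_min = beds[night], wakes[night]
        bed_dt = dt.datetime.combine(night_date, dt.time(0)) + dt.timedelta(minutes=bed_min)
        wake_dt = dt.datetime.combine(night_date + dt.timedelta(days=1),
                                      dt.time(0)) + dt.timedelta(minutes=wake_min)
        sleep_rows.append((subject_id, night_date, bed_dt, wake_dt))
        if cfg.diary_jitter_sd_min > 0:
            bed_min = int(np.clip(round(bed_min + rng.normal(0, cfg.diary_jitter_sd_min)),
                                  1260, 1439))
            wake_min = int(np.clip(round(wake_min + rng.normal(0, cfg.diary_jitter_sd_min)),
                                   300, 600))
        diary.append(DiaryEntry(subject_id, night_date,
                                dt.time(bed_min // 60, bed_min % 60),
                                dt.time(wake_min // 60, wake_min % 60)))
        # mark sleep minutes inside the recording
        rec_start = dt.datetime.combine(start, dt.time(0))
        lo = max(0, int((bed_dt - rec_start).total_seconds() // 60))
        hi = min(days * MINUTES_PER_DAY, int((wake_dt - rec_start).total_seconds() // 60))
        if hi > lo:
            sleep_minute[lo:hi] = True

    # --- per-day activity --------------------------------------------------
    for d in range(days):
        is_weekend = (start + dt.timedelta(days=d)).weekday() >= 5
        day_slice = slice(d * MINUTES_PER_DAY, (d + 1) * MINUTES_PER_DAY)
        awake_idx = np.flatnonzero(~sleep_minute[day_slice]) + d * MINUTES_PER_DAY
        if awake_idx.size == 0:
            continue
        sig = cfg.day_jitter_sigma
        mult = cfg.weekend_multiplier if is_weekend else 1.0
        day_bands = {
            b: band_targets[b] * mult * rng.lognormal(-0.5 * sig * sig, sig)
            for b in BAND_COLUMNS
        }
        cadence = _build_day_cadence(cfg, rng, awake_idx.size, day_bands, pmf)
        steps_min[awake_idx] = cadence

    # --- counts and axis channels ------------------------------------------
    cad_epoch = np.repeat(steps_min, 4)
    sleep_epoch = np.repeat(sleep_minute, 4)
    counts = np.zeros(n_epochs, dtype=float)
    active = cad_epoch > 0
    if active.any():
        counts[active] = np.round(cadence_to_counts_map(cad_epoch[active], cfg, rng))
    # sedentary fidgeting on awake zero-cadence epochs (stays sedentary)
    quiet = ~active & ~sleep_epoch
    fidget = rng.random(int(quiet.sum())) < 0.30
    vals = rng.integers(1, 26, size=int(quiet.sum()))
    counts[quiet] = np.where(fidget, vals, 0)
    # non-ambulatory high-intensity bursts on zero-cadence awake minutes;
    # the burst propensity varies between subjects (mean-one lognormal), which
    # is what spreads count-based MVPA across children at fixed step volume
    zero_awake_minutes = np.flatnonzero((steps_min == 0) & ~sleep_minute)
    sig_s = cfg.nonambulatory_subject_sigma
    subject_frac = (cfg.nonambulatory_fraction
                    * rel_volume ** cfg.nonambulatory_coupling
                    * rng.lognormal(-0.5 * sig_s * sig_s, sig_s))
    n_burst = int(round(subject_frac * (~sleep_minute).sum()))
    n_burst = min(n_burst, zero_awake_minutes.size)
    if n_burst > 0:
        burst_minutes = rng.choice(zero_awake_minutes, size=n_burst, replace=False)
        burst_epochs = (burst_minutes[:, None] * 4 + np.arange(4)).ravel()
        sigb = 0.5
        counts[burst_epochs] = np.round(
            cfg.burst_counts_scale
            * rng.lognormal(-0.5 * sigb * sigb, sigb, size=burst_epochs.size))
    counts[sleep_epoch] = rng.integers(0, 6, size=int(sleep_epoch.sum()))
    counts = np.clip(counts, 0, None)

    ax = np.empty((n_epochs, 3))
    ax[:, 0] = base_x + rng.normal(0, 0.008, n_epochs)
    ax[:, 1] = base_y + rng.normal(0, 0.008, n_epochs)
    ax[:, 2] = base_z + rng.normal(0, 0.010, n_epochs)
    ax[sleep_epoch, 0] = 0.55 + rng.normal(0, 0.010, int(sleep_epoch.sum()))
    ax[sleep_epoch, 1] = 0.60 + rng.normal(0, 0.010, int(sleep_epoch.sum()))
    ax[sleep_epoch, 2] = 0.40 + rng.normal(0, 0.010, int(sleep_epoch.sum()))
    sd = (0.018 + 0.0004 * counts[:, None]
          + np.abs(rng.normal(0, 0.003, (n_epochs, 3))))
    sd = np.clip(sd, 0.014, 0.5)

    # --- ground truth of the activity stream (pre-overwrite) ---------------
    truth_rows = []
    cuts = CutPoints()
    for d in range(days):
        date = start + dt.timedelta(days=d)
        mins = slice(d * MINUTES_PER_DAY, (d + 1) * MINUTES_PER_DAY)
        eps = slice(d * SLOTS_PER_DAY, (d + 1) * SLOTS_PER_DAY)
        awake_m = ~sleep_minute[mins]
        steps_d = steps_min[mins][awake_m]
        row = {"subject_id": subject_id, "date": date,
               "awake_min": int(awake_m.sum()), "steps": float(steps_d.sum())}
        row.update(_band_minutes(steps_d, DEFAULT_BANDS))
        codes = _intensity_codes(counts[eps][~sleep_epoch[eps]], cuts)
        for code, label in enumerate(["sedentary", "light", "moderate", "vigorous"]):
            row[f"{label}_min"] = float((codes == code).sum()) / 4.0
        row["mvpa_min"] = row["moderate_min"] + row["vigorous_min"]
        truth_rows.append(row)

    # --- plant nonwear and malfunction -------------------------------------
    intervals: list[tuple[int, int, str]] = []  # [start_min, end_min), kind

    def overlaps(lo: int, hi: int) -> bool:
        return any(lo < e and hi > s for s, e, _ in intervals)

    n_nw = rng.poisson(cfg.nonwear_episodes_per_day * days)
    for _ in range(n_nw):
        for _attempt in range(20):
            d = int(rng.integers(0, days))
            dur = int(rng.choice(list(cfg.nonwear_durations_min)))
            awake_idx = np.flatnonzero(~sleep_minute[d * MINUTES_PER_DAY:(d + 1) * MINUTES_PER_DAY])
            if awake_idx.size == 0:
                continue
            lo_q = int(math.ceil((awake_idx[0]) / 15))
            hi_q = int(math.floor((awake_idx[-1] + 1) / 15)) - dur // 15
            if hi_q <= lo_q:
                continue
            q = int(rng.integers(lo_q, hi_q))
            lo = d * MINUTES_PER_DAY + q * 15
            hi = lo + dur
            if not overlaps(lo, hi):
                intervals.append((lo, hi, "nonwear"))
                break
    n_mf = rng.poisson(cfg.malfunction_per_week * days / 7.0)
    for _ in range(n_mf):
        for _attempt in range(20):
            d = int(rng.integers(0, days))
            awake_idx = np.flatnonzero(~sleep_minute[d * MINUTES_PER_DAY:(d + 1) * MINUTES_PER_DAY])
            if awake_idx.size == 0:
                continue
            q = int(rng.integers(int(math.ceil(awake_idx[0] / 15)),
                                 int(math.floor((awake_idx[-1] + 1) / 15)) - 1))
            lo = d * MINUTES_PER_DAY + q * 15
            hi = lo + 15
            if not overlaps(lo, hi):
                intervals.append((lo, hi, "malfunction"))
                break

    steps_emit = steps_min.copy()
    for lo, hi, kind in intervals:
        eps = slice(lo * 4, hi * 4)
        steps_emit[lo:hi] = 0.0
        counts[eps] = 0.0
        n_ep = hi * 4 - lo * 4
        if kind == "nonwear":
            ax[eps, 0] = 0.008 + rng.normal(0, 0.001, n_ep)
            ax[eps, 1] = 0.012 + rng.normal(0, 0.001, n_ep)
            ax[eps, 2] = 1.000 + rng.normal(0, 0.001, n_ep)
            sd[eps] = 0.002 + np.abs(rng.normal(0, 0.0005, (n_ep, 3)))
        else:
            ax[eps] = rng.uniform(5.8, 6.5, (n_ep, 3))
            sd[eps] = 0.05

    # --- assemble ----------------------------------------------------------
    index = pd.date_range(dt.datetime.combine(start, dt.time(0)),
                          periods=n_epochs, freq="15s")
    steps60 = np.full(n_epochs, np.nan)
    steps60[::4] = steps_emit
    data = pd.DataFrame({
        "counts15": np.round(counts),
        "steps60": steps60,
        "ax_mean": np.round(ax[:, 0], 6),
        "ay_mean": np.round(ax[:, 1], 6),
        "az_mean": np.round(ax[:, 2], 6),
        "ax_sd": np.round(sd[:, 0], 6),
        "ay_sd": np.round(sd[:, 1], 6),
        "az_sd": np.round(sd[:, 2], 6),
    }, index=index)
    series = EpochSeries.from_frame(subject_id, data)

    rec_start = dt.datetime.combine(start, dt.time(0))
    interval_rows = [
        (subject_id, rec_start + dt.timedelta(minutes=lo),
         rec_start + dt.timedelta(minutes=hi), kind)
        for lo, hi, kind in sorted(intervals)
    ]
    meta = {"subject_id": subject_id, "sex": sex, "weight_status": weight_status}
    return series, diary, truth_rows, sleep_rows, interval_rows, meta


def generate_cohort(config: SyntheticConfig,
                    outdir: str | Path | None = None,
                    overwrite: bool = False) -> SyntheticCohort:
    """Simulate a full cohort; optionally write epoch files and the diary."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_subjects)

    all_series, all_diary = [], []
    truth_rows, sleep_rows, interval_rows, meta_rows = [], [], [], []
    for i, child in enumerate(children):
        sid = f"S{i + 1:03d}"
        series, diary, t_rows, s_rows, i_rows, meta = simulate_subject(sid, config, child)
        all_series.append(series)
        all_diary.extend(diary)
        truth_rows.extend(t_rows)
        sleep_rows.extend(s_rows)
        interval_rows.extend(i_rows)
        meta_rows.append(meta)

    truth = GroundTruth(
        subjects=pd.DataFrame(meta_rows),
        sleep_windows=pd.DataFrame(sleep_rows,
                                   columns=["subject_id", "date", "bed", "wake"]),
        nonwear_intervals=pd.DataFrame(interval_rows,
                                       columns=["subject_id", "start", "end", "kind"]),
        day_truth=pd.DataFrame(truth_rows),
    )
    cohort = SyntheticCohort(all_series, all_diary, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cohort.epoch_paths = [
            write_epoch_file(s, outdir / f"{s.subject_id}.csv", overwrite=overwrite)
            for s in all_series
        ]
        cohort.diary_path = write_diary(all_diary, outdir / "diary.csv",
                                        overwrite=overwrite)
    return cohort


# ---------------------------------------------------------------------------
# Subject-level cohort tables with planned regression structure


def linear_cohort(n: int = 105, r2: float = 0.74, seed: int = 0,
                  slope: float = 0.006586, intercept: float = -12.44,
                  steps_mean: float = 8676.8, steps_sd: float = 2202.9,
                  with_bands: bool = True) -> pd.DataFrame:
    """Subject-level table where MVPA is a noisy linear function of steps/day
    with a *planned population* r².

    Defaults place the 60 min/day MVPA guideline at ~11,000 steps/day and
    the cohort MVPA mean near 45 min/day.  With ``with_bands`` the table
    also carries cadence-band and peak-cadence predictors correlated with
    the steps/day driver (but less predictive of MVPA than steps/day), plus
    TZC, counts/15 s and LMVPA columns — the full analysis-layer schema.
    """
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    steps = rng.normal(steps_mean, steps_sd, n)
    signal_sd = abs(slope) * steps_sd
    noise_sd = signal_sd * math.sqrt(1.0 / r2 - 1.0)
    mvpa = intercept + slope * steps + rng.normal(0, noise_sd, n)
    mvpa = np.clip(mvpa, 0.5, None)
    z = (steps - steps_mean) / steps_sd
    table = {
        "subject_id": [f"S{i + 1:03d}" for i in range(n)],
        "steps_per_day": steps,
        "mvpa_min": mvpa,
    }
    if with_bands:
        rho = {"band_1_19": 0.35, "band_20_39": 0.60, "band_40_59": 0.60,
               "band_60_79": 0.55, "band_80_99": 0.55, "band_100_119": 0.50,
               "band_120_plus": 0.40, "peak60": 0.55, "peak30": 0.50,
               "peak1": 0.45}
        for name, r in rho.items():
            mu, sd = reference.COHORT_DESCRIPTIVES[name]
            vals = mu + sd * (r * z + math.sqrt(1 - r * r) * rng.standard_normal(n))
            table[name] = np.clip(vals, 0, None)
        mu, sd = reference.COHORT_DESCRIPTIVES["tzc_min"]
        table["tzc_min"] = np.clip(
            mu + sd * (-0.5 * z + math.sqrt(0.75) * rng.standard_normal(n)), 0, None)
        table["mean_counts15"] = np.clip(
            375 + 90 * (0.81 * z + math.sqrt(1 - 0.81 ** 2) * rng.standard_normal(n)),
            20, None)
        lm_mu = reference.mean("light_min") + reference.mean("mvpa_min")
        table["lmvpa_min"] = np.clip(
            lm_mu + 55 * (0.63 * z + math.sqrt(1 - 0.63 ** 2) * rng.standard_normal(n)),
            10, None)
    frame = pd.DataFrame(table)
    frame["meets_guideline"] = frame["mvpa_min"] >= 60.0
    return frame
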