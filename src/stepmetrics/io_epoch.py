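"""Reading and writing of epoch files, sleep diaries and derived tables.

The package's native epoch format is a plain CSV with a small ``#`` header
block, one row per 15-s epoch::

    # stepmetrics-epoch v1
    # subject_id: S01
    # epoch_seconds: 15
    # start: 2015-01-05T00:00:00
    timestamp,counts15,steps60,ax_mean,ay_mean,az_mean,ax_sd,ay_sd,az_sd
    2015-01-05T00:00:00,0,0,0.090000,0.112000,0.980000,0.018000,...

``counts15`` holds vertical-axis activity counts accumulated over the 15-s
epoch; ``steps60`` holds steps accumulated over the 60-s epoch and is
populated only on rows whose timestamp starts a minute (empty elsewhere);
the six trailing columns are per-axis mean and standard deviation of
acceleration in g over the epoch.  Timestamps are naive local time on a
strict 15-s grid aligned to clock quarter-minutes; gaps are an error.

The diary CSV is ``subject_id,date,bed_time,wake_time``; a bed time later
than the wake time denotes a window spanning into the next calendar date.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import io
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("stepmetrics")

EPOCH_SECONDS = 15
STEPS60_MAX = 300  # >300 steps/min is physiologically impossible; reject early

EPOCH_COLUMNS = [
    "timestamp", "counts15", "steps60",
    "ax_mean", "ay_mean", "az_mean", "ax_sd", "ay_sd", "az_sd",
]
AXIS_MEAN_COLUMNS = ["ax_mean", "ay_mean", "az_mean"]
AXIS_SD_COLUMNS = ["ax_sd", "ay_sd", "az_sd"]


class StepmetricsError(Exception):
    """Base class for all package errors."""


class FormatError(StepmetricsError):
    """Malformed file header or unparseable field."""


class GridError(StepmetricsError):
    """Timestamps not strictly increasing on the 15-s grid, or gapped."""


class SanityError(StepmetricsError):
    """Physically impossible channel value (e.g. steps60 > 300)."""


class ConfigError(StepmetricsError):
    """Invalid configuration or missing required per-subject inputs."""


@dataclasses.dataclass
class DiaryEntry:
    """One night's self-reported bed and wake times."""

    subject_id: str
    date: dt.date
    bed_time: dt.time
    wake_time: dt.time

    def window(self) -> tuple[dt.datetime, dt.datetime]:
        """Bed-to-wake interval; crosses midnight iff bed_time > wake_time."""
        start = dt.datetime.combine(self.date, self.bed_time)
        wake_date = self.date
        if self.bed_time > self.wake_time:
            wake_date = self.date + dt.timedelta(days=1)
        end = dt.datetime.combine(wake_date, self.wake_time)
        return start, end


@dataclasses.dataclass
class EpochSeries:
    """One subject's epoch stream plus wear/sleep/imputation mask channels.

    ``data`` is indexed by a naive 15-s DatetimeIndex and has the channel
    columns of :data:`EPOCH_COLUMNS` (minus ``timestamp``).  The three masks
    are boolean arrays aligned with ``data``; they start all-False and are
    filled in by :mod:`stepmetrics.preprocess`.
    """

    subject_id: str
    data: pd.DataFrame
    mask_nonwear: np.ndarray
    mask_imputed: np.ndarray
    mask_sleep: np.ndarray

    @classmethod
    def from_frame(cls, subject_id: str, data: pd.DataFrame) -> "EpochSeries":
        n = len(data)
        series = cls(
            subject_id=subject_id,
            data=data,
            mask_nonwear=np.zeros(n, dtype=bool),
            mask_imputed=np.zeros(n, dtype=bool),
            mask_sleep=np.zeros(n, dtype=bool),
        )
        series.validate()
        return series

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "EpochSeries":
        return EpochSeries(
            self.subject_id,
            self.data.copy(),
            self.mask_nonwear.copy(),
            self.mask_imputed.copy(),
            self.mask_sleep.copy(),
        )

    def validate(self) -> None:
        idx = self.data.index
        if len(idx) == 0:
            raise GridError(f"{self.subject_id}: empty epoch series")
        if not isinstance(idx, pd.DatetimeIndex):
            raise GridError(f"{self.subject_id}: index must be datetimes")
        if idx.tz is not None:
            raise GridError(f"{self.subject_id}: timestamps must be naive local time")
        # normalize index metadata (name, inferred freq) so round-trips compare equal
        self.data.index = pd.DatetimeIndex(idx.values, name="timestamp")
        idx = self.data.index
        secs = idx.second.values
        if np.any(idx.microsecond.values != 0) or np.any(secs % EPOCH_SECONDS != 0):
            raise GridError(f"{self.subject_id}: timestamps off the 15-s grid")
        deltas = np.diff(idx.values).astype("timedelta64[s]").astype(int)
        if len(deltas) and not np.all(deltas == EPOCH_SECONDS):
            bad = int(np.flatnonzero(deltas != EPOCH_SECONDS)[0])
            raise GridError(
                f"{self.subject_id}: non-contiguous or non-monotone grid at row {bad + 1}"
            )
        for mask in (self.mask_nonwear, self.mask_imputed, self.mask_sleep):
            if len(mask) != len(idx):
                raise GridError(f"{self.subject_id}: mask length mismatch")
        if (self.mask_imputed & ~self.mask_nonwear).any():
            raise SanityError(
                f"{self.subject_id}: imputed epochs must be a subset of nonwear epochs"
            )
        counts = self.data["counts15"]
        if (counts.dropna() < 0).any():
            raise SanityError(f"{self.subject_id}: negative counts15")
        steps = self.data["steps60"]
        minute_start = secs == 0
        if steps[~minute_start].notna().any():
            raise GridError(
                f"{self.subject_id}: steps60 present off minute-start epochs"
            )
        s = steps.dropna()
        if (s < 0).any() or (s > STEPS60_MAX).any():
            raise SanityError(
                f"{self.subject_id}: steps60 outside [0, {STEPS60_MAX}]"
            )
        for col in AXIS_SD_COLUMNS:
            if (self.data[col].dropna() < 0).any():
                raise SanityError(f"{self.subject_id}: negative {col}")

    # Derived boolean channels used throughout the pipeline -----------------

    @property
    def worn(self) -> np.ndarray:
        """Device on the body: everything not flagged nonwear/malfunction."""
        return ~self.mask_nonwear

    @property
    def usable(self) -> np.ndarray:
        """Epochs entering metric denominators: worn, or nonwear recovered
        by imputation, and carrying a counts value."""
        has_counts = self.data["counts15"].notna().values
        return (~self.mask_nonwear | self.mask_imputed) & has_counts


# ---------------------------------------------------------------------------
# Epoch files


def _parse_header(lines: list[str], path: os.PathLike,
                  magic: str = "stepmetrics-epoch v1") -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if not body:
            continue
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
        else:
            meta.setdefault("magic", body)
    if meta.get("magic") != magic:
        raise FormatError(f"{path}: missing '{magic}' header line")
    for key in ("subject_id", "epoch_seconds", "start"):
        if key not in meta:
            raise FormatError(f"{path}: header missing '{key}'")
    return meta


def read_epoch_file(path: str | os.PathLike,
                    dialect: str = "stepmetrics") -> EpochSeries:
    """Parse one subject's epoch CSV into an :class:`EpochSeries`.

    All masks come back False; grid gaps, off-grid timestamps and
    out-of-range channels raise rather than being silently repaired.
    """
    if dialect != "stepmetrics":
        raise FormatError(f"unknown epoch dialect {dialect!r}")
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    header = [ln for ln in lines if ln.startswith("#")]
    body = "\n".join(ln for ln in lines if not ln.startswith("#"))
    meta = _parse_header(header, path)
    if int(meta["epoch_seconds"]) != EPOCH_SECONDS:
        raise FormatError(
            f"{path}: epoch_seconds={meta['epoch_seconds']}, expected {EPOCH_SECONDS}"
        )
    try:
        frame = pd.read_csv(io.StringIO(body))
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"{path}: unparseable CSV body: {exc}") from exc
    missing = set(EPOCH_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    try:
        ts = pd.to_datetime(frame["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: bad timestamp: {exc}") from exc
    data = frame[EPOCH_COLUMNS[1:]].astype(float)
    data.index = pd.DatetimeIndex(ts.values, name="timestamp")
    if data["counts15"].isna().all():
        raise FormatError(f"{path}: counts15 entirely missing")
    declared_start = pd.Timestamp(meta["start"])
    if len(data) and data.index[0] != declared_start:
        raise FormatError(
            f"{path}: declared start {declared_start} != first timestamp {data.index[0]}"
        )
    try:
        series = EpochSeries.from_frame(str(meta["subject_id"]), data)
    except (GridError, SanityError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc
    return series


def write_epoch_file(series: EpochSeries, path: str | os.PathLike,
                     overwrite: bool = False) -> Path:
    """Write an epoch CSV readable by :func:`read_epoch_file` (its inverse).

    Acceleration channels are written with 6 decimals; the generator rounds
    its output to the same precision, so write→read round-trips exactly.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")
    data = series.data
    with open(path, "w", newline="") as fh:
        fh.write("# stepmetrics-epoch v1\n")
        fh.write(f"# subject_id: {series.subject_id}\n")
        fh.write(f"# epoch_seconds: {EPOCH_SECONDS}\n")
        fh.write(f"# start: {data.index[0].isoformat()}\n")
        fh.write(",".join(EPOCH_COLUMNS) + "\n")
        counts = data["counts15"].values
        steps = data["steps60"].values
        axes = data[AXIS_MEAN_COLUMNS + AXIS_SD_COLUMNS].values
        stamps = data.index
        for i in range(len(data)):
            c = "" if np.isnan(counts[i]) else str(int(round(counts[i])))
            s = "" if np.isnan(steps[i]) else str(int(round(steps[i])))
            ax = ",".join(f"{v:.6f}" for v in axes[i])
            fh.write(f"{stamps[i].isoformat()},{c},{s},{ax}\n")
    return path


MASK_COLUMNS = ["nonwear", "imputed", "sleep"]


def write_cleaned_epoch_file(series: EpochSeries, path: str | os.PathLike,
                             overwrite: bool = False) -> Path:
    """Serialize a preprocessed series including masks and imputed values.

    Floats are written with shortest round-trip precision, so reading the
    file back reproduces the in-memory series exactly (bit-for-bit); this
    is what makes staged and single-shot pipeline runs byte-identical.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")
    frame = series.data.copy()
    frame["nonwear"] = series.mask_nonwear.astype(int)
    frame["imputed"] = series.mask_imputed.astype(int)
    frame["sleep"] = series.mask_sleep.astype(int)
    with open(path, "w", newline="") as fh:
        fh.write("# stepmetrics-cleaned v1\n")
        fh.write(f"# subject_id: {series.subject_id}\n")
        fh.write(f"# epoch_seconds: {EPOCH_SECONDS}\n")
        fh.write(f"# start: {frame.index[0].isoformat()}\n")
        frame.index.name = "timestamp"
        frame.to_csv(fh, date_format="%Y-%m-%dT%H:%M:%S")
    return path


def read_cleaned_epoch_file(path: str | os.PathLike) -> EpochSeries:
    """Inverse of :func:`write_cleaned_epoch_file`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header = [ln for ln in lines if ln.startswith("#")]
    body = "\n".join(ln for ln in lines if not ln.startswith("#"))
    meta = _parse_header(header, path, magic="stepmetrics-cleaned v1")
    frame = pd.read_csv(io.StringIO(body))
    ts = pd.to_datetime(frame["timestamp"], format="ISO8601")
    masks = {c: frame[c].to_numpy(int).astype(bool) for c in MASK_COLUMNS}
    data = frame[EPOCH_COLUMNS[1:]].astype(float)
    data.index = pd.DatetimeIndex(ts.values, name="timestamp")
    series = EpochSeries(
        subject_id=str(meta["subject_id"]),
        data=data,
        mask_nonwear=masks["nonwear"],
        mask_imputed=masks["imputed"],
        mask_sleep=masks["sleep"],
    )
    series.validate()
    return series


# ---------------------------------------------------------------------------
# Diaries


def read_diary(path: str | os.PathLike) -> list[DiaryEntry]:
    """Read a sleep diary CSV; one entry per subject-night."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "date", "bed_time", "wake_time"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: diary missing columns {sorted(missing)}")
    if len(frame) == 0:
        logger.warning("diary %s is empty", path)
        return []
    entries = []
    for row in frame.itertuples(index=False):
        try:
            date = dt.date.fromisoformat(str(row.date))
            bed = _parse_clock(str(row.bed_time))
            wake = _parse_clock(str(row.wake_time))
        except ValueError as exc:
            raise FormatError(f"{path}: unparseable diary row {row}: {exc}") from exc
        entries.append(DiaryEntry(str(row.subject_id), date, bed, wake))
    return entries


def _parse_clock(text: str) -> dt.time:
    parts = text.strip().split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"bad clock time {text!r}")
    h, m = int(parts[0]), int(parts[1])
    s = int(parts[2]) if len(parts) == 3 else 0
    return dt.time(h, m, s)


def write_diary(entries: list[DiaryEntry], path: str | os.PathLike,
                overwrite: bool = False) -> Path:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")
    with open(path, "w", newline="") as fh:
        fh.write("subject_id,date,bed_time,wake_time\n")
        for e in entries:
            fh.write(
                f"{e.subject_id},{e.date.isoformat()},"
                f"{e.bed_time.strftime('%H:%M')},{e.wake_time.strftime('%H:%M')}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Derived tables


def write_tables(cohort: pd.DataFrame, daydata: pd.DataFrame,
                 outdir: str | os.PathLike, overwrite: bool = False) -> dict[str, Path]:
    """Serialize the subject-level and day-level tables as tidy CSVs.

    Reals are written to 12 significant digits, integers bit-exactly, so a
    read-back reproduces the values to that precision.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "subject_summary": outdir / "subject_summary.csv",
        "day_metrics": outdir / "day_metrics.csv",
    }
    for p in paths.values():
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True")
    cohort.to_csv(paths["subject_summary"], index=False, float_format="%.12g")
    daydata.to_csv(paths["day_metrics"], index=False, float_format="%.12g")
    return paths


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a table written by :func:`write_tables`."""
    frame = pd.read_csv(path, dtype={"subject_id": str})
    if "date" in frame.columns:
        frame["date"] = pd.to_datetime(frame["date"]).dt.date
    return frame
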