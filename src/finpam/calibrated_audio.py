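"""Calibrated audio access: counts-to-SPL conversion, recording schedules,
duty cycles and analysis subsampling.

Autonomous recorders store 16-bit integer "counts". With a hydrophone
sensitivity ``S`` (dB re 1 V/µPa), an analogue gain ``G`` (dB) and a digital
gain ``M`` (dB), a count magnitude ``c`` maps to sound pressure level

    SPL [dB re 1 µPa] = 20 log10(c) - S - G - M

so the whole chain collapses into a single additive constant ``-S-G-M``.
Applying the constant per sample yields a calibrated pressure series in µPa,
which commutes with any subsequent linear spectral estimate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "CalibrationSpec",
    "RecordingSchedule",
    "SubsamplingScheme",
    "AudioSegment",
    "counts_to_spl",
    "spl_to_counts",
    "calibrate_counts",
    "enumerate_files",
    "apply_subsampling",
    "recorded_day_count",
    "read_wav",
    "write_wav",
    "wav_filename",
    "parse_wav_filename",
]


@dataclass(frozen=True)
class CalibrationSpec:
    """Recorder calibration constants.

    Parameters
    ----------
    sensitivity_db :
        Hydrophone sensitivity ``S`` in dB re 1 V/µPa (negative).
    gain_db :
        System amplifier gain ``G`` in dB.
    digital_gain_db :
        Digital (ADC) gain ``M`` in dB.

    The defaults are those of an AURAL-M2 with an HTI-68-MIN hydrophone
    (S = -164 dB, G = 22 dB, M = 84 dB), giving a combined constant of
    +58 dB.
    """

    sensitivity_db: float = -164.0
    gain_db: float = 22.0
    digital_gain_db: float = 84.0

    def __post_init__(self) -> None:
        for v in (self.sensitivity_db, self.gain_db, self.digital_gain_db):
            if not np.isfinite(v):
                raise ValueError("calibration constants must be finite")

    @property
    def constant_db(self) -> float:
        """Combined additive constant ``-S - G - M`` in dB."""
        return -(self.sensitivity_db + self.gain_db + self.digital_gain_db)

    @property
    def pressure_per_count(self) -> float:
        """Linear scale factor: µPa of pressure per saved count."""
        return 10.0 ** (self.constant_db / 20.0)


def counts_to_spl(c, calib: CalibrationSpec) -> np.ndarray | float:
    """Convert a positive count magnitude to SPL in dB re 1 µPa.

    ``SPL = 20 log10(c) - S - G - M``; strictly increasing in ``c``.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("count magnitude must be positive")
    out = 20.0 * np.log10(c) + calib.constant_db
    return float(out) if out.ndim == 0 else out


def spl_to_counts(spl, calib: CalibrationSpec) -> np.ndarray | float:
    """Inverse of :func:`counts_to_spl`."""
    spl = np.asarray(spl, dtype=float)
    out = 10.0 ** ((spl - calib.constant_db) / 20.0)
    return float(out) if out.ndim == 0 else out


def calibrate_counts(counts, calib: CalibrationSpec) -> np.ndarray:
    """Apply the calibration per sample, returning pressure in µPa."""
    return np.asarray(counts, dtype=float) * calib.pressure_per_count


@dataclass
class AudioSegment:
    """A calibrated slice of recording: pressure samples with a time base.

    ``pressure`` is in µPa; ``start`` is the UTC start time of the segment.
    """

    start: pd.Timestamp
    sample_rate: float
    pressure: np.ndarray

    @property
    def duration_s(self) -> float:
        return len(self.pressure) / self.sample_rate

    @classmethod
    def from_counts(cls, start, sample_rate, counts, calib: CalibrationSpec):
        return cls(pd.Timestamp(start), float(sample_rate),
                   calibrate_counts(counts, calib))


# ---------------------------------------------------------------------------
# Recording schedules and subsampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecordingSchedule:
    """Duty-cycled recording plan.

    ``duty = (record_minutes, period_minutes)``: the recorder stores one
    file of ``file_duration_s`` at the start of every ``period_minutes``
    window.  A 5 min / 60 min duty cycle records 1/12 of elapsed time.
    """

    start: pd.Timestamp
    end: pd.Timestamp
    file_duration_s: float
    duty: tuple[float, float] = (5.0, 60.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if self.end <= self.start:
            raise ValueError("schedule end must be after start")
        rec, per = self.duty
        if rec > per:
            raise ValueError("record minutes cannot exceed period minutes")

    @property
    def duty_fraction(self) -> float:
        return self.duty[0] / self.duty[1]


def enumerate_files(schedule: RecordingSchedule) -> pd.DataFrame:
    """List every recorded file of a schedule.

    Returns a DataFrame with columns ``file_id``, ``start_utc`` and
    ``duration_s``, one row per recorded interval, non-overlapping, with a
    gap of ``period - record`` minutes between consecutive intervals.
    """
    period = timedelta(minutes=schedule.duty[1])
    starts = []
    t = schedule.start
    while t < schedule.end:
        starts.append(t)
        t = t + period
    df = pd.DataFrame({
        "file_id": [wav_filename(s, with_extension=False) for s in starts],
        "start_utc": starts,
        "duration_s": schedule.file_duration_s,
    })
    return df


@dataclass(frozen=True)
class SubsamplingScheme:
    """Deterministic analysis subsampling: every ``file_stride``-th file of
    every ``day_stride``-th day, anchored at the first file / first day."""

    file_stride: int = 1
    day_stride: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if self.file_stride < 1 or self.day_stride < 1:
            raise ValueError("strides must be positive integers")


# Table-style presets used by the different metrics.
SCHEME_LTS_FIN = SubsamplingScheme(2, 1, "every second file on all days")
SCHEME_DAO = SubsamplingScheme(1, 2, "all files on every second day")
SCHEME_CAB = SubsamplingScheme(7, 6, "every seventh file of every sixth day")


def apply_subsampling(files: pd.DataFrame, scheme: SubsamplingScheme) -> pd.DataFrame:
    """Select files per a stride scheme.

    ``files`` must carry a ``start_utc`` column in time order. Selection is
    deterministic and idempotent: days are enumerated from the first day in
    steps of ``day_stride``; within each selected day files are taken from
    the first in steps of ``file_stride``.  The selection is a projection —
    the output frame records the applied scheme (``DataFrame.attrs``) and
    re-applying the same scheme returns it unchanged.
    """
    key = (scheme.file_stride, scheme.day_stride)
    if files.attrs.get("subsampling_applied") == key:
        return files
    if files.empty:
        return files
    start = pd.to_datetime(files["start_utc"])
    if not start.is_monotonic_increasing:
        raise ValueError("files must be time-ordered")
    days = start.dt.normalize()
    unique_days = days.drop_duplicates().reset_index(drop=True)
    selected_days = set(unique_days[:: scheme.day_stride])
    keep = np.zeros(len(files), dtype=bool)
    for day in selected_days:
        idx = np.flatnonzero((days == day).to_numpy())
        keep[idx[:: scheme.file_stride]] = True
    out = files.loc[keep]
    out.attrs["subsampling_applied"] = key
    return out


def recorded_day_count(start_date, end_date) -> int:
    """Calendar-day span, end-exclusive and leap-aware.

    E.g. a deployment from 2013-01-16 to 2016-02-10 covers 1120 days.
    """
    start = pd.Timestamp(start_date).normalize()
    end = pd.Timestamp(end_date).normalize()
    if end < start:
        raise ValueError("end date before start date")
    return int((end - start).days)


# ---------------------------------------------------------------------------
# WAV I/O (16-bit PCM RIFF) and file naming
# ---------------------------------------------------------------------------

_WAV_NAME_RE = re.compile(r"(\d{8})_(\d{6})")


def wav_filename(start_utc, with_extension: bool = True) -> str:
    """Canonical file name encoding the UTC start time: YYYYMMDD_HHMMSS."""
    stem = pd.Timestamp(start_utc).strftime("%Y%m%d_%H%M%S")
    return stem + (".wav" if with_extension else "")


def parse_wav_filename(name: str) -> pd.Timestamp:
    m = _WAV_NAME_RE.search(Path(name).name)
    if m is None:
        raise ValueError(f"file name {name!r} does not encode a start time")
    return pd.to_datetime(m.group(1) + m.group(2), format="%Y%m%d%H%M%S")


def read_wav(path) -> tuple[float, np.ndarray]:
    """Read a 16-bit PCM WAV file, returning (sample_rate, counts)."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    return float(rate), data.astype(np.int64)


def write_wav(path, sample_rate: float, counts) -> None:
    """Write integer counts as canonical 16-bit PCM RIFF."""
    arr = np.clip(np.asarray(counts), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(sample_rate), arr)


def load_segment(path, calib: CalibrationSpec,
                 start: pd.Timestamp | None = None) -> AudioSegment:
    """Read a WAV file into a calibrated :class:`AudioSegment`.

    The start time is parsed from the file name if not given.
    """
    if start is None:
        start = parse_wav_filename(str(path))
    rate, counts = read_wav(path)
    return AudioSegment.from_counts(start, rate, counts, calib)


def write_manifest(files: pd.DataFrame, path) -> None:
    files.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["start_utc"] = pd.to_datetime(df["start_utc"])
    return df
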