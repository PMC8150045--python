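"""Welch spectral densities, quietest-window selection and long-term
spectrograms (LTS).

An LTS condenses months of duty-cycled recordings into one PSD per analysed
file.  To suppress mooring-induced noise (flow noise, shackle rattle), the
PSD of each file is computed on the *quietest* 10 s of that file — the
window minimising broadband mean-square pressure — rather than on the whole
file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .calibrated_audio import AudioSegment

logger = logging.getLogger(__name__)

__all__ = [
    "PsdConfig",
    "PsdRecord",
    "LongTermSpectrogram",
    "welch_psd",
    "fft_resolution",
    "quietest_window",
    "build_lts",
    "PSD_LTS_FIN",
    "PSD_DAO",
    "PSD_CAB",
]

_DB_FLOOR = 1e-30  # linear densities at/below this map to -300 dB


@dataclass(frozen=True)
class PsdConfig:
    """Welch estimator settings.

    ``nfft`` is both the segment (window) length in samples and the FFT
    size; frequency resolution is ``sample_rate / nfft``.
    """

    nfft: int
    window_shape: str = "hann"
    overlap_fraction: float = 0.5
    sample_rate: float = 32768.0

    def __post_init__(self) -> None:
        if self.nfft < 2:
            raise ValueError("nfft must be at least 2")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap fraction must be in [0, 1)")
        if self.window_shape not in ("hann", "hamming"):
            raise ValueError("window_shape must be 'hann' or 'hamming'")


# Analysis presets: the LTS/FIN chain uses a 2^14-point Hamming window at
# 32768 Hz (2.0 Hz bins), daily-occurrence screening a 20000-point Hanning
# window (1.6384 Hz bins), and call counting a 334-point Hanning window with
# 90% overlap on 500 Hz decimated audio.
PSD_LTS_FIN = PsdConfig(nfft=2 ** 14, window_shape="hamming",
                        overlap_fraction=0.5, sample_rate=32768.0)
PSD_DAO = PsdConfig(nfft=20000, window_shape="hann",
                    overlap_fraction=0.5, sample_rate=32768.0)
PSD_CAB = PsdConfig(nfft=334, window_shape="hann",
                    overlap_fraction=0.9, sample_rate=500.0)


def fft_resolution(cfg: PsdConfig) -> float:
    """Frequency bin width in Hz: ``sample_rate / nfft``."""
    return cfg.sample_rate / cfg.nfft


@dataclass
class PsdRecord:
    """A single one-sided power spectral density.

    ``density_db`` is in dB re 1 µPa²/Hz on ``frequencies`` (Hz, strictly
    increasing from 0 to Nyquist).  Use :attr:`density_linear` for the
    linear-unit view.
    """

    timestamp: pd.Timestamp | None
    frequencies: np.ndarray
    density_db: np.ndarray

    @property
    def density_linear(self) -> np.ndarray:
        return 10.0 ** (self.density_db / 10.0)

    @classmethod
    def from_linear(cls, timestamp, frequencies, density):
        density = np.asarray(density, dtype=float)
        db = 10.0 * np.log10(np.maximum(density, _DB_FLOOR))
        return cls(timestamp, np.asarray(frequencies, float), db)


def welch_psd(segment: AudioSegment | np.ndarray, cfg: PsdConfig,
              timestamp: pd.Timestamp | None = None) -> PsdRecord:
    """Average-periodogram (Welch) PSD of a calibrated pressure series.

    Density scaling: a unit-variance white input yields a flat density of
    ``1 / Nyquist`` in linear units.  Mean removal only; no further
    detrending.

    Raises ``ValueError`` if the segment is shorter than one window.
    """
    if isinstance(segment, AudioSegment):
        x = segment.pressure
        fs = segment.sample_rate
        timestamp = timestamp or segment.start
    else:
        x = np.asarray(segment, dtype=float)
        fs = cfg.sample_rate
    if len(x) < cfg.nfft:
        raise ValueError(
            f"segment of {len(x)} samples is shorter than one "
            f"{cfg.nfft}-sample window")
    freqs, density = signal.welch(
        x, fs=fs, window=cfg.window_shape, nperseg=cfg.nfft,
        noverlap=int(cfg.overlap_fraction * cfg.nfft), nfft=cfg.nfft,
        detrend="constant", scaling="density", return_onesided=True)
    return PsdRecord.from_linear(timestamp, freqs, density)


def quietest_window(x: np.ndarray | AudioSegment, sample_rate: float | None = None,
                    window_seconds: float = 10.0,
                    hop_seconds: float = 1.0) -> tuple[float, np.ndarray]:
    """Locate the quietest window of a file.

    Quietness is broadband mean-square pressure (after removing the file
    mean); the earliest window wins ties.  Returns ``(offset_seconds,
    window_samples)``.
    """
    if isinstance(x, AudioSegment):
        sample_rate = x.sample_rate
        x = x.pressure
    if sample_rate is None:
        raise ValueError("sample_rate required for raw arrays")
    x = np.asarray(x, dtype=float)
    n_win = int(round(window_seconds * sample_rate))
    hop = max(1, int(round(hop_seconds * sample_rate)))
    if len(x) < n_win:
        raise ValueError("file shorter than the analysis window")
    xd = x - x.mean()
    csum = np.concatenate(([0.0], np.cumsum(xd * xd)))
    offsets = np.arange(0, len(x) - n_win + 1, hop)
    energy = csum[offsets + n_win] - csum[offsets]
    best = offsets[int(np.argmin(energy))]  # argmin takes the first minimum
    return best / sample_rate, x[best:best + n_win]


@dataclass
class LongTermSpectrogram:
    """One PSD column per analysed file, in time order.

    ``density_db`` has shape (n_frequencies, n_times); missing files are
    NaN columns, never interpolated.
    """

    times: pd.DatetimeIndex
    frequencies: np.ndarray
    density_db: np.ndarray

    def __post_init__(self) -> None:
        if self.density_db.shape != (len(self.frequencies), len(self.times)):
            raise ValueError("density matrix does not match axis vectors")

    @property
    def n_columns(self) -> int:
        return len(self.times)

    def column(self, i: int) -> PsdRecord:
        return PsdRecord(self.times[i], self.frequencies, self.density_db[:, i])

    def iter_records(self) -> Iterable[PsdRecord]:
        for i in range(self.n_columns):
            yield self.column(i)

    def band_mean_db(self, lo: float, hi: float) -> np.ndarray:
        """Time series of mean linear density over [lo, hi], in dB."""
        sel = (self.frequencies >= lo) & (self.frequencies <= hi)
        if not sel.any():
            raise ValueError(f"no frequency bins inside [{lo}, {hi}] Hz")
        lin = 10.0 ** (self.density_db[sel] / 10.0)
        return 10.0 * np.log10(np.maximum(lin.mean(axis=0), _DB_FLOOR))

    def to_xarray(self):
        import xarray as xr
        return xr.DataArray(
            self.density_db,
            coords={"frequency": self.frequencies, "time": self.times},
            dims=("frequency", "time"),
            name="psd_db",
            attrs={"units": "dB re 1 uPa^2/Hz"},
        )

    def to_netcdf(self, path) -> None:
        self.to_xarray().to_dataset().to_netcdf(path, engine="scipy")


def build_lts(segments: Iterable[AudioSegment | None], cfg: PsdConfig,
              window_seconds: float = 10.0, hop_seconds: float = 1.0,
              timestamps: Sequence[pd.Timestamp] | None = None,
              ) -> LongTermSpectrogram:
    """Assemble an LTS from an iterable of calibrated segments.

    Each segment contributes the Welch PSD of its quietest
    ``window_seconds``; ``None`` entries (unreadable/missing files) become
    NaN columns.  When ``timestamps`` is given it labels the columns
    (required if any entry is ``None``).
    """
    times: list[pd.Timestamp] = []
    columns: list[np.ndarray | None] = []
    freqs: np.ndarray | None = None
    for i, seg in enumerate(segments):
        if seg is None:
            if timestamps is None:
                raise ValueError("timestamps required when segments are missing")
            times.append(pd.Timestamp(timestamps[i]))
            columns.append(None)
            continue
        try:
            _, quiet = quietest_window(seg, window_seconds=window_seconds,
                                       hop_seconds=hop_seconds)
            rec = welch_psd(quiet, cfg, timestamp=seg.start)
        except ValueError as exc:
            logger.warning("segment at %s skipped: %s", seg.start, exc)
            times.append(seg.start)
            columns.append(None)
            continue
        if freqs is None:
            freqs = rec.frequencies
        times.append(seg.start)
        columns.append(rec.density_db)
    if freqs is None:
        raise ValueError("no readable segments")
    mat = np.full((len(freqs), len(columns)), np.nan)
    for j, col in enumerate(columns):
        if col is not None:
            mat[:, j] = col
    return LongTermSpectrogram(pd.DatetimeIndex(times), freqs, mat)
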