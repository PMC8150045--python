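"""FIN band-SNR acoustic indices.

A FIN index expresses the acoustic power in a whale-call band as a
signal-to-noise ratio against two bracing noise bands:

    FIN [dB] = 10 log10( S_sig / (0.5 (S_lo + S_hi)) )

with ``S`` the mean linear power spectral density over each band.  Because
any calibration error offsets all three bands equally, the ratio is immune
to a constant dB miscalibration of the recorder — which is what makes FIN
values comparable across instruments.

Seasonal structure is brought out with a 14-day centred running mean, the
typical time scale of polar environmental change (ice, insolation, biomass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral_analysis import LongTermSpectrogram, PsdRecord, _DB_FLOOR

__all__ = [
    "BandSet",
    "FinSeries",
    "BAND_PRESETS",
    "band_density",
    "fin_snr",
    "fin_series",
    "running_mean",
    "count_ratio_to_db",
]


@dataclass(frozen=True)
class BandSet:
    """A call band bracketed by two noise bands (all [lo, hi] in Hz)."""

    signal: tuple[float, float]
    noise_low: tuple[float, float]
    noise_high: tuple[float, float]
    label: str = ""

    def __post_init__(self) -> None:
        for band in (self.signal, self.noise_low, self.noise_high):
            if band[0] > band[1]:
                raise ValueError(f"band {band} has lo > hi")
        if not (self.noise_low[1] <= self.signal[0]
                and self.signal[1] <= self.noise_high[0]):
            raise ValueError("bands must be ordered noise_low <= signal <= noise_high")


#: Band conventions for FIN indices used across the literature.  Key rows:
#: ``fin21`` / ``fin86`` are the Antarctic 20-22 / 86-88 Hz conventions used
#: throughout this package.
BAND_PRESETS: dict[str, BandSet] = {
    "fin21": BandSet((20, 22), (8, 10), (30, 32), "Antarctic 20-22 Hz"),
    "fin86": BandSet((86, 88), (80, 82), (92, 94), "Antarctic 86-88 Hz"),
    "fin21_ei_scripps": BandSet((21, 22), (9, 10), (33, 34),
                                "Antarctic 21-22 Hz (EI-SCRIPPS)"),
    "fin89_wap": BandSet((89, 90), (80, 81), (98, 99), "Antarctic 89-90 Hz (WAP)"),
    "fin_juan_fernandez_low": BandSet((16, 22), (10, 11), (35, 36),
                                      "Juan Fernandez 16-22 Hz"),
    "fin_juan_fernandez_high": BandSet((84, 86), (70, 71), (100, 101),
                                       "Juan Fernandez 84-86 Hz"),
    "fin_arctic": BandSet((19, 28), (13, 17), (33, 37), "Arctic 19-28 Hz"),
    "fin_north_atlantic": BandSet((19, 22), (8, 13), (40, 45),
                                  "North Atlantic 19-22 Hz"),
    "fin_socal": BandSet((22, 23), (10, 11), (34, 35),
                         "Southern California Bight 22-23 Hz"),
}


def band_density(psd: PsdRecord, band: tuple[float, float]) -> float:
    """Mean linear density over bins whose centres lie in ``[lo, hi]``.

    The interval is closed on both ends: with 2-Hz bins, the 86-88 Hz band
    averages the 86 and 88 Hz bins.
    """
    lo, hi = band
    sel = (psd.frequencies >= lo) & (psd.frequencies <= hi)
    if not sel.any():
        raise ValueError(f"no PSD bins with centres inside [{lo}, {hi}] Hz")
    return float(psd.density_linear[sel].mean())


def fin_snr(psd: PsdRecord, bands: BandSet) -> float:
    """FIN index of one PSD, in dB.

    ``10 log10( S_signal / (0.5 (S_noise_low + S_noise_high)) )`` on linear
    densities.  A zero combined noise density yields ``+inf`` so that
    downstream smoothing can exclude the value.
    """
    s_sig = band_density(psd, bands.signal)
    s_noise = 0.5 * (band_density(psd, bands.noise_low)
                     + band_density(psd, bands.noise_high))
    if s_noise <= 10.0 * _DB_FLOOR:  # at/below the dB-floor sentinel
        return np.inf
    return 10.0 * np.log10(max(s_sig, _DB_FLOOR) / s_noise)


@dataclass
class FinSeries:
    """A FIN index time series with optional smoothing."""

    timestamps: pd.DatetimeIndex
    snr_db: np.ndarray
    band_set: BandSet
    smoothing_window_days: float | None = None
    snr_db_smoothed: np.ndarray | None = None

    def smooth(self, window_days: float = 14.0) -> "FinSeries":
        self.smoothing_window_days = window_days
        self.snr_db_smoothed = running_mean(self.timestamps, self.snr_db,
                                            window_days)
        return self

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "timestamp_utc": self.timestamps,
            "snr_db_raw": self.snr_db,
            "snr_db_smoothed": (self.snr_db_smoothed
                                if self.snr_db_smoothed is not None else np.nan),
            "band_label": self.band_set.label,
        })
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def fin_series(lts: LongTermSpectrogram, bands: BandSet,
               smooth_days: float | None = 14.0) -> FinSeries:
    """FIN index per LTS column; NaN columns and infinite ratios propagate
    as missing values, ignored by the running mean."""
    vals = np.empty(lts.n_columns)
    for i in range(lts.n_columns):
        col = lts.density_db[:, i]
        if np.isnan(col).all():
            vals[i] = np.nan
            continue
        snr = fin_snr(lts.column(i), bands)
        vals[i] = snr if np.isfinite(snr) else np.nan
    series = FinSeries(lts.times, vals, bands)
    if smooth_days is not None:
        series.smooth(smooth_days)
    return series


def running_mean(timestamps, values, window_days: float = 14.0) -> np.ndarray:
    """Centred running mean over a time-based window.

    At each sample the mean is taken over samples in ``[t - w/2, t + w/2)``
    (so a 14-day window on a 2-hour grid holds 168 samples in the
    interior), truncated at the series edges; NaNs are ignored.
    """
    ts = pd.DatetimeIndex(timestamps)
    if not ts.is_monotonic_increasing:
        raise ValueError("timestamps must be sorted")
    values = np.asarray(values, dtype=float)
    t = ts.asi8.astype(np.float64)
    half = window_days * 86400e9 / 2.0
    finite = np.isfinite(values)
    v = np.where(finite, values, 0.0)
    cs_v = np.concatenate(([0.0], np.cumsum(v)))
    cs_n = np.concatenate(([0.0], np.cumsum(finite.astype(float))))
    left = np.searchsorted(t, t - half, side="left")
    right = np.searchsorted(t, t + half, side="left")
    counts = cs_n[right] - cs_n[left]
    sums = cs_v[right] - cs_v[left]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def count_ratio_to_db(n2: float, n1: float) -> float:
    """Level difference implied by a change in caller/call numbers:
    ``10 log10(n2 / n1)`` dB.  A tenfold increase in calls raises a band
    SNR by about 10 dB."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("call counts must be positive")
    return 10.0 * np.log10(n2 / n1)
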