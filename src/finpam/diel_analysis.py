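"""Diel analysis: solar altitude, light-regime classification and the
Kruskal-Wallis test on call abundance across light regimes.

Three light regimes partition every minute of the day: 'light' (sun
altitude > 0°), 'twilight' (0° down to -12°, i.e. through nautical
twilight) and 'dark' (below -12°).  Local time at the site is true solar
time for 56° W, a fixed UTC - 3 h 40 min with no daylight saving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LOCAL_UTC_OFFSET",
    "SITE_LAT",
    "SITE_LON",
    "DielTestResult",
    "sun_altitude",
    "classify_light",
    "kruskal_wallis",
    "local_time",
    "utc_from_local",
    "assign_light_periods",
]

#: Fixed local-time convention: UTC - 3 h 40 min (true solar time at 56° W).
LOCAL_UTC_OFFSET = pd.Timedelta(hours=-3, minutes=-40)

#: Recording-site coordinates (61°00.88' S, 55°58.53' W).
SITE_LAT = -(61 + 0.88 / 60)
SITE_LON = -(55 + 58.53 / 60)

TWILIGHT_UPPER_DEG = 0.0
TWILIGHT_LOWER_DEG = -12.0


def local_time(utc) -> pd.Timestamp | pd.DatetimeIndex:
    """Apply the fixed UTC - 3 h 40 min offset."""
    if isinstance(utc, (pd.DatetimeIndex, pd.Series)):
        return utc + LOCAL_UTC_OFFSET
    return pd.Timestamp(utc) + LOCAL_UTC_OFFSET


def utc_from_local(local) -> pd.Timestamp | pd.DatetimeIndex:
    if isinstance(local, (pd.DatetimeIndex, pd.Series)):
        return local - LOCAL_UTC_OFFSET
    return pd.Timestamp(local) - LOCAL_UTC_OFFSET


def sun_altitude(time_utc, lat_deg: float, lon_deg: float):
    """Geometric solar altitude in degrees (no refraction).

    Low-accuracy solar-position expansion (fractional-year Fourier series
    for declination and the equation of time), good to a few tenths of a
    degree — sufficient to split a day into light / twilight / dark.
    Longitude is positive east.
    """
    ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(time_utc, dtype="datetime64[ns]")))
    doy = ts.dayofyear.to_numpy().astype(float)
    frac_hour = (ts.hour + ts.minute / 60.0 + ts.second / 3600.0).to_numpy()
    gamma = 2.0 * np.pi / 365.0 * (doy - 1.0 + (frac_hour - 12.0) / 24.0)

    eqtime = 229.18 * (0.000075 + 0.001868 * np.cos(gamma)
                       - 0.032077 * np.sin(gamma)
                       - 0.014615 * np.cos(2 * gamma)
                       - 0.040849 * np.sin(2 * gamma))
    decl = (0.006918 - 0.399912 * np.cos(gamma) + 0.070257 * np.sin(gamma)
            - 0.006758 * np.cos(2 * gamma) + 0.000907 * np.sin(2 * gamma)
            - 0.002697 * np.cos(3 * gamma) + 0.00148 * np.sin(3 * gamma))

    tst = frac_hour * 60.0 + eqtime + 4.0 * lon_deg  # true solar time, minutes
    ha = np.deg2rad(tst / 4.0 - 180.0)  # hour angle
    lat = np.deg2rad(lat_deg)
    sin_alt = (np.sin(lat) * np.sin(decl)
               + np.cos(lat) * np.cos(decl) * np.cos(ha))
    alt = np.rad2deg(np.arcsin(np.clip(sin_alt, -1.0, 1.0)))
    if np.isscalar(time_utc) or isinstance(time_utc, (pd.Timestamp, str)):
        return float(alt[0])
    return alt


def classify_light(altitude_deg):
    """Map solar altitude to 'light' / 'twilight' / 'dark'.

    Boundary altitudes (exactly 0° or -12°) are assigned to twilight.
    """
    alt = np.asarray(altitude_deg, dtype=float)
    out = np.where(alt > TWILIGHT_UPPER_DEG, "light",
                   np.where(alt < TWILIGHT_LOWER_DEG, "dark", "twilight"))
    if out.ndim == 0:
        return str(out)
    return out


def assign_light_periods(times_utc, lat_deg: float = SITE_LAT,
                         lon_deg: float = SITE_LON):
    """Light regime for each timestamp (e.g. count-interval midpoints)."""
    return classify_light(sun_altitude(times_utc, lat_deg, lon_deg))


@dataclass
class DielTestResult:
    """Kruskal-Wallis comparison of call abundance across light regimes."""

    H: float
    df: int
    p: float
    group_sizes: tuple[int, ...]
    critical_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    def to_dict(self) -> dict:
        return {"H": self.H, "df": self.df, "p": self.p,
                "group_sizes": list(self.group_sizes),
                "critical_value": self.critical_value, "alpha": self.alpha}


def kruskal_wallis(groups, alpha: float = 0.05) -> DielTestResult:
    """Kruskal-Wallis H test on mid-ranks with tie correction.

    The p-value uses the chi-squared approximation with ``k - 1`` degrees
    of freedom; the chi-squared critical value at ``alpha`` is reported
    alongside.  By convention, identical constant groups (all observations
    equal, H undefined 0/0 under tie correction) return H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size == 0:
            raise ValueError("groups must be nonempty")
    df = len(groups) - 1
    crit = float(stats.chi2.ppf(1.0 - alpha, df))
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return DielTestResult(0.0, df, 1.0, tuple(len(g) for g in groups),
                              crit, alpha)
    h, p = stats.kruskal(*groups)
    return DielTestResult(float(h), df, float(p),
                          tuple(len(g) for g in groups), crit, alpha)


def diel_test(intervals: pd.DataFrame, lat_deg: float = SITE_LAT,
              lon_deg: float = SITE_LON, alpha: float = 0.05,
              count_column: str = "n_calls") -> DielTestResult:
    """Test call abundance against light regime.

    ``intervals`` needs ``start_utc``, ``duration_s`` and a count column;
    censored or excluded rows (boolean columns, if present) are dropped.
    Each usable interval contributes one observation, grouped by the light
    regime of its midpoint.
    """
    df = intervals.copy()
    for flag in ("censored", "excluded"):
        if flag in df.columns:
            df = df[~df[flag].astype(bool)]
    if df.empty:
        raise ValueError("no usable intervals")
    mid = pd.DatetimeIndex(pd.to_datetime(df["start_utc"])) \
        + pd.to_timedelta(df["duration_s"] / 2.0, unit="s")
    period = assign_light_periods(mid, lat_deg, lon_deg)
    groups = [df.loc[period == name, count_column].to_numpy(dtype=float)
              for name in ("light", "twilight", "dark")]
    groups = [g for g in groups if g.size > 0]
    return kruskal_wallis(groups, alpha=alpha)
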