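"""Solar geometry from the NOAA general solar position calculations.

Implements the low-precision ephemeris used by the NOAA solar calculator
(Meeus, *Astronomical Algorithms*, ch. 25): geometric solar elevation
without atmospheric refraction.  Agreement with the NOAA reference is a
few hundredths of a degree over 1990-2025, far inside the half-degree
the downstream day/night classification needs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _julian_day(ts_utc: pd.DatetimeIndex) -> np.ndarray:
    # Unix epoch 1970-01-01T00:00Z is JD 2440587.5
    return ts_utc.asi8 / 86400e9 + 2440587.5


def solar_elevation(lat, lon, timestamp_utc) -> np.ndarray | float:
    """Geometric solar elevation angle in degrees, in [-90, 90].

    Parameters
    ----------
    lat, lon : float or array
        WGS84 decimal degrees.
    timestamp_utc : datetime-like, str, or sequence
        Instant(s) of observation.  Naive timestamps are taken as UTC;
        timezone-aware ones are converted.
    """
    scalar = np.isscalar(lat) and np.isscalar(lon) and not isinstance(
        timestamp_utc, (list, tuple, np.ndarray, pd.Series, pd.DatetimeIndex))
    ts = pd.DatetimeIndex(pd.to_datetime(
        [timestamp_utc] if scalar else timestamp_utc, utc=True)).tz_convert("UTC")
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("latitude must be in [-90, 90], longitude in [-180, 180]")

    jd = _julian_day(ts)
    T = (jd - 2451545.0) / 36525.0  # Julian centuries since J2000

    L0 = np.mod(280.46646 + T * (36000.76983 + 0.0003032 * T), 360.0)
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    Mr = np.radians(M)
    C = (np.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
         + np.sin(2 * Mr) * (0.019993 - 0.000101 * T)
         + np.sin(3 * Mr) * 0.000289)
    true_long = L0 + C
    omega = np.radians(125.04 - 1934.136 * T)
    lam_app = np.radians(true_long - 0.00569 - 0.00478 * np.sin(omega))

    eps0 = (23.0 + (26.0 + (21.448 - T * (46.8150 + T * (0.00059 - T * 0.001813)))
                    / 60.0) / 60.0)
    eps = np.radians(eps0 + 0.00256 * np.cos(omega))

    decl = np.arcsin(np.sin(eps) * np.sin(lam_app))

    y = np.tan(eps / 2.0) ** 2
    L0r = np.radians(L0)
    eqtime = 4.0 * np.degrees(
        y * np.sin(2 * L0r) - 2 * e * np.sin(Mr)
        + 4 * e * y * np.sin(Mr) * np.cos(2 * L0r)
        - 0.5 * y * y * np.sin(4 * L0r) - 1.25 * e * e * np.sin(2 * Mr))

    minutes = (ts.hour * 60.0 + ts.minute + ts.second / 60.0
               + ts.microsecond / 6e7).to_numpy(dtype=float)
    tst = np.mod(minutes + eqtime + 4.0 * lon, 1440.0)
    ha = np.radians(tst / 4.0 - 180.0)

    latr = np.radians(lat)
    cos_zen = (np.sin(latr) * np.sin(decl)
               + np.cos(latr) * np.cos(decl) * np.cos(ha))
    elev = 90.0 - np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
    return float(elev[0]) if scalar else elev
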