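"""Activity classification: active vs resting (GPS clusters) and
nocturnal vs diurnal (solar elevation).

An observation is *nocturnal* when the sun is more than ``twilight_deg``
(default 6) degrees below the horizon at its time and place — i.e. beyond
civil twilight.  GPS fixes belonging to a sequential spatio-temporal
cluster are taken to represent resting and marked inactive; all remaining
GPS fixes, and all camera-trap or direct detections, count as active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geo import haversine_km
from ._solar import solar_elevation

__all__ = [
    "solar_elevation", "is_nocturnal_elevation", "classify_nocturnal",
    "detect_clusters", "nocturnal_proportion", "Cluster", "ClusterLabeling",
]

OBS_COLUMNS = ["site_id", "unit_id", "timestamp", "lon", "lat", "method"]


def is_nocturnal_elevation(elevation_deg, threshold_deg: float = -6.0):
    """True where the solar elevation is strictly below the threshold."""
    return np.asarray(elevation_deg) < threshold_deg


def classify_nocturnal(records: pd.DataFrame, threshold_deg: float = -6.0,
                       site_centroid: tuple[float, float] | None = None) -> pd.Series:
    """Flag each observation as nocturnal from solar elevation.

    Uses the record's own coordinates; rows with missing lon/lat fall back
    to ``site_centroid`` (lon, lat) when given.  The threshold is strict:
    an observation exactly at the threshold elevation is diurnal.
    """
    lon = records["lon"].to_numpy(dtype=float).copy()
    lat = records["lat"].to_numpy(dtype=float).copy()
    missing = ~(np.isfinite(lon) & np.isfinite(lat))
    if missing.any():
        if site_centroid is None:
            raise ValueError("records without coordinates and no site centroid")
        lon[missing], lat[missing] = site_centroid
    elev = solar_elevation(lat, lon, records["timestamp"])
    return pd.Series(is_nocturnal_elevation(elev, threshold_deg),
                     index=records.index, name="nocturnal")


@dataclass
class Cluster:
    cluster_id: int
    member_index: list = field(default_factory=list)
    lon: float = 0.0   # running centroid
    lat: float = 0.0
    first_time: pd.Timestamp | None = None
    last_time: pd.Timestamp | None = None

    @property
    def n(self) -> int:
        return len(self.member_index)


@dataclass
class ClusterLabeling:
    """Per-record cluster ids (0 = unclustered) plus per-cluster summaries."""

    labels: pd.Series
    clusters: pd.DataFrame  # cluster_id, lon, lat, first_time, last_time, n

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def detect_clusters(track: pd.DataFrame, radius_m: float = 100.0,
                    window_days: float = 2.0,
                    min_fixes: int = 3) -> ClusterLabeling:
    """Sequential single-pass clustering of one GPS unit's fixes.

    A candidate cluster opens at the first unassigned fix.  Each subsequent
    fix joins the open candidate if it lies within ``radius_m`` of the
    running centroid (recomputed after every addition) and within
    ``window_days`` of the candidate's last member; otherwise the candidate
    closes — kept as a cluster if it reached ``min_fixes`` members,
    dissolved back to active otherwise — and a new candidate opens at the
    current fix.  Fixes in kept clusters are inactive (resting); the rest
    are active.

    The track must contain a single ``unit_id`` with strictly increasing
    timestamps.
    """
    if track["unit_id"].nunique() > 1:
        raise ValueError("detect_clusters expects a single unit's track")
    ts = pd.to_datetime(track["timestamp"], utc=True)
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("track timestamps must be strictly increasing")
    lon = track["lon"].to_numpy(dtype=float)
    lat = track["lat"].to_numpy(dtype=float)
    window = pd.Timedelta(days=window_days)

    labels = np.zeros(len(track), dtype=int)
    kept: list[Cluster] = []
    open_c: Cluster | None = None
    next_id = 1

    def close(c: Cluster | None):
        nonlocal next_id
        if c is not None and c.n >= min_fixes:
            c.cluster_id = next_id
            next_id += 1
            kept.append(c)

    for i in range(len(track)):
        t = ts.iloc[i]
        if open_c is not None:
            within_window = (t - open_c.last_time) <= window
            dist_m = haversine_km(lon[i], lat[i], open_c.lon, open_c.lat) * 1000.0
            if within_window and dist_m <= radius_m:
                open_c.member_index.append(i)
                members = open_c.member_index
                open_c.lon = float(np.mean(lon[members]))
                open_c.lat = float(np.mean(lat[members]))
                open_c.last_time = t
                continue
            close(open_c)
        open_c = Cluster(0, [i], float(lon[i]), float(lat[i]), t, t)
    close(open_c)

    rows = []
    for c in kept:
        labels[c.member_index] = c.cluster_id
        rows.append({"cluster_id": c.cluster_id, "lon": c.lon, "lat": c.lat,
                     "first_time": c.first_time, "last_time": c.last_time,
                     "n": c.n})
    summary = pd.DataFrame(
        rows, columns=["cluster_id", "lon", "lat", "first_time", "last_time", "n"])
    return ClusterLabeling(pd.Series(labels, index=track.index, name="cluster_id"),
                           summary)


def label_activity(track: pd.DataFrame, **cluster_kwargs) -> pd.Series:
    """Active/inactive labels for a GPS track (inactive = clustered)."""
    labeling = detect_clusters(track, **cluster_kwargs)
    return pd.Series(np.where(labeling.labels.to_numpy() > 0, "inactive", "active"),
                     index=track.index, name="active")


def nocturnal_proportion(records: pd.DataFrame,
                         group: str | None = None) -> tuple[float, int]:
    """Proportion of active observations that are nocturnal, with its n.

    ``records`` must already be filtered to active observations and carry a
    boolean ``nocturnal`` column; if ``group`` is given, only rows whose
    ``category`` equals it are used.  Returns ``(P, n)`` for the RR
    variance formula.
    """
    sub = records if group is None else records[records["category"] == group]
    n = len(sub)
    if n == 0:
        raise ValueError(f"no active observations in group {group!r}")
    return float(sub["nocturnal"].sum() / n), n
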