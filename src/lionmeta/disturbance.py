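"""Spatial sample units and the low/high disturbance dichotomy.

Sites are partitioned into sample units (grid cells sized from mean daily
displacement, or native camera stations), each unit gets a disturbance
value, and units are split into low- and high-disturbance groups at the
1st/3rd quartiles — falling back to a median split when either quartile
group would hold fewer than ``min_group`` units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geo import LocalEqualArea, haversine_km

UNIT_COLUMNS = ["unit_id", "lon", "lat", "disturbance_value", "category"]


class DegenerateMetricError(ValueError):
    """All disturbance values identical; no split is possible."""


def mean_daily_displacement(track: pd.DataFrame) -> float | None:
    """Mean distance (km) between first fixes of consecutive calendar days.

    Returns None for tracks spanning a single day or with no consecutive
    day pairs — the caller should then fall back to a 1-km grid.
    """
    ts = pd.to_datetime(track["timestamp"], utc=True)
    df = track.assign(_date=ts.dt.normalize()).sort_values("timestamp")
    firsts = df.groupby("_date", sort=True).first()
    if len(firsts) < 2:
        return None
    dates = firsts.index
    dists = []
    for i in range(len(dates) - 1):
        if (dates[i + 1] - dates[i]) == pd.Timedelta(days=1):
            dists.append(haversine_km(firsts["lon"].iloc[i], firsts["lat"].iloc[i],
                                      firsts["lon"].iloc[i + 1],
                                      firsts["lat"].iloc[i + 1]))
    if not dists:
        return None
    return float(np.mean(dists))


@dataclass
class Grid:
    """Square grid in a local equal-area projection centred on the site."""

    proj: LocalEqualArea
    x0: float          # km, lower-left corner
    y0: float
    cell_side_km: float
    ncols: int
    nrows: int

    def cell_index(self, lon, lat):
        """Column/row of the cell containing each point (may be outside).

        Cells are half-open on their east/north edges, except that points
        on the grid's outer boundary are clipped into the last cell so the
        covering is closed.
        """
        x, y = self.proj.forward(lon, lat)
        tol = 1e-2  # cells; ~10 m at a 1-km cell, below any GPS error
        fx = (np.asarray(x) - self.x0) / self.cell_side_km
        fy = (np.asarray(y) - self.y0) / self.cell_side_km
        col = np.floor(fx).astype(int)
        row = np.floor(fy).astype(int)
        col = np.where((col == self.ncols) & (fx <= self.ncols + tol),
                       self.ncols - 1, col)
        row = np.where((row == self.nrows) & (fy <= self.nrows + tol),
                       self.nrows - 1, row)
        col = np.where((col == -1) & (fx >= -tol), 0, col)
        row = np.where((row == -1) & (fy >= -tol), 0, row)
        return col, row

    def unit_id_of(self, lon, lat):
        col, row = self.cell_index(lon, lat)
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        ids = np.where(inside,
                       np.char.add(np.char.add("cell_", row.astype(str)),
                                   np.char.add("_", col.astype(str))),
                       "")
        return pd.Series(ids)


def build_grid(site_extent: pd.DataFrame | np.ndarray,
               cell_side_km: float) -> tuple[pd.DataFrame, Grid]:
    """Tile the extent of a set of points with square cells.

    ``site_extent`` supplies lon/lat points (a DataFrame with lon/lat
    columns or an (n, 2) array) whose bounding box, in a local equal-area
    projection about their centroid, is covered by axis-aligned square
    cells of side ``cell_side_km``.  Returns the unit table (one row per
    cell, centroids back in lon/lat) and the Grid geometry.
    """
    if cell_side_km <= 0:
        raise ValueError("cell_side_km must be positive")
    if isinstance(site_extent, pd.DataFrame):
        lon = site_extent["lon"].to_numpy(dtype=float)
        lat = site_extent["lat"].to_numpy(dtype=float)
    else:
        arr = np.asarray(site_extent, dtype=float)
        lon, lat = arr[:, 0], arr[:, 1]
    if lon.size == 0:
        raise ValueError("empty site extent")
    proj = LocalEqualArea(float(np.mean(lon)), float(np.mean(lat)))
    x, y = proj.forward(lon, lat)
    x0, y0 = float(np.min(x)), float(np.min(y))
    span_x = max(float(np.max(x)) - x0, 0.0)
    span_y = max(float(np.max(y)) - y0, 0.0)
    # Spans within 1% of a cell of a whole count snap down to it (metres at
    # study scale, below GPS error); cell_index clips boundary points back
    # into the outermost cell with the same tolerance.
    ncols = max(1, int(np.ceil(span_x / cell_side_km - 1e-2)))
    nrows = max(1, int(np.ceil(span_y / cell_side_km - 1e-2)))
    grid = Grid(proj, x0, y0, cell_side_km, ncols, nrows)

    rows, cols = np.mgrid[0:nrows, 0:ncols]
    cx = x0 + (cols.ravel() + 0.5) * cell_side_km
    cy = y0 + (rows.ravel() + 0.5) * cell_side_km
    clon, clat = proj.inverse(cx, cy)
    units = pd.DataFrame({
        "unit_id": [f"cell_{r}_{c}" for r, c in zip(rows.ravel(), cols.ravel())],
        "lon": np.asarray(clon, dtype=float),
        "lat": np.asarray(clat, dtype=float),
    })
    return units, grid


def assign_categories(units: pd.DataFrame, direction: str = "higher_is_disturbed",
                      min_group: int = 60) -> pd.DataFrame:
    """Split units into low/high disturbance groups.

    Quartile mode: units at or below the 1st quartile of the
    disturbance-oriented metric are ``low``, at or above the 3rd quartile
    ``high``, the middle ``excluded``.  If either group would have fewer
    than ``min_group`` units, a median split is used instead (<= median is
    low, > median high, nothing excluded).  ``direction`` states whether
    larger raw values mean more disturbance (``higher_is_disturbed``) or
    less (``lower_is_disturbed``, e.g. distance to a village).  Quantiles
    use linear interpolation; the chosen mode is recorded in a ``mode``
    column.
    """
    if direction not in ("higher_is_disturbed", "lower_is_disturbed"):
        raise ValueError(f"unknown direction {direction!r}")
    values = units["disturbance_value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("disturbance values must be finite")
    if np.ptp(values) == 0:
        raise DegenerateMetricError("all disturbance values identical")
    oriented = values if direction == "higher_is_disturbed" else -values

    q1, q3 = np.quantile(oriented, [0.25, 0.75])  # type-7 linear interpolation
    low = oriented <= q1
    high = oriented >= q3
    if low.sum() >= min_group and high.sum() >= min_group:
        mode = "quartile"
        category = np.where(low, "low", np.where(high, "high", "excluded"))
    else:
        mode = "median"
        med = np.quantile(oriented, 0.5)
        category = np.where(oriented <= med, "low", "high")
    out = units.copy()
    out["category"] = category
    out["mode"] = mode
    return out


def summarize_groups(observations: pd.DataFrame,
                     units: pd.DataFrame) -> dict:
    """Per-group space-use and nocturnality summaries for effect sizes.

    Space use per unit is the count of active observations falling in that
    unit (every unit in a group contributes, including zero counts); the
    group mean, sample SD (n-1) and unit count feed Hedges' d.  Nocturnal
    and active observation counts are pooled over each group's units for
    the RR stage.  Observations must carry ``unit_id``, ``active`` and
    ``nocturnal``; units must carry categories.
    """
    cats = units.set_index("unit_id")["category"]
    active = observations[observations["active"] == "active"].copy()
    active["category"] = active["unit_id"].map(cats)

    out: dict = {}
    for g in ("low", "high"):
        unit_ids = cats.index[cats == g]
        counts = (active[active["category"] == g]
                  .groupby("unit_id").size()
                  .reindex(unit_ids, fill_value=0)
                  .astype(float))
        n_units = len(unit_ids)
        if n_units < 2:
            raise ValueError(
                f"group {g!r} has {n_units} unit(s); need >= 2 for SMD")
        grp_active = active[active["category"] == g]
        out[g] = {
            "space_use": counts,
            "mean": float(counts.mean()),
            "sd": float(counts.std(ddof=1)),
            "n_units": n_units,
            "n_active": int(len(grp_active)),
            "n_nocturnal": int(grp_active["nocturnal"].sum())
            if "nocturnal" in grp_active else 0,
        }
    return out
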