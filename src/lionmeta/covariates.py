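"""Site-level moderators from rasters over circular buffers.

Six moderators are extracted per site: mean cattle density (CAT_a), mean
human footprint (HFI_a), spatial CV of human footprint (HFI_sp), and three
vegetation-greenness (NDVI) metrics from a monthly stack — overall mean
(NDVI_a), mean within-month spatial CV (NDVI_sp), and the temporal CV of
monthly means (NDVI_tm).  The buffer is a circle around the site centroid
with area equal to the study area (or the dataset-wide minimum area in the
uniform variant).

Rasters are simple lon/lat-gridded arrays read/written as plain-text ESRI
ASCII grids (.asc); zonal membership is cell-centre-in-circle by great-
circle distance, with no partial-cell weighting.  All standard deviations
inside CV formulas use the population convention (divisor n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._geo import haversine_km

MODERATORS = ["CAT_a", "HFI_a", "HFI_sp", "NDVI_a", "NDVI_sp", "NDVI_tm"]


class CoverageError(ValueError):
    """Buffer does not intersect any valid raster cell."""


@dataclass
class Raster:
    """Single-band raster on a regular lon/lat grid.

    ``values[0, 0]`` is the north-west cell (row-major, top row first),
    matching the ASCII-grid layout.  ``nodata`` cells are excluded from
    zonal statistics.
    """

    values: np.ndarray          # 2-D float array
    xllcorner: float            # lon of west edge, degrees
    yllcorner: float            # lat of south edge, degrees
    cellsize: float             # degrees
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nrows, ncols = self.shape
        lon = self.xllcorner + (np.arange(ncols) + 0.5) * self.cellsize
        lat = self.yllcorner + (nrows - np.arange(nrows) - 0.5) * self.cellsize
        return np.meshgrid(lon, lat)

    def write_asc(self, path: str | Path):
        nrows, ncols = self.shape
        header = (f"ncols {ncols}\nnrows {nrows}\n"
                  f"xllcorner {self.xllcorner!r}\nyllcorner {self.yllcorner!r}\n"
                  f"cellsize {self.cellsize!r}\nNODATA_value {self.nodata!r}\n")
        body = "\n".join(" ".join(repr(float(v)) for v in row)
                         for row in self.values)
        Path(path).write_text(header + body + "\n")

    @classmethod
    def read_asc(cls, path: str | Path) -> "Raster":
        lines = Path(path).read_text().splitlines()
        hdr = {}
        i = 0
        while i < len(lines) and lines[i].split()[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"):
            key, val = lines[i].split()
            hdr[key.lower()] = float(val)
            i += 1
        values = np.loadtxt(lines[i:], dtype=float, ndmin=2)
        if values.shape != (int(hdr["nrows"]), int(hdr["ncols"])):
            raise ValueError(f"{path}: grid shape does not match header")
        return cls(values, hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"],
                   hdr.get("nodata_value", -9999.0))


@dataclass
class MonthlyRasterStack:
    """Dated monthly grids (e.g. NDVI) sharing one georeference."""

    months: list[tuple[int, int]]       # (year, month), strictly increasing
    rasters: list[Raster] = field(repr=False, default_factory=list)

    def __post_init__(self):
        if len(self.months) != len(self.rasters):
            raise ValueError("months and rasters must align")
        keys = [y * 12 + m for y, m in self.months]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError("month list must be strictly increasing")
        shapes = {r.shape for r in self.rasters}
        if len(shapes) > 1:
            raise ValueError("all months must share one grid shape")

    def __len__(self) -> int:
        return len(self.months)

    def subset(self, start: tuple[int, int], end: tuple[int, int]
               ) -> "MonthlyRasterStack":
        """Months with start <= (year, month) <= end, inclusive."""
        lo, hi = (start[0] * 12 + start[1]), (end[0] * 12 + end[1])
        keep = [i for i, (y, m) in enumerate(self.months) if lo <= y * 12 + m <= hi]
        if not keep:
            raise ValueError("no months in the requested window")
        return MonthlyRasterStack([self.months[i] for i in keep],
                                  [self.rasters[i] for i in keep])

    def write_dir(self, directory: str | Path):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for (y, m), r in zip(self.months, self.rasters):
            r.write_asc(directory / f"{y:04d}-{m:02d}.asc")

    @classmethod
    def read_dir(cls, directory: str | Path) -> "MonthlyRasterStack":
        files = sorted(Path(directory).glob("[0-9][0-9][0-9][0-9]-[0-9][0-9].asc"))
        if not files:
            raise FileNotFoundError(f"no YYYY-MM.asc files in {directory}")
        months = [(int(f.stem[:4]), int(f.stem[5:7])) for f in files]
        return cls(months, [Raster.read_asc(f) for f in files])


def buffer_radius(area_km2: float) -> float:
    """Radius (km) of the circle whose area equals the study area."""
    if not area_km2 > 0:
        raise ValueError("study area must be positive")
    return float(np.sqrt(area_km2 / np.pi))


def _buffer_values(raster: Raster, center: tuple[float, float],
                   radius_km: float) -> np.ndarray:
    lon0, lat0 = center
    glon, glat = raster.cell_centers()
    inside = haversine_km(glon, glat, lon0, lat0) <= radius_km
    vals = raster.values[inside]
    vals = vals[vals != raster.nodata]
    if vals.size == 0:
        raise CoverageError("buffer covers no valid raster cell")
    return vals


def zonal_mean_cv(raster: Raster, center: tuple[float, float],
                  radius_km: float) -> tuple[float, float]:
    """Mean and population CV of cells whose centres fall in the buffer."""
    vals = _buffer_values(raster, center, radius_km)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    if mean == 0.0:
        if sd == 0.0:
            return 0.0, 0.0
        raise ZeroDivisionError("zonal mean is zero; CV undefined")
    return mean, sd / mean


def ndvi_metrics(stack: MonthlyRasterStack, center: tuple[float, float],
                 radius_km: float) -> tuple[float, float, float]:
    """Mean, spatial-CV and temporal-CV summaries of a monthly NDVI stack.

    With per-month buffer mean mu_i and population SD sigma_i over the
    n months::

        NDVI_a  = mean_i(mu_i)
        NDVI_sp = mean_i(sigma_i / mu_i)
        NDVI_tm = popstd_i(mu_i) / NDVI_a
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 months")
    mus, sigmas = [], []
    for r in stack.rasters:
        vals = _buffer_values(r, center, radius_km)
        if vals.size < 2:
            raise CoverageError("buffer must cover at least 2 cells")
        mus.append(vals.mean())
        sigmas.append(vals.std(ddof=0))
    mu = np.array(mus)
    sigma = np.array(sigmas)
    if np.any(mu == 0):
        raise ZeroDivisionError("a monthly mean NDVI is zero; spatial CV undefined")
    ndvi_a = float(mu.mean())
    if ndvi_a == 0:
        raise ZeroDivisionError("overall mean NDVI is zero; temporal CV undefined")
    ndvi_sp = float(np.mean(sigma / mu))
    ndvi_tm = float(np.sqrt(np.mean((mu - ndvi_a) ** 2)) / ndvi_a)
    return ndvi_a, ndvi_sp, ndvi_tm


def select_hfi_year(median_study_date) -> int:
    """Choose the human-footprint epoch (2000 or 2019) nearer the study.

    Dates up to 2009-12-31 map to the 2000 layer; from 2010-01-01 on
    (including the exact midpoint boundary) to the 2019 layer.
    """
    date = pd.Timestamp(median_study_date)
    return 2019 if date >= pd.Timestamp("2010-01-01") else 2000


def scale_and_screen(covariates: pd.DataFrame, r_max: float = 0.6,
                     columns: list[str] | None = None
                     ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Z-score the moderator columns and flag collinear pairs.

    Columns are centred and scaled by the sample SD (n-1).  Pairs with
    |Pearson r| > ``r_max`` are returned as forbidden pairs that must not
    co-occur in a candidate model.
    """
    columns = columns or [c for c in MODERATORS if c in covariates.columns]
    if len(covariates) < 3:
        raise ValueError("need at least 3 sites to scale and screen")
    out = covariates.copy()
    for c in columns:
        sd = out[c].std(ddof=1)
        # guard against exactly-constant columns whose float std is ~1e-17
        if not sd > 1e-10 * max(1.0, abs(out[c].mean())):
            raise ValueError(f"column {c!r} has zero variance; cannot scale")
        out[c] = (out[c] - out[c].mean()) / sd
    corr = out[columns].corr()
    forbidden = [(a, b)
                 for i, a in enumerate(columns)
                 for b in columns[i + 1:]
                 if abs(corr.loc[a, b]) > r_max]
    return out, forbidden
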