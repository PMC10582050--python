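"""Readers, writers, configuration and the end-to-end pipeline driver.

All tables are CSV; rasters are plain-text ASCII grids (see
:mod:`lionmeta.covariates`); the pipeline configuration is YAML.  Every
result bundle carries a provenance record (package version, seed,
parameters, config hash) and is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import classify_nocturnal, label_activity, nocturnal_proportion
from .covariates import (MODERATORS, MonthlyRasterStack, Raster, buffer_radius,
                         ndvi_metrics, scale_and_screen, select_hfi_year,
                         zonal_mean_cv)
from .disturbance import (assign_categories, build_grid,
                          mean_daily_displacement, summarize_groups)
from .effects import hedges_d, log_response_ratio
from .meta import (MetaModel, aicc, fit_ml_meta, forest_table, heterogeneity,
                   model_search, qe_test)

OBS_REQUIRED = ["site_id", "unit_id", "timestamp", "lon", "lat", "method"]
METHODS = {"gps", "camera", "direct"}


class SchemaError(ValueError):
    pass


@dataclass
class ValidationReport:
    n_rows: int
    n_rejected: int
    rejected_rows: list = field(default_factory=list)  # (row, reason)

    @property
    def fraction_rejected(self) -> float:
        return self.n_rejected / self.n_rows if self.n_rows else 0.0


def read_observations(path: str | Path, site_utc_offset: float | None = None,
                      max_bad_fraction: float = 0.01
                      ) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate an observation CSV.

    Validates required columns, coordinate ranges, the method enum and
    timestamp parseability; timestamps are normalised to UTC.  Naive
    timestamps use ``site_utc_offset`` (hours) when configured, and are
    rejected otherwise.  Invalid rows are dropped and reported; more than
    ``max_bad_fraction`` invalid rows is an error.
    """
    df = pd.read_csv(path, dtype={"site_id": str, "unit_id": str})
    missing = [c for c in OBS_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    bad: list[tuple[int, str]] = []
    raw = df["timestamp"].astype(str).str.strip()
    has_offset = raw.str.contains(r"(?:Z|[+-]\d{2}:?\d{2})$", regex=True)
    utc = pd.Series(pd.NaT, index=df.index, dtype="datetime64[ns, UTC]")
    aware = pd.to_datetime(raw[has_offset], errors="coerce", utc=True)
    utc.loc[has_offset] = aware
    naive = pd.to_datetime(raw[~has_offset], errors="coerce")
    if site_utc_offset is not None:
        utc.loc[~has_offset] = (naive - pd.Timedelta(hours=site_utc_offset)
                                ).dt.tz_localize("UTC")
    else:
        for i in naive.index[naive.notna()]:
            bad.append((int(i), "timestamp lacks a UTC offset and no site "
                                "default offset is configured"))
    for i in df.index[utc.isna()]:
        if not any(j == int(i) for j, _ in bad):
            bad.append((int(i), "unparseable timestamp"))
    df = df.assign(timestamp=utc)

    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    for i in df.index[~((lon >= -180) & (lon <= 180) & (lat >= -90) & (lat <= 90))]:
        bad.append((int(i), f"coordinates out of range (lon={df.loc[i,'lon']}, "
                            f"lat={df.loc[i,'lat']})"))
    for i in df.index[~df["method"].isin(METHODS)]:
        bad.append((int(i), f"unknown method {df.loc[i,'method']!r}"))

    bad_idx = sorted({i for i, _ in bad})
    report = ValidationReport(n_rows=len(df), n_rejected=len(bad_idx),
                              rejected_rows=bad)
    if report.fraction_rejected > max_bad_fraction:
        raise SchemaError(
            f"{path}: {report.n_rejected}/{report.n_rows} rows invalid "
            f"(> {max_bad_fraction:.0%}); first: {bad[:3]}")
    clean = df.drop(index=bad_idx).reset_index(drop=True)
    clean["lon"] = pd.to_numeric(clean["lon"])
    clean["lat"] = pd.to_numeric(clean["lat"])
    return clean, report


def write_observations(df: pd.DataFrame, path: str | Path):
    out = df.copy()
    if pd.api.types.is_datetime64_any_dtype(out["timestamp"]):
        out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end pipeline.

    ``data_dir`` must hold ``sites.csv`` (site_id, lon, lat, area_km2,
    method, temporal_eligible, direction, utc_offset) and per-site
    ``<site_id>_observations.csv``; optionally ``<site_id>_units.csv``
    (unit_id, lon, lat, disturbance_value) — sites without a unit table
    get a grid built from mean daily displacement and a disturbance
    raster.  Covariates come from ``covariates.csv`` or are extracted
    from rasters (``cattle.asc``, ``hfi_2000.asc``, ``hfi_2019.asc``,
    ``ndvi/YYYY-MM.asc``).
    """

    data_dir: str
    out_dir: str = "results"
    radius_m: float = 100.0
    window_days: float = 2.0
    min_fixes: int = 3
    twilight_deg: float = -6.0
    direction: str = "higher_is_disturbed"
    min_group: int = 60
    cell_side_km: float | None = None       # override; default delta-bar
    buffer_variant: str = "site_specific"   # or "uniform_min"
    ndvi_window: str = "long_term"          # or "study_months"
    r_max: float = 0.6
    search: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self):
        if not Path(self.data_dir).is_dir():
            raise FileNotFoundError(f"data_dir {self.data_dir} does not exist")
        if not (Path(self.data_dir) / "sites.csv").exists():
            raise FileNotFoundError("sites.csv missing from data_dir")
        if self.min_fixes < 1 or self.radius_m <= 0 or self.window_days <= 0:
            raise ValueError("activity parameters out of range")
        if self.direction not in ("higher_is_disturbed", "lower_is_disturbed"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Per-site processing
# ---------------------------------------------------------------------------

def _site_units(site, obs: pd.DataFrame, data_dir: Path,
                cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unit table for a site, plus observations tagged with unit_id."""
    unit_path = data_dir / f"{site.site_id}_units.csv"
    if unit_path.exists():
        units = pd.read_csv(unit_path, dtype={"unit_id": str})
        return units, obs
    # Grid path: cell side from mean daily displacement (1 km fallback),
    # disturbance sampled from the HFI raster at cell centroids.
    side = cfg.cell_side_km
    if side is None:
        side = mean_daily_displacement(obs) or 1.0
    units, grid = build_grid(obs, side)
    obs = obs.assign(unit_id=grid.unit_id_of(obs["lon"], obs["lat"]).to_numpy())
    year = select_hfi_year(site.median_date if hasattr(site, "median_date")
                           else "2015-01-01")
    hfi_path = data_dir / f"hfi_{year}.asc"
    if not hfi_path.exists():
        raise FileNotFoundError(
            f"site {site.site_id}: no unit table and no {hfi_path.name} "
            "raster to derive disturbance values")
    hfi = Raster.read_asc(hfi_path)
    glon, glat = hfi.cell_centers()
    flat_lon, flat_lat = glon.ravel(), glat.ravel()
    vals = []
    for lo, la in zip(units["lon"], units["lat"]):
        j = np.argmin((flat_lon - lo) ** 2 + (flat_lat - la) ** 2)
        vals.append(hfi.values.ravel()[j])
    units["disturbance_value"] = vals
    # drop cells with no observations at all on both tails to keep groups
    # data-bearing?  No: all cells are legitimate zero-use sample units.
    return units, obs


def process_site(site, data_dir: Path, cfg: PipelineConfig) -> dict:
    """Observations -> activity flags -> dichotomy -> effect sizes."""
    obs, report = read_observations(
        data_dir / f"{site.site_id}_observations.csv",
        site_utc_offset=getattr(site, "utc_offset", None))
    obs = obs.sort_values(["unit_id", "timestamp"]).reset_index(drop=True)

    # activity: GPS fixes in sequential clusters are inactive
    if (obs["method"] == "gps").any():
        parts = []
        for _, track in obs.groupby("unit_id", sort=True):
            track = track.sort_values("timestamp")
            track = track.assign(active=label_activity(
                track, radius_m=cfg.radius_m, window_days=cfg.window_days,
                min_fixes=cfg.min_fixes))
            parts.append(track)
        obs = pd.concat(parts).sort_index()
    else:
        obs = obs.assign(active="active")

    obs["nocturnal"] = classify_nocturnal(
        obs, threshold_deg=cfg.twilight_deg,
        site_centroid=(site.lon, site.lat))

    units, obs = _site_units(site, obs, data_dir, cfg)
    direction = getattr(site, "direction", None) or cfg.direction
    units = assign_categories(units, direction=direction,
                              min_group=cfg.min_group)
    groups = summarize_groups(obs, units)

    out = {"site_id": site.site_id, "mode": units["mode"].iloc[0],
           "validation": report, "units": units, "observations": obs}
    d, var_d = hedges_d(groups["low"]["mean"], groups["low"]["sd"],
                        groups["low"]["n_units"],
                        groups["high"]["mean"], groups["high"]["sd"],
                        groups["high"]["n_units"])
    out["spatial"] = {"estimate": d, "variance": var_d,
                      "n_low": groups["low"]["n_units"],
                      "n_high": groups["high"]["n_units"]}
    if getattr(site, "temporal_eligible", True):
        active = obs[obs["active"] == "active"].copy()
        active["category"] = active["unit_id"].map(
            units.set_index("unit_id")["category"])
        p_low, n_low = nocturnal_proportion(active, "low")
        p_high, n_high = nocturnal_proportion(active, "high")
        rr, var_rr = log_response_ratio(p_low, n_low, p_high, n_high)
        out["temporal"] = {"estimate": rr, "variance": var_rr,
                           "n_low": n_low, "n_high": n_high,
                           "p_low": p_low, "p_high": p_high}
    return out


# ---------------------------------------------------------------------------
# Covariate extraction and the meta stage
# ---------------------------------------------------------------------------

def extract_site_covariates(sites: pd.DataFrame, data_dir: Path,
                            cfg: PipelineConfig) -> pd.DataFrame:
    """Six moderators per site from the rasters in ``data_dir``."""
    cattle = Raster.read_asc(data_dir / "cattle.asc")
    hfi = {y: Raster.read_asc(data_dir / f"hfi_{y}.asc")
           for y in (2000, 2019)
           if (data_dir / f"hfi_{y}.asc").exists()}
    stack = MonthlyRasterStack.read_dir(data_dir / "ndvi")
    min_area = float(sites["area_km2"].min())
    rows = []
    for site in sites.itertuples():
        area = min_area if cfg.buffer_variant == "uniform_min" else site.area_km2
        radius = buffer_radius(area)
        center = (site.lon, site.lat)
        cat_a, _ = zonal_mean_cv(cattle, center, radius)
        year = select_hfi_year(site.median_date)
        hfi_r = hfi.get(year) or next(iter(hfi.values()))
        hfi_a, hfi_sp = zonal_mean_cv(hfi_r, center, radius)
        site_stack = stack
        if cfg.ndvi_window == "study_months":
            start = pd.Timestamp(site.study_start)
            end = pd.Timestamp(site.study_end)
            site_stack = stack.subset((start.year, start.month),
                                      (end.year, end.month))
        ndvi_a, ndvi_sp, ndvi_tm = ndvi_metrics(site_stack, center, radius)
        rows.append({"site_id": site.site_id, "CAT_a": cat_a, "HFI_a": hfi_a,
                     "HFI_sp": hfi_sp, "NDVI_a": ndvi_a, "NDVI_sp": ndvi_sp,
                     "NDVI_tm": ndvi_tm})
    return pd.DataFrame(rows)


def fit_meta_stage(effects: pd.DataFrame, covariates: pd.DataFrame,
                   response: str, r_max: float = 0.6,
                   search: bool = True) -> dict:
    """Join effects to scaled covariates and fit the meta-regression."""
    merged = effects.merge(covariates, on="site_id", how="inner")
    mods = [c for c in MODERATORS if c in merged.columns]
    scaled, forbidden = scale_and_screen(merged, r_max=r_max, columns=mods)
    y = merged["estimate"].to_numpy()
    v = merged["variance"].to_numpy()
    overall = fit_ml_meta(y, v, response=response)
    result = {
        "response": response,
        "k": int(len(merged)),
        "overall": overall,
        "heterogeneity": heterogeneity(overall),
        "qe": qe_test(overall),
        "forbidden_pairs": forbidden,
        "forest": forest_table(overall, merged["site_id"]),
    }
    if search:
        table = model_search(y, v, scaled, moderators=mods,
                             forbidden_pairs=forbidden, response=response)
        result["search"] = table
        result["best"] = table["model"].iloc[0]
        result["best_heterogeneity"] = heterogeneity(table["model"].iloc[0])
        result["best_qe"] = qe_test(table["model"].iloc[0])
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Chain all stages: observations -> effects -> covariates -> models.

    Returns the result bundle and writes CSV/JSON outputs (effect sizes,
    scaled covariates, AICc tables, forest-plot data, provenance) to
    ``config.out_dir``.
    """
    config.validate()
    data_dir = Path(config.data_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sites = pd.read_csv(data_dir / "sites.csv", dtype={"site_id": str})

    effect_rows, site_results = [], {}
    for site in sites.itertuples():
        try:
            res = process_site(site, data_dir, config)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage 'site-processing' failed at site "
                f"{site.site_id}: {exc}") from exc
        site_results[site.site_id] = res
        for response in ("spatial", "temporal"):
            if response in res:
                effect_rows.append({"site_id": site.site_id,
                                    "response": response, **res[response]})
    effects = pd.DataFrame(effect_rows)

    if (data_dir / "covariates.csv").exists():
        covariates = pd.read_csv(data_dir / "covariates.csv",
                                 dtype={"site_id": str})
    else:
        covariates = extract_site_covariates(sites, data_dir, config)

    models = {}
    for response in ("spatial", "temporal"):
        sub = effects[effects["response"] == response]
        if len(sub) >= 3:
            models[response] = fit_meta_stage(
                sub[["site_id", "estimate", "variance"]], covariates,
                response, r_max=config.r_max, search=config.search)

    bundle = {"config": config, "effects": effects, "covariates": covariates,
              "models": models, "sites": site_results,
              "provenance": {"package": "lionmeta", "version": __version__,
                             "seed": config.seed,
                             "config_hash": config.content_hash(),
                             "parameters": asdict(config)}}
    _write_bundle(bundle, out_dir)
    return bundle


def _model_json(result: dict) -> dict:
    def coef(m: MetaModel):
        return m.coefficients.reset_index().to_dict(orient="records")

    def safe_aicc(m: MetaModel):
        try:
            return aicc(m)
        except Exception:
            return None     # undefined for k <= p_fixed + 2

    out = {"response": result["response"], "k": result["k"],
           "overall": {"coefficients": coef(result["overall"]),
                       "tau2": result["overall"].tau2_hat,
                       "logLik": result["overall"].logLik,
                       "AICc": safe_aicc(result["overall"]),
                       "heterogeneity": {
                           k: v for k, v in result["heterogeneity"].items()},
                       "QE": dict(zip(("stat", "df", "p"), result["qe"]))}}
    if "best" in result:
        out["best"] = {"moderators": result["best"].moderators,
                       "coefficients": coef(result["best"]),
                       "tau2": result["best"].tau2_hat,
                       "AICc": safe_aicc(result["best"]),
                       "QE": dict(zip(("stat", "df", "p"), result["best_qe"]))}
    return out


def _write_bundle(bundle: dict, out_dir: Path):
    h = bundle["provenance"]["config_hash"]
    bundle["effects"].to_csv(out_dir / "effect_sizes.csv", index=False)
    bundle["covariates"].to_csv(out_dir / "covariates.csv", index=False)
    for response, result in bundle["models"].items():
        if "search" in result:
            result["search"].drop(columns="model").to_csv(
                out_dir / f"aicc_{response}.csv", index=False)
        result["forest"].to_csv(out_dir / f"forest_{response}.csv", index=False)
        (out_dir / f"model_{response}.json").write_text(
            json.dumps({"config_hash": h, **_model_json(result)}, indent=2,
                       default=float))
    (out_dir / "provenance.json").write_text(
        json.dumps(bundle["provenance"], indent=2, default=str))


# ---------------------------------------------------------------------------
# Synthetic study writer (pairs with run_pipeline)
# ---------------------------------------------------------------------------

def write_synthetic_study(directory: str | Path, n_sites: int = 10,
                          p_low: float = 0.40, p_high: float = 0.50,
                          target_d: float = -0.3, n_units: int = 80,
                          seed: int = 0) -> dict:
    """Write a complete synthetic study to disk for the pipeline.

    Every site gets the same planted nocturnality pair and d target, so
    the planted RR is ``ln(p_low / p_high)`` at each site.  Also writes a
    covariate table with independent moderators.  Returns the truth.
    """
    from .synth import SiteParams, simulate_site_observations

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    site_rows, cov_rows = [], []
    for i in range(n_sites):
        sid = f"site_{i:03d}"
        params = SiteParams(site_id=sid, n_units=n_units, target_d=target_d,
                            p_low=p_low, p_high=p_high,
                            lon=float(rng.uniform(10, 35)),
                            lat=float(rng.uniform(-25, -5)))
        obs, units = simulate_site_observations(
            params, seed=int(rng.integers(0, 2**31 - 1)))
        write_observations(obs, directory / f"{sid}_observations.csv")
        units[["unit_id", "lon", "lat", "disturbance_value"]].to_csv(
            directory / f"{sid}_units.csv", index=False)
        site_rows.append({"site_id": sid, "lon": params.lon, "lat": params.lat,
                          "area_km2": 1000.0, "method": "camera",
                          "temporal_eligible": True,
                          "direction": "higher_is_disturbed",
                          "median_date": "2015-06-01"})
        cov_rows.append({"site_id": sid,
                         **{m: float(rng.normal(0, 1)) for m in MODERATORS}})
    pd.DataFrame(site_rows).to_csv(directory / "sites.csv", index=False)
    pd.DataFrame(cov_rows).to_csv(directory / "covariates.csv", index=False)
    return {"rr": float(np.log(p_low / p_high)), "d": target_d,
            "p_low": p_low, "p_high": p_high, "seed": seed}
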