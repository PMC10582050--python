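"""Synthetic study generator with known ground truth.

Every downstream stage — activity classification, dichotomization, effect
sizes, meta-regression — can be exercised against a recoverable planted
truth.  The generators invert the analysis model: per-site true effects
are drawn from a normal random-effects distribution with moderator
effects; per-site observation tables realise planted nocturnality
proportions and standardized-mean-difference targets through negative-
binomial observation counts; GPS tracks carry planted rest bouts that the
sequential cluster rule must find; monthly raster stacks hit configurable
mean and spatial/temporal coefficient-of-variation targets.

Being a meta-analysis, the emulated study has no canonical generative
model; all distributions here are package choices, documented in the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .covariates import MODERATORS, MonthlyRasterStack, Raster
from .effects import small_sample_correction


class InvalidConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Meta-level generator: effect sizes + covariates with planted (mu, tau2, beta)
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Planted parameters behind a synthetic meta-dataset."""

    mu: float
    tau2: float
    beta: dict[str, float]
    site_effects: np.ndarray
    site_params: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.tau2 < 0:
            raise InvalidConfigError("tau2 must be >= 0")


_DEFAULT_MODERATOR_SPEC = {
    "CAT_a": ("lognormal", np.log(10.0), 1.0),      # head / km^2
    "HFI_a": ("uniform", 1.0, 20.0),                # index units
    "HFI_sp": ("lognormal", np.log(0.6), 0.4),
    "NDVI_a": ("uniform", 0.2, 0.6),
    "NDVI_sp": ("uniform", 0.1, 0.4),
    "NDVI_tm": ("uniform", 0.05, 0.35),
}


def _draw(rng: np.random.Generator, spec: tuple, size: int) -> np.ndarray:
    kind, a, b = spec
    if kind == "normal":
        return rng.normal(a, b, size)
    if kind == "uniform":
        return rng.uniform(a, b, size)
    if kind == "lognormal":
        return rng.lognormal(a, b, size)
    raise InvalidConfigError(f"unknown distribution kind {kind!r}")


def simulate_meta_dataset(k: int, mu: float, tau2: float,
                          beta: dict[str, float] | None = None,
                          moderator_spec: dict[str, tuple] | None = None,
                          seed: int = 0,
                          variance_dist: tuple = ("lognormal", np.log(0.045), 0.5),
                          ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate k site-level effects under the random-effects model.

    True effects are ``theta_i = mu + Xs_i . beta + N(0, tau2)`` where
    ``Xs`` are the *scaled* (z-scored) moderators; observed effects add
    sampling noise ``N(0, v_i)`` with ``v_i`` drawn from
    ``variance_dist`` (``("fixed", v)`` pins them).  Returns the
    effect-size table, the **unscaled** covariate table, and the truth.
    """
    if k < 2:
        raise InvalidConfigError("need k >= 2 sites")
    if tau2 < 0:
        raise InvalidConfigError("tau2 must be >= 0")
    beta = dict(beta or {})
    moderator_spec = dict(moderator_spec
                          or {m: _DEFAULT_MODERATOR_SPEC[m] for m in beta}
                          or {})
    unknown = set(beta) - set(moderator_spec)
    if unknown:
        raise InvalidConfigError(f"beta given for unspecified moderators {unknown}")
    rng = np.random.default_rng(seed)

    site_ids = [f"site_{i:03d}" for i in range(k)]
    cov = pd.DataFrame({"site_id": site_ids})
    lin = np.zeros(k)
    for name, spec in moderator_spec.items():
        x = _draw(rng, spec, k)
        cov[name] = x
        b = beta.get(name, 0.0)
        if b != 0.0:
            xs = (x - x.mean()) / x.std(ddof=1)
            lin += b * xs

    theta = mu + lin + rng.normal(0.0, np.sqrt(tau2), k)
    if variance_dist[0] == "fixed":
        v = np.full(k, float(variance_dist[1]))
    else:
        v = _draw(rng, variance_dist, k)
    if np.any(v <= 0):
        raise InvalidConfigError("sampling variances must be positive")
    y = theta + rng.normal(0.0, np.sqrt(v))

    effects = pd.DataFrame({"site_id": site_ids, "estimate": y, "variance": v})
    truth = SyntheticTruth(mu=mu, tau2=tau2, beta=beta, site_effects=theta,
                           seed=seed)
    return effects, cov, truth


# ---------------------------------------------------------------------------
# Site-level generator: observation tables with planted d and RR
# ---------------------------------------------------------------------------

@dataclass
class SiteParams:
    """Generating parameters for one site's observation table.

    ``target_d`` is the planted Hedges' d of space use between the
    high- and low-disturbance groups (negative = avoidance);
    ``p_low``/``p_high`` are the nocturnal proportions of active
    observations, so the planted RR is ``ln(p_low / p_high)``.
    Per-unit active-observation counts are negative binomial with the
    given low-group mean and dispersion (gamma shape; larger = closer to
    Poisson).
    """

    site_id: str = "site_000"
    n_units: int = 80            # per disturbance group
    target_d: float = 0.0
    p_low: float = 0.4
    p_high: float = 0.4
    mean_count: float = 5.0      # low-group NB mean per unit
    dispersion: float = 8.0      # NB size parameter
    lon: float = 17.0            # site centroid, WGS84
    lat: float = -20.0

    def __post_init__(self):
        if self.n_units < 2:
            raise InvalidConfigError("need >= 2 units per group")
        for name in ("p_low", "p_high"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise InvalidConfigError(f"{name} must be strictly in (0, 1)")
        if self.mean_count <= 0 or self.dispersion <= 0:
            raise InvalidConfigError(
                "mean_count and dispersion must be positive (zero within-group "
                "variance cannot realise a nonzero d target)")


def _nb_sd(mean: float, dispersion: float) -> float:
    return float(np.sqrt(mean + mean * mean / dispersion))


def solve_high_group_mean(params: SiteParams) -> float:
    """High-group NB mean whose large-sample expected Hedges' d hits the
    target, given the low-group mean and shared dispersion."""
    m0, theta = params.mean_count, params.dispersion
    d_raw = params.target_d / small_sample_correction(params.n_units,
                                                      params.n_units)
    if d_raw == 0.0:
        return m0

    def f(m1: float) -> float:
        s_pool = np.sqrt((_nb_sd(m0, theta) ** 2 + _nb_sd(m1, theta) ** 2) / 2.0)
        return (m1 - m0) / s_pool - d_raw

    lo, hi = (1e-9, m0) if d_raw < 0 else (m0, m0 * 100.0 + 100.0)
    if f(lo) * f(hi) > 0:
        raise InvalidConfigError(
            f"d target {params.target_d} unreachable from mean_count "
            f"{m0} and dispersion {theta}")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def _nb_draw(rng, mean, dispersion, size):
    return rng.negative_binomial(dispersion, dispersion / (dispersion + mean),
                                 size)


def simulate_site_observations(params: SiteParams, seed: int = 0
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observation and sample-unit tables realising the planted targets.

    Each group's units receive negative-binomial active-observation
    counts (group means solved so expected d equals ``target_d``); each
    observation is nocturnal with its group's probability, and gets a
    timestamp at local midnight (nocturnal) or local noon (diurnal) so
    the solar classifier recovers the flag.  Units carry planted
    disturbance values — low group U(0,1), high group U(2,3) — so the
    dichotomization stage recovers the grouping.
    """
    rng = np.random.default_rng(seed)
    mean_high = solve_high_group_mean(params)
    obs_rows, unit_rows = [], []
    t0 = pd.Timestamp("2015-06-01", tz="UTC")
    # local solar midnight/noon in UTC at the site longitude
    offset = pd.Timedelta(hours=-params.lon / 15.0)
    day = 0
    for group, mean_g, p_noct, lon_off in (
            ("low", params.mean_count, params.p_low, -0.1),
            ("high", mean_high, params.p_high, 0.1)):
        counts = _nb_draw(rng, mean_g, params.dispersion, params.n_units)
        for u in range(params.n_units):
            unit_id = f"{params.site_id}_{group}_{u:03d}"
            lon = params.lon + lon_off + 0.02 * (u % 10)
            lat = params.lat + 0.02 * (u // 10)
            dist_val = rng.uniform(0.0, 1.0) if group == "low" else rng.uniform(2.0, 3.0)
            unit_rows.append({"unit_id": unit_id, "lon": lon, "lat": lat,
                              "disturbance_value": dist_val,
                              "true_group": group,
                              "active_count": int(counts[u])})
            nocturnal = rng.random(counts[u]) < p_noct
            for j, is_n in enumerate(nocturnal):
                ts = (t0 + pd.Timedelta(days=day % 3650) + offset
                      + (pd.Timedelta(hours=0) if is_n else pd.Timedelta(hours=12)))
                day += 1
                obs_rows.append({
                    "site_id": params.site_id, "unit_id": unit_id,
                    "timestamp": ts.isoformat(), "lon": lon, "lat": lat,
                    "method": "camera", "active": "active",
                    "nocturnal": bool(is_n)})
    observations = pd.DataFrame(obs_rows, columns=[
        "site_id", "unit_id", "timestamp", "lon", "lat", "method", "active",
        "nocturnal"])
    units = pd.DataFrame(unit_rows)
    return observations, units


# ---------------------------------------------------------------------------
# GPS track generator with planted rest bouts
# ---------------------------------------------------------------------------

@dataclass
class RestBout:
    start_fix: int
    n_fixes: int
    jitter_m: float = 20.0

    def __post_init__(self):
        if self.n_fixes < 3:
            raise InvalidConfigError("a rest bout needs >= 3 fixes")


def simulate_gps_track(n_days: int, fixes_per_day: int = 8,
                       step_km: float = 1.0,
                       rest_bouts: list[RestBout] | None = None,
                       seed: int = 0, start: tuple[float, float] = (17.0, -20.0),
                       search_radius_m: float = 100.0,
                       site_id: str = "site_000",
                       unit_id: str = "lion_01") -> pd.DataFrame:
    """A GPS track marching steadily east with planted stationary bouts.

    Travelling fixes advance ``step_km`` (> 0.2 required) east per fix, so
    every pair of non-bout fixes is separated by more than 200 m; bout
    fixes are uniformly jittered within ``jitter_m`` of the bout anchor.
    Bout jitter at or beyond half the cluster search radius is rejected:
    below that bound every bout fix is guaranteed within the radius of
    any running centroid of bout fixes.
    """
    if n_days < 1:
        raise InvalidConfigError("n_days must be >= 1")
    if step_km <= 0.2:
        raise InvalidConfigError("step_km must exceed 0.2 km to keep "
                                 "travelling fixes > 200 m apart")
    rest_bouts = list(rest_bouts or [])
    n_fixes = n_days * fixes_per_day
    in_bout = np.full(n_fixes, -1)
    for b, bout in enumerate(rest_bouts):
        if bout.jitter_m >= search_radius_m / 2.0:
            raise InvalidConfigError(
                f"bout jitter {bout.jitter_m} m >= half the {search_radius_m} m "
                "search radius; cluster membership not guaranteed")
        if bout.start_fix < 0 or bout.start_fix + bout.n_fixes > n_fixes:
            raise InvalidConfigError("rest bout exceeds the track")
        if np.any(in_bout[bout.start_fix:bout.start_fix + bout.n_fixes] >= 0):
            raise InvalidConfigError("rest bouts overlap")
        in_bout[bout.start_fix:bout.start_fix + bout.n_fixes] = b

    rng = np.random.default_rng(seed)
    lon0, lat0 = start
    km_per_deg_lon = 111.32 * np.cos(np.radians(lat0))
    interval = pd.Timedelta(hours=24.0 / fixes_per_day)
    t0 = pd.Timestamp("2016-01-01 00:00", tz="UTC")

    rows = []
    east_km = 0.0
    for i in range(n_fixes):
        b = in_bout[i]
        if b >= 0:
            jit = rest_bouts[b].jitter_m / 1000.0
            r = jit * np.sqrt(rng.random())
            ang = rng.uniform(0, 2 * np.pi)
            lon = lon0 + (east_km + r * np.cos(ang)) / km_per_deg_lon
            lat = lat0 + r * np.sin(ang) / 110.57
            if i == rest_bouts[b].start_fix + rest_bouts[b].n_fixes - 1:
                east_km += step_km  # leave the bout site
        else:
            lon = lon0 + east_km / km_per_deg_lon
            lat = lat0
            east_km += step_km
        rows.append({"site_id": site_id, "unit_id": unit_id,
                     "timestamp": (t0 + i * interval).isoformat(),
                     "lon": lon, "lat": lat, "method": "gps"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monthly raster stacks with target mean and CVs
# ---------------------------------------------------------------------------

@dataclass
class SyntheticRasterSpec:
    """Recipe for a monthly NDVI stack with calibrated statistics."""

    n_months: int
    grid_shape: tuple[int, int]
    mean_curve: np.ndarray                 # per-month target mean, in (-1, 1)
    target_spatial_cv: float = 0.0
    target_temporal_cv: float = 0.0
    seed: int = 0
    center: tuple[float, float] = (17.0, -20.0)   # lon, lat of grid centre
    cellsize_deg: float = 0.0025
    start_month: tuple[int, int] = (2000, 1)

    def __post_init__(self):
        self.mean_curve = np.asarray(self.mean_curve, dtype=float)
        if self.n_months < 2:
            raise InvalidConfigError("need >= 2 months")
        if min(self.grid_shape) < 2:
            raise InvalidConfigError("grid must be at least 2 x 2")
        if self.mean_curve.shape != (self.n_months,):
            raise InvalidConfigError("mean_curve length must equal n_months")
        if np.any(np.abs(self.mean_curve) >= 1):
            raise InvalidConfigError("mean NDVI must lie strictly in (-1, 1)")
        if self.target_spatial_cv < 0 or self.target_temporal_cv < 0:
            raise InvalidConfigError("target CVs must be >= 0")


def simulate_ndvi_stack(spec: SyntheticRasterSpec) -> MonthlyRasterStack:
    """Generate a monthly stack hitting the spec's statistical targets.

    The month-mean curve is rescaled about its grand mean so that its
    population CV equals ``target_temporal_cv``; each month's field is the
    month mean times i.i.d. unit-mean lognormal multipliers whose CV is
    ``target_spatial_cv``; values are clipped to [-1, 1].  Configurations
    whose 3-sigma envelope escapes [-1, 1] are rejected rather than
    silently clipped into bias.
    """
    m = spec.mean_curve
    mbar = float(m.mean())
    if spec.target_temporal_cv == 0.0:
        mprime = np.full(spec.n_months, mbar)
    else:
        s0 = float(m.std(ddof=0))
        if s0 == 0.0:
            raise InvalidConfigError(
                "constant mean_curve cannot realise a nonzero temporal CV")
        mprime = mbar + (m - mbar) * (spec.target_temporal_cv * abs(mbar) / s0)
    if np.any(np.abs(mprime) >= 1.0):
        raise InvalidConfigError("temporal CV target pushes month means "
                                 "outside (-1, 1)")

    cv = spec.target_spatial_cv
    if cv > 0:
        if np.any(mprime <= 0):
            raise InvalidConfigError("spatial CV requires positive month means")
        sigma2 = np.log1p(cv * cv)
        sigma = np.sqrt(sigma2)
        # Reject only when clipping would visibly bias the calibration:
        # a one-sigma multiplier already escaping [-1, 1] means >~16% of
        # pixels would clip.  Milder tail clipping is accepted.
        if np.max(mprime) * np.exp(-sigma2 / 2.0 + sigma) > 1.0:
            raise InvalidConfigError("spatial CV target pushes values "
                                     "outside [-1, 1]")

    rng = np.random.default_rng(spec.seed)
    nrows, ncols = spec.grid_shape
    lon0, lat0 = spec.center
    xll = lon0 - ncols * spec.cellsize_deg / 2.0
    yll = lat0 - nrows * spec.cellsize_deg / 2.0

    y0, m0 = spec.start_month
    months, rasters = [], []
    for i in range(spec.n_months):
        if cv > 0:
            mult = rng.lognormal(-sigma2 / 2.0, sigma, (nrows, ncols))
        else:
            mult = np.ones((nrows, ncols))
        values = np.clip(mprime[i] * mult, -1.0, 1.0)
        total = (y0 * 12 + (m0 - 1)) + i
        months.append((total // 12, total % 12 + 1))
        rasters.append(Raster(values, xll, yll, spec.cellsize_deg))
    return MonthlyRasterStack(months, rasters)


# ---------------------------------------------------------------------------
# Synthetic stand-in for a deposited per-site effect-size + covariate table
# ---------------------------------------------------------------------------

SPATIAL_BETA = {"HFI_sp": 0.286, "NDVI_sp": -0.893, "NDVI_tm": 0.218}
TEMPORAL_BETA = {"HFI_sp": 0.061, "CAT_a": -0.102, "NDVI_a": -0.015,
                 "NDVI_sp": -0.061}


def example_site_table(seed: int = 0, n_sites: int = 31, n_spatial: int = 30,
                       n_temporal: int = 18
                       ) -> tuple[pd.DataFrame, dict]:
    """SYNTHETIC per-site effect-size and covariate table.

    A stand-in, generated (not measured) table with the schema of a
    deposited meta-analysis data table: one row per site with spatial
    (SMD) and/or temporal (RR) effect sizes, sampling variances, the six
    unscaled moderators, and study metadata.  The planted means, between-
    site variances and moderator coefficients are the study conditions of
    a range-wide lion disturbance meta-analysis (31 sites: 30 spatial and
    18 temporal effects, 17 paired); returned ``truth`` records them.
    """
    if not (n_spatial <= n_sites and n_temporal <= n_sites):
        raise InvalidConfigError("effect counts cannot exceed site count")
    rng = np.random.default_rng(seed)
    mu_s, tau2_s = -0.268, 0.25
    mu_t, tau2_t = -0.068, 0.05

    cov = pd.DataFrame({"site_id": [f"site_{i:03d}" for i in range(n_sites)]})
    xs = {}
    for name in MODERATORS:
        x = _draw(rng, _DEFAULT_MODERATOR_SPEC[name], n_sites)
        cov[name] = x
        xs[name] = (x - x.mean()) / x.std(ddof=1)

    def planted(mu, tau2, beta):
        lin = sum(b * xs[nm] for nm, b in beta.items())
        return mu + lin + rng.normal(0.0, np.sqrt(tau2), n_sites)

    theta_s = planted(mu_s, tau2_s, SPATIAL_BETA)
    theta_t = planted(mu_t, tau2_t, TEMPORAL_BETA)
    v_s = rng.lognormal(np.log(0.045), 0.5, n_sites)
    v_t = rng.lognormal(np.log(0.010), 0.6, n_sites)
    smd = theta_s + rng.normal(0.0, np.sqrt(v_s))
    rr = theta_t + rng.normal(0.0, np.sqrt(v_t))

    # choose which sites have which response: first `n_both` have both
    n_both = n_spatial + n_temporal - n_sites
    has_s = np.zeros(n_sites, bool)
    has_t = np.zeros(n_sites, bool)
    has_s[:n_both] = has_t[:n_both] = True
    has_s[n_both:n_spatial] = True
    has_t[n_spatial:] = True

    table = cov.copy()
    table["smd"] = np.where(has_s, smd, np.nan)
    table["smd_var"] = np.where(has_s, v_s, np.nan)
    table["rr"] = np.where(has_t, rr, np.nan)
    table["rr_var"] = np.where(has_t, v_t, np.nan)
    table["median_date"] = pd.to_datetime("1995-01-01") + pd.to_timedelta(
        rng.integers(0, 365 * 24, n_sites), unit="D")
    table["area_km2"] = rng.lognormal(np.log(1500.0), 1.0, n_sites)
    table["fenced"] = rng.random(n_sites) < 0.3
    table["method"] = rng.choice(["gps", "camera", "direct"], n_sites,
                                 p=[0.45, 0.40, 0.15])
    table["disturbance_type"] = rng.choice(
        ["infrastructure", "direct_activity", "both"], n_sites)

    truth = {"mu_spatial": mu_s, "tau2_spatial": tau2_s,
             "beta_spatial": SPATIAL_BETA,
             "mu_temporal": mu_t, "tau2_temporal": tau2_t,
             "beta_temporal": TEMPORAL_BETA, "seed": seed}
    return table, truth
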