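# Methods

This note documents the statistical model, the conventions the package
pins where the underlying field practice varies, the synthetic-data
generators, and known limitations.

## Analysis model

Each study site contributes up to two effect sizes comparing lion
activity between low- and high-disturbance domains of that site.

**Spatial response (Hedges' d).** Space use per sample unit is the count
of active observations (optionally per unit effort; off by default since
study-native effort measures are heterogeneous). With group means x̄,
sample SDs s (divisor n−1) and unit counts n over the low/high groups:

    d  = J · (x̄_high − x̄_low) / s_pooled,   J = 1 − 3/(4m − 1),  m = n_low + n_high − 2
    Var(d) = 1/n_low + 1/n_high + d² / (2 (n_low + n_high))

The subtraction order is high − low so that d < 0 indicates avoidance of
disturbance. J is the standard small-sample approximation to the exact
gamma-function correction; at the site sizes this pipeline targets the
difference is below 10⁻³.

**Temporal response (log response ratio).** With P the proportion of
*active* observations that are nocturnal and n the active counts:

    RR = ln(P_low / P_high)
    Var(RR) = (1 − P_low)/(n_low P_low) + (1 − P_high)/(n_high P_high)

RR < 0 indicates a nocturnal shift under disturbance. The back-transform
(e^(−RR) − 1)·100 is the percent increase of P_high relative to P_low.
Boundary proportions (0 or 1) make Var(RR) undefined; the package raises
rather than silently applying a continuity correction.

**Nocturnality.** An observation is nocturnal when the solar elevation at
its time and coordinates (or the site centroid when coordinates are
missing) is strictly below −6° — beyond civil twilight. The threshold is
configurable per site. Solar positions use the NOAA low-precision
ephemeris (geometric elevation, no atmospheric refraction); agreement
with the NOAA reference calculator is within a few hundredths of a degree
over 1990–2025, far inside what a ±6° threshold needs.

**Activity.** GPS fixes are classified resting when they belong to a
sequential spatio-temporal cluster: a candidate opens at the first
unassigned fix; each later fix joins if it is within 100 m of the running
centroid (recomputed after every addition) *and* within 2 days of the
cluster's last member; a fix that fails either test closes the candidate
(kept if it reached 3 fixes, dissolved otherwise) and opens a new one at
itself. Closing on a failed radius test — not only on a temporal gap — is
a deliberate choice: it lets a second resting site inside the temporal
window form its own cluster, and it reproduces every boundary case we
pin in tests (scattered fixes never cluster; co-located fixes with >2-day
gaps never cluster; two bouts are never merged). Camera-trap and direct
observations are always active. Distances are great-circle (haversine,
IUGG mean radius); the error against the ellipsoid is irrelevant at the
100-m scale. Sites whose direct-observation surveys ran only in daytime
are flagged `temporal_eligible = False` and excluded from the RR stage.

**Disturbance dichotomy.** Sample units are native stations when the
study has them; otherwise a square grid in a Lambert azimuthal equal-area
projection about the site centroid, with cell side equal to the mean
daily displacement δ̄ (mean great-circle distance between first fixes of
consecutive calendar days; 1 km when δ̄ is not computable). "δ̄ km²
grid" is read as cells of side δ̄ km. Units at or below the 1st quartile
of the disturbance-oriented metric are low, at or above the 3rd quartile
high, the middle excluded; if either group would have < 60 units the
median split (≤ median → low) is used instead. Quantiles use the common
linear-interpolation (type-7) convention; ties at cutoffs are included in
the group. The 60-unit default comes from a two-tailed two-sample t-test
power analysis: n = 64 per group gives 80% power at α = 0.05 for
d = 0.5 (the conventional medium effect — the helper exposes d as a
parameter rather than asserting it). The `direction` flag records
whether larger metric values mean more disturbance (distance-to-village
metrics are `lower_is_disturbed`); flipping it exactly swaps group
labels.

**Site covariates.** Moderators are extracted over a circular buffer
centred on the site centroid with area equal to the study area
(r = √(area/π)); a sensitivity variant uses the dataset-wide minimum
area for all sites. Zonal membership is cell-centre-in-circle by
great-circle distance, with no partial-cell weighting (boundary effects
are negligible at 250-m NDVI resolution). For a monthly NDVI stack with
per-month buffer mean μ_i and SD σ_i over n months:

    NDVI_a  = (1/n) Σ μ_i
    NDVI_sp = (1/n) Σ (σ_i / μ_i)
    NDVI_tm = sqrt( Σ (μ_i − NDVI_a)² / n ) / NDVI_a

All SDs inside these CVs use the population convention (divisor n),
matching the explicit divisor-n form of the temporal CV; this is pinned
behind one function. The human-footprint epoch (2000 vs 2019 layers) is
the one nearer the survey's median date, with the exact midpoint
(2010-01-01) assigned to 2019. NDVI windows: `long_term` uses the full
stack, `study_months` the inclusive month range of the survey.
Covariates are z-scored (sample SD) before modelling, and pairs with
|Pearson r| > 0.6 are barred from co-occurring in any candidate model
(absolute value: a perfectly anti-correlated pair is equally collinear).

**Meta-regression.** Effects are modelled as
y_i = x_iᵀβ + u_i + e_i, u_i ~ N(0, τ²), e_i ~ N(0, v_i) with known v_i.
τ² is estimated by maximising the marginal normal likelihood (ML, not
REML — REML is available behind the model-fitting API for sensitivity
only), via bounded 1-D optimisation to 10⁻¹⁰ with an explicit check of
the τ² = 0 boundary; β by weighted least squares at τ̂² with weights
1/(v_i + τ̂²). Wald 95% CIs use z = Φ⁻¹(0.975). With one effect per site
per response, a site-level random effect is exactly this random-effects
model. Heterogeneity: I² = 100 τ̂²/(τ̂² + s²) with the Higgins–Thompson
typical within-study variance s² = (k−1)Σw / ((Σw)² − Σw²), w = 1/v;
the τ² CI inverts the generalised Q profile (Q_gen(τ²) equated to
χ² quantiles at k − p df), and the I² CI plugs in the τ² bounds — the
Q-profile method is the convention of the standard meta-analysis
software this implementation is cross-checked against. Q_E is the
weighted residual sum of squares of the fixed-effects (τ² = 0) fit.
AICc = −2ℓ + 2p + 2p(p+1)/(k−p−1) counts τ² as a parameter
(p = p_fixed + 1) and uses the constant-inclusive likelihood, so values
are comparable with that software. The all-subsets search fits every
subset of the six moderators not containing a screened pair (64 models
when nothing is screened), and reports ΔAICc and Akaike weights; models
within 2 ΔAICc of the best are considered competitive.

**Side analyses.** Sites with both responses: unweighted OLS of spatial
on temporal effects with the slope F-test. Study characteristics:
one-way ANOVA for categorical characteristics, OLS for continuous ones.
Outlier scanning uses Dixon's Q with the conventional ratio family by
sample size (r10 for n = 3–7, r11 for 8–10, r21 for 11–13, r22 for
14–30), two-sided on the more extreme tail; the p-value is Monte-Carlo
from standard-normal null samples (10⁵ replicates, seeded; standard
error < 0.002) rather than interpolated critical-value tables, for
reproducibility.

## Synthetic-data generators

The emulated study is a meta-analysis, so there is no canonical
generative model; every distribution below is a package choice, made
once and documented here.

- **Meta level** (`simulate_meta_dataset`): moderators drawn from
  documented site-realistic distributions (e.g. cattle density
  lognormal around 10 head/km², NDVI means uniform on [0.2, 0.6]);
  true effects θ_i = μ + X_scaled·β + N(0, τ²); sampling variances
  lognormal (median 0.045 for SMD-like, 0.01 for RR-like scales);
  observed y_i = θ_i + N(0, v_i).
- **Site level** (`simulate_site_observations`): per-unit active counts
  are negative binomial (overdispersed, mimicking camera/GPS intensity
  data) with the high-group mean solved numerically so the large-sample
  J-corrected expected d equals the target at the NB-implied pooled SD.
  Nocturnal flags are Bernoulli(p_group), and each observation's
  timestamp is local solar midnight (nocturnal) or noon (diurnal), so
  the solar classifier recovers the planted flag exactly. Unit
  disturbance values are U(0,1) for the low group and U(2,3) for the
  high group, so the dichotomization stage recovers the grouping under
  either rule.
- **Tracks** (`simulate_gps_track`): fixes march steadily east
  (step > 0.2 km, guaranteeing non-bout fixes are pairwise > 200 m
  apart); rest bouts jitter uniformly within < 50 m of an anchor —
  below half the 100-m search radius, which guarantees membership of
  any running centroid of bout fixes.
- **Rasters** (`simulate_ndvi_stack`): the month-mean curve is rescaled
  about its grand mean to hit the target temporal CV; each month is the
  month mean times i.i.d. unit-mean lognormal multipliers with the
  target spatial CV; values are clipped to [−1, 1], and configurations
  whose one-sigma multiplier already escapes the range (≈16%+ of pixels
  clipping) are rejected as uncalibratable. Realized NDVI_a is within
  5% and the CV metrics within 10% of targets on grids of ~2500 cells.

What the generators do **not** emulate: behaviourally realistic movement
(no correlated random walks), landscape covariance between NDVI and
disturbance (independent unless configured), detection error, or
effort heterogeneity. Passing recovery tests therefore demonstrates the
estimators and pipeline plumbing, not robustness to those real-data
features.

## Numerical conventions and degenerate inputs

- Quantiles: type-7; ties included at cutoffs (≤/≥ in quartile mode,
  ≤ median → low in median mode).
- τ² optimisation: bounded [0, max(10·var(y), 10⁻³)], xatol 10⁻¹⁰,
  boundary ℓ(0) compared explicitly; Q-profile roots by Brent to 10⁻¹².
- Zero pooled SD, boundary proportions, all-identical disturbance
  metrics, empty buffers, zero-variance covariate columns and
  rank-deficient designs all raise typed errors naming the offender;
  nothing is silently patched.
- Grids: spans within 1% of a cell of a whole count snap down to it
  (metres at study scale — below the distortion of re-projecting an
  extent between local projections), and boundary points clip into the
  outermost cell with the same tolerance.
- Constant-column detection uses a relative 10⁻¹⁰ floor because the
  float std of an exactly-constant column is ~10⁻¹⁷, not 0.

## Problem sizes

The test suite and the acceptance script use deliberately moderate
sizes — tens of sites, tens of units per group, 10⁴-replicate coverage
runs, 100-replicate recovery experiments at k = 200, and a τ² grid of
2×10⁴ points — chosen so the whole verification cycle completes in a
few minutes on a single core while keeping Monte-Carlo standard errors
well inside the asserted tolerances.

## Known limitations

- The spatial effect uses observation counts per unit as the space-use
  measure; occupancy- or density-based measures from original studies
  are not reconstructed.
- No multivariate (joint spatial+temporal) meta-analysis; the two
  responses are modelled separately and compared post hoc by OLS.
- No publication-bias diagnostics, no lunar illumination, no kill-site
  inference from clusters, and no continuous (non-dichotomized)
  disturbance modelling.
- The Dixon test addresses a single outlier; masking by multiple
  outliers is out of scope.
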