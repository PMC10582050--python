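"""Synthetic generators: determinism, planted-parameter recovery, track
geometry contracts, and raster calibration."""

import numpy as np
import pandas as pd
import pytest

from lionmeta._geo import haversine_km
from lionmeta.activity import detect_clusters
from lionmeta.covariates import ndvi_metrics
from lionmeta.effects import hedges_d, log_response_ratio
from lionmeta.synth import (InvalidConfigError, RestBout, SiteParams,
                            SyntheticRasterSpec, example_site_table,
                            simulate_gps_track, simulate_meta_dataset,
                            simulate_ndvi_stack, simulate_site_observations,
                            solve_high_group_mean)


class TestSimulateMetaDataset:
    def test_determinism(self):
        a = simulate_meta_dataset(20, -0.3, 0.1, {"HFI_sp": 0.2}, seed=5)
        b = simulate_meta_dataset(20, -0.3, 0.1, {"HFI_sp": 0.2}, seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        assert np.array_equal(a[2].site_effects, b[2].site_effects)

    def test_degenerate_variances_collapse_to_mu(self):
        eff, _, _ = simulate_meta_dataset(
            30, -0.25, 0.0, seed=3, variance_dist=("fixed", 1e-12))
        assert np.all(np.abs(eff["estimate"] - (-0.25)) < 1e-5)

    def test_invalid_configs(self):
        with pytest.raises(InvalidConfigError):
            simulate_meta_dataset(1, 0.0, 0.1)
        with pytest.raises(InvalidConfigError):
            simulate_meta_dataset(10, 0.0, -0.1)

    def test_covariates_returned_unscaled(self):
        _, cov, _ = simulate_meta_dataset(200, 0.0, 0.1, {"CAT_a": -0.5},
                                          seed=8)
        assert cov["CAT_a"].mean() > 1.0   # lognormal head/km2, not z-scores


class TestSimulateSiteObservations:
    def test_determinism(self):
        p = SiteParams(n_units=20, target_d=-0.4, p_low=0.3, p_high=0.5)
        a = simulate_site_observations(p, seed=2)
        b = simulate_site_observations(p, seed=2)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_equal_proportions_give_zero_rr(self):
        p = SiteParams(n_units=150, mean_count=6.0, p_low=0.45, p_high=0.45)
        obs, _ = simulate_site_observations(p, seed=4)
        for group in ("low", "high"):
            sub = obs[obs["unit_id"].str.contains(f"_{group}_")]
            assert abs(sub["nocturnal"].mean() - 0.45) < 3 * np.sqrt(
                0.45 * 0.55 / len(sub))

    def test_planted_rr_recovered(self):
        """p_low=0.40, p_high=0.50 at ~150 active obs per group: the
        effect-size stage lands within 3 MC SE of ln(0.8)."""
        p = SiteParams(n_units=30, mean_count=5.0, p_low=0.40, p_high=0.50)
        rrs, ses = [], []
        for seed in range(8):
            obs, _ = simulate_site_observations(p, seed=seed)
            grp = {}
            for g in ("low", "high"):
                sub = obs[obs["unit_id"].str.contains(f"_{g}_")]
                grp[g] = (sub["nocturnal"].mean(), len(sub))
            rr, var = log_response_ratio(grp["low"][0], grp["low"][1],
                                         grp["high"][0], grp["high"][1])
            rrs.append(rr)
            ses.append(np.sqrt(var))
        pooled_se = np.sqrt(np.mean(np.square(ses)) / len(rrs))
        assert abs(np.mean(rrs) - np.log(0.8)) < 3 * pooled_se

    def test_planted_d_recovered(self):
        """Planted d = -0.5 with 100 units/group recovered within 3 SE of
        the replicate mean."""
        p = SiteParams(n_units=100, target_d=-0.5, mean_count=5.0)
        ds = []
        for seed in range(12):
            _, units = simulate_site_observations(p, seed=seed)
            lo = units[units["true_group"] == "low"]["active_count"]
            hi = units[units["true_group"] == "high"]["active_count"]
            d, _ = hedges_d(lo.mean(), lo.std(ddof=1), len(lo),
                            hi.mean(), hi.std(ddof=1), len(hi))
            ds.append(d)
        se_mean = np.std(ds, ddof=1) / np.sqrt(len(ds))
        assert abs(np.mean(ds) - (-0.5)) < 3 * se_mean

    def test_solved_mean_hits_target_exactly(self):
        p = SiteParams(n_units=60, target_d=-0.5, mean_count=5.0,
                       dispersion=8.0)
        m1 = solve_high_group_mean(p)
        from lionmeta.effects import small_sample_correction
        sd = lambda m: np.sqrt(m + m * m / 8.0)
        s_pool = np.sqrt((sd(5.0) ** 2 + sd(m1) ** 2) / 2)
        d = small_sample_correction(60, 60) * (m1 - 5.0) / s_pool
        assert d == pytest.approx(-0.5, abs=1e-10)

    def test_invalid_configs(self):
        with pytest.raises(InvalidConfigError):
            SiteParams(n_units=1)
        with pytest.raises(InvalidConfigError):
            SiteParams(p_low=0.0)
        with pytest.raises(InvalidConfigError):
            SiteParams(mean_count=0.0, target_d=-0.5)


class TestSimulateGpsTrack:
    def test_determinism(self):
        a = simulate_gps_track(4, rest_bouts=[RestBout(3, 4)], seed=9)
        b = simulate_gps_track(4, rest_bouts=[RestBout(3, 4)], seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_no_bouts_no_clusters(self):
        track = simulate_gps_track(5, fixes_per_day=6, seed=1)
        assert detect_clusters(track).n_clusters == 0

    def test_one_bout_exactly_recovered(self):
        track = simulate_gps_track(3, fixes_per_day=8,
                                   rest_bouts=[RestBout(5, 4, 20.0)], seed=2)
        labeling = detect_clusters(track)
        assert labeling.n_clusters == 1
        members = np.flatnonzero(labeling.labels.to_numpy() > 0)
        assert members.tolist() == [5, 6, 7, 8]

    def test_two_distant_bouts_never_merge(self):
        track = simulate_gps_track(
            10, fixes_per_day=4,
            rest_bouts=[RestBout(0, 4, 15.0), RestBout(24, 4, 15.0)], seed=3)
        labeling = detect_clusters(track)
        assert labeling.n_clusters == 2
        ids = labeling.labels[labeling.labels > 0]
        assert ids.nunique() == 2

    def test_geometry_contracts(self):
        bout = RestBout(6, 5, 25.0)
        track = simulate_gps_track(4, fixes_per_day=6, step_km=0.6,
                                   rest_bouts=[bout], seed=4)
        lon = track["lon"].to_numpy()
        lat = track["lat"].to_numpy()
        in_bout = np.zeros(len(track), bool)
        in_bout[6:11] = True
        outside = np.flatnonzero(~in_bout)
        for i, j in zip(outside, outside[1:]):
            assert haversine_km(lon[i], lat[i], lon[j], lat[j]) * 1000 > 200
        anchor = (lon[6], lat[6])
        for i in range(6, 11):
            assert haversine_km(lon[i], lat[i], *anchor) * 1000 <= 2 * 25.0

    def test_invalid_configs(self):
        with pytest.raises(InvalidConfigError):
            simulate_gps_track(2, rest_bouts=[RestBout(0, 4, 60.0)])
        with pytest.raises(InvalidConfigError):
            RestBout(0, 2)
        with pytest.raises(InvalidConfigError):
            simulate_gps_track(1, fixes_per_day=4,
                               rest_bouts=[RestBout(2, 4, 10.0)])
        with pytest.raises(InvalidConfigError):
            simulate_gps_track(2, step_km=0.1)


class TestSimulateNdviStack:
    def test_constant_targets_give_constant_stack(self):
        spec = SyntheticRasterSpec(3, (4, 4), np.full(3, 0.37), 0.0, 0.0,
                                   seed=1)
        stack = simulate_ndvi_stack(spec)
        for r in stack.rasters:
            assert np.all(r.values == pytest.approx(0.37))

    def test_determinism(self):
        spec = SyntheticRasterSpec(6, (10, 10), np.linspace(0.3, 0.5, 6),
                                   0.2, 0.1, seed=6)
        a = simulate_ndvi_stack(spec)
        b = simulate_ndvi_stack(spec)
        for ra, rb in zip(a.rasters, b.rasters):
            assert np.array_equal(ra.values, rb.values)

    def test_sinusoid_calibration(self):
        months = np.arange(12)
        curve = 0.45 + 0.10 * np.sin(2 * np.pi * months / 12)
        spec = SyntheticRasterSpec(12, (50, 50), curve, 0.2, 0.15, seed=7)
        stack = simulate_ndvi_stack(spec)
        a, sp, tm = ndvi_metrics(stack, spec.center, 1e4)
        assert abs(a - curve.mean()) / curve.mean() < 0.05
        assert abs(sp - 0.2) / 0.2 < 0.10
        assert abs(tm - 0.15) / 0.15 < 0.10

    def test_values_stay_in_ndvi_range(self):
        spec = SyntheticRasterSpec(6, (30, 30), np.full(6, 0.5), 0.3, 0.0,
                                   seed=8)
        stack = simulate_ndvi_stack(spec)
        for r in stack.rasters:
            assert np.all(r.values >= -1.0) and np.all(r.values <= 1.0)

    def test_impossible_targets_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_ndvi_stack(SyntheticRasterSpec(
                4, (5, 5), np.full(4, 0.9), 0.8, 0.0, seed=1))
        with pytest.raises(InvalidConfigError):
            simulate_ndvi_stack(SyntheticRasterSpec(
                4, (5, 5), np.full(4, 0.5), 0.0, 0.3, seed=1))
        with pytest.raises(InvalidConfigError):
            SyntheticRasterSpec(1, (5, 5), np.array([0.5]))
        with pytest.raises(InvalidConfigError):
            SyntheticRasterSpec(3, (1, 5), np.full(3, 0.5))


class TestExampleSiteTable:
    def test_shape_and_determinism(self):
        a, truth = example_site_table(seed=0)
        b, _ = example_site_table(seed=0)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 31
        assert a["smd"].notna().sum() == 30
        assert a["rr"].notna().sum() == 18
        assert (a["smd"].notna() & a["rr"].notna()).sum() == 17
        assert truth["mu_spatial"] == -0.268
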