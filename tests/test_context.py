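"""Foraging-range KDEs, tercile thresholds, condition proportions."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from scipy.stats import chi2

from flapwave.context import (
    CategoryThresholds,
    category_thresholds,
    condition_proportions,
    foraging_kde_95,
    monthly_env_in_kde,
)
from flapwave.geo import laea_unproject

COLONY = (-54.0, -38.05)


def gaussian_fixes(rng, n=5000, sd_km=50.0):
    x = rng.normal(0, sd_km, n)
    y = rng.normal(0, sd_km, n)
    lat, lon = laea_unproject(x, y, *COLONY)
    return pd.DataFrame({"lat": lat, "lon": lon})


class TestForagingKDE:
    def test_gaussian_cloud_area_matches_ellipse(self, rng):
        """95% region area within 20% of the analytic chi-square ellipse."""
        region = foraging_kde_95(gaussian_fixes(rng), colony=COLONY)
        analytic = np.pi * chi2.ppf(0.95, 2) * 50.0**2
        assert abs(region.area_km2 - analytic) / analytic < 0.20
        assert 0.94 <= region.mass <= 0.96

    def test_two_clusters_keep_mass_contract(self, rng):
        a = gaussian_fixes(rng, n=2500, sd_km=30.0)
        x = rng.normal(600, 30.0, 2500)
        y = rng.normal(0, 30.0, 2500)
        lat, lon = laea_unproject(x, y, *COLONY)
        fixes = pd.concat([a, pd.DataFrame({"lat": lat, "lon": lon})], ignore_index=True)
        region = foraging_kde_95(fixes, colony=COLONY)
        assert 0.94 <= region.mass <= 0.96

    def test_contains_centre_not_far_field(self, rng):
        region = foraging_kde_95(gaussian_fixes(rng), colony=COLONY)
        assert region.contains(COLONY[0], COLONY[1])
        far_lat, far_lon = laea_unproject(2000.0, 2000.0, *COLONY)
        assert not region.contains(far_lat, far_lon)

    def test_degenerate_fixes_rejected(self):
        fixes = pd.DataFrame({"lat": [-54.0] * 600, "lon": [-38.0] * 600})
        with pytest.raises(ValueError):
            foraging_kde_95(fixes, colony=COLONY)

    def test_too_few_fixes_rejected(self, rng):
        with pytest.raises(ValueError):
            foraging_kde_95(gaussian_fixes(rng, n=100), colony=COLONY)


class TestMonthlyEnv:
    @staticmethod
    def _monthly(field_fn, years=2):
        lats = np.arange(-58.0, -49.9, 0.5)
        lons = np.arange(-44.0, -31.9, 0.5)
        time = pd.date_range("2020-01-01", periods=12 * years, freq="MS")
        glon, glat = np.meshgrid(lons, lats)
        base = field_fn(glat, glon)
        data = np.broadcast_to(base, (len(time),) + base.shape).copy()
        return xr.Dataset(
            {
                "windspeed": (("time", "lat", "lon"), data),
                "swh": (("time", "lat", "lon"), data / 4.0),
            },
            coords={"time": time, "lat": lats, "lon": lons},
        )

    def test_constant_field_every_month(self, rng):
        region = foraging_kde_95(gaussian_fixes(rng), colony=COLONY)
        monthly = self._monthly(lambda la, lo: np.full_like(la, 8.0))
        out = monthly_env_in_kde(region, monthly)
        assert len(out) == 12
        assert np.allclose(out["windspeed"], 8.0)
        assert np.allclose(out["swell_height"], 2.0)

    def test_missing_cells_do_not_bias_constant_field(self, rng):
        region = foraging_kde_95(gaussian_fixes(rng), colony=COLONY)
        monthly = self._monthly(lambda la, lo: np.full_like(la, 8.0))
        vals = monthly["windspeed"].values
        vals[:, ::2, :] = np.nan  # mask half the cells, sea-ice style
        out = monthly_env_in_kde(region, monthly)
        assert np.allclose(out["windspeed"], 8.0)

    def test_empty_intersection_rejected(self, rng):
        region = foraging_kde_95(gaussian_fixes(rng, sd_km=20.0), colony=COLONY)
        lats = np.arange(20.0, 30.0, 0.5)
        lons = np.arange(100.0, 110.0, 0.5)
        time = pd.date_range("2020-01-01", periods=12, freq="MS")
        far = xr.Dataset(
            {
                "windspeed": (("time", "lat", "lon"), np.ones((12, len(lats), len(lons)))),
                "swh": (("time", "lat", "lon"), np.ones((12, len(lats), len(lons)))),
            },
            coords={"time": time, "lat": lats, "lon": lons},
        )
        with pytest.raises(ValueError):
            monthly_env_in_kde(region, far)


def _basin_table(rng, n_birds=40, rows=300, wind=None, swell=None, species=("sp1", "sp2")):
    frames = []
    for b in range(n_birds):
        w = wind if wind is not None else rng.gamma(7.0, 4.5, rows)
        s = swell if swell is not None else rng.gamma(9.0, 0.28, rows)
        frames.append(
            pd.DataFrame(
                {
                    "bird_id": f"b{b:03d}",
                    "species": species[b % len(species)],
                    "windspeed": w,
                    "swell_height": s,
                    "BWA": rng.uniform(0, 180, rows),
                    "BSA": rng.uniform(0, 180, rows),
                    "complete_trip": True,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestThresholds:
    def test_uniform_swell_has_analytic_terciles(self, rng):
        """Uniform(0, 3) swell heights give thresholds ~1 and ~2."""
        table = _basin_table(rng, n_birds=40, rows=300)
        table["swell_height"] = rng.uniform(0.0, 3.0, len(table))
        thr = category_thresholds({"A": table}, n_per_basin=34, seed=0)
        assert abs(thr.swell_t1 - 1.0) < 0.05
        assert abs(thr.swell_t2 - 2.0) < 0.05

    def test_same_seed_reproduces(self, rng):
        table = _basin_table(rng)
        t1 = category_thresholds({"A": table}, n_per_basin=20, seed=4)
        t2 = category_thresholds({"A": table}, n_per_basin=20, seed=4)
        assert (t1.wind_t1, t1.wind_t2, t1.birds_used) == (t2.wind_t1, t2.wind_t2, t2.birds_used)

    def test_quantile_equivariance_under_shift(self, rng):
        """Shifting every value by delta shifts both thresholds by delta."""
        table = _basin_table(rng)
        t0 = category_thresholds({"A": table}, n_per_basin=20, seed=1)
        shifted = table.assign(
            windspeed=table["windspeed"] + 5.0, swell_height=table["swell_height"] + 0.7
        )
        t1 = category_thresholds({"A": shifted}, n_per_basin=20, seed=1)
        assert t1.wind_t1 == pytest.approx(t0.wind_t1 + 5.0)
        assert t1.wind_t2 == pytest.approx(t0.wind_t2 + 5.0)
        assert t1.swell_t1 == pytest.approx(t0.swell_t1 + 0.7)

    def test_all_equal_values_reported_as_error(self, rng):
        table = _basin_table(rng)
        table["windspeed"] = 10.0
        with pytest.raises(ValueError):
            category_thresholds({"A": table}, n_per_basin=20, seed=0)

    def test_scarce_species_named_in_error(self, rng):
        table = _basin_table(rng, n_birds=6)
        with pytest.raises(ValueError, match="sp1"):
            category_thresholds({"A": table}, n_per_basin=34, seed=0)


class TestProportions:
    THRESHOLDS = CategoryThresholds(wind_t1=27.1, wind_t2=39.4, swell_t1=2.18, swell_t2=3.11)

    def test_all_tailwind(self, rng):
        table = _basin_table(rng, n_birds=4, rows=50)
        table["BWA"] = 0.0
        props = condition_proportions(table, self.THRESHOLDS)
        tail = props.query("classification == 'bwa' and category == 'tail'")
        assert tail["proportion"].iloc[0] == 1.0

    def test_partition_sums_to_one(self, rng):
        props = condition_proportions(_basin_table(rng, n_birds=6, rows=80), self.THRESHOLDS)
        sums = props.groupby("classification")["proportion"].sum()
        assert np.allclose(sums, 1.0)

    def test_uniform_angles_near_equal_thirds(self, rng):
        table = _basin_table(rng, n_birds=10, rows=1000)
        props = condition_proportions(table, self.THRESHOLDS)
        bwa = props[props["classification"] == "bwa"]["proportion"]
        assert np.allclose(bwa, 1 / 3, atol=0.02)

    def test_invariant_to_row_order_and_relabeling(self, rng):
        table = _basin_table(rng, n_birds=5, rows=60)
        p0 = condition_proportions(table, self.THRESHOLDS)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        relabeled = shuffled.assign(bird_id=shuffled["bird_id"].map(lambda b: "x" + b))
        p1 = condition_proportions(relabeled, self.THRESHOLDS)
        pd.testing.assert_frame_equal(p0, p1)
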