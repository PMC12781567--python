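"""Wind and swell availability and use: foraging-range KDEs and condition categories.

Summaries that put the flap-rate models in context: the 95% kernel
utilization region of each species' complete foraging tracks, monthly
wind/swell climatologies inside that region, tercile thresholds of the
experienced windspeed and swell-height distributions computed on a
species-balanced subset of birds, and the proportion of flight time
each bird spends in each magnitude and relative-angle category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.stats import gaussian_kde

from .geo import laea_project

__all__ = [
    "ForagingKDE",
    "CategoryThresholds",
    "foraging_kde_95",
    "monthly_env_in_kde",
    "category_thresholds",
    "condition_proportions",
]


@dataclass
class ForagingKDE:
    """A species' utilization region from a 2-D Gaussian KDE.

    Fixes are projected with an equal-area azimuthal projection about
    the colony; the region is the density super-level set holding
    ``mass`` of the KDE probability (within the 94-96% contract for the
    default 95%). ``contains`` answers point-in-region queries in
    lat/lon.
    """

    species: str
    kde: gaussian_kde
    threshold: float
    colony: tuple
    bandwidth: float
    mass: float
    area_km2: float

    def contains(self, lat, lon) -> np.ndarray:
        x, y = laea_project(np.asarray(lat, float), np.asarray(lon, float), *self.colony)
        return (self.kde(np.vstack([np.ravel(x), np.ravel(y)])) >= self.threshold).reshape(
            np.shape(lat)
        )


def foraging_kde_95(
    fixes: pd.DataFrame,
    colony: tuple,
    species: str = "",
    mass: float = 0.95,
    grid_n: int = 256,
) -> ForagingKDE:
    """95% utilization region of pooled complete-trip fixes.

    A Gaussian KDE with reference (Silverman) bandwidth is fitted to the
    equal-area-projected fixes; the density threshold is chosen on a
    grid so the enclosed KDE mass equals ``mass`` to grid precision.
    """
    if len(fixes) < 500:
        raise ValueError("need at least 500 fixes for the utilization KDE")
    lat = fixes["lat"].to_numpy(dtype=float)
    lon = fixes["lon"].to_numpy(dtype=float)
    x, y = laea_project(lat, lon, *colony)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate fixes: zero spatial variance")
    kde = gaussian_kde(np.vstack([x, y]), bw_method="silverman")
    pad = 4.0 * np.sqrt(max(np.var(x), np.var(y)))
    gx = np.linspace(x.min() - pad, x.max() + pad, grid_n)
    gy = np.linspace(y.min() - pad, y.max() + pad, grid_n)
    gxx, gyy = np.meshgrid(gx, gy, indexing="ij")
    dens = kde(np.vstack([gxx.ravel(), gyy.ravel()]))
    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
    order = np.argsort(dens)[::-1]
    cum = np.cumsum(dens[order]) * cell
    total = dens.sum() * cell
    k = int(np.searchsorted(cum, mass * total))
    k = min(k, dens.size - 1)
    threshold = float(dens[order][k])
    inside = dens >= threshold
    got_mass = float(dens[inside].sum() * cell / total)
    return ForagingKDE(
        species=species,
        kde=kde,
        threshold=threshold,
        colony=tuple(colony),
        bandwidth=float(kde.factor),
        mass=got_mass,
        area_km2=float(inside.sum() * cell),
    )


def monthly_env_in_kde(region: ForagingKDE, monthly: xr.Dataset) -> pd.DataFrame:
    """Calendar-month climatology of windspeed and swell inside the region.

    ``monthly`` carries monthly-mean fields ``windspeed`` (m/s or km/h,
    passed through) and ``swh`` (m) on dims (time, lat, lon). Cells
    whose centers fall inside the utilization region are averaged with
    cos(lat) area weights; missing cells (e.g. sea ice) are excluded.
    Returns 12 rows of multi-year means per calendar month.
    """
    lats = monthly["lat"].values
    lons = monthly["lon"].values
    glon, glat = np.meshgrid(lons, lats)
    inside = region.contains(glat, glon)
    if not inside.any():
        raise ValueError("utilization region does not intersect the monthly grid")
    w = np.cos(np.radians(glat)) * inside
    months = pd.DatetimeIndex(monthly["time"].values).month
    rows = []
    for m in range(1, 13):
        sel = months == m
        if not sel.any():
            rows.append({"month": m, "windspeed": np.nan, "swell_height": np.nan})
            continue
        out = {"month": m}
        for var, name in (("windspeed", "windspeed"), ("swh", "swell_height")):
            f = monthly[var].values[sel]  # (n_years, nlat, nlon)
            ww = np.broadcast_to(w, f.shape) * np.isfinite(f)
            s = np.nansum(f * ww)
            out[name] = float(s / ww.sum()) if ww.sum() > 0 else np.nan
        rows.append(out)
    return pd.DataFrame(rows)


@dataclass
class CategoryThresholds:
    """Tercile breakpoints of experienced windspeed (km/h) and swell (m)."""

    wind_t1: float
    wind_t2: float
    swell_t1: float
    swell_t2: float
    birds_used: tuple = ()

    def __post_init__(self) -> None:
        if not (self.wind_t1 < self.wind_t2 and self.swell_t1 < self.swell_t2):
            raise ValueError("degenerate thresholds: t1 must be < t2")


def category_thresholds(
    tables_by_basin: dict[str, pd.DataFrame],
    n_per_basin: int = 34,
    seed: int | None = None,
) -> CategoryThresholds:
    """Tercile thresholds from a species-balanced subset of complete trips.

    From each ocean basin, ``n_per_basin`` birds with complete trips are
    drawn without replacement, equally many per species within the
    basin; the 1/3 and 2/3 quantiles of the pooled windspeed and
    swell-height rows of that subset become the low/medium/high breaks
    applied to every species.
    """
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    pooled = []
    for basin in sorted(tables_by_basin):
        table = tables_by_basin[basin]
        ct = table[table["complete_trip"]]
        species_list = sorted(ct["species"].unique()) if "species" in ct else [""]
        per_species = n_per_basin // len(species_list)
        for sp in species_list:
            sub = ct if sp == "" else ct[ct["species"] == sp]
            birds = np.sort(sub["bird_id"].unique())
            if birds.size < per_species:
                raise ValueError(
                    f"species {sp!r} in basin {basin!r} has only {birds.size} "
                    f"complete-trip birds, need {per_species}"
                )
            pick = rng.choice(birds, size=per_species, replace=False)
            chosen.extend(pick.tolist())
            pooled.append(sub[sub["bird_id"].isin(pick)])
    rows = pd.concat(pooled, ignore_index=True)
    w1, w2 = np.quantile(rows["windspeed"].to_numpy(dtype=float), [1 / 3, 2 / 3])
    s1, s2 = np.quantile(rows["swell_height"].to_numpy(dtype=float), [1 / 3, 2 / 3])
    return CategoryThresholds(
        wind_t1=float(w1), wind_t2=float(w2), swell_t1=float(s1), swell_t2=float(s2),
        birds_used=tuple(chosen),
    )


def _magnitude_cat(x: np.ndarray, t1: float, t2: float) -> np.ndarray:
    """low / med / high with breaks closed on the left: med = [t1, t2)."""
    return np.where(x < t1, "low", np.where(x < t2, "med", "high"))


def _angle_cat(a: np.ndarray, bins: tuple, labels: tuple) -> np.ndarray:
    lo, hi = bins
    return np.where(a < lo, labels[0], np.where(a < hi, labels[1], labels[2]))


def condition_proportions(
    table: pd.DataFrame,
    thresholds: CategoryThresholds,
    angle_bins: tuple = (60.0, 120.0),
) -> pd.DataFrame:
    """Species-mean proportions of flight time per condition category.

    Four classifications: windspeed and swell magnitude (low/med/high by
    the tercile thresholds) and BWA/BSA direction (tail/cross/head and
    with/across/against, by the ``angle_bins`` boundaries on the 0-180
    scale). Proportions are computed per bird and then averaged across
    birds, so each classification sums to 1.
    """
    classes = {
        "wind": (_magnitude_cat(table["windspeed"].to_numpy(float), thresholds.wind_t1, thresholds.wind_t2), ("low", "med", "high")),
        "swell": (_magnitude_cat(table["swell_height"].to_numpy(float), thresholds.swell_t1, thresholds.swell_t2), ("low", "med", "high")),
        "bwa": (_angle_cat(table["BWA"].to_numpy(float), angle_bins, ("tail", "cross", "head")), ("tail", "cross", "head")),
        "bsa": (_angle_cat(table["BSA"].to_numpy(float), angle_bins, ("with", "across", "against")), ("with", "across", "against")),
    }
    birds = table["bird_id"].to_numpy()
    rows = []
    for name, (cats, labels) in classes.items():
        df = pd.DataFrame({"bird_id": birds, "cat": cats})
        per_bird = (
            df.groupby("bird_id")["cat"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=labels, fill_value=0.0)
        )
        mean = per_bird.mean(axis=0)
        for label in labels:
            rows.append(
                {"classification": name, "category": label, "proportion": float(mean[label])}
            )
    return pd.DataFrame(rows)
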