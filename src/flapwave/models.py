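"""The six candidate flap-rate models, selection by AICc, and the reduction statistic.

Candidate structures for hourly flap counts (all with a per-bird random
intercept and log link):

====== =============================================
Model  Environmental terms
====== =============================================
0      none (null)
I      s(windspeed)
II     s(swell_height)
III    te(windspeed, BWA)
IV     te(swell_height, BSA)
V      te(windspeed, swell_height)
====== =============================================

Models are compared by AICc and Akaike weights. Prediction surfaces of
the two-variable models are trimmed to the 99% kernel-density region of
the observed covariate space before interpretation, and the headline
statistic is the percent reduction in predicted flap rate from the 95th
to the 5th quantile of the masked surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .gam import GAM, SmoothTerm, aicc, estimate_nb_alpha

__all__ = [
    "MODEL_IDS",
    "ModelSpec",
    "ModelFit",
    "fit_flap_model",
    "fit_all_models",
    "model_selection_table",
    "kde_mask_99",
    "KDEMask",
    "PredictionSurface",
    "predict_surface",
    "flap_reduction",
    "ReductionResult",
    "conditional_profile",
    "downsample_robustness",
]

MODEL_IDS = ("0", "I", "II", "III", "IV", "V")

_STRUCTURES: dict[str, tuple] = {
    "0": (),
    "I": (("spline", ("windspeed",)),),
    "II": (("spline", ("swell_height",)),),
    "III": (("tensor", ("windspeed", "BWA")),),
    "IV": (("tensor", ("swell_height", "BSA")),),
    "V": (("tensor", ("windspeed", "swell_height")),),
}

_TERM_LABELS = {
    "0": "Null",
    "I": "Windspeed",
    "II": "Swell height",
    "III": "Windspeed, BWA",
    "IV": "Swell height, BSA",
    "V": "Windspeed, Swell height",
}


@dataclass
class ModelSpec:
    """One of the six candidate structures, by id."""

    id: str
    k: int = 5

    def __post_init__(self) -> None:
        if self.id not in MODEL_IDS:
            raise ValueError(f"model id must be one of {MODEL_IDS}, got {self.id!r}")

    @property
    def term_label(self) -> str:
        return _TERM_LABELS[self.id]

    def terms(self) -> list[SmoothTerm]:
        out = [SmoothTerm(kind, vars, k=self.k) for kind, vars in _STRUCTURES[self.id]]
        out.append(SmoothTerm("random", ("bird_id",)))
        return out

    @property
    def surface_vars(self) -> tuple | None:
        st = _STRUCTURES[self.id]
        if st and st[0][0] == "tensor":
            return st[0][1]
        return None


@dataclass
class ModelFit:
    """A fitted candidate model with its comparison statistics."""

    spec: ModelSpec
    gam: GAM
    aicc: float
    edf: float
    loglik: float
    r2: float
    dev_explained: float
    n: int
    data: pd.DataFrame


def fit_flap_model(
    table: pd.DataFrame,
    spec: ModelSpec,
    family: str = "nb",
    alpha: float | None = None,
    min_rows: int = 200,
    min_birds: int = 5,
) -> ModelFit:
    """Fit one candidate model to a species' hourly flight table.

    With ``family="nb"`` and no explicit ``alpha``, the NB2 dispersion
    is estimated by moments from a Poisson null fit; pass a shared
    ``alpha`` when several candidates must sit on the same likelihood
    (as :func:`fit_all_models` does).
    """
    if len(table) < min_rows:
        raise ValueError(f"need >= {min_rows} rows, got {len(table)}")
    if table["bird_id"].nunique() < min_birds:
        raise ValueError(f"need >= {min_birds} birds, got {table['bird_id'].nunique()}")
    if family == "nb" and alpha is None:
        alpha = shared_nb_alpha(table)
    gam = GAM(ModelSpec(spec.id, spec.k).terms(), family=family, alpha=alpha or 0.0)
    try:
        gam.fit(table)
    except (np.linalg.LinAlgError, RuntimeError) as err:
        raise RuntimeError(f"Model {spec.id} ({spec.term_label}) failed: {err}") from err
    return ModelFit(
        spec=spec,
        gam=gam,
        aicc=gam.aicc_,
        edf=gam.edf_,
        loglik=gam.loglik_,
        r2=gam.r2_,
        dev_explained=gam.dev_explained_,
        n=gam.n_,
        data=table,
    )


def shared_nb_alpha(table: pd.DataFrame) -> float:
    """NB2 dispersion for a species table, from a Poisson null fit."""
    null = GAM(ModelSpec("0").terms(), family="poisson").fit(table)
    return estimate_nb_alpha(null.y_, null.mu_)


def fit_all_models(
    table: pd.DataFrame, family: str = "nb", k: int = 5
) -> dict[str, ModelFit]:
    """Fit Models 0 and I-V on identical rows with a shared dispersion."""
    alpha = shared_nb_alpha(table) if family == "nb" else None
    return {
        mid: fit_flap_model(table, ModelSpec(mid, k), family=family, alpha=alpha)
        for mid in MODEL_IDS
    }


def model_selection_table(fits: dict[str, ModelFit]) -> pd.DataFrame:
    """Rank candidate fits by AICc with Akaike weights.

    All fits must be on identical rows. Columns mirror the standard
    selection report: AICc, dAICc (0 at the best model), effective df,
    Akaike weight exp(-d/2)/sum, R2 and deviance explained.
    """
    ns = {f.n for f in fits.values()}
    if len(ns) != 1:
        raise ValueError("fits were made on different row sets")
    rows = []
    for mid, f in fits.items():
        rows.append(
            {
                "model": mid,
                "terms": f.spec.term_label,
                "AICc": f.aicc,
                "df": f.edf,
                "R2": f.r2,
                "DE": f.dev_explained,
            }
        )
    out = pd.DataFrame(rows)
    out["dAICc"] = out["AICc"] - out["AICc"].min()
    rel = np.exp(-out["dAICc"] / 2.0)
    out["weight"] = rel / rel.sum()
    out = out.sort_values("AICc", ignore_index=True)
    return out[["model", "terms", "AICc", "dAICc", "df", "weight", "R2", "DE"]]


# ---------------------------------------------------------------------------
# KDE trimming and the reduction statistic
# ---------------------------------------------------------------------------


@dataclass
class KDEMask:
    """Density-threshold mask over a 2-D covariate space."""

    kde: gaussian_kde
    threshold: float

    def __call__(self, x1, x2) -> np.ndarray:
        pts = np.vstack([np.ravel(x1), np.ravel(x2)])
        return (self.kde(pts) >= self.threshold).reshape(np.shape(x1))


def kde_mask_99(x1, x2, percentile: float = 99.0) -> KDEMask:
    """Mask retaining the densest region holding ~`percentile`% of the points.

    A Gaussian-product KDE with normal-reference (Silverman) bandwidth
    is fitted to the observed points; the region is {z : f(z) >= c}
    where c is the (100 - percentile) quantile of the density evaluated
    at the points themselves, so at least ~percentile% of observations
    fall inside (up to ties).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 100:
        raise ValueError("need at least 100 points for the KDE mask")
    if np.std(x1) == 0 or np.std(x2) == 0:
        raise ValueError("degenerate (zero-variance) dimension")
    kde = gaussian_kde(np.vstack([x1, x2]), bw_method="silverman")
    dens = kde(np.vstack([x1, x2]))
    c = np.percentile(dens, 100.0 - percentile)
    return KDEMask(kde, float(c))


@dataclass
class PredictionSurface:
    """Model predictions on a 2-D covariate grid with its KDE mask."""

    var1: str
    var2: str
    x1: np.ndarray  # grid axis 1
    x2: np.ndarray  # grid axis 2
    rate: np.ndarray  # (len(x1), len(x2)) predicted flaps/hour
    mask: np.ndarray  # same shape, True inside the KDE region

    @property
    def masked_rates(self) -> np.ndarray:
        return self.rate[self.mask]


def predict_surface(
    fit: ModelFit,
    n_grid: int = 40,
    kde_percentile: float = 99.0,
) -> PredictionSurface:
    """Evaluate a tensor-product model over its covariate grid and mask it."""
    vars2 = fit.spec.surface_vars
    if vars2 is None:
        raise ValueError(f"Model {fit.spec.id} has no 2-D surface")
    v1, v2 = vars2
    obs1 = fit.data[v1].to_numpy(dtype=float)
    obs2 = fit.data[v2].to_numpy(dtype=float)
    x1 = np.linspace(obs1.min(), obs1.max(), n_grid)
    x2 = np.linspace(obs2.min(), obs2.max(), n_grid)
    g1, g2 = np.meshgrid(x1, x2, indexing="ij")
    newdata = pd.DataFrame(
        {v1: g1.ravel(), v2: g2.ravel(), "bird_id": fit.data["bird_id"].iloc[0]}
    )
    mu = fit.gam.predict(newdata, population=True).reshape(n_grid, n_grid)
    mask = kde_mask_99(obs1, obs2, percentile=kde_percentile)(g1, g2)
    return PredictionSurface(v1, v2, x1, x2, mu, mask)


@dataclass
class ReductionResult:
    """Flap-rate reduction across the masked prediction space."""

    max_rate: float  # 95th quantile of masked predictions, flaps/hour
    min_rate: float  # 5th quantile
    reduction_pct: float  # 100 * (max - min) / max, 2 decimals

    @classmethod
    def from_quantiles(cls, max_rate: float, min_rate: float) -> "ReductionResult":
        """Reduction statistic from an already-computed quantile pair."""
        pct = 0.0 if max_rate <= 0 else round(100.0 * (max_rate - min_rate) / max_rate, 2)
        return cls(max_rate=float(max_rate), min_rate=float(min_rate), reduction_pct=pct)


def flap_reduction(
    surface: PredictionSurface | np.ndarray,
    q_low: float = 5.0,
    q_high: float = 95.0,
    min_cells: int = 20,
) -> ReductionResult:
    """Percent reduction from the 95th to the 5th quantile of predictions.

    Quantiles are taken over the KDE-masked grid cells with equal cell
    weights and linear interpolation; the reduction is
    ``100 * (max - min) / max``, reported to 2 decimals. Multiplying all
    predictions by a positive constant leaves the result unchanged.
    """
    rates = (
        surface.masked_rates if isinstance(surface, PredictionSurface) else np.asarray(surface, dtype=float)
    )
    if rates.size < min_cells:
        raise ValueError(f"need >= {min_cells} masked cells, got {rates.size}")
    hi = float(np.percentile(rates, q_high))
    lo = float(np.percentile(rates, q_low))
    pct = 0.0 if hi <= 0 else round(100.0 * (hi - lo) / hi, 2)
    return ReductionResult(max_rate=hi, min_rate=lo, reduction_pct=pct)


def conditional_profile(
    fit: ModelFit,
    free_var: str,
    n_points: int = 100,
) -> pd.DataFrame:
    """Model V predictions along one variable, the other held at its mean.

    The held variable is fixed at the mean observed value, the random
    effect at the population level; 95% pointwise intervals come from
    the penalized coefficient covariance. The free variable runs over
    the central span of its observed support.
    """
    vars2 = fit.spec.surface_vars
    if vars2 is None or free_var not in vars2:
        raise ValueError(f"{free_var!r} is not a surface variable of Model {fit.spec.id}")
    held_var = vars2[0] if vars2[1] == free_var else vars2[1]
    obs = fit.data[free_var].to_numpy(dtype=float)
    xs = np.linspace(obs.min(), obs.max(), n_points)
    newdata = pd.DataFrame(
        {
            free_var: xs,
            held_var: float(fit.data[held_var].mean()),
            "bird_id": fit.data["bird_id"].iloc[0],
        }
    )
    mu, se = fit.gam.predict(newdata, population=True, se=True)
    return pd.DataFrame(
        {
            free_var: xs,
            "rate": mu,
            "lo95": mu * np.exp(-1.96 * se),
            "hi95": mu * np.exp(1.96 * se),
        }
    )


def downsample_robustness(
    table: pd.DataFrame,
    n_birds: int = 18,
    ratio: tuple = (12, 6),
    reps: int = 100,
    seed: int | None = None,
    family: str = "nb",
    n_grid: int = 25,
) -> dict:
    """Down-sampled Model V refits: robustness of the surface to sample size.

    Each rep draws ``ratio[0]`` brood-guard and ``ratio[1]`` incubation
    birds without replacement (18 total by default, the smallest
    species' sample), refits Model V on their rows, and evaluates the
    surface on a fixed covariate grid. Returns the per-cell 5-95%
    quantile envelope across reps together with the full-data surface.
    """
    rng = np.random.default_rng(seed)
    bg = table.loc[table["stage"] == "brood-guard", "bird_id"].unique()
    inc = table.loc[table["stage"] == "incubation", "bird_id"].unique()
    if bg.size < ratio[0] or inc.size < ratio[1]:
        raise ValueError(
            f"need >= {ratio[0]} brood-guard and >= {ratio[1]} incubation birds, "
            f"have {bg.size} and {inc.size}"
        )
    full_fit = fit_flap_model(table, ModelSpec("V"), family=family)
    full_surface = predict_surface(full_fit, n_grid=n_grid)
    g1, g2 = np.meshgrid(full_surface.x1, full_surface.x2, indexing="ij")
    grid_df_base = pd.DataFrame({"windspeed": g1.ravel(), "swell_height": g2.ravel()})

    surfaces = np.empty((reps, n_grid, n_grid))
    for r in range(reps):
        birds = np.concatenate(
            [
                rng.choice(bg, size=ratio[0], replace=False),
                rng.choice(inc, size=ratio[1], replace=False),
            ]
        )
        sub = table[table["bird_id"].isin(birds)]
        fit = fit_flap_model(sub, ModelSpec("V"), family=family, min_birds=2)
        nd = grid_df_base.assign(bird_id=sub["bird_id"].iloc[0])
        surfaces[r] = fit.gam.predict(nd, population=True).reshape(n_grid, n_grid)
    lo = np.percentile(surfaces, 5.0, axis=0)
    hi = np.percentile(surfaces, 95.0, axis=0)
    return {
        "full_surface": full_surface,
        "envelope_lo": lo,
        "envelope_hi": hi,
        "surfaces": surfaces,
    }
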