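"""Flap-rate model suite: AICc, selection, KDE trimming, reduction, robustness."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from flapwave.gam import aicc
from flapwave.models import (
    ModelFit,
    ModelSpec,
    ReductionResult,
    conditional_profile,
    downsample_robustness,
    fit_all_models,
    fit_flap_model,
    flap_reduction,
    kde_mask_99,
    model_selection_table,
    predict_surface,
    shared_nb_alpha,
)
from flapwave.synth import SimConfig, gen_hourly_table


class TestAicc:
    def test_zero_edf_reduces_to_minus_two_loglik(self):
        assert aicc(-123.4, 0.0, 50) == pytest.approx(246.8)

    def test_stated_formula_arithmetic(self):
        # -2*(-100) + 2*5 + 2*5*6/(100-5-1)
        assert aicc(-100.0, 5.0, 100) == pytest.approx(210.6382978723)

    def test_approaches_aic_for_large_n(self):
        assert abs(aicc(-100.0, 5.0, 10**6) - 210.0) < 0.01

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5.0, 6)


class TestSelectionTable:
    @staticmethod
    def _fits_with_aiccs(values):
        fits = {}
        data = pd.DataFrame({"bird_id": ["b"] * 10})
        for mid, a in zip("0 I II III IV V".split(), values):
            fits[mid] = ModelFit(
                spec=ModelSpec(mid), gam=None, aicc=a, edf=5.0, loglik=0.0,
                r2=0.5, dev_explained=0.5, n=10, data=data,
            )
        return fits

    def test_equal_aicc_gives_equal_weights(self):
        table = model_selection_table(self._fits_with_aiccs([100.0] * 6))
        assert np.allclose(table["weight"], 1 / 6)
        assert np.allclose(table["dAICc"], 0.0)

    def test_twenty_unit_lead_dominates(self):
        table = model_selection_table(self._fits_with_aiccs([120, 120, 120, 120, 120, 100]))
        assert table.iloc[0]["model"] == "V"
        assert table.iloc[0]["weight"] > 0.999

    def test_weights_sum_to_one_and_track_ranking(self, rng):
        table = model_selection_table(
            self._fits_with_aiccs(list(100 + 30 * rng.random(6)))
        )
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(table["AICc"]) >= 0)
        assert np.all(np.diff(table["weight"]) <= 1e-12)


class TestReduction:
    @pytest.mark.parametrize(
        "mx,mn,expected",
        [
            (1549.0, 167.5, 89.19),
            (1952.0, 160.0, 91.80),
            (1512.0, 116.4, 92.30),
            (1043.0, 68.71, 93.41),
            (1429.0, 129.9, 90.91),
        ],
    )
    def test_quantile_pairs_give_printed_percentages(self, mx, mn, expected):
        assert ReductionResult.from_quantiles(mx, mn).reduction_pct == expected

    def test_equal_max_min_gives_zero(self):
        assert ReductionResult.from_quantiles(500.0, 500.0).reduction_pct == 0.0

    def test_scale_invariance(self, rng):
        rates = rng.gamma(3.0, 200.0, 400)
        r1 = flap_reduction(rates)
        r2 = flap_reduction(rates * 7.3)
        assert r1.reduction_pct == r2.reduction_pct

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            flap_reduction(np.ones(10))


class TestKDEMask:
    def test_observed_points_mostly_inside(self, rng):
        x = rng.normal(size=2000)
        y = rng.normal(size=2000) + 0.3 * x
        mask = kde_mask_99(x, y)
        assert mask(x, y).mean() >= 0.98

    def test_far_outlier_excluded(self, rng):
        x = rng.normal(size=500)
        y = rng.normal(size=500)
        mask = kde_mask_99(x, y)
        assert not mask(np.array([15.0]), np.array([15.0]))[0]

    def test_area_matches_analytic_gaussian_ellipse(self, rng):
        """The 99% region of a standard normal sample ~ the chi-square ellipse."""
        x = rng.normal(size=5000)
        y = rng.normal(size=5000)
        mask = kde_mask_99(x, y)
        g = np.linspace(-5, 5, 220)
        gx, gy = np.meshgrid(g, g, indexing="ij")
        cell = (g[1] - g[0]) ** 2
        area = mask(gx.ravel(), gy.ravel()).sum() * cell
        analytic = np.pi * chi2.ppf(0.99, 2)
        assert abs(area - analytic) / analytic < 0.15

    def test_degenerate_dimension_rejected(self, rng):
        with pytest.raises(ValueError):
            kde_mask_99(np.ones(200), rng.normal(size=200))


class TestModelFitting:
    def test_wind_only_truth_favors_wind_model(self):
        """With flaps driven by windspeed only, Model I beats Model II."""
        cfg = SimConfig(response_coefs=(np.log(800.0), -0.08, 0.0))
        table = gen_hourly_table(cfg, seed=21, n_birds=10, hours_per_bird=60)
        fits = fit_all_models(table)
        assert fits["I"].dev_explained > fits["II"].dev_explained
        assert fits["I"].aicc < fits["II"].aicc

    def test_both_effects_put_model_v_first(self, hourly_table):
        fits = fit_all_models(hourly_table)
        table = model_selection_table(fits)
        assert table.iloc[0]["model"] == "V"

    def test_permuting_covariate_destroys_fit(self):
        """Shuffled windspeed almost never matches the true fit's R^2."""
        cfg = SimConfig(response_coefs=(np.log(800.0), -0.08, 0.0))
        table = gen_hourly_table(cfg, seed=31, n_birds=8, hours_per_bird=50)
        alpha = shared_nb_alpha(table)
        true_fit = fit_flap_model(table, ModelSpec("I"), alpha=alpha)
        rng = np.random.default_rng(5)
        beats = 0
        for _ in range(100):
            perm = table.copy()
            perm["windspeed"] = rng.permutation(perm["windspeed"].to_numpy())
            pf = fit_flap_model(perm, ModelSpec("I"), alpha=alpha)
            beats += pf.r2 < true_fit.r2
        assert beats >= 99

    def test_null_never_beats_true_structure(self):
        """Model 0 never has lower AICc than Model V on data with real effects."""
        for seed in range(20):
            table = gen_hourly_table(
                SimConfig(seed=0), seed=500 + seed, n_birds=10, hours_per_bird=50
            )
            fits = fit_all_models(table)
            assert fits["V"].aicc < fits["0"].aicc

    def test_null_truth_rarely_rewards_complexity(self):
        """Intercept-only truth: I-V gain < 2 AICc over Model 0 in >= 80% of runs."""
        cfg = SimConfig(response_coefs=(np.log(800.0), 0.0, 0.0))
        ok = 0
        runs = 50
        for r in range(runs):
            table = gen_hourly_table(cfg, seed=1000 + r, n_birds=8, hours_per_bird=60)
            fits = fit_all_models(table)
            a0 = fits["0"].aicc
            ok += all(a0 - fits[m].aicc < 2.0 for m in "I II III IV V".split())
        assert ok / runs >= 0.8

    def test_preconditions_enforced(self, hourly_table):
        with pytest.raises(ValueError):
            fit_flap_model(hourly_table.head(100), ModelSpec("I"))
        with pytest.raises(ValueError):
            fit_flap_model(
                hourly_table[hourly_table["bird_id"].isin(["bird000", "bird001"])],
                ModelSpec("I"),
            )


@pytest.fixture(scope="module")
def v_fit(hourly_table):
    return fit_all_models(hourly_table)["V"]


class TestSurfaceAndProfile:
    def test_surface_mask_covers_observations(self, v_fit, hourly_table):
        surface = predict_surface(v_fit)
        assert surface.mask.mean() > 0.3
        reduction = flap_reduction(surface)
        assert 0 <= reduction.reduction_pct < 100
        assert reduction.min_rate <= reduction.max_rate

    def test_profile_decreasing_under_decreasing_truth(self, v_fit):
        prof = conditional_profile(v_fit, "windspeed")
        central = prof.iloc[10:90]
        assert np.all(np.diff(central["rate"]) < 0)

    def test_profile_consistent_with_surface(self, v_fit):
        """The profile at the held mean equals a direct prediction there."""
        prof = conditional_profile(v_fit, "windspeed", n_points=11)
        held = float(v_fit.data["swell_height"].mean())
        nd = pd.DataFrame(
            {
                "windspeed": prof["windspeed"],
                "swell_height": held,
                "bird_id": v_fit.data["bird_id"].iloc[0],
            }
        )
        direct = v_fit.gam.predict(nd, population=True)
        assert np.allclose(direct, prof["rate"], rtol=1e-10)

    def test_interval_width_shrinks_with_sample_size(self):
        cfg = SimConfig(seed=0)
        widths = {}
        for n_birds, hours, label in ((6, 85, "small"), (25, 200, "large")):
            table = gen_hourly_table(cfg, seed=77, n_birds=n_birds, hours_per_bird=hours)
            fit = fit_all_models(table)["V"]
            prof = conditional_profile(fit, "windspeed")
            widths[label] = np.median(prof["hi95"] - prof["lo95"])
        assert widths["large"] / widths["small"] < 1.0


class TestDownsampleRobustness:
    def test_same_seed_identical_envelopes(self, hourly_table):
        r1 = downsample_robustness(hourly_table, reps=3, seed=9)
        r2 = downsample_robustness(hourly_table, reps=3, seed=9)
        assert np.array_equal(r1["envelope_lo"], r2["envelope_lo"])
        assert np.array_equal(r1["surfaces"], r2["surfaces"])

    def test_each_rep_uses_18_distinct_birds(self, hourly_table, monkeypatch):
        seen = []
        import flapwave.models as m

        original = m.fit_flap_model

        def spy(table, spec, **kw):
            seen.append(set(table["bird_id"].unique()))
            return original(table, spec, **kw)

        monkeypatch.setattr(m, "fit_flap_model", spy)
        downsample_robustness(hourly_table, reps=4, seed=3)
        for birds in seen[1:]:  # first call is the full-data fit
            assert len(birds) == 18

    def test_full_surface_inside_envelope(self, hourly_table):
        rob = downsample_robustness(hourly_table, reps=12, seed=2)
        full = rob["full_surface"].rate
        inside = (full >= rob["envelope_lo"]) & (full <= rob["envelope_hi"])
        assert inside.mean() >= 0.8

    def test_too_few_stage_birds_rejected(self, hourly_table):
        sub = hourly_table[hourly_table["bird_id"].isin(hourly_table["bird_id"].unique()[:10])]
        with pytest.raises(ValueError):
            downsample_robustness(sub, reps=2, seed=0)
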