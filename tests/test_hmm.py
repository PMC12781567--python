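"""Movement-state HMM: metrics, oracle equivalence, recovery, immersion check."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flapwave.hmm import (
    HMMParams,
    StateSequence,
    StepSeries,
    _emission_loglik,
    decode_states,
    fit_hmm,
    hmm_loglik,
    track_steps_angles,
    validate_against_immersion,
)

WELL_SEPARATED = HMMParams(
    tpm=np.array([[0.8, 0.1, 0.1], [0.15, 0.7, 0.15], [0.05, 0.15, 0.8]]),
    step_mean=np.array([0.1, 3.0, 8.0]),
    step_sd=np.array([0.08, 1.5, 3.0]),
    turn_mean=np.zeros(3),
    turn_kappa=np.array([0.3, 1.0, 15.0]),
    init=np.array([1 / 3, 1 / 3, 1 / 3]),
)


def simulate(params: HMMParams, T: int, rng) -> tuple[StepSeries, np.ndarray]:
    states = np.empty(T, dtype=int)
    s = rng.choice(3, p=params.init)
    for t in range(T):
        states[t] = s
        s = rng.choice(3, p=params.tpm[s])
    shape = (params.step_mean / params.step_sd) ** 2
    scale = params.step_sd**2 / params.step_mean
    steps = rng.gamma(shape[states], scale[states])
    turns = rng.vonmises(params.turn_mean[states[1:]], params.turn_kappa[states[1:]])
    return StepSeries(steps, turns), states


def brute_force(series: StepSeries, params: HMMParams):
    """Exhaustive enumeration over all 3^T paths: total and best path."""
    logb = _emission_loglik(series, params)
    T = len(series)
    total, best, best_path = -np.inf, -np.inf, None
    for path in itertools.product(range(3), repeat=T):
        lp = np.log(params.init[path[0]]) + logb[0, path[0]]
        for t in range(1, T):
            lp += np.log(params.tpm[path[t - 1], path[t]]) + logb[t, path[t]]
        total = np.logaddexp(total, lp)
        if lp > best:
            best, best_path = lp, path
    return total, best_path


class TestStepsAngles:
    def test_one_degree_longitude_on_equator(self):
        track = pd.DataFrame(
            {
                "timestamp": pd.date_range("2022-01-01", periods=3, freq="10min"),
                "lat": [0.0, 0.0, 0.0],
                "lon": [0.0, 1.0, 2.0],
            }
        )
        s = track_steps_angles(track)
        assert np.allclose(s.steps, 111.19, atol=0.01)

    def test_collinear_fixes_give_zero_turn(self):
        track = pd.DataFrame(
            {
                "timestamp": pd.date_range("2022-01-01", periods=3, freq="10min"),
                "lat": [0.0, 0.0, 0.0],
                "lon": [0.0, 0.5, 1.0],
            }
        )
        s = track_steps_angles(track)
        assert np.allclose(s.turns, 0.0, atol=1e-9)

    def test_stationary_bird_emits_missing_turns(self):
        track = pd.DataFrame(
            {
                "timestamp": pd.date_range("2022-01-01", periods=4, freq="10min"),
                "lat": [10.0] * 4,
                "lon": [20.0] * 4,
            }
        )
        s = track_steps_angles(track)
        assert np.allclose(s.steps, 0.0)
        assert np.all(np.isnan(s.turns))

    def test_too_few_fixes_rejected(self):
        track = pd.DataFrame(
            {
                "timestamp": pd.date_range("2022-01-01", periods=2, freq="10min"),
                "lat": [0.0, 1.0],
                "lon": [0.0, 1.0],
            }
        )
        with pytest.raises(ValueError):
            track_steps_angles(track)


class TestOracleEquivalence:
    def test_forward_and_viterbi_match_enumeration(self, rng):
        """Forward likelihood and Viterbi path equal the 3^T-path oracle."""
        for _ in range(20):
            T = int(rng.integers(2, 9))
            series, _ = simulate(WELL_SEPARATED, T, rng)
            ll = hmm_loglik(series, WELL_SEPARATED)
            total, best_path = brute_force(series, WELL_SEPARATED)
            assert np.isclose(ll, total, atol=1e-8)
            assert tuple(decode_states(WELL_SEPARATED, series).labels) == best_path

    def test_relabeling_leaves_likelihood_invariant(self, rng):
        series, _ = simulate(WELL_SEPARATED, 50, rng)
        perm = np.array([2, 0, 1])
        permuted = HMMParams(
            WELL_SEPARATED.tpm[np.ix_(perm, perm)],
            WELL_SEPARATED.step_mean[perm],
            WELL_SEPARATED.step_sd[perm],
            WELL_SEPARATED.turn_mean[perm],
            WELL_SEPARATED.turn_kappa[perm],
            WELL_SEPARATED.init[perm],
        )
        assert np.isclose(
            hmm_loglik(series, WELL_SEPARATED), hmm_loglik(series, permuted)
        )


class TestFitting:
    def test_parameter_recovery_on_well_separated_truth(self, rng):
        """2000 intervals: step means within 10%, tpm within 0.05, decode >= 95%."""
        series, states = simulate(WELL_SEPARATED, 2000, rng)
        params, ll = fit_hmm(series, n_starts=8, seed=0)
        assert np.all(
            np.abs(params.step_mean - WELL_SEPARATED.step_mean)
            / WELL_SEPARATED.step_mean
            < 0.10
        )
        assert np.max(np.abs(params.tpm - WELL_SEPARATED.tpm)) < 0.05
        decoded = decode_states(params, series)
        assert (decoded.labels == states).mean() >= 0.95

    def test_straight_track_decodes_as_commute(self):
        """Near-deterministic straight fast movement is called commuting."""
        T = 60
        series = StepSeries(np.full(T, 8.0), np.zeros(T - 1))
        decoded = decode_states(WELL_SEPARATED, series)
        assert np.all(decoded.labels == 2)

    def test_single_state_data_matches_one_state_fit(self, rng):
        """On iid single-state data the HMM gains almost nothing over 1 state."""
        n = 200
        steps = rng.gamma(4.0, 0.75, n)  # mean 3 km
        turns = rng.vonmises(0.0, 1.0, n - 1)
        series = StepSeries(steps, turns)
        params, ll3 = fit_hmm(series, n_starts=6, seed=1)
        a, _, scale = stats.gamma.fit(steps, floc=0)
        ll1 = stats.gamma.logpdf(steps, a, scale=scale).sum()
        kappa, _, _ = stats.vonmises.fit(turns, fscale=1)
        ll1 += stats.vonmises.logpdf(turns, kappa).sum()
        assert ll3 >= ll1 - 1e-6  # the 3-state model nests the 1-state fit
        # spurious mixture gain is bounded (order extra-params/2, not O(n))
        assert (ll3 - ll1) / n < 0.1

    def test_too_few_intervals_rejected(self, rng):
        series, _ = simulate(WELL_SEPARATED, 50, rng)
        with pytest.raises(ValueError):
            fit_hmm(series, n_starts=1, seed=0)


class TestImmersionValidation:
    @staticmethod
    def _states_and_log(n_rest: int, flip: float, seed: int):
        times = pd.date_range("2022-01-01", periods=n_rest, freq="10min")
        states = StateSequence(np.zeros(n_rest, dtype=int), times=times)
        rng = np.random.default_rng(seed)
        flips = rng.random(n_rest) < flip
        rows = [
            (t, t + pd.Timedelta(minutes=10), "dry" if f else "wet")
            for t, f in zip(times, flips)
        ]
        imm = pd.DataFrame(rows, columns=["start", "end", "state"])
        return states, imm

    def test_perfect_immersion_gives_full_agreement(self):
        states, imm = self._states_and_log(50, 0.0, 0)
        assert validate_against_immersion(states, imm) == 1.0

    def test_all_dry_gives_zero(self):
        states, imm = self._states_and_log(50, 1.0, 0)
        assert validate_against_immersion(states, imm) == 0.0

    def test_two_percent_flips_give_binomial_agreement(self):
        """1000 rest intervals at 2% flip error: agreement 0.98 +/- 0.01."""
        states, imm = self._states_and_log(1000, 0.02, 7)
        agreement = validate_against_immersion(states, imm)
        assert abs(agreement - 0.98) <= 0.01

    def test_short_wet_records_ignored(self):
        times = pd.date_range("2022-01-01", periods=2, freq="10min")
        states = StateSequence(np.zeros(2, dtype=int), times=times)
        imm = pd.DataFrame(
            {
                "start": [times[0], times[1]],
                "end": [times[0] + pd.Timedelta(seconds=3), times[1] + pd.Timedelta(minutes=10)],
                "state": ["wet", "wet"],
            }
        )
        # the 3-second record is below the two-sample minimum and is dropped
        assert validate_against_immersion(states, imm) == 0.5

    def test_no_rest_intervals_is_missing(self):
        times = pd.date_range("2022-01-01", periods=5, freq="10min")
        states = StateSequence(np.full(5, 2, dtype=int), times=times)
        imm = pd.DataFrame(
            {"start": [times[0]], "end": [times[-1]], "state": ["wet"]}
        )
        assert np.isnan(validate_against_immersion(states, imm))
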