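"""Movement-state segmentation with a 3-state hidden Markov model.

Tracks interpolated to 10-minute fixes are reduced to step lengths and
turn angles, and a 3-state HMM — resting on water, foraging, commuting —
is fitted to those metrics pooled across birds. Emissions are gamma
(step length, km) and von Mises (turn angle, radians); the two flight
states are grouped downstream when flap rates are analysed. Decoded
rest states can be validated against leg-mounted immersion (wet/dry)
records.

Fitting maximises the forward-algorithm log-likelihood directly by
quasi-Newton optimisation from several random starts, which keeps the
likelihood identical to the exhaustive-enumeration oracle used in the
test-suite. States are relabeled after fitting so that mean step length
orders rest < forage < commute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, i0e

from .geo import haversine_km, initial_bearing

__all__ = [
    "STATE_NAMES",
    "StepSeries",
    "HMMParams",
    "StateSequence",
    "track_steps_angles",
    "hmm_loglik",
    "fit_hmm",
    "decode_states",
    "validate_against_immersion",
]

STATE_NAMES = ("rest", "forage", "commute")
STEP_FLOOR_KM = 0.001  # 1 m floor replacing exact-zero steps


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class StepSeries:
    """Step lengths (km per 10-min interval) and turn angles (radians).

    There is one fewer turn than steps; missing values (track gaps,
    undefined turns at stationary fixes) are NaN and contribute nothing
    to the likelihood.
    """

    steps: np.ndarray
    turns: np.ndarray
    times: pd.DatetimeIndex | None = None
    bird_id: str = ""

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=float)
        self.turns = np.asarray(self.turns, dtype=float)
        if self.turns.size != max(self.steps.size - 1, 0):
            raise ValueError("expected one fewer turn than steps")
        valid = self.steps[np.isfinite(self.steps)]
        if np.any(valid < 0):
            raise ValueError("step lengths must be non-negative")

    def __len__(self) -> int:
        return self.steps.size


@dataclass
class HMMParams:
    """3-state HMM parameters: transition matrix plus emission parameters."""

    tpm: np.ndarray
    step_mean: np.ndarray
    step_sd: np.ndarray
    turn_mean: np.ndarray
    turn_kappa: np.ndarray
    init: np.ndarray

    def __post_init__(self) -> None:
        self.tpm = np.asarray(self.tpm, dtype=float)
        for name in ("step_mean", "step_sd", "turn_mean", "turn_kappa", "init"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.tpm.shape != (3, 3):
            raise ValueError("tpm must be 3x3")
        if np.any(np.abs(self.tpm.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("tpm rows must sum to 1")
        if np.any(self.step_mean <= 0) or np.any(self.step_sd <= 0):
            raise ValueError("gamma means and sds must be positive")
        if np.any(self.turn_kappa < 0):
            raise ValueError("von Mises kappa must be >= 0")


@dataclass
class StateSequence:
    """Decoded per-interval state labels (0=rest, 1=forage, 2=commute)."""

    labels: np.ndarray
    times: pd.DatetimeIndex | None = None
    bird_id: str = ""
    interval_min: int = 10

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and not np.all(np.isin(self.labels, [0, 1, 2])):
            raise ValueError("labels must be in {0, 1, 2}")

    @property
    def names(self) -> np.ndarray:
        return np.array(STATE_NAMES)[self.labels]

    @property
    def flight(self) -> np.ndarray:
        """True where the bird is in a flight state (forage or commute)."""
        return self.labels >= 1


# ---------------------------------------------------------------------------
# step/turn metrics
# ---------------------------------------------------------------------------


def track_steps_angles(track: pd.DataFrame) -> StepSeries:
    """Compute step lengths and turn angles from a 10-min interpolated track.

    Steps are great-circle (haversine) distances between consecutive
    fixes; turns are the signed change in initial bearing between
    consecutive steps, wrapped to (-pi, pi]. A turn is undefined (NaN)
    when either adjacent step is zero or a position is missing.
    """
    if len(track) < 3:
        raise ValueError("need at least 3 fixes to form steps and turns")
    lat = track["lat"].to_numpy(dtype=float)
    lon = track["lon"].to_numpy(dtype=float)
    steps = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    bearings = initial_bearing(lat[:-1], lon[:-1], lat[1:], lon[1:])
    bearings = np.where(steps > 0, bearings, np.nan)
    d = np.radians(bearings[1:] - bearings[:-1])
    turns = np.mod(-d + np.pi, 2 * np.pi)  # wrap...
    turns = -(turns - np.pi)  # ...to (-pi, pi]
    times = None
    if "timestamp" in track.columns:
        times = pd.DatetimeIndex(track["timestamp"])[:-1]
    bird = str(track["bird_id"].iloc[0]) if "bird_id" in track.columns else ""
    return StepSeries(steps, turns, times=times, bird_id=bird)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

try:  # jit the recursions when numba is present; plain numpy otherwise
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally installed
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _forward_core(logb: np.ndarray, logA: np.ndarray, loginit: np.ndarray) -> float:
    T, S = logb.shape
    alpha = loginit + logb[0]
    for t in range(1, T):
        new = np.empty(S)
        for j in range(S):
            m = -np.inf
            for i in range(S):
                v = alpha[i] + logA[i, j]
                if v > m:
                    m = v
            s = 0.0
            for i in range(S):
                s += np.exp(alpha[i] + logA[i, j] - m)
            new[j] = m + np.log(s) + logb[t, j]
        alpha = new
    m = np.max(alpha)
    return m + np.log(np.sum(np.exp(alpha - m)))


@njit(cache=True)
def _viterbi_core(logb: np.ndarray, logA: np.ndarray, loginit: np.ndarray) -> np.ndarray:
    T, S = logb.shape
    delta = loginit + logb[0]
    back = np.zeros((T, S), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(S)
        for j in range(S):
            best = -np.inf
            arg = 0
            for i in range(S):
                v = delta[i] + logA[i, j]
                if v > best:  # strict: ties resolve to the lower state index
                    best = v
                    arg = i
            new[j] = best + logb[t, j]
            back[t, j] = arg
        delta = new
    path = np.zeros(T, dtype=np.int64)
    best = -np.inf
    for j in range(S):
        if delta[j] > best:
            best = delta[j]
            path[T - 1] = j
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def _emission_loglik(series: StepSeries, params: HMMParams) -> np.ndarray:
    """Per-interval, per-state emission log-density (T, 3); NaN obs add 0."""
    steps = np.maximum(series.steps, STEP_FLOOR_KM)
    T = steps.size
    turn_obs = np.full(T, np.nan)
    if series.turns.size:
        turn_obs[1:] = series.turns
    mean, sd = params.step_mean, params.step_sd
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    logb = np.zeros((T, 3))
    fin = np.isfinite(steps)
    x = steps[fin, None]
    logb[fin] += (
        (shape - 1.0) * np.log(x) - x / scale - gammaln(shape) - shape * np.log(scale)
    )
    fin_t = np.isfinite(turn_obs)
    k = params.turn_kappa
    xt = turn_obs[fin_t, None]
    log_i0 = np.log(i0e(k)) + k
    logb[fin_t] += k * np.cos(xt - params.turn_mean) - np.log(2 * np.pi) - log_i0
    return logb


def hmm_loglik(series_list: list[StepSeries] | StepSeries, params: HMMParams) -> float:
    """Forward-algorithm log-likelihood, summed over independent sequences."""
    if isinstance(series_list, StepSeries):
        series_list = [series_list]
    with np.errstate(divide="ignore"):
        logA = np.log(params.tpm)
        loginit = np.log(params.init)
    total = 0.0
    for s in series_list:
        logb = _emission_loglik(s, params)
        total += float(_forward_core(logb, logA, loginit))
    return total


def _stationary(tpm: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(tpm.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.abs(np.real(vecs[:, i]))
    return v / v.sum()


def _unpack(theta: np.ndarray) -> HMMParams:
    tpm = np.empty((3, 3))
    for r in range(3):
        logits = np.array([0.0, theta[2 * r], theta[2 * r + 1]])
        e = np.exp(logits - logits.max())
        p = e / e.sum()
        # diagonal entry first, then the two off-diagonals in column order
        cols = [r] + [c for c in range(3) if c != r]
        tpm[r, cols] = p
    step_mean = np.exp(theta[6:9])
    step_sd = np.exp(theta[9:12])
    turn_mean = theta[12:15]
    turn_kappa = np.exp(theta[15:18])
    return HMMParams(tpm, step_mean, step_sd, turn_mean, turn_kappa, _stationary(tpm))


def _relabel(params: HMMParams) -> HMMParams:
    order = np.argsort(params.step_mean)
    return HMMParams(
        params.tpm[np.ix_(order, order)],
        params.step_mean[order],
        params.step_sd[order],
        params.turn_mean[order],
        params.turn_kappa[order],
        params.init[order],
    )


def fit_hmm(
    series_list: list[StepSeries] | StepSeries,
    n_starts: int = 25,
    seed: int | None = None,
) -> tuple[HMMParams, float]:
    """Fit the 3-state HMM by direct likelihood maximisation.

    Pooled fitting treats birds as independent sequences (likelihoods
    sum; the chain does not bridge trips). Starts are drawn around
    data-quantile initial values; the best of ``n_starts`` converged
    fits is returned, relabeled so step means order rest < forage <
    commute, together with its log-likelihood.
    """
    if isinstance(series_list, StepSeries):
        series_list = [series_list]
    all_steps = np.concatenate([np.maximum(s.steps, STEP_FLOOR_KM) for s in series_list])
    all_steps = all_steps[np.isfinite(all_steps)]
    if all_steps.size < 100:
        raise ValueError("need at least 100 intervals to fit the HMM")
    rng = np.random.default_rng(seed)
    q = np.quantile(all_steps, [0.15, 0.5, 0.85])
    q = np.maximum(q, STEP_FLOOR_KM * 2)

    def nll(theta: np.ndarray) -> float:
        try:
            p = _unpack(theta)
        except ValueError:
            return 1e12
        ll = hmm_loglik(series_list, p)
        return 1e12 if not np.isfinite(ll) else -ll

    best: tuple[float, np.ndarray] | None = None
    n_fail = 0
    for _ in range(max(1, n_starts)):
        theta0 = np.concatenate(
            [
                rng.normal(-1.5, 0.5, size=6),  # tpm off-diagonal logits
                np.log(q) + rng.normal(0, 0.3, size=3),  # step means
                np.log(q * 0.6) + rng.normal(0, 0.3, size=3),  # step sds
                rng.normal(0, 0.3, size=3),  # turn means
                rng.normal(0, 0.7, size=3),  # log kappas
            ]
        )
        res = minimize(nll, theta0, method="L-BFGS-B", options={"maxiter": 300})
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            n_fail += 1
            continue
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x)
    if best is None:
        raise RuntimeError(
            f"HMM optimisation failed on all {n_starts} starts ({n_fail} rejected)"
        )
    params = _relabel(_unpack(best[1]))
    return params, -best[0]


def decode_states(params: HMMParams, series: StepSeries) -> StateSequence:
    """Viterbi most-probable state path; ties break toward the lower index."""
    with np.errstate(divide="ignore"):
        logA = np.log(params.tpm)
        loginit = np.log(params.init)
    logb = _emission_loglik(series, params)
    path = np.asarray(_viterbi_core(logb, logA, loginit))
    return StateSequence(path, times=series.times, bird_id=series.bird_id)


# ---------------------------------------------------------------------------
# immersion validation
# ---------------------------------------------------------------------------


def validate_against_immersion(
    states: StateSequence,
    immersion: pd.DataFrame,
    min_wet_s: float = 6.0,
) -> float:
    """Fraction of HMM-rest intervals that the immersion log calls on-water.

    A 10-minute interval is immersion-on-water if any wet record of
    duration >= ``min_wet_s`` (two 3-s samples) overlaps it. Returns
    ``|HMM-rest AND wet| / |HMM-rest|``, or NaN when the decoded track
    has no rest intervals.
    """
    if states.times is None:
        raise ValueError("state sequence carries no timestamps")
    wet = immersion[immersion["state"].str.lower() == "wet"].copy()
    wet_start = pd.to_datetime(wet["start"]).to_numpy()
    wet_end = pd.to_datetime(wet["end"]).to_numpy()
    dur = (wet_end - wet_start) / np.timedelta64(1, "s")
    keep = dur >= min_wet_s
    wet_start, wet_end = wet_start[keep], wet_end[keep]
    order = np.argsort(wet_start)
    wet_start, wet_end = wet_start[order], wet_end[order]

    rest_idx = np.flatnonzero(states.labels == 0)
    if rest_idx.size == 0:
        return float("nan")
    iv_start = states.times.to_numpy()[rest_idx]
    iv_end = iv_start + np.timedelta64(states.interval_min * 60, "s")
    # wet records are non-overlapping, so sorting by start also sorts ends;
    # an interval overlaps some wet record iff the first record ending after
    # the interval starts also begins before the interval ends
    hits = np.zeros(rest_idx.size, dtype=bool)
    for n in range(rest_idx.size):
        lo = np.searchsorted(wet_end, iv_start[n], side="right")
        hits[n] = lo < wet_start.size and wet_start[lo] < iv_end[n]
    return float(hits.mean())
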