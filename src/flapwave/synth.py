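"""Synthetic biologging cohorts with known ground truth.

Generates every input stream the pipeline consumes — 25 Hz tri-axial
accelerometer traces, 10-minute GPS tracks from a 3-state movement
model, 3-second immersion (wet/dry) logs, and hourly gridded wind/swell
fields — together with the ground truth (state sequence, wingbeat
times, hourly counts, response coefficients) needed to test each stage.

The generative model mirrors the structure the analysis assumes: tracks
follow a 3-state Markov chain (rest on water / forage / commute) with
per-state gamma step lengths and von Mises turn angles; wingbeats are
positive half-sine bursts riding on a noisy 1 g heave baseline with a
slow soaring undulation; hourly expected flap counts follow a log-linear
response exp(b0 + b1*windspeed + b2*swell_height) modulated by a
per-bird lognormal random effect, so model-recovery tests have a known
target. Everything is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .accel import AccelTrace
from .geo import destination_point, initial_bearing
from .trackenv import EnvGrid, extract_env

__all__ = [
    "EnvGridSpec",
    "SimConfig",
    "GroundTruth",
    "BirdData",
    "Cohort",
    "gen_track",
    "gen_accel_trace",
    "gen_env_grid",
    "gen_cohort",
    "gen_hourly_table",
]

STATE_REST, STATE_FORAGE, STATE_COMMUTE = 0, 1, 2

# Bird Island, South Georgia — default colony for the synthetic cohorts
DEFAULT_COLONY = (-54.0, -38.05)


@dataclass
class EnvGridSpec:
    """Extent, resolution and statistics of the synthetic environment grid."""

    lat_min: float = -64.0
    lat_max: float = -44.0
    lon_min: float = -56.0
    lon_max: float = -20.0
    resolution: float = 0.5  # degrees
    smoothness: float = 2.0  # spatial correlation scale, degrees
    time_smoothness_h: float = 3.0
    wind_mean: float = 8.0  # m/s, mean zonal (u) component
    wind_sd: float = 3.0  # m/s, per-component field sd
    swell_mean: float = 2.5  # m
    swell_sd: float = 0.8  # m
    swell_dir_mean: float = 270.0  # degrees, prevailing from the west
    swell_dir_sd: float = 40.0
    constant: dict | None = None  # e.g. {"u10": 3, "v10": 4, "swh": 2, "mwd": 270}

    def validate(self) -> None:
        if self.resolution <= 0:
            raise ValueError("grid resolution must be positive")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("grid extent is empty")


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort generator.

    Defaults follow the resolutions of the field deployment the pipeline
    targets: 25 Hz accelerometry, 10-minute GPS, 3-second immersion
    sampling, ~3 Hz wingbeats of ~1.2 g riding on 0.15 g sensor noise,
    and hourly 0.5-degree environment grids.
    """

    seed: int = 0
    n_birds: int = 5
    trip_hours: float = 48.0
    accel_rate: float = 25.0
    gps_interval: float = 10.0  # minutes
    flap_freq: float = 3.0  # Hz
    flap_amp: float = 1.2  # g
    noise_sd: float = 0.15  # g
    state_tpm: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.85, 0.10, 0.05], [0.10, 0.80, 0.10], [0.05, 0.10, 0.85]]
        )
    )
    step_means: tuple = (0.1, 3.0, 8.0)  # km per 10 min, per state
    step_sds: tuple = (0.08, 1.5, 3.0)
    turn_concentrations: tuple = (0.3, 1.0, 15.0)  # von Mises kappa per state
    response_coefs: tuple = (7.5, -0.035, -0.2)  # log flaps/h ~ 1, wind km/h, swell m
    bird_sd: float = 0.25  # lognormal random-intercept sd on the hourly rate
    env_grid_spec: EnvGridSpec = field(default_factory=EnvGridSpec)
    colony: tuple = DEFAULT_COLONY
    start_time: str = "2022-01-05T00:00:00"
    bout_duration_s: float = 3.0
    default_hourly_flaps: float = 800.0  # flight flap rate when no response is wired in
    undulation_amp: float = 0.1  # g, soaring undulation
    undulation_freq: tuple = (0.1, 0.3)  # Hz band of the undulation
    within_bout_cv: float = 0.0  # optional within-bout wingbeat-frequency variability
    immersion_flip_error: float = 0.0  # per-10-min-interval wet/dry flip probability
    immersion_resolution_s: float = 3.0

    def validate(self) -> None:
        tpm = np.asarray(self.state_tpm, dtype=float)
        if tpm.shape != (3, 3) or np.any(tpm < 0):
            raise ValueError("state_tpm must be a non-negative 3x3 matrix")
        if np.any(np.abs(tpm.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("state_tpm rows must sum to 1 within 1e-12")
        if self.flap_amp <= self.noise_sd:
            raise ValueError("flap_amp must exceed noise_sd")
        if self.flap_freq >= self.accel_rate / 2:
            raise ValueError("flap_freq must be below the Nyquist frequency")
        self.env_grid_spec.validate()

    @property
    def n_intervals(self) -> int:
        return int(round(self.trip_hours * 60 / self.gps_interval))


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    states: np.ndarray  # per-10-min labels, 0=rest 1=forage 2=commute
    state_times: pd.DatetimeIndex
    flap_times: np.ndarray  # POSIX seconds of true wingbeat peaks
    hourly_flaps: pd.Series  # true counts per clock hour
    response_coefs: tuple


@dataclass
class BirdData:
    bird_id: str
    track: pd.DataFrame  # 10-min GPS fixes
    accel: AccelTrace
    immersion: pd.DataFrame  # start, end, state in {wet, dry}
    truth: GroundTruth
    stage: str = "incubation"
    complete_trip: bool = True


@dataclass
class Cohort:
    config: SimConfig
    env: EnvGrid
    birds: dict[str, BirdData]


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


def _markov_chain(tpm: np.ndarray, n: int, start: int, rng) -> np.ndarray:
    states = np.empty(n, dtype=int)
    s = start
    cum = np.cumsum(tpm, axis=1)
    u = rng.random(n)
    for t in range(n):
        states[t] = s
        s = int(np.searchsorted(cum[s], u[t]))
    return states


def gen_track(config: SimConfig, seed: int) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one foraging trip as a 3-state correlated random walk.

    Positions are produced at the GPS interval from per-state gamma step
    lengths and von Mises turn angles; the trip starts at the colony,
    and in the final 20% of intervals the heading is steered back toward
    the colony so trips complete. The returned ground truth carries the
    state sequence (flap fields are filled by :func:`gen_accel_trace`).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_intervals
    tpm = np.asarray(config.state_tpm, dtype=float)
    states = _markov_chain(tpm, n, STATE_COMMUTE, rng)

    means = np.asarray(config.step_means, dtype=float)
    sds = np.asarray(config.step_sds, dtype=float)
    shape = (means / sds) ** 2
    scale = sds**2 / means
    steps = rng.gamma(shape[states], scale[states])
    kappas = np.asarray(config.turn_concentrations, dtype=float)
    turns = rng.vonmises(0.0, kappas[states])

    lat = np.empty(n + 1)
    lon = np.empty(n + 1)
    lat[0], lon[0] = config.colony
    bearing = rng.uniform(0.0, 360.0)
    homeward_from = int(np.ceil(0.8 * n))
    for t in range(n):
        if t >= homeward_from:
            home = float(initial_bearing(lat[t], lon[t], *config.colony))
            bearing = home + np.degrees(turns[t]) * 0.3
        else:
            bearing = (bearing + np.degrees(turns[t])) % 360.0
        lat[t + 1], lon[t + 1] = destination_point(lat[t], lon[t], bearing, steps[t])

    t0 = pd.Timestamp(config.start_time)
    times = pd.date_range(t0, periods=n + 1, freq=f"{int(config.gps_interval)}min")
    track = pd.DataFrame({"timestamp": times, "lat": lat, "lon": lon})
    truth = GroundTruth(
        states=states,
        state_times=times[:-1],
        flap_times=np.empty(0),
        hourly_flaps=pd.Series(dtype=int),
        response_coefs=config.response_coefs,
    )
    return track, truth


# ---------------------------------------------------------------------------
# accelerometry
# ---------------------------------------------------------------------------


def gen_accel_trace(
    truth: GroundTruth,
    config: SimConfig,
    seed: int,
    expected_flaps_per_interval: np.ndarray | None = None,
) -> tuple[AccelTrace, np.ndarray]:
    """Synthesize a heave-axis trace with planted wingbeat bursts.

    The heave channel is a 1 g gravity baseline plus Gaussian sensor
    noise plus, in flight states, a low-frequency (0.1-0.3 Hz) soaring
    undulation. Wingbeats come in bouts: each bout is a train of
    positive half-sine spikes at ``flap_freq`` with amplitude
    ``flap_amp``; the per-interval bout count is Poisson with mean set
    by the expected flap count, so hourly totals carry the programmed
    environmental signal. Rest intervals contain no flaps. Returns the
    trace and the true peak instants (also written into ``truth``).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n_int = truth.states.size
    if expected_flaps_per_interval is not None and (
        len(expected_flaps_per_interval) != n_int
    ):
        raise ValueError("expected flap counts do not match the state sequence length")
    rate = config.accel_rate
    interval_s = config.gps_interval * 60.0
    n_samples = int(round(n_int * interval_s * rate))
    t0 = truth.state_times[0].timestamp()
    times = t0 + np.arange(n_samples) / rate

    az = 1.0 + rng.normal(0.0, config.noise_sd, n_samples)
    ax = rng.normal(0.0, config.noise_sd, n_samples)
    ay = rng.normal(0.0, config.noise_sd, n_samples)

    flaps_per_bout = max(1, int(round(config.bout_duration_s * config.flap_freq)))
    flap_times: list[np.ndarray] = []
    samp_per_int = int(round(interval_s * rate))
    for i in range(n_int):
        if truth.states[i] == STATE_REST:
            continue
        i0 = i * samp_per_int
        # soaring undulation: slow sinusoid the LULU stage must reject
        f_und = rng.uniform(*config.undulation_freq)
        phase = rng.uniform(0, 2 * np.pi)
        tt = np.arange(samp_per_int) / rate
        az[i0 : i0 + samp_per_int] += config.undulation_amp * np.sin(
            2 * np.pi * f_und * tt + phase
        )
        if expected_flaps_per_interval is not None:
            expected = float(expected_flaps_per_interval[i])
        else:
            expected = config.default_hourly_flaps * interval_s / 3600.0
        n_bouts = rng.poisson(expected / flaps_per_bout)
        if n_bouts == 0:
            continue
        # non-overlapping bout slots so planted peaks never collide
        slot = config.bout_duration_s + 1.0
        n_slots = int(interval_s // slot)
        n_bouts = min(n_bouts, n_slots)
        chosen = rng.choice(n_slots, size=n_bouts, replace=False)
        jitter = rng.uniform(0, slot - config.bout_duration_s, size=n_bouts)
        for s_idx, jit in zip(chosen, jitter):
            b0 = i * interval_s + s_idx * slot + jit
            freq = config.flap_freq
            if config.within_bout_cv > 0:
                freq *= max(0.2, 1.0 + rng.normal(0, config.within_bout_cv))
            k = np.arange(flaps_per_bout)
            peaks = b0 + (k + 0.25) / freq
            dur = flaps_per_bout / freq
            j0 = int(np.ceil(b0 * rate))
            j1 = min(int(np.floor((b0 + dur) * rate)), n_samples - 1)
            if j1 <= j0:
                continue
            tseg = np.arange(j0, j1 + 1) / rate
            az[j0 : j1 + 1] += config.flap_amp * np.maximum(
                0.0, np.sin(2 * np.pi * freq * (tseg - b0))
            )
            flap_times.append(t0 + peaks[peaks < (b0 + dur)])

    ft = np.sort(np.concatenate(flap_times)) if flap_times else np.empty(0)
    truth.flap_times = ft
    hours = pd.date_range(
        truth.state_times[0].floor("h"),
        periods=int(np.ceil(config.trip_hours)),
        freq="h",
    )
    edges = np.append(hours.asi8 / 1e9, (hours[-1] + pd.Timedelta(hours=1)).value / 1e9)
    counts, _ = np.histogram(ft, bins=edges)
    truth.hourly_flaps = pd.Series(counts, index=hours, name="flaps")
    trace = AccelTrace(times, ax, ay, az, rate=rate)
    return trace, ft


# ---------------------------------------------------------------------------
# environment grid
# ---------------------------------------------------------------------------


def _smooth_field(rng, shape, spec: EnvGridSpec) -> np.ndarray:
    """Unit-variance Gaussian random field, smooth in time and space."""
    noise = rng.standard_normal(shape)
    sigma = (
        spec.time_smoothness_h,
        spec.smoothness / spec.resolution,
        spec.smoothness / spec.resolution,
    )
    f = gaussian_filter(noise, sigma=sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def gen_env_grid(
    spec: EnvGridSpec, seed: int, hours: pd.DatetimeIndex
) -> EnvGrid:
    """Generate hourly wind and swell fields on a regular lat/lon grid.

    Fields are smooth Gaussian random surfaces; the swell-height field
    is drawn from noise independent of the wind components (swell is
    generated by distant weather systems, not local wind), and is
    clamped at zero. With ``spec.constant`` set, every cell holds the
    given constant values — handy for exactness tests.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    lats = np.arange(spec.lat_min, spec.lat_max + spec.resolution / 2, spec.resolution)
    lons = np.arange(spec.lon_min, spec.lon_max + spec.resolution / 2, spec.resolution)
    shape = (len(hours), len(lats), len(lons))
    if spec.constant is not None:
        c = spec.constant
        data = {
            v: (("time", "lat", "lon"), np.full(shape, float(c[v])))
            for v in ("u10", "v10", "swh", "mwd")
        }
    else:
        u = spec.wind_mean + spec.wind_sd * _smooth_field(rng, shape, spec)
        v = spec.wind_sd * _smooth_field(rng, shape, spec)
        swh = np.maximum(
            0.0, spec.swell_mean + spec.swell_sd * _smooth_field(rng, shape, spec)
        )
        mwd = np.mod(
            spec.swell_dir_mean + spec.swell_dir_sd * _smooth_field(rng, shape, spec),
            360.0,
        )
        data = {
            "u10": (("time", "lat", "lon"), u),
            "v10": (("time", "lat", "lon"), v),
            "swh": (("time", "lat", "lon"), swh),
            "mwd": (("time", "lat", "lon"), mwd),
        }
    ds = xr.Dataset(data, coords={"time": hours, "lat": lats, "lon": lons})
    return EnvGrid(ds)


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------


def _immersion_log(
    truth: GroundTruth, config: SimConfig, rng
) -> pd.DataFrame:
    """Wet/dry record at the immersion resolution with interval-level flips.

    Rest intervals are recorded wet and flight intervals dry; each
    10-minute interval independently flips with probability
    ``immersion_flip_error`` (a mis-recorded interval), which makes the
    expected agreement of rest-vs-wet equal 1 - flip rate.
    """
    interval = pd.Timedelta(minutes=config.gps_interval)
    rows = []
    flips = rng.random(truth.states.size) < config.immersion_flip_error
    for i, s in enumerate(truth.states):
        wet = (s == STATE_REST) != flips[i]
        start = truth.state_times[i]
        rows.append((start, start + interval, "wet" if wet else "dry"))
    df = pd.DataFrame(rows, columns=["start", "end", "state"])
    # merge consecutive records of equal state (3-s-aligned by construction)
    grp = (df["state"] != df["state"].shift()).cumsum()
    return df.groupby(grp).agg(
        start=("start", "first"), end=("end", "last"), state=("state", "first")
    ).reset_index(drop=True)


def expected_rate(coefs, windspeed_kmh, swell_m) -> np.ndarray:
    """True hourly flap rate exp(b0 + b1*windspeed + b2*swell)."""
    b0, b1, b2 = coefs
    return np.exp(b0 + b1 * np.asarray(windspeed_kmh) + b2 * np.asarray(swell_m))


def gen_cohort(config: SimConfig) -> Cohort:
    """Generate a full multi-bird cohort: accel + GPS + immersion + env + truth.

    Hourly expected flap counts follow the configured log-linear
    response to windspeed and swell height at the bird's position,
    scaled by a lognormal per-bird random effect, so downstream model
    fits have a known target. Bird seeds are spawned from the config
    seed, so the whole cohort is reproducible and birds are independent.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    env_seed, *bird_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_birds + 1)]
    t0 = pd.Timestamp(config.start_time)
    hours = pd.date_range(
        t0.floor("h"), periods=int(np.ceil(config.trip_hours)) + 1, freq="h"
    )
    env = gen_env_grid(config.env_grid_spec, env_seed, hours)
    b0, b1, b2 = config.response_coefs
    birds: dict[str, BirdData] = {}
    for bi, bseed in enumerate(bird_seeds):
        bird_id = f"bird{bi:03d}"
        rng = np.random.default_rng(bseed)
        track, truth = gen_track(config, seed=bseed)
        bird_effect = rng.normal(0.0, config.bird_sd)
        expected = np.zeros(truth.states.size)
        spec = config.env_grid_spec
        for i in range(truth.states.size):
            if truth.states[i] == STATE_REST:
                continue
            # clip to the grid so an excursion past the extent still has a
            # well-defined true response
            e = extract_env(
                env,
                float(np.clip(track["lat"].iloc[i], spec.lat_min, spec.lat_max)),
                float(np.clip(track["lon"].iloc[i], spec.lon_min, spec.lon_max)),
                truth.state_times[i].floor("h"),
            )
            rate = np.exp(
                b0 + b1 * e["windspeed"] + b2 * e["swell_height"] + bird_effect
            )
            expected[i] = rate * config.gps_interval / 60.0
        accel, _ = gen_accel_trace(
            truth, config, seed=bseed + 1, expected_flaps_per_interval=expected
        )
        immersion = _immersion_log(truth, config, rng)
        immersion.insert(0, "bird_id", bird_id)
        track = track.copy()
        track.insert(0, "bird_id", bird_id)
        stage = "brood-guard" if bi % 3 != 2 else "incubation"
        birds[bird_id] = BirdData(
            bird_id=bird_id,
            track=track,
            accel=accel,
            immersion=immersion,
            truth=truth,
            stage=stage,
        )
    return Cohort(config=config, env=env, birds=birds)


# ---------------------------------------------------------------------------
# direct hourly-table generator (fast path for model recovery)
# ---------------------------------------------------------------------------


def gen_hourly_table(
    config: SimConfig,
    seed: int,
    n_birds: int | None = None,
    hours_per_bird: int = 100,
    brood_guard_fraction: float = 2 / 3,
) -> pd.DataFrame:
    """Sample an hourly flight table straight from the response model.

    Skips the accelerometer/HMM stages: windspeed and swell height are
    drawn from realistic marginals (gamma; means 32 km/h and 2.5 m),
    relative angles uniform on [0, 180], and hourly flap counts are
    Poisson with mean exp(b0 + b1*wind + b2*swell + bird effect). Used
    for model-selection and reduction recovery tests where only the
    hourly table matters.
    """
    rng = np.random.default_rng(seed)
    n_birds = n_birds or config.n_birds
    b0, b1, b2 = config.response_coefs
    rows = []
    t0 = pd.Timestamp(config.start_time).floor("h")
    for bi in range(n_birds):
        eff = rng.normal(0.0, config.bird_sd)
        wind = rng.gamma(7.1, 32.0 / 7.1, size=hours_per_bird)
        swell = rng.gamma(9.8, 2.5 / 9.8, size=hours_per_bird)
        bwa = rng.uniform(0.0, 180.0, size=hours_per_bird)
        bsa = rng.uniform(0.0, 180.0, size=hours_per_bird)
        mu = np.exp(b0 + b1 * wind + b2 * swell + eff)
        flaps = rng.poisson(mu)
        stage = "brood-guard" if bi < round(brood_guard_fraction * n_birds) else "incubation"
        for h in range(hours_per_bird):
            rows.append(
                {
                    "bird_id": f"bird{bi:03d}",
                    "hour": t0 + pd.Timedelta(hours=h),
                    "flaps": int(flaps[h]),
                    "windspeed": wind[h],
                    "swell_height": swell[h],
                    "BWA": bwa[h],
                    "BSA": bsa[h],
                    "stage": stage,
                    "complete_trip": True,
                }
            )
    return pd.DataFrame(rows)
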