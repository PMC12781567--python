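"""End-to-end orchestration: accel -> states -> sync -> models -> context.

Stages are pure functions over files in a run directory; every run
writes a manifest recording the config hash, the seeds, and a checksum
of every artifact, so identical configs produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .accel import FlapDetectionConfig, detect_flaps, flaps_per_hour, rotate_to_animal_frame
from .hmm import decode_states, fit_hmm, track_steps_angles, validate_against_immersion
from .models import fit_all_models, flap_reduction, model_selection_table, predict_surface
from .context import category_thresholds, condition_proportions
from .synth import SimConfig, gen_cohort
from .trackenv import DropLog, hourly_aggregate, interpolate_track

log = logging.getLogger("flapwave")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Structured configuration of a full pipeline run."""

    outdir: str = "flapwave_run"
    seed: int = 0
    simulate: dict | None = None  # SimConfig overrides; None = read real inputs
    accel_dir: str | None = None
    gps_path: str | None = None
    immersion_path: str | None = None
    env_path: str | None = None
    detection: dict = field(default_factory=dict)  # FlapDetectionConfig fields
    hmm_n_starts: int = 25
    model_family: str = "nb"
    basis_dim: int = 5
    kde_percentile: float = 99.0
    quantile_pair: tuple = (5.0, 95.0)
    n_per_basin: int | None = None
    angle_bins: tuple = (60.0, 120.0)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("accel_dir", "gps_path", "env_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"config {name} missing or absent: {p}")

    def sha256(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all artifacts under ``config.outdir``.

    With ``config.simulate`` set, a synthetic cohort is generated first
    and written in the pipeline's own input formats; otherwise the
    configured real input paths are read. Returns the in-memory result
    bundle (hourly table, state sequences, selection table, surfaces,
    reductions, context summaries, drop log).
    """
    logging.basicConfig(level=config.log_level)
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- inputs ----------------------------------------------------------
    if config.simulate is not None:
        sim = SimConfig(**{**config.simulate, "seed": config.seed})
        log.info("simulating cohort of %d birds", sim.n_birds)
        cohort = gen_cohort(sim)
        env = cohort.env
        birds = {
            b: {
                "accel": d.accel,
                "track_raw": d.track,
                "immersion": d.immersion,
                "stage": d.stage,
                "complete_trip": d.complete_trip,
            }
            for b, d in cohort.birds.items()
        }
        fio.write_env_netcdf(env, out / "env.nc")
    else:
        env = fio.read_env_netcdf(config.env_path)
        gps = fio.read_gps_csv(config.gps_path)
        immersion = (
            fio.read_immersion_csv(config.immersion_path)
            if config.immersion_path
            else None
        )
        birds = {}
        for bird_id, g in gps.groupby("bird_id"):
            acc_path = Path(config.accel_dir) / f"{bird_id}.csv"
            if not acc_path.exists():
                raise FileNotFoundError(f"no accelerometer file for bird {bird_id!r}")
            birds[str(bird_id)] = {
                "accel": fio.read_accel_csv(acc_path),
                "track_raw": g,
                "immersion": (
                    immersion[immersion["bird_id"] == bird_id]
                    if immersion is not None
                    else None
                ),
                "stage": str(g["stage"].iloc[0]) if "stage" in g else "",
                "complete_trip": True,
            }

    # ---- flaps -----------------------------------------------------------
    det = FlapDetectionConfig(**config.detection)
    events = {}
    for bird_id, d in birds.items():
        trace = rotate_to_animal_frame(d["accel"])
        events[bird_id] = detect_flaps(trace, det, bird_id=bird_id)
        log.info("bird %s: %d flaps detected", bird_id, events[bird_id].n_flaps)

    # ---- states ----------------------------------------------------------
    tracks = {b: interpolate_track(d["track_raw"]) for b, d in birds.items()}
    series = {b: track_steps_angles(t.assign(bird_id=b)) for b, t in tracks.items()}
    params, loglik = fit_hmm(list(series.values()), n_starts=config.hmm_n_starts, seed=config.seed)
    log.info("HMM fitted, log-likelihood %.1f", loglik)
    states = {b: decode_states(params, s) for b, s in series.items()}
    agreements = {}
    for b, d in birds.items():
        if d.get("immersion") is not None and len(d["immersion"]):
            agreements[b] = validate_against_immersion(states[b], d["immersion"])
        fio.write_states_csv(states[b], out / f"states_{b}.csv")

    # ---- sync ------------------------------------------------------------
    drop_log = DropLog()
    tables = []
    for b in birds:
        t = hourly_aggregate(
            states[b], events[b], tracks[b], env,
            bird_id=b, stage=birds[b]["stage"],
            complete_trip=birds[b]["complete_trip"], drop_log=drop_log,
        )
        if len(t):
            tables.append(t)
    hourly = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    fio.write_hourly_table(hourly, out / "hourly_table.csv")
    drop_log.to_frame().to_csv(out / "dropped_hours.csv", index=False)
    for _, hour, reason in drop_log.records:
        log.debug("dropped hour %s: %s", hour, reason)

    # ---- models ----------------------------------------------------------
    results: dict = {
        "hourly_table": hourly,
        "states": states,
        "hmm_params": params,
        "immersion_agreement": agreements,
        "drop_log": drop_log.to_frame(),
    }
    if len(hourly) >= 200 and hourly["bird_id"].nunique() >= 5:
        fits = fit_all_models(hourly, family=config.model_family, k=config.basis_dim)
        selection = model_selection_table(fits)
        selection.to_csv(out / "model_selection.csv", index=False)
        surface = predict_surface(fits["V"], kde_percentile=config.kde_percentile)
        reduction = flap_reduction(
            surface, q_low=config.quantile_pair[0], q_high=config.quantile_pair[1]
        )
        pd.DataFrame(
            {
                "x1": np.repeat(surface.x1, surface.x2.size),
                "x2": np.tile(surface.x2, surface.x1.size),
                "rate": surface.rate.ravel(),
                "inside": surface.mask.ravel(),
            }
        ).to_csv(out / "surface_V.csv", index=False)
        results.update(fits=fits, selection=selection, surface=surface, reduction=reduction)
        log.info(
            "Model V reduction: %.2f%% (max %.1f, min %.1f flaps/h)",
            reduction.reduction_pct, reduction.max_rate, reduction.min_rate,
        )
    else:
        log.warning("hourly table too small for model fitting; skipping model stage")

    # ---- context ---------------------------------------------------------
    if len(hourly):
        n_pb = config.n_per_basin or min(34, hourly["bird_id"].nunique())
        try:
            thresholds = category_thresholds(
                {"basin": hourly}, n_per_basin=n_pb, seed=config.seed
            )
            proportions = condition_proportions(hourly, thresholds, config.angle_bins)
            proportions.to_csv(out / "condition_proportions.csv", index=False)
            results.update(thresholds=thresholds, proportions=proportions)
        except ValueError as err:
            log.warning("context stage skipped: %s", err)

    # ---- manifest --------------------------------------------------------
    artifacts = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "outputs": {p.name: _checksum(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
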