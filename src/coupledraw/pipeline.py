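"""End-to-end orchestration: simulate -> behaviour -> spectral -> coherence
-> ANN -> evaluation, with a run manifest for reproducibility.

Every stage writes its table under the output directory; the manifest
records the package version, master seed, configuration hash and the files
each stage produced, so a rerun from the same manifest reproduces every
numeric output exactly (archive dialect) or within 16-bit quantisation
(EDF dialect).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behaviour, coherence, evaluation, io, neuralnet, spectral
from .core import BAND_PRESETS, MOTOR_CHANNELS, substream
from .synthetic import SessionConfig, generate_session

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full-run configuration (YAML-serialisable)."""

    out_dir: str = "coupledraw-run"
    seed: int = 0
    band_preset: str = "default"
    floor_px: float = 1.0
    eeg_dialect: str = "archive"
    n_iterations: int = 1000
    min_appearances: int = 5
    session: SessionConfig = field(default_factory=SessionConfig)
    train: neuralnet.TrainConfig = field(default_factory=neuralnet.TrainConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        session = SessionConfig(**{
            **raw.pop("session", {}), "seed": raw.get("seed", 0),
        })
        train = neuralnet.TrainConfig(**raw.pop("train", {}))
        return cls(session=session, train=train, **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bands = BAND_PRESETS[cfg.band_preset]
    channels = list(cfg.session.channels)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }

    def stage(name: str):
        logger.info("stage %s", name)
        t0 = time.time()
        manifest["stages"][name] = {"started": t0}
        return t0

    # --- simulate ----------------------------------------------------------
    t0 = stage("simulate")
    session_cfg = dataclasses.replace(cfg.session, seed=cfg.seed)
    trials, eeg, truth = generate_session(session_cfg)
    io.write_trajectories(trials, out / "trajectories.csv")
    io.write_events(eeg.events, out / "events.csv")
    if cfg.eeg_dialect == "edf":
        io.write_edf(eeg, out / "eeg.edf")
    else:
        io.write_eeg_archive(eeg, out / "eeg")
    truth.frame(trials).to_csv(out / "ground_truth.csv", index=False)
    manifest["stages"]["simulate"].update(
        seconds=time.time() - t0,
        outputs=["trajectories.csv", "events.csv", "ground_truth.csv"],
    )

    # --- behaviour ---------------------------------------------------------
    t0 = stage("behaviour")
    curv = behaviour.curvature_table(trials, cfg.floor_px)
    curv.to_csv(out / "ci.csv", index=False)
    behaviour.summarise_conditions(curv).to_csv(out / "condition_summary.csv", index=False)
    ci = curv.set_index("trial_id")["ci"]
    manifest["stages"]["behaviour"].update(
        seconds=time.time() - t0, outputs=["ci.csv", "condition_summary.csv"],
    )

    # --- spectral ----------------------------------------------------------
    t0 = stage("spectral")
    filtered = spectral.bandpass_filter(eeg)
    epochs = spectral.epoch_trials(filtered)
    tf_maps = spectral.session_tf_maps(epochs, channels)
    erd = spectral.erd_table(tf_maps, bands, channels)
    erd.to_csv(out / "erd.csv", index=False)
    features = spectral.feature_matrix(tf_maps, bands, channels)
    io.write_features(
        features, out / "features",
        meta={"channels": channels, "bands": [b.name for b in bands],
              "freq_grid": spectral.FREQ_GRID.tolist()},
    )
    manifest["stages"]["spectral"].update(
        seconds=time.time() - t0, outputs=["erd.csv", "features.npz", "features.json"],
    )

    # --- coherence ---------------------------------------------------------
    t0 = stage("coherence")
    coh = coherence.coherence_table(epochs, channels, bands)
    coh.to_csv(out / "coherence.csv", index=False)
    manifest["stages"]["coherence"].update(
        seconds=time.time() - t0, outputs=["coherence.csv"],
    )

    # --- ann ---------------------------------------------------------------
    t0 = stage("ann")
    ann = neuralnet.iterate_splits(
        features, ci, n_iter=cfg.n_iterations, cfg=cfg.train, seed=cfg.seed,
        min_appearances=cfg.min_appearances,
    )
    ann.predictions.to_csv(out / "predictions.csv", index=False)
    ann.iterations.to_csv(out / "iterations.csv", index=False)
    manifest["stages"]["ann"].update(
        seconds=time.time() - t0, outputs=["predictions.csv", "iterations.csv"],
        mean_r=ann.mean_r, n_iterations=ann.n_iterations,
    )

    # --- evaluation --------------------------------------------------------
    t0 = stage("evaluate")
    rep_erd = evaluation.correlate_erd(erd, ci)
    rep_coh = evaluation.correlate_coherence(coh, ci)
    rep_ann = evaluation.evaluate_ann(
        ann.predictions, ci, scatter_path=str(out / "ann_scatter.png"))
    report = pd.concat([rep_erd, rep_coh, rep_ann], ignore_index=True)
    report.to_csv(out / "correlation_report.csv", index=False)
    summary = evaluation.compare_approaches([rep_erd, rep_coh, rep_ann])
    summary.to_csv(out / "approach_summary.csv", index=False)
    manifest["stages"]["evaluate"].update(
        seconds=time.time() - t0,
        outputs=["correlation_report.csv", "approach_summary.csv", "ann_scatter.png"],
    )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
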