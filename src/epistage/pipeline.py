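"""End-to-end orchestration: generate -> preprocess -> featurize -> graph ->
train -> evaluate -> stats.

A :class:`RunConfig` pins every knob of a run; one global seed fans out
deterministically to the generator, the dataset split, and training, so a run
directory is fully reproducible from the resolved-config copy written into it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .complexity import ComplexityParams, FeatureMatrix, MEASURE_NAMES, extract_features
from .evaluation import evaluate
from .gcnn import ModelConfig, TrainConfig, predict, train_model
from .graphs import build_graph, export_manifest, split_dataset, standardize_features
from .preprocess import BandSpec, preprocess_recording
from .signal_io import Recording, Stage, read_recording
from .stats import stage_separation_report
from .synthetic import GeneratorConfig, StageParams, default_stage_params, generate_dataset

__all__ = ["RunConfig", "run_pipeline", "run_per_subject", "featurize_recordings"]

log = logging.getLogger("epistage")


def _derive_seed(seed: int, *keys: int) -> int:
    return int(np.random.default_rng([seed, *keys]).integers(2**31))


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    source: str = "synthetic"  # "synthetic" | "files"
    # synthetic source
    fs: float = 1000.0
    duration: float = 600.0
    n_channels: int = 8
    recordings_per_stage: int = 1
    # files source: list of {path, format, fs, stage, subject_id}
    input_files: list = field(default_factory=list)
    # preprocessing
    epoch_seconds: float = 1.0
    band_low: float = 250.0
    band_high: float = 500.0
    # features
    complexity: ComplexityParams = field(default_factory=ComplexityParams)
    # split / model / training
    split_ratios: tuple[float, float, float] = (0.5, 0.2, 0.3)
    standardize: bool = True
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    # bookkeeping
    seed: int = 0
    output_dir: str = "runs/run"
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        if self.source not in ("synthetic", "files"):
            raise ValueError(f"unknown source {self.source!r}")
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if self.band_high > self.fs / 2 + 1e-9:
            raise ValueError(
                f"band_high={self.band_high} exceeds Nyquist {self.fs / 2}"
            )
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split_ratios must sum to 1")

    @property
    def band(self) -> BandSpec:
        return BandSpec(self.band_low, self.band_high)

    # -- (de)serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        out = {}
        for f in dataclasses.fields(self):
            out[f.name] = enc(getattr(self, f.name))
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "complexity" in raw and isinstance(raw["complexity"], dict):
            raw["complexity"] = ComplexityParams(**raw["complexity"])
        if "model" in raw and isinstance(raw["model"], dict):
            m = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["model"].items()
            }
            raw["model"] = ModelConfig(**m)
        if "train" in raw and isinstance(raw["train"], dict):
            raw["train"] = TrainConfig(**raw["train"])
        if "split_ratios" in raw:
            raw["split_ratios"] = tuple(raw["split_ratios"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# stages

def _load_recordings(cfg: RunConfig, stage_params: Optional[dict] = None) -> list[Recording]:
    if cfg.source == "synthetic":
        gen = GeneratorConfig(
            fs=cfg.fs,
            duration=cfg.duration,
            n_channels=cfg.n_channels,
            seed=_derive_seed(cfg.seed, 0),
            stage_params=stage_params or {},
        )
        return generate_dataset(
            gen, cfg.recordings_per_stage, subject_id=cfg.subject_id
        )
    recs = []
    for item in cfg.input_files:
        recs.append(
            read_recording(
                item["path"],
                format=item.get("format"),
                fs_override=item.get("fs"),
                stage=item.get("stage"),
                subject_id=item.get("subject_id"),
            )
        )
    return recs


def featurize_recordings(
    recordings: list[Recording],
    epoch_seconds: float = 1.0,
    band: BandSpec = BandSpec(),
    params: Optional[ComplexityParams] = None,
) -> list[FeatureMatrix]:
    """Preprocess each recording and extract one feature matrix per epoch."""
    params = params or ComplexityParams()
    out = []
    for rec in recordings:
        for ep in preprocess_recording(rec, epoch_seconds, band):
            out.append(extract_features(ep, params))
    return out


def _features_to_csv(fms: list[FeatureMatrix], path) -> None:
    rows = []
    for fm in fms:
        for c in range(fm.n_channels):
            row = {
                "subject_id": fm.subject_id,
                "stage": fm.stage.value,
                "epoch_index": fm.epoch_index,
                "channel": fm.channel_names[c] if fm.channel_names else str(c),
            }
            row.update(dict(zip(MEASURE_NAMES, fm.values[c])))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.DEBUG)
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (outdir / "run.log").resolve()
        for h in log.handlers
    ):
        fh = logging.FileHandler(outdir / "run.log")
        fh.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        log.addHandler(fh)


def run_pipeline(
    cfg: RunConfig,
    feature_matrices: Optional[list[FeatureMatrix]] = None,
    stage_params: Optional[dict] = None,
) -> Path:
    """Execute the full pipeline; returns the run directory.

    ``feature_matrices`` short-circuits generation/featurization (used by
    :func:`run_per_subject` to pool subjects without recomputing features).
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    cfg.to_yaml(outdir / "config.yaml")
    t0 = time.time()

    if feature_matrices is None:
        log.info("loading/generating recordings (source=%s)", cfg.source)
        recordings = _load_recordings(cfg, stage_params)
        log.info("featurizing %d recordings", len(recordings))
        feature_matrices = featurize_recordings(
            recordings, cfg.epoch_seconds, cfg.band, cfg.complexity
        )
    _features_to_csv(feature_matrices, outdir / "features.csv")

    log.info("building %d graph samples", len(feature_matrices))
    samples = [build_graph(fm) for fm in feature_matrices]
    split = split_dataset(
        samples, cfg.split_ratios, seed=_derive_seed(cfg.seed, 1), stratify=True
    )
    export_manifest(split, outdir / "split_manifest.csv")
    if cfg.standardize:
        split, _scaler = standardize_features(split)

    tcfg = replace(cfg.train, seed=_derive_seed(cfg.seed, 2))
    log.info(
        "training GCNN: %d train / %d val / %d test samples, %d epochs",
        len(split.train),
        len(split.validation),
        len(split.test),
        tcfg.epochs,
    )
    model, history = train_model(split, cfg.model, tcfg, logger=log)
    model.save(outdir / "model.npz")
    pd.DataFrame(
        {
            "epoch": np.arange(len(history.train_loss)),
            "train_loss": history.train_loss,
            "val_loss": history.val_loss,
            "val_accuracy": history.val_accuracy,
        }
    ).to_csv(outdir / "train_history.csv", index=False)

    y_pred, _probs = predict(model, split.test)
    y_true = [s.label for s in split.test]
    report = evaluate(y_true, y_pred)
    report.to_json(outdir / "eval_report.json")
    report.confusion_to_csv(outdir / "confusion.csv")
    log.info("test accuracy %.4f on %d samples", report.accuracy, report.n_samples)

    stats_rep = stage_separation_report(feature_matrices)
    stats_rep.table_to_csv(outdir / "stats_table.csv")
    stats_rep.scores_to_csv(outdir / "pca_scores.csv")

    log.info("run complete in %.1f s -> %s", time.time() - t0, outdir)
    return outdir


def _jittered_stage_params(seed: int, subject_index: int) -> dict:
    """Per-subject generator parameters: multiplicative jitter on the defaults.

    Emulates inter-subject heterogeneity so pooled (combined) training faces a
    harder problem than per-subject training.
    """
    rng = np.random.default_rng([seed, 100 + subject_index])
    out = {}
    for stage in (Stage.NORMAL, Stage.ACUTE, Stage.CHRONIC):
        p = default_stage_params(stage)
        factor = lambda sd: float(np.exp(rng.normal(0.0, sd)))
        out[stage] = StageParams(
            stage=stage,
            noise_sd=p.noise_sd * factor(0.25),
            pink_sd=p.pink_sd * factor(0.25),
            burst_rate=p.burst_rate * factor(0.2) if p.burst_rate else 0.0,
            burst_freq=float(np.clip(p.burst_freq * factor(0.08), 250.0, 500.0)),
            burst_amp=p.burst_amp * factor(0.3) if p.burst_amp else 0.0,
            regularity=float(np.clip(p.regularity * factor(0.25), 0.0, 1.0)),
        )
    return out


def run_per_subject(cfg: RunConfig, subjects: list[str]) -> tuple[Path, pd.DataFrame]:
    """Train one model per subject plus one pooled model; summarize like a
    per-subject results table (accuracy + per-stage F1, 'combined' last row).
    """
    if not subjects:
        raise ValueError("need at least one subject")
    base = Path(cfg.output_dir)
    base.mkdir(parents=True, exist_ok=True)
    rows = []
    all_features: list[FeatureMatrix] = []
    for s_idx, subject in enumerate(subjects):
        sub_cfg = replace(
            cfg,
            output_dir=str(base / subject),
            subject_id=subject,
            seed=_derive_seed(cfg.seed, 10 + s_idx),
        )
        stage_params = _jittered_stage_params(cfg.seed, s_idx)
        recordings = _load_recordings(sub_cfg, stage_params)
        fms = featurize_recordings(
            recordings, cfg.epoch_seconds, cfg.band, cfg.complexity
        )
        all_features.extend(fms)
        outdir = run_pipeline(sub_cfg, feature_matrices=fms)
        with open(outdir / "eval_report.json") as fh:
            rep = json.load(fh)
        rows.append(
            {
                "subject": subject,
                "accuracy": rep["accuracy"],
                "f1_normal": rep["f1"][0],
                "f1_acute": rep["f1"][1],
                "f1_chronic": rep["f1"][2],
            }
        )
    combined_cfg = replace(
        cfg,
        output_dir=str(base / "combined"),
        subject_id="combined",
        seed=_derive_seed(cfg.seed, 99),
    )
    outdir = run_pipeline(combined_cfg, feature_matrices=all_features)
    with open(outdir / "eval_report.json") as fh:
        rep = json.load(fh)
    rows.append(
        {
            "subject": "combined",
            "accuracy": rep["accuracy"],
            "f1_normal": rep["f1"][0],
            "f1_acute": rep["f1"][1],
            "f1_chronic": rep["f1"][2],
        }
    )
    summary = pd.DataFrame(rows)
    summary.to_csv(base / "summary.csv", index=False)
    return base, summary
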