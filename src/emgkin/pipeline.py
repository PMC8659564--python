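"""Configuration handling and staged pipeline orchestration.

A single YAML document configures every stage.  Unknown keys are rejected
by name, seeds are mandatory (no silent entropy), and every artefact is
stamped with a hash of the configuration that produced it, so any run can
be reproduced from its logged hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import io as _io
from .evaluation import cc_ablation, loso_cv, prepare_dataset
from .features import DEFAULT_CHANNEL_JOINT_MAP, estimate_lag_profile
from .preprocessing import fit_scaler, normalize
from .regressors import ModelConfig, train_lstm, train_mlp
from .synthetic import SynthConfig, generate_dataset

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "STAGES"]

log = logging.getLogger("emgkin")

STAGES = ("simulate", "preprocess", "features", "train", "evaluate", "all")

_SECTION_FIELDS = {
    "synth": {f.name for f in dataclasses.fields(SynthConfig)},
    "preprocess": {"n_points", "min_prominence", "min_separation_s", "rectify"},
    "features": {"wavelet_name", "level", "k_max", "channel_joint_map"},
    "model": {f.name for f in dataclasses.fields(ModelConfig)},
    "evaluation": {"K", "use_cc", "seed"},
    "paths": {"workdir"},
}


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclasses.dataclass
class PipelineConfig:
    synth: SynthConfig
    preprocess: dict
    features: dict
    model: ModelConfig
    evaluation: dict
    workdir: Path
    raw: dict

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc or {})
        unknown = set(doc) - set(_SECTION_FIELDS)
        if unknown:
            raise ConfigError(f"unknown configuration section(s): {sorted(unknown)}")
        for section, allowed in _SECTION_FIELDS.items():
            entries = doc.get(section) or {}
            bad = set(entries) - allowed
            if bad:
                raise ConfigError(
                    f"unknown key(s) {sorted(bad)} in section {section!r}"
                )
        synth_kwargs = dict(doc.get("synth") or {})
        for tup_key in ("loads", "rom_load_scale", "channels", "joints", "lag_range_ms"):
            if tup_key in synth_kwargs and isinstance(synth_kwargs[tup_key], list):
                synth_kwargs[tup_key] = tuple(synth_kwargs[tup_key])
        model_kwargs = dict(doc.get("model") or {})
        if isinstance(model_kwargs.get("betas"), list):
            model_kwargs["betas"] = tuple(model_kwargs["betas"])
        return cls(
            synth=SynthConfig(**synth_kwargs),
            preprocess=dict(doc.get("preprocess") or {}),
            features=dict(doc.get("features") or {}),
            model=ModelConfig(**model_kwargs),
            evaluation={"K": 5, "use_cc": True, "seed": 0, **(doc.get("evaluation") or {})},
            workdir=Path((doc.get("paths") or {}).get("workdir", "emgkin_run")),
            raw=doc,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(doc)

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _require(path: Path, stage_hint: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artefact {path}; run the {stage_hint!r} stage first"
        )
    return path


def run_pipeline(config: PipelineConfig, stage: str = "all") -> dict:
    """Run one pipeline stage (or all of them) and return artefact paths.

    Stages are idempotent for a fixed configuration and seed; each writes
    its artefacts under ``config.workdir`` stamped with the config hash.
    """
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}; choose from {STAGES}")
    wd = config.workdir
    wd.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    arte = {
        "dataset": wd / "dataset.h5",
        "cycles": wd / "cycles.h5",
        "lags": wd / "lag_profile.json",
        "checkpoint": wd / "model.npz",
        "report_json": wd / "report.json",
        "report_csv": wd / "report.csv",
        "predictions": wd / "predictions.csv",
    }
    stages = [stage] if stage != "all" else list(STAGES[:-1])

    if "simulate" in stages:
        recs = generate_dataset(config.synth)
        _io.save_recordings(arte["dataset"], recs, config_hash=h)
        log.info("simulate: %d recordings -> %s", len(recs), arte["dataset"])

    if "preprocess" in stages:
        recs = _io.load_recordings(_require(arte["dataset"], "simulate"))
        prep = prepare_dataset(
            recs,
            n_points=config.preprocess.get("n_points", 1000),
            wavelet_name=config.features.get("wavelet_name", "sym8"),
            level=config.features.get("level", 8),
            prep_kwargs={
                k: v for k, v in config.preprocess.items() if k != "n_points"
            },
        )
        _io.save_cycle_sets(arte["cycles"], [cs for cs, _ in prep.sets], config_hash=h)
        n_cycles = sum(cs.n_cycles for cs, _ in prep.sets)
        log.info("preprocess: %d cycles -> %s", n_cycles, arte["cycles"])

    if "features" in stages or "train" in stages:
        recs = _io.load_recordings(_require(arte["dataset"], "simulate"))
        prep = prepare_dataset(
            recs,
            n_points=config.preprocess.get("n_points", 1000),
            wavelet_name=config.features.get("wavelet_name", "sym8"),
            level=config.features.get("level", 8),
            prep_kwargs={
                k: v for k, v in config.preprocess.items() if k != "n_points"
            },
        )
        feats = np.hstack([env for _, env in prep.sets])
        targs = np.hstack([cs.targets for cs, _ in prep.sets])
        profile = estimate_lag_profile(
            normalize(feats, fit_scaler(feats)),
            normalize(targs, fit_scaler(targs)),
            prep.channels,
            prep.joints,
            k_max=config.features.get("k_max", 300),
            channel_joint_map=config.features.get(
                "channel_joint_map", DEFAULT_CHANNEL_JOINT_MAP
            ),
        )
        arte["lags"].write_text(profile.to_json())
        log.info("features: pooled lags %s -> %s", profile.lags.tolist(), arte["lags"])

    if "train" in stages:
        # final model on the full data set (per-fold models are re-fitted
        # inside the evaluation stage)
        feat_scaler = fit_scaler(feats)
        targ_scaler = fit_scaler(targs)
        cfg = dataclasses.replace(
            config.model, seq_len=config.preprocess.get("n_points", 1000)
        )
        fn = normalize(feats, feat_scaler)
        tn = normalize(targs, targ_scaler)
        if cfg.arch == "lstm":
            model, trace = train_lstm(fn, tn, cfg)
            arrays = {f"param_{i}": p for i, p in enumerate(model.parameters())}
        else:
            model, trace = train_mlp(fn, tn, cfg)
            arrays = {
                "W1": model.params.W1,
                "b1": model.params.b1,
                "W2": model.params.W2,
                "b2": model.params.b2,
            }
        np.savez(
            arte["checkpoint"],
            config_json=json.dumps(dataclasses.asdict(cfg)),
            loss_trace=np.asarray(trace),
            feat_min=feat_scaler.x_min,
            feat_max=feat_scaler.x_max,
            targ_min=targ_scaler.x_min,
            targ_max=targ_scaler.x_max,
            lag_profile_json=profile.to_json(),
            config_hash=h,
            **arrays,
        )
        log.info(
            "train: %d epochs, final loss %.3g -> %s",
            len(trace),
            trace[-1] if trace else float("nan"),
            arte["checkpoint"],
        )

    if "evaluate" in stages:
        recs = _io.load_recordings(_require(arte["dataset"], "simulate"))
        cfg = config.model
        kwargs = dict(
            n_points=config.preprocess.get("n_points", 1000),
            wavelet_name=config.features.get("wavelet_name", "sym8"),
            level=config.features.get("level", 8),
            k_max=config.features.get("k_max", 300),
            channel_joint_map=config.features.get("channel_joint_map"),
            prep_kwargs={
                k: v for k, v in config.preprocess.items() if k != "n_points"
            },
        )
        if config.evaluation.get("use_cc", True):
            report, conc = loso_cv(recs, cfg, use_cc=True, **kwargs)
        else:
            report, conc = loso_cv(recs, cfg, use_cc=False, **kwargs)
        _io.save_report(
            report,
            arte["report_json"],
            arte["report_csv"],
            extra={"config_hash": h},
        )
        import pandas as pd

        pd.DataFrame(
            {
                **{f"pred_{j}": conc["pred"][i] for i, j in enumerate(report.joints)},
                **{f"truth_{j}": conc["truth"][i] for i, j in enumerate(report.joints)},
            }
        ).to_csv(arte["predictions"], index=False)
        log.info(
            "evaluate: %d subject-joint scores -> %s",
            len(report.per_subject),
            arte["report_json"],
        )

    return arte
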