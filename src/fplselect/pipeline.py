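"""End-to-end pipeline: (extract) -> split -> select -> evaluate.

A :class:`RunConfig` fully describes a run — a single master seed fans out
deterministically to the split, network initialisation and repeat seeds —
and a saved resolved config re-runs bit-identically.  Every artifact file
carries the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .evaluation import SplitSpec, evaluate_subset
from .features import FeatureMatrix
from .io import load_features_csv, load_segments_h5
from .network import BaseNetConfig, TrainConfig
from .selection import (PruneCriteria, ScheduleParams, StopCriteria,
                        run_selection, target_count)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("fplselect")


@dataclass
class RunConfig:
    seed: int = 0
    features_csv: str | None = None
    segments_h5: str | None = None
    fraction: float = 0.05
    f: float = 0.2
    final_prec: float = 0.75
    max_epochs: int = 20
    max_psovft: float = 0.05
    max_epochs_final: int = 500
    hidden_sizes: tuple[int, ...] = (256, 128, 64)
    dropout_prob: float = 0.0
    learning_rate: float = 1e-3
    batch_size: int = 64
    eval_epochs: int = 70
    eval_repeats: int = 4
    out_dir: str = "run_out"
    extra: dict = field(default_factory=dict)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        d["hidden_sizes"] = tuple(d.get("hidden_sizes", (256, 128, 64)))
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _load_inputs(config: RunConfig) -> FeatureMatrix:
    if config.features_csv:
        path = Path(config.features_csv)
        if not path.exists():
            raise FileNotFoundError(f"features file not found: {path}")
        return load_features_csv(path)
    if config.segments_h5:
        from .features import extract_features

        path = Path(config.segments_h5)
        if not path.exists():
            raise FileNotFoundError(f"segments file not found: {path}")
        return extract_features(load_segments_h5(path))
    raise ValueError("config must provide features_csv or segments_h5")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured run; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        features = _load_inputs(config)
        chash = config.config_hash
        log.info("run %s: %d samples x %d features", chash,
                 features.n_samples, features.n_features)

        des = target_count(config.fraction, features.n_features)
        train_cfg = TrainConfig(learning_rate=config.learning_rate,
                                batch_size=config.batch_size,
                                seed=config.seed, epochs=config.eval_epochs)
        net_cfg = BaseNetConfig(hidden_sizes=config.hidden_sizes,
                                dropout_prob=config.dropout_prob)
        split = SplitSpec(seed=config.seed)

        result = run_selection(
            features,
            sched=ScheduleParams(f=config.f),
            crit=PruneCriteria(final_prec=config.final_prec,
                               max_epochs=config.max_epochs,
                               max_psovft=config.max_psovft),
            stop=StopCriteria(des_feat_num=des,
                              max_epochs_final=config.max_epochs_final),
            train_config=train_cfg, net_config=net_cfg, split_spec=split)
        for ev in result.prune_events:
            log.info("prune @epoch %d: %d -> %d (trigger=%s)", ev.epoch,
                     ev.d_before, ev.d_after, ev.trigger)

        report, _ = evaluate_subset(features, result.selected_names,
                                    repeats=config.eval_repeats,
                                    net_config=net_cfg,
                                    train_config=train_cfg, split_spec=split)

        payload = {"config_hash": chash,
                   "des_feat_num": des,
                   "selection": result.to_dict(),
                   "evaluation": report.to_dict()}
        (out / "result.json").write_text(json.dumps(payload, indent=2))
        (out / "selected.txt").write_text(
            f"# config {chash}\n" + "\n".join(result.selected_names) + "\n")
        trace = pd.DataFrame(result.trace.to_dict())
        trace.insert(0, "config_hash", chash)
        trace.to_csv(out / "trace.csv", index=False)
        (out / "config_resolved.yaml").write_text(
            f"# config {chash}\n" + config.to_yaml())
        log.info("run %s finished: %d features selected, precision %.3f",
                 chash, len(result.selected_names), report.precision)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
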