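"""Run configuration: one flat document of every tunable, with the study
defaults (10-s / 0.2 STE windows, 13 MFCCs at 25 ms / 50%, 500-1000-1000
units, theta 3.5, eta 0.1, 500 epochs, seed 1234, k = 5)."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import scipy
import sklearn
import yaml

from .ffnet import TrainConfig


@dataclass
class RunConfig:
    # segmentation
    ste_window_s: float = 10.0
    ste_overlap: float = 0.0
    ste_threshold: float = 0.2
    # features
    n_mfcc: int = 13
    frame_ms: float = 25.0
    frame_overlap: float = 0.5
    # forward-forward network
    layer_sizes: tuple[int, ...] = (500, 1000, 1000)
    theta: float = 3.5
    learning_rate: float = 0.1
    epochs: int = 500
    seed: int = 1234
    goodness_kind: str = "rms"
    # spectral subtraction
    ss_alpha: float = 1.0
    ss_beta: float = 0.01
    ss_noise_profile_ms: float = 250.0
    # evaluation
    k_folds: int = 5
    cv_seed: int = 0

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, epochs=self.epochs, seed=self.seed,
            theta=self.theta, goodness_kind=self.goodness_kind,
            layer_sizes=tuple(self.layer_sizes),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.layer_sizes = tuple(cfg.layer_sizes)
        return cfg


def write_repro_record(out_dir, config: RunConfig, extra: dict | None = None) -> Path:
    """Reproducibility record (config + versions) written next to outputs."""
    from . import __version__

    record = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "chirpff": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "config": asdict(config),
    }
    if extra:
        record.update(extra)
    out = Path(out_dir) / "run_record.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(record, indent=2, default=str))
    return out
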