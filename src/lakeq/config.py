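"""Run configuration: every knob of the learning pipeline in one place.

A ``RunConfig`` round-trips through YAML, and every artifact-writing command
stores the resolved config (plus its hash and seed) next to its outputs so a
run can be regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # data split (rows): first train_rows train, next test_rows test
    train_rows: int = 900
    test_rows: int = 90
    # preprocessing
    smooth_window: int = 5
    # base forecasters
    models: list[str] = field(
        default_factory=lambda: ["persistence", "linear_ar", "window_mean"]
    )
    # error stage: a null arm anchors compensation at the identity when the
    # errors carry no structure; short lags avoid fitting white residuals
    stage2_models: list[str] = field(
        default_factory=lambda: ["zero", "ridge_ar"]
    )
    model_window: int = 24
    stage2_window: int = 6
    # triple-Q learning
    alpha: float = 0.1
    gamma: float = 0.9
    c: float = 1.0
    eps_scale: float = 0.2
    eps_offset: float = 0.1
    n_episodes: int = 500
    patience: int = 50          # early stop after this many stable episodes
    reward_zscore: bool = True  # z-score channels (train stats) for rewards
    # out-of-sample scoring: base models are fitted on the first
    # eval_fraction of each stage's series and the learning walk covers the
    # remainder, so fitted models are rewarded on data they did not see and
    # deployment errors match the learned error series; None scores in
    # sample.  refit_every switches to expanding-window refits (more data
    # per fit, mixed error distribution).
    eval_fraction: float | None = 0.5
    refit_every: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.train_rows < 2 or self.test_rows < 1:
            raise ValueError("split sizes must be positive")
        if self.n_episodes < 1:
            raise ValueError("n_episodes must be >= 1")

    @property
    def resolved_stage2_models(self) -> list[str]:
        return list(self.stage2_models)

    @property
    def resolved_stage2_window(self) -> int:
        return self.stage2_window

    def resolved_eval_start(self, n_rows: int, window: int) -> int | None:
        """First out-of-sample-scored row for an n_rows series."""
        if self.eval_fraction is None:
            return None
        start = int(round(self.eval_fraction * n_rows))
        # keep both the initial fit split and the walk viable
        return min(max(start, window + 2), n_rows - 2)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def write_yaml(self, path) -> None:
        payload = self.to_dict()
        payload["config_hash"] = self.config_hash()
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.pop("config_hash", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)
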