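"""Run configuration: a small validated record that round-trips via YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]

_PRESETS = ("ch_default", "ad_default", "surrogate")


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run.

    ``presets`` lists the cohorts to simulate (one entry per group); with
    two or more groups the group-statistics stage runs.  Every stochastic
    stage draws from ``seed`` through independent sub-streams.
    """

    presets: list[str] = field(default_factory=lambda: ["ch_default"])
    n_subjects: int = 10
    duration_s: float = 540.0
    K: int = 10
    n_restarts: int = 10
    seed: int = 0
    band: str = "wide"
    orthogonalize: bool = True
    trim_s: float = 1.0
    window_s: float = 5.0
    n_perm: int = 1000
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    max_iter: int = 500
    restart_iter: int = 15

    def __post_init__(self):
        for p in self.presets:
            if p not in _PRESETS:
                raise ValueError(f"unknown preset {p!r}; choose from {_PRESETS}")
        if not self.presets:
            raise ValueError("at least one preset required")
        if self.K < 1 or self.n_restarts < 1 or self.n_subjects < 1:
            raise ValueError("K, n_restarts and n_subjects must be positive")
        if self.duration_s <= 0 or self.window_s <= 0:
            raise ValueError("durations must be positive")
        if self.seed is None:
            raise ValueError("an explicit seed is required")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)
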