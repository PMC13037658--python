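"""Benchmark configuration: JSON with validated defaults.

Defaults mirror the standard experiment: K = 100 latent components with the
first 7 (size) components clamped, N = 17 surfaces per trajectory spanning
|z| <= 3, eight trajectory seeds, and 10 cross-validation runs holding out
10% of channels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class BenchConfig:
    preset: str = "tiny"
    master_seed: int = 0
    K: int = 100
    N: int = 17
    Z: float = 3.0
    size_components: list[int] = field(default_factory=lambda: list(range(1, 8)))
    trajectory_seeds: list[int] = field(default_factory=lambda: list(range(1, 9)))
    calibration_target_mm: float = 3.5
    smoothness_mm: float = 20.0
    n_datasets: int = 3
    n_trials: int = 336
    snr_db: float = -1.77
    methods: list[str] = field(default_factory=lambda: ["EBB", "IID"])
    metrics: list[str] = field(default_factory=lambda: ["free_energy"])
    n_null_runs: int = 2
    cv_runs: int = 10
    cv_holdout_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.N % 2 == 0 or self.N < 3:
            raise ValueError("N must be odd and >= 3")
        if self.Z <= 0:
            raise ValueError("Z must be positive")
        if self.K < 1 or self.K <= len(self.size_components):
            raise ValueError("K must exceed the number of size components")
        if any(not 1 <= i <= self.K for i in self.size_components):
            raise ValueError("size_components must lie in 1..K")
        if self.preset not in ("tiny", "standard"):
            raise ValueError("preset must be 'tiny' or 'standard'")
        if not self.trajectory_seeds:
            raise ValueError("need at least one trajectory seed")
        if not 0 < self.cv_holdout_frac < 1:
            raise ValueError("cv_holdout_frac must be in (0, 1)")
        for m in self.metrics:
            if m not in ("free_energy", "r2", "cv_error", "gamma_max"):
                raise ValueError(f"unknown metric {m!r}")
        for m in self.methods:
            if m.upper() not in ("IID", "EBB", "GS"):
                raise ValueError(f"unknown method {m!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name for f in dataclasses.fields(BenchConfig)}


def load_config(path: str | Path | None = None) -> BenchConfig:
    """Load a JSON configuration, filling defaults; unknown keys are rejected.

    An empty (or whitespace-only) file yields the full defaults.
    """
    if path is None:
        return BenchConfig()
    text = Path(path).read_text()
    data = json.loads(text) if text.strip() else {}
    if not isinstance(data, dict):
        raise ValueError("configuration file must contain a JSON object")
    unknown = set(data) - _FIELDS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return BenchConfig(**data)


def dump_config(config: BenchConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")
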