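"""Run configuration: one YAML document, per-stage named seeds."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    # synthetic cohort
    grid_shape: tuple = (20, 20, 20)
    n_parcels: int = 64
    n_patients: int = 247
    n_controls: int = 81
    substrate_size: int = 2
    effect_beta: float = 30.0
    age_gamma: float = 0.2
    noise_sd: float = 5.0
    mu0: float = 80.0
    score_ceiling: float = 100.0
    age_range: tuple = (20.0, 75.0)
    lesion_size_range: tuple = (0.01, 0.15)
    ability_scale: float = 6.0
    # analysis knobs
    tau: float = 0.25
    m_min: int = 2
    n_bins: int = 8
    b_max: int = 16
    n_sweeps: int = 4
    n_boot: int = 1000
    alpha: float = 0.05
    lesion_reference: str = "permutation"
    # master seed; stage seeds derive from it by name
    seed: int = 0

    def __post_init__(self):
        checks = [
            (self.n_parcels >= 4, "n_parcels must be >= 4"),
            (self.n_patients >= 1, "n_patients must be >= 1"),
            (0 < self.tau <= 1, "tau must lie in (0, 1]"),
            (self.m_min >= 1, "m_min must be >= 1"),
            (self.n_bins >= 2, "n_bins must be >= 2"),
            (self.n_boot >= 100, "n_boot must be >= 100"),
            (0 < self.alpha < 1, "alpha must lie in (0, 1)"),
            (self.noise_sd >= 0, "noise_sd must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.age_range = tuple(float(v) for v in self.age_range)
        self.lesion_size_range = tuple(float(v) for v in self.lesion_size_range)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed: master seed combined with a stable
        hash of the stage name (so stage reordering cannot change draws)."""
        h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
        return int((self.seed * 1_000_003 + h) % (2**31 - 1))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def write_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
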