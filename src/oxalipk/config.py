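"""Run configuration: a validated, flat YAML-backed schema.

Unknown keys are rejected rather than ignored so that a typo in a config
file cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised on an invalid or unknown configuration key/value."""


@dataclass
class AnalysisConfig:
    """Everything a pipeline run needs, with the study defaults built in."""

    seed: int = 1
    output_dir: str = "runs/latest"

    # study design overrides
    n_per_arm: int = 5
    doses: tuple[float, ...] = (3.0, 8.0)
    renal_effect: bool = True  # generator ties true CL to creatinine

    # generator truth (population parameters); None = final-model defaults
    truth_theta: tuple[float, float, float, float] | None = None  # V1, V2, CL, CL2
    truth_iiv_pct: tuple[float, float, float] | None = None  # on V1, CL, CL2
    truth_sigma_pct: float | None = None

    # estimation
    n_terminal: int | str = 3
    se_method: str = "hessian"

    # validation replicate counts (scaled-down defaults; full size = 1000)
    bootstrap_n: int = 200
    vpc_n: int = 1000

    # renal-impairment simulation
    cr_grid: tuple[float, ...] = (0.3, 0.5, 1.0, 1.5, 2.5)
    mc_n: int = 1000
    sim_dose: float = 8.0
    use_anchor_regression: bool = False  # use the literature-anchored line instead of the fitted one

    plots: bool = False

    def __post_init__(self) -> None:
        if self.seed < 0 or self.seed >= 2**31:
            raise ConfigError("seed must be a non-negative 31-bit integer")
        if self.n_per_arm < 1:
            raise ConfigError("n_per_arm must be >= 1")
        if self.se_method not in ("hessian", "sandwich"):
            raise ConfigError("se_method must be 'hessian' or 'sandwich'")
        for name in ("bootstrap_n", "vpc_n", "mc_n"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("doses", "cr_grid", "truth_theta", "truth_iiv_pct"):
            if key in d and d[key] is not None:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out
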