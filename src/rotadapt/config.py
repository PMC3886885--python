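"""Experiment configuration: a nested, YAML-round-trippable record.

Angles are stored in **degrees** on disk and at the command line, and
converted to radians when the configuration is compiled into model objects.
"""

from __future__ import annotations

import copy
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .experiments import RewardSpec, ScheduleSpec, ShapingSpec, TaskSpec
from .model import LearningSpec, NoiseSpec, TuningField

__all__ = ["ExperimentConfig", "ConfigError"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid experiment configuration; the message lists offending fields."""


@dataclass
class ExperimentConfig:
    """Flat-on-disk, nested-in-memory experiment configuration.

    ``learning.eta_tilde`` is the normalized learning rate (the per-rewarded-
    trial contraction parameter); the raw rate ``eta`` is derived from it and
    the tuning normalization when the config is compiled.
    """

    tuning: dict = field(default_factory=lambda: {"N": 60, "rho": 1.0, "U_target": 1.0})
    task: dict = field(default_factory=lambda: {"gamma_deg": 30.0, "n0": 0.1})
    noise: dict = field(default_factory=lambda: {"sigma": 0.2})
    learning: dict = field(default_factory=lambda: {"eta_tilde": 0.5})
    reward: dict = field(default_factory=lambda: {"family": "binary", "T": 0.0})
    schedule: dict = field(
        default_factory=lambda: {
            "m": 1,
            "mode": "cyclic",
            "target_dirs_deg": None,
            "start_index": 0,
        }
    )
    shaping: dict = field(
        default_factory=lambda: {
            "kind": "none",
            "n0_init": 0.4,
            "n0_step": 0.05,
            "n0_final": 0.1,
            "gamma_step_deg": 5.0,
            "block_len": 25,
            "ema_timescale": 100.0,
            "steady_tol": 0.02,
            "per_target_monitoring": True,
            "adaptive": False,
        }
    )
    n_trials: int = 5000
    n_realizations: int = 1
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    # ---------------------------------------------------------------- dict io
    def to_dict(self) -> dict:
        return copy.deepcopy(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        base = cls()
        d = copy.deepcopy(d)
        bad: list[str] = []
        for key, val in d.items():
            if not hasattr(base, key):
                bad.append(key)
                continue
            cur = getattr(base, key)
            if isinstance(cur, dict):
                if not isinstance(val, dict):
                    bad.append(key)
                    continue
                unknown = set(val) - set(cur)
                if unknown:
                    bad.extend(f"{key}.{u}" for u in sorted(unknown))
                cur.update({k: v for k, v in val.items() if k in cur})
            else:
                setattr(base, key, val)
        if bad:
            raise ConfigError(f"unknown configuration fields: {', '.join(sorted(bad))}")
        base.validate()
        return base

    # ---------------------------------------------------------------- yaml io
    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    # -------------------------------------------------------------- overrides
    def with_overrides(self, overrides: dict[str, Any]) -> "ExperimentConfig":
        """Apply dotted-path overrides, e.g. ``{"noise.sigma": 0.2}``."""
        d = self.to_dict()
        bad = []
        for dotted, value in overrides.items():
            parts = dotted.split(".")
            node = d
            try:
                for p in parts[:-1]:
                    node = node[p]
                if parts[-1] not in node:
                    raise KeyError(parts[-1])
                old = node[parts[-1]]
                if isinstance(old, bool) and isinstance(value, str):
                    value = value.lower() in ("1", "true", "yes")
                elif isinstance(old, (int, float)) and not isinstance(old, bool):
                    value = type(old)(float(value))
                node[parts[-1]] = value
            except (KeyError, TypeError):
                bad.append(dotted)
        if bad:
            raise ConfigError(f"unknown override fields: {', '.join(bad)}")
        return ExperimentConfig.from_dict(d)

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        bad = []
        if self.tuning["N"] < 4:
            bad.append("tuning.N (need >= 4)")
        if self.tuning["rho"] < 0:
            bad.append("tuning.rho (need >= 0)")
        if not (0 <= self.task["n0"] < 1):
            bad.append("task.n0 (need 0 <= n0 < 1)")
        if self.noise["sigma"] < 0:
            bad.append("noise.sigma (need >= 0)")
        if self.learning.get("eta_tilde", 0) < 0:
            bad.append("learning.eta_tilde (need >= 0)")
        if self.reward["family"] not in ("binary", "smooth_deterministic", "stochastic_bernoulli"):
            bad.append("reward.family")
        if self.reward["family"] != "binary" and self.reward["T"] <= 0:
            bad.append("reward.T (need > 0 for non-binary families)")
        if self.schedule["m"] < 1:
            bad.append("schedule.m (need >= 1)")
        if self.schedule["mode"] not in ("cyclic", "random_uniform"):
            bad.append("schedule.mode")
        if self.shaping["kind"] not in ("none", "target_size", "rotation_angle"):
            bad.append("shaping.kind")
        if self.n_trials < 1:
            bad.append("n_trials")
        if self.n_realizations < 1:
            bad.append("n_realizations")
        if bad:
            raise ConfigError(f"invalid configuration fields: {', '.join(bad)}")

    # -------------------------------------------------------------- compile
    def build(self) -> dict:
        """Compile the configuration into model objects (angles -> radians)."""
        self.validate()
        fld = TuningField(
            N=int(self.tuning["N"]),
            rho=float(self.tuning["rho"]),
            U_target=float(self.tuning.get("U_target", 1.0)),
        )
        reward = RewardSpec(family=self.reward["family"], T=float(self.reward["T"]))
        task = TaskSpec(
            field=fld,
            gamma=float(np.deg2rad(self.task["gamma_deg"])),
            n0=float(self.task["n0"]),
            reward=reward,
        )
        dirs = self.schedule.get("target_dirs_deg")
        schedule = ScheduleSpec(
            m=int(self.schedule["m"]),
            mode=self.schedule["mode"],
            target_dirs=None if dirs is None else tuple(np.deg2rad(d) for d in dirs),
            start_index=int(self.schedule.get("start_index", 0)),
        )
        sh = self.shaping
        shaping = ShapingSpec(
            kind=sh["kind"],
            n0_init=float(sh["n0_init"]),
            n0_step=float(sh["n0_step"]),
            n0_final=float(sh["n0_final"]),
            gamma_step=float(np.deg2rad(sh["gamma_step_deg"])),
            block_len=int(sh["block_len"]),
            ema_timescale=float(sh["ema_timescale"]),
            steady_tol=float(sh["steady_tol"]),
            per_target_monitoring=bool(sh["per_target_monitoring"]),
            adaptive=bool(sh.get("adaptive", False)),
        )
        noise = NoiseSpec(sigma=float(self.noise["sigma"]))
        learning = LearningSpec.from_eta_tilde(float(self.learning["eta_tilde"]), fld)
        return {
            "field": fld,
            "task": task,
            "schedule": schedule,
            "shaping": shaping,
            "noise": noise,
            "learning": learning,
            "n_trials": int(self.n_trials),
            "n_realizations": int(self.n_realizations),
            "seed": int(self.seed),
        }
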