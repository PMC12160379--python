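"""Run configuration: one YAML file with per-stage sections.

Sections map onto the pipeline stages: ``generator`` (synthetic cohort),
``model`` (bases/penalties/selection, optionally overridden per joint),
``winter`` (index windows and absence epsilon), ``report`` (draws, speeds),
plus a global ``seed``, ``out_dir`` and ``verbosity``.  Unknown keys are
rejected so typos fail loudly before any stage runs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .fosr import ModelSpec
from .preprocess import JOINTS
from .synthetic import GeneratorConfig

log = logging.getLogger("gaitpower")

_MODEL_KEYS = {
    "covariates",
    "k_time",
    "k_cov",
    "k_age",
    "k_speed",
    "k_time3",
    "penalty_order",
    "selection",
    "maxiter",
    "tol",
    "size",
}


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: dict = field(default_factory=dict)  # global + per-joint overrides
    winter: dict = field(default_factory=dict)  # window_overrides, absence_epsilon
    report: dict = field(default_factory=dict)  # n_draws, speeds
    joints: tuple[str, ...] = JOINTS
    seed: int = 0
    out_dir: str = "gaitpower_out"
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        self.joints = tuple(self.joints)
        unknown = set(self.joints) - set(JOINTS)
        if unknown:
            raise ValueError(f"unknown joints: {sorted(unknown)}")
        bad = set(self.model) - _MODEL_KEYS - set(JOINTS)
        if bad:
            raise ValueError(f"unknown model config keys: {sorted(bad)}")
        bad = set(self.winter) - {"window_overrides", "absence_epsilon"}
        if bad:
            raise ValueError(f"unknown winter config keys: {sorted(bad)}")
        bad = set(self.report) - {"n_draws", "speeds", "smoothing_uncertainty"}
        if bad:
            raise ValueError(f"unknown report config keys: {sorted(bad)}")

    def model_spec(self, joint: str) -> ModelSpec:
        """ModelSpec for one joint: global model keys + per-joint overrides."""
        opts: dict[str, Any] = {k: v for k, v in self.model.items() if k in _MODEL_KEYS}
        opts.update(self.model.get(joint, {}))
        size = opts.pop("size", "default")
        if "covariates" in opts:
            opts["covariates"] = tuple(opts["covariates"])
        return ModelSpec.for_joint(joint, size=size, **opts)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["effect_scale"] = dict(self.generator.effect_scale)
        d["generator"]["age_range"] = list(self.generator.age_range)
        d["joints"] = list(self.joints)
        return d


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> RunConfig:
    """Build a RunConfig from YAML plus flat overrides; rejects unknown keys."""
    raw: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file does not exist: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        for k, v in overrides.items():
            if v is not None:
                raw[k] = v
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    gen = raw.pop("generator", {})
    if isinstance(gen, dict):
        gen_known = {f.name for f in dataclasses.fields(GeneratorConfig)}
        bad = set(gen) - gen_known
        if bad:
            raise ValueError(f"unknown generator config keys: {sorted(bad)}")
        if "age_range" in gen:
            gen["age_range"] = tuple(gen["age_range"])
        if "seed" not in gen and "seed" in raw:
            gen["seed"] = raw["seed"]
        gen = GeneratorConfig(**gen)
    return RunConfig(generator=gen, **raw)


def setup_logging(verbosity: str = "INFO") -> None:
    """Structured logging to stderr; results go to files only."""
    logging.basicConfig(
        level=getattr(logging, verbosity.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        force=True,
    )
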