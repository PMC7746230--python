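"""Run configuration: calibration, analysis and layout parameters.

Loadable from a YAML key=value file; every CLI subcommand logs the
effective configuration so stochastic stages are reproducible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple

import yaml

from .core import ValidationError

log = logging.getLogger("afmbone")

# substrate -> reference solution used for display normalization
DEFAULT_REFERENCE_MAP = {"mica": "EDTA", "HA": "H2O"}


@dataclass
class RunConfig:
    # calibration
    temperature: float = 298.0            # K
    spring_constant_range: Tuple[float, float] = (0.001, 10.0)  # N/m
    beta: float = 1.0                     # thermal-method correction factor
    # analysis
    threshold_fraction: float = 0.01      # pulling-length cut, fraction of max force
    contact_threshold: float = 15e-9      # N, full-contact trigger
    integration_rule: str = "trapezoid"
    flat_curve_policy: str = "reject"     # "reject" | "zero"
    equal_variance: bool = True           # Student (pooled) unpaired t form
    stress_radius: str = "outer"          # bending-stress fiber: outer | mean
    # experiment layout
    reference_map: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_MAP))
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.threshold_fraction < 1.0):
            raise ValidationError("threshold_fraction must be in (0, 1)")
        if self.contact_threshold <= 0:
            raise ValidationError("contact_threshold must be positive")
        if self.integration_rule != "trapezoid":
            raise ValidationError(
                f"unknown integration rule {self.integration_rule!r}")
        if self.flat_curve_policy not in ("reject", "zero"):
            raise ValidationError("flat_curve_policy must be reject|zero")
        for substrate, ref in self.reference_map.items():
            if not isinstance(ref, str) or not ref:
                raise ValidationError(
                    f"substrate {substrate!r} needs exactly one reference solution")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError("config file must hold a key/value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "spring_constant_range" in data:
            data["spring_constant_range"] = tuple(data["spring_constant_range"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["spring_constant_range"] = list(d["spring_constant_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def log_effective(self) -> None:
        log.info("effective configuration: %s", asdict(self))
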