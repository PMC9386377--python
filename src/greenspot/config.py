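"""Pipeline configuration: schema, defaults, validation, YAML/JSON round-trip.

Defaults mirror the operating values of the reference system: 640x480 working
resolution, 5x5 mean filter, 3x3 open/close element, 8 concentric rings,
5-fold cross-validation, and the 2^-15..2^15 x 2^-10..2^10 hyperparameter
grid.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    # preprocessing
    target_w: int = 640
    target_h: int = 480
    mean_kernel: int = 5
    se_size: int = 3
    min_area: int = 50
    # shape features
    n_rings: int = 8
    ring_denominator: str = "annulus"    # or "blob"
    # classifier
    n_folds: int = 5
    c_exponents: tuple[int, int] = (-15, 15)
    sigma_exponents: tuple[int, int] = (-10, 10)
    seed: int = 0
    # synthetic data / simulation
    n_per_class: int = 25
    scenario_path: str | None = None
    sprayer_path: str | None = None
    out_dir: str = "greenspot_out"

    def validate(self) -> "PipelineConfig":
        if self.n_rings < 3:
            raise ValueError("n_rings must be >= 3 for the quadratic ring fit")
        if self.ring_denominator not in ("annulus", "blob"):
            raise ValueError(f"unknown ring_denominator {self.ring_denominator!r}")
        for name in ("mean_kernel", "se_size"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {v}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        for pth_name in ("scenario_path", "sprayer_path"):
            pth = getattr(self, pth_name)
            if pth is not None and not Path(pth).exists():
                raise FileNotFoundError(f"{pth_name} does not exist: {pth}")
        return self


_FIELDS = set(PipelineConfig.__dataclass_fields__)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML or JSON config; unknown keys are rejected."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(data) - _FIELDS
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    for key in ("c_exponents", "sigma_exponents"):
        if key in data:
            data[key] = tuple(data[key])
    return PipelineConfig(**data).validate()


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    data = asdict(cfg)
    for key in ("c_exponents", "sigma_exponents"):
        data[key] = list(data[key])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
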