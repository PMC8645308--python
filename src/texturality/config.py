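"""Resolved run configuration shared by the CLI subcommands."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classifier import PRESETS, SVMHyperparams
from .errors import ValidationError
from .pyramid import PyramidConfig
from .summary_features import FrequencyMap

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a run needs; written next to each command's outputs."""

    n_scales: int = 4
    n_orientations: int = 4
    neighborhood: int = 7
    image_size: int = 256
    deg_per_image: float = 4.1
    select_k: int = 6
    preset: str | None = None
    box_constraint: float | None = None
    kernel_scale: float | None = None
    folds: int = 10
    seed: int = 0
    min_trials: int = 4

    def pyramid_config(self) -> PyramidConfig:
        return PyramidConfig(
            n_scales=self.n_scales,
            n_orientations=self.n_orientations,
            neighborhood=self.neighborhood,
            image_size=self.image_size,
        )

    def frequency_map(self) -> FrequencyMap:
        return FrequencyMap(
            image_size=self.image_size,
            deg_per_image=self.deg_per_image,
            n_scales=self.n_scales,
        )

    def hyperparams(self) -> SVMHyperparams:
        if self.preset is not None:
            if self.preset not in PRESETS:
                raise ValidationError(
                    f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}"
                )
            return PRESETS[self.preset]
        if self.box_constraint is not None and self.kernel_scale is not None:
            return SVMHyperparams(self.box_constraint, self.kernel_scale)
        raise ValidationError(
            "either a preset or both box_constraint and kernel_scale required"
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        ) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.pyramid_config()  # validate eagerly
        return cfg

    def write_resolved(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))
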