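"""Strictly validated JSON pipeline configuration.

One schema covers segmentation parameters, statistics parameters, the
simulation block, and seeds. Unknown keys are rejected (naming the key) so
a typo cannot silently fall back to a default, and every run embeds the
SHA-256 hash of its canonical serialised config in its outputs for
provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .errors import ConfigError
from .gmm import GMMConfig
from .segment import SegmentationConfig


@dataclass
class SimulationBlock:
    phantoms_per_group: int = 3
    grid_shape: tuple = (64, 64, 64)
    noise_sd: float = 5.0
    cohort_design: str = "three_group"  # or "als_hc"


@dataclass
class StatsBlock:
    fwe_method: str = "bonferroni"
    alpha: float = 0.05
    covariates: tuple = ("age", "sex", "tiv_mm3")


@dataclass
class PipelineConfig:
    sigma_mm: float = 1.0
    brightness_threshold: float | None = None
    radius_factor: float = 3.0
    gmm_mode: str = "map"
    gmm_tol: float = 1e-6
    gmm_max_iter: int = 500
    gmm_init: str = "quantile"
    min_component_voxels: int | None = None
    simulation: SimulationBlock = field(default_factory=SimulationBlock)
    stats: StatsBlock = field(default_factory=StatsBlock)
    seed: int = 0

    def segmentation_config(self, seed: int | None = None) -> SegmentationConfig:
        return SegmentationConfig(
            sigma_mm=self.sigma_mm,
            brightness_threshold=self.brightness_threshold,
            radius_factor=self.radius_factor,
            gmm=GMMConfig(
                mode=self.gmm_mode,
                tol=self.gmm_tol,
                max_iter=self.gmm_max_iter,
                init=self.gmm_init,
                seed=seed,
            ),
            min_component_voxels=self.min_component_voxels,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["grid_shape"] = list(self.simulation.grid_shape)
        d["stats"]["covariates"] = list(self.stats.covariates)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if not isinstance(data, dict):
            raise ConfigError("config must be a JSON object")
        data = dict(data)
        kwargs = {}
        for block_name, block_cls in (("simulation", SimulationBlock),
                                      ("stats", StatsBlock)):
            if block_name in data:
                block = data.pop(block_name)
                if not isinstance(block, dict):
                    raise ConfigError(f"'{block_name}' must be an object")
                allowed = {f.name for f in dataclasses.fields(block_cls)}
                unknown = set(block) - allowed
                if unknown:
                    raise ConfigError(
                        f"unknown key(s) in '{block_name}': {sorted(unknown)}"
                    )
                if "grid_shape" in block:
                    block["grid_shape"] = tuple(block["grid_shape"])
                if "covariates" in block:
                    block["covariates"] = tuple(block["covariates"])
                kwargs[block_name] = block_cls(**block)
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        # sigma_mm is the one pipeline parameter with a canonical stated
        # value; an explicit entry is required so configs are self-documenting
        if "sigma_mm" not in data:
            raise ConfigError("missing required field 'sigma_mm'")
        kwargs.update(data)
        try:
            cfg = cls(**kwargs)
        except TypeError as e:
            raise ConfigError(str(e)) from e
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as e:
            raise ConfigError(f"invalid JSON: {e}") from e
        return cls.from_dict(data)

    def validate(self) -> None:
        if self.sigma_mm is None or self.sigma_mm <= 0:
            raise ConfigError("field 'sigma_mm' must be a positive number")
        if self.brightness_threshold is not None and self.brightness_threshold <= 0:
            raise ConfigError("field 'brightness_threshold' must be positive "
                              "or null")
        if self.gmm_mode not in ("ml", "map"):
            raise ConfigError("field 'gmm_mode' must be 'ml' or 'map'")
        if self.gmm_init not in ("quantile", "random"):
            raise ConfigError("field 'gmm_init' must be 'quantile' or 'random'")
        if self.stats.fwe_method not in ("bonferroni", "holm"):
            raise ConfigError("field 'stats.fwe_method' must be 'bonferroni' "
                              "or 'holm'")
        if not 0 < self.stats.alpha < 1:
            raise ConfigError("field 'stats.alpha' must be in (0, 1)")
        if self.simulation.cohort_design not in ("three_group", "als_hc"):
            raise ConfigError("field 'simulation.cohort_design' must be "
                              "'three_group' or 'als_hc'")
        if self.simulation.phantoms_per_group < 1:
            raise ConfigError("field 'simulation.phantoms_per_group' must be "
                              ">= 1")
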