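"""Pipeline configuration: one structured file drives every stage.

Every threshold and default lives here; omitted keys are filled from
the documented defaults, and a config round-trips through YAML
unchanged.  All randomness flows from the single root ``seed``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .channel import ChannelGeometry
from .simulate import (AcquisitionConfig, ArtifactsConfig, PhenotypeConfig,
                       default_phenotypes)


@dataclass
class PipelineConfig:
    seed: int = 0
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    phenotypes: list[PhenotypeConfig] = field(
        default_factory=default_phenotypes)
    n_per_phenotype: int = 50
    mean_gap_s: float = 0.010
    artifacts: ArtifactsConfig = field(default_factory=ArtifactsConfig)
    # event filters
    hull_threshold: float = 1.1
    radius_sd_threshold: float = 3.0
    # tracking
    max_displacement: float = 15.0
    entry_threshold: float = 0.0
    # learning protocol
    split_ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    stratified: bool = True
    class_pair: tuple[str, str] = ("HL60", "HL60d")
    extended_moments: bool = False
    models: list[str] = field(default_factory=lambda: ["random_forest"])
    gru_units: int = 24
    gru_epochs: int = 175
    cnn_gru_units: int = 24
    cnn_gru_epochs: int = 30
    # enrichment
    rarity: float = 0.001

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = self.geometry.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "geometry" in d:
            d["geometry"] = ChannelGeometry.from_dict(d["geometry"])
        if "acquisition" in d:
            a = dict(d["acquisition"])
            if "frame_shape" in a:
                a["frame_shape"] = tuple(a["frame_shape"])
            d["acquisition"] = AcquisitionConfig(**a)
        if "phenotypes" in d:
            d["phenotypes"] = [PhenotypeConfig(**p) for p in d["phenotypes"]]
        if "artifacts" in d:
            d["artifacts"] = ArtifactsConfig(**d["artifacts"])
        for key in ("split_ratios", "class_pair"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
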