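"""Pipeline configuration with the orchard operating-point defaults.

Every default matches the operating point of the method: 640x480 working
resolution, 40x40 patch size, 40 px cluster-diameter threshold, circle
radii 30–50 px with Hough sensitivity 0.97, 15 px duplicate threshold,
radius-10 disk dilation, 0.6 NCC acceptance, k = 5 neighbours, hidden
width J = 7, stride 8 px and a 200 mm baseline.  Configurations
round-trip through YAML unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class PipelineConfig:
    image_size: tuple[int, int] = (640, 480)
    patch_size: int = 40
    cluster_diameter: float = 40.0
    r_min: int = 30
    r_max: int = 50
    sensitivity: float = 0.97
    dedup_threshold: float = 15.0
    dilation_radius: int = 10
    ncc_threshold: float = 0.6
    disparity_max: int = 200
    knn_k: int = 5
    bp_hidden: int = 7
    seed: int = 1234
    stride: int = 8
    baseline_mm: float = 200.0
    row_tolerance: float = 1.0

    def __post_init__(self) -> None:
        self.image_size = tuple(self.image_size)  # type: ignore[assignment]

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["image_size"] = list(self.image_size)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def override(self, **kwargs) -> "PipelineConfig":
        """Copy with flag overrides; flags win over file values."""
        doc = asdict(self)
        doc.update({k: v for k, v in kwargs.items() if v is not None})
        return PipelineConfig.from_dict(doc)
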