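"""Run configuration: every pipeline constant in one auditable place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .errors import InvalidParameterError


@dataclass
class RunConfig:
    """All tunable constants of the reconstruction + analysis pipeline.

    Defaults are the pipeline's published operating point: 2.5x excision
    radius, first 20 shape modes, 1 degree ray spacing with a 4-intersection
    cap, 200-point cluster floor, regional extents of 2.2x / 1.9x / 0.86x
    the acetabular radius.
    """

    # shape model
    n_modes: int = 20
    n_training: int = 57
    allow_scale: bool = True
    # frame / excision
    excision_factor: float = 2.5
    n_rim_points: int = 19
    body_axes_hint: tuple = (0.0, 1.0, 0.0)
    # ray casting
    angular_spacing_deg: float = 1.0
    max_intersections: int = 4
    # defect extraction
    cluster_min_size: int = 200
    min_interval_thickness_mm: float = 2.0
    densify_step_mm: float = 1.0
    min_component_cm3: float = 0.5
    # regions (x acetabular radius)
    superior_extent_factor: float = 2.2
    anteroposterior_extent_factor: float = 1.9
    medial_wall_radius_factor: float = 0.86
    # voxel pitches (mm)
    boolean_pitch_mm: float = 0.7
    metrics_pitch_mm: float = 0.7
    dice_pitch_mm: float = 1.0
    truth_pitch_mm: float = 0.5
    mesh_pitch_mm: float = 1.25
    # synthetic suite
    seed: int = 1
    n_per_size: int = 4

    def validate(self):
        positive = ("excision_factor", "angular_spacing_deg",
                    "min_interval_thickness_mm", "densify_step_mm",
                    "superior_extent_factor", "anteroposterior_extent_factor",
                    "medial_wall_radius_factor", "boolean_pitch_mm",
                    "metrics_pitch_mm", "dice_pitch_mm", "truth_pitch_mm",
                    "mesh_pitch_mm")
        for name in positive:
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        for name in ("n_modes", "n_training", "cluster_min_size",
                     "max_intersections", "n_rim_points"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["body_axes_hint"] = list(self.body_axes_hint)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if "body_axes_hint" in data:
            data = dict(data)
            data["body_axes_hint"] = tuple(data["body_axes_hint"])
        cfg = cls(**data)
        return cfg.validate()
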