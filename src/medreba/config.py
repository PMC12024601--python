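"""YAML-backed session configuration."""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .joint_angles import DEFAULT_VISIBILITY_THRESHOLD, PostureFlags
from .reba_core import Adjustments


@dataclass
class AssessConfig:
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD
    adjustments: Adjustments = field(default_factory=Adjustments)
    flags: PostureFlags = field(default_factory=PostureFlags)
    neck_reference: str = "absolute"  # or "trunk_relative"

    @classmethod
    def from_dict(cls, data: dict) -> "AssessConfig":
        adj = Adjustments(**data.get("adjustments", {}))
        flags = PostureFlags(**data.get("flags", {}))
        return cls(
            visibility_threshold=float(
                data.get("visibility_threshold", DEFAULT_VISIBILITY_THRESHOLD)),
            adjustments=adj,
            flags=flags,
            neck_reference=data.get("neck_reference", "absolute"),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "AssessConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
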