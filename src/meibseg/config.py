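"""YAML experiment configuration.

One YAML file drives every command; each command reads its own section and
CLI flags override config values.  ``load_config`` validates the section
names and types up front so a bad config fails before any data is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ProjectConfig", "load_config", "DEFAULT_CONFIG"]

_KNOWN_SECTIONS = {
    "generate", "preprocess", "split", "train_classifier", "train_prior",
    "train_seg", "predict", "evaluate", "common",
}


@dataclass
class ProjectConfig:
    seed: int = 0
    image_height: int = 64
    image_width: int = 128
    sections: dict = field(default_factory=dict)

    def section(self, name: str) -> dict:
        return dict(self.sections.get(name, {}))


DEFAULT_CONFIG = ProjectConfig()


def load_config(path: str | Path | None) -> ProjectConfig:
    if path is None:
        return ProjectConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    common = raw.get("common", {})
    for key in ("seed", "image_height", "image_width"):
        if key in common and not isinstance(common[key], int):
            raise ValueError(f"common.{key} must be an integer")
    cfg = ProjectConfig(
        seed=common.get("seed", 0),
        image_height=common.get("image_height", 64),
        image_width=common.get("image_width", 128),
        sections={k: v for k, v in raw.items() if k != "common"},
    )
    return cfg
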