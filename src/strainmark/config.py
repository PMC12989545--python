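"""One-document YAML configuration for the whole pipeline.

A config file may carry any subset of the sections below; omitted keys
take their defaults. Unknown keys at any level are a hard error — a
typo must never silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .melt import MeltConfig
from .novelty import NoveltyConfig
from .primers import PrimerCriteria
from .uniqueness import ScreenConfig


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    primers: PrimerCriteria = field(default_factory=PrimerCriteria)
    melt: MeltConfig = field(default_factory=MeltConfig)
    novelty: NoveltyConfig = field(default_factory=NoveltyConfig)
    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        if not isinstance(doc, dict):
            raise ConfigError("config document must be a mapping")
        sections = {
            "screen": ScreenConfig,
            "primers": PrimerCriteria,
            "melt": MeltConfig,
            "novelty": NoveltyConfig,
        }
        kwargs: dict = {}
        for key, value in doc.items():
            if key == "seed":
                kwargs["seed"] = int(value)
            elif key in sections:
                klass = sections[key]
                known = {f.name for f in dataclasses.fields(klass)}
                unknown = set(value or {}) - known
                if unknown:
                    raise ConfigError(
                        f"unknown key {sorted(unknown)[0]!r} in section {key!r}"
                    )
                kwargs[key] = klass(**(value or {}))
            else:
                raise ConfigError(f"unknown config key {key!r}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "screen": dataclasses.asdict(self.screen),
            "primers": dataclasses.asdict(self.primers),
            "melt": dataclasses.asdict(self.melt),
            "novelty": dataclasses.asdict(self.novelty),
            "seed": self.seed,
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
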