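"""Run configuration: one YAML-serializable object spanning all stages.

Every output artifact written by the orchestrator embeds the hash of the
configuration that produced it, so two runs are comparable by hash alone.
Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ihc import IhcConfig
from .pet import PetConfig
from .stats import PipelineConfig

__all__ = ["RunConfig", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "heteroduo_out"
    microns_per_pixel: float | None = None  # overrides TIFF tags when set
    max_patient_failure_fraction: float = 0.2
    ihc: IhcConfig = field(default_factory=IhcConfig)
    pet: PetConfig = field(default_factory=PetConfig)
    stats: PipelineConfig = field(default_factory=PipelineConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(klass, data):
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(data) - names
            if unknown:
                raise ValueError(
                    f"unknown {klass.__name__} keys: {sorted(unknown)}"
                )
            return klass(**data)

        sub = {}
        for key, klass in (("ihc", IhcConfig), ("pet", PetConfig),
                           ("stats", PipelineConfig)):
            if key in raw:
                data = raw.pop(key)
                if "ihc_prefixes" in data:
                    data["ihc_prefixes"] = tuple(data["ihc_prefixes"])
                sub[key] = build(klass, data)
        cfg = build(RunConfig, raw)
        return dataclasses.replace(cfg, **sub)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the analysis configuration (covers every stage).

    The output directory is excluded: two runs of the same analysis into
    different directories are the same run.
    """
    d = cfg.to_dict()
    d.pop("out_dir", None)
    canon = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
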