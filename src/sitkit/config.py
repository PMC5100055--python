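"""Structured configuration aggregating every stage's parameters.

All thresholds of the decision procedure live in one auditable place
and round-trip losslessly through YAML.  Precedence when running the
CLI is flags > config file > defaults.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .align import AlignParams
from .decontam import DecontamConfig
from .masking import MaskParams
from .simulate import SimParams
from .sit import TmdParams

__all__ = ["ToolConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class ToolConfig:
    mask: MaskParams = field(default_factory=MaskParams)
    align: AlignParams = field(default_factory=AlignParams)
    decontam: DecontamConfig = field(default_factory=DecontamConfig)
    tmd: TmdParams = field(default_factory=TmdParams)
    sim: SimParams = field(default_factory=SimParams)
    motif_margin: int = 15
    support_threshold: float = 70.0
    seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["decontam"]["excluded_pairs"] = sorted(
            sorted(pair) for pair in self.decontam.excluded_pairs
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ToolConfig":
        d = dict(d)
        kwargs = {}
        if "mask" in d:
            kwargs["mask"] = MaskParams(**d.pop("mask"))
        if "align" in d:
            kwargs["align"] = AlignParams(**d.pop("align"))
        if "decontam" in d:
            dec = dict(d.pop("decontam"))
            if "excluded_pairs" in dec:
                dec["excluded_pairs"] = frozenset(
                    frozenset(pair) for pair in dec["excluded_pairs"]
                )
            kwargs["decontam"] = DecontamConfig(**dec)
        if "tmd" in d:
            kwargs["tmd"] = TmdParams(**d.pop("tmd"))
        if "sim" in d:
            kwargs["sim"] = SimParams(**d.pop("sim"))
        kwargs.update(d)
        return cls(**kwargs)

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def with_seed(self, seed: int) -> "ToolConfig":
        return replace(self, seed=seed, sim=replace(self.sim, seed=seed))


def load_config(path: str | Path) -> ToolConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ToolConfig.from_dict(data)


def save_config(cfg: ToolConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
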