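"""Run configuration: one serializable source of truth for an experiment.

A :class:`RunConfig` mirrors the CLI flags 1:1, round-trips losslessly
through YAML, and hashes canonically so every output artefact can name the
exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    metric: str = "smi"
    bins: int | None = None
    linkage: str = "average"
    k: int | None = None
    k_min: int = 2
    k_max: int = 10
    svm_c: float = 1.0
    svm_gamma: float | str = "scale"
    fraction: float = 0.55
    seeds: tuple[int, ...] = (0,)

    def validate(self) -> None:
        if self.metric not in ("mi", "smi", "smi-scalar", "random"):
            raise ValueError(f"invalid metric {self.metric!r}")
        if self.linkage not in ("average", "single", "complete"):
            raise ValueError(f"invalid linkage {self.linkage!r}")
        if self.bins is not None and self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must be in (0, 1)")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be > 0")
        if not self.seeds:
            raise ValueError("need at least one seed")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seeds"] = list(self.seeds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        if "seeds" in d:
            d["seeds"] = tuple(int(s) for s in d["seeds"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Short stable digest of the canonical JSON form."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
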