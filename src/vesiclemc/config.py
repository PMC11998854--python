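"""Run configuration: YAML round-trip, strict keys, provenance manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .energetics import EnergyParams
from .engine import SimParams

__all__ = ["RunConfig", "load_config", "write_manifest"]

SCHEMA_VERSION = 1


def _strict_build(cls, data: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Full parameter tree of a simulation or analysis run."""

    sim: SimParams = field(default_factory=SimParams)
    schema_version: int = SCHEMA_VERSION
    out_dir: str = "runs"
    label: str = "run"
    delta_mu: float = 0.0
    mu_eq: Optional[float] = None    # calibrated when absent
    lmax: Optional[int] = None       # spectrum cutoff; None = N-based default
    snapshot_every: int = 0          # 0 = final configurations only

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        version = data.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema {version}")
        if "sim" in data:
            sim = dict(data["sim"])
            if "energy" in sim:
                sim["energy"] = _strict_build(EnergyParams,
                                              dict(sim["energy"]),
                                              "sim.energy")
            data["sim"] = _strict_build(SimParams, sim, "sim")
        return _strict_build(cls, data, "run config")

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str) -> RunConfig:
    return RunConfig.from_yaml(Path(path).read_text())


def write_manifest(cfg: RunConfig, out_dir: str, extra: Optional[dict] = None
                   ) -> Path:
    """Write a reproducibility manifest: resolved config, its hash, seed
    and version info, sufficient to re-run bit-for-bit."""
    from . import __version__
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.sim.seed,
        "package_version": __version__,
        "python": platform.python_version(),
    }
    if extra:
        manifest["extra"] = extra
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
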