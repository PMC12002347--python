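"""Run configuration: plain-text (YAML) round trip, strict key checking,
and the manifest written next to every run's outputs."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .parameters import ModelParameters
from .stimulus import NoiseConfig

__all__ = ["ProtocolConfig", "RunConfig", "load_config", "write_manifest"]


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing of the feeding-command protocol and output sampling."""

    plateau_ms: float = 250.0
    isi_ms: float = 250.0
    t_first_ms: float = 100.0
    t_total_ms: float = 5_000.0
    dt_out_ms: float = 0.5

    def __post_init__(self):
        for name in ("plateau_ms", "isi_ms", "t_first_ms", "t_total_ms",
                     "dt_out_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one run.

    Defaults reproduce the reference conditions: the standard constants,
    no noise, the 250/250 ms protocol.
    """

    params: ModelParameters = field(default_factory=ModelParameters)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    seed: int = 0
    out_dir: str = "."

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "noise": dataclasses.asdict(self.noise),
            "protocol": dataclasses.asdict(self.protocol),
            "seed": self.seed,
            "out_dir": self.out_dir,
        }


def _build_strict(cls, d: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise KeyError(f"unknown key(s) at {path}: {sorted(unknown)}; "
                       f"valid keys: {sorted(known)}")
    return cls(**d)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; omitted keys take the reference
    defaults, unknown keys raise with their key path."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw)}")
    top_known = {"params", "noise", "protocol", "seed", "out_dir"}
    unknown = set(raw) - top_known
    if unknown:
        raise KeyError(f"unknown top-level key(s): {sorted(unknown)}; "
                       f"valid keys: {sorted(top_known)}")
    params = ModelParameters.from_dict(raw.get("params", {}) or {})
    noise = _build_strict(NoiseConfig, raw.get("noise", {}) or {}, "noise")
    protocol = _build_strict(ProtocolConfig, raw.get("protocol", {}) or {},
                             "protocol")
    return RunConfig(params=params, noise=noise, protocol=protocol,
                     seed=int(raw.get("seed", 0)),
                     out_dir=str(raw.get("out_dir", ".")))


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def write_manifest(out_dir, cfg: RunConfig, extra: dict | None = None) -> Path:
    """Write the reproducibility manifest (resolved config + seeds +
    package version) as JSON next to a run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "pharynxsim",
        "version": __version__,
        "config": cfg.to_dict(),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
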