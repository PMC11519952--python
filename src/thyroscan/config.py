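"""Run configuration and seed derivation.

One global seed fans out to fixed per-module child seeds so that modules
stay reproducible independently of each other's draw counts.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


def child_seed(seed: int, name: str) -> int:
    """Deterministic per-module child seed, always below 2**31."""
    h = zlib.crc32(name.encode("utf-8"))
    return int((seed ^ h) % (2**31))


_SECTIONS = ("phantom", "control", "bo", "rl", "tirads")


@dataclass
class RunConfig:
    """Global configuration of a reproducible run.

    Section dicts are passed through to the corresponding module
    constructors; unknown top-level keys are rejected on load.
    """

    seed: int = 0
    output_dir: str = "runs"
    phantom: dict = field(default_factory=dict)
    control: dict = field(default_factory=dict)
    bo: dict = field(default_factory=dict)
    rl: dict = field(default_factory=dict)
    tirads: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {"seed", "output_dir", *_SECTIONS}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def module_seed(self, name: str) -> int:
        return child_seed(self.seed, name)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def run_header(self) -> dict:
        from . import __version__

        return {
            "version": __version__,
            "seed": self.seed,
            "config_hash": self.config_hash(),
        }
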