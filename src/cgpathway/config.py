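"""Declarative run configuration.

A single JSON (or TOML) file describes a whole run: endpoint files and
selections, every energy constant, every morph knob, and the analysis
parameters.  The loaded configuration is echoed verbatim into the
output directory so runs are self-describing, and a sha256 of its
canonical JSON form is logged as the run identity.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

from .energy import EnergyParams
from .errors import InputError
from .morph import MorphConfig


@dataclass
class RunConfig:
    start_path: str = ""
    target_path: str = ""
    chains: list[str] | None = None
    model_index: int = 0
    hetero_names: list[str] = field(default_factory=list)
    energy: EnergyParams = field(default_factory=EnergyParams)
    morph: MorphConfig = field(default_factory=MorphConfig)
    n_intermediates: int = 30
    endpoint_relax_iters: int = 200
    smooth_window: int = 1
    prominence_threshold: float = 0.5
    tau: float = 0.25
    out_dir: str = "cgpathway_out"
    seed: int = 0

    def __post_init__(self) -> None:
        # the master seed drives every stochastic stage
        self.morph.seed = self.seed

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "energy" in d and not isinstance(d["energy"], EnergyParams):
            d["energy"] = EnergyParams.from_dict(d["energy"])
        if "morph" in d and not isinstance(d["morph"], MorphConfig):
            d["morph"] = MorphConfig.from_dict(d["morph"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise InputError(f"bad configuration key: {exc}") from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        try:
            if path.suffix.lower() == ".toml":
                with open(path, "rb") as fh:
                    data = tomllib.load(fh)
            else:
                with open(path) as fh:
                    data = json.load(fh)
        except (OSError, ValueError) as exc:
            raise InputError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(data)

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def sha256(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()
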