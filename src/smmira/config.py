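"""Run configuration: YAML-backed settings for the CLI workflows."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ensemble import EnsembleConfig
from .errors import ConfigError
from .ni import NIConfig
from .rbm import RBMConfig


@dataclass
class DataConfig:
    edges: str = ""
    sm_universe: str | None = None
    mirna_universe: str | None = None
    sm_similarities: list[str] = field(default_factory=list)
    mirna_similarities: list[str] = field(default_factory=list)
    sm_weights: list[float] | None = None
    mirna_weights: list[float] | None = None


@dataclass
class EvalConfig:
    protocol: str = "global_loocv"
    kfold_k: int = 5
    repetitions: int = 1
    seed: int = 0
    tune_per_fold: bool = False
    rbm_retrain: str = "full"


@dataclass
class RunConfig:
    data: DataConfig = field(default_factory=DataConfig)
    ni: NIConfig = field(default_factory=NIConfig)
    rbm: RBMConfig = field(default_factory=RBMConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            data = DataConfig(**raw.get("data", {}))
            ni_raw = dict(raw.get("ni", {}))
            if "grid" in ni_raw:
                ni_raw["grid"] = tuple(float(x) for x in ni_raw["grid"])
            ni = NIConfig(**ni_raw)
            rbm = RBMConfig(**raw.get("rbm", {}))
            ensemble = EnsembleConfig(**raw.get("ensemble", {}))
            ev = EvalConfig(**raw.get("eval", {}))
        except TypeError as exc:
            raise ConfigError(f"unrecognized configuration key: {exc}") from exc
        return cls(data=data, ni=ni, rbm=rbm, ensemble=ensemble, eval=ev)

    def provenance(self, input_paths: list[str | Path]) -> dict:
        """Checksums and settings sufficient to reproduce a run."""
        checksums = {}
        for p in input_paths:
            p = Path(p)
            checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        cfg = {
            "data": vars(self.data),
            "ni": {"grid": list(self.ni.grid), "sigma_upper": self.ni.sigma_upper},
            "rbm": {
                "hidden_units": self.rbm.hidden_units,
                "learning_rate": self.rbm.learning_rate,
                "epochs": self.rbm.epochs,
                "batch_size": self.rbm.batch_size,
                "cd_steps": self.rbm.cd_steps,
                "seed": self.rbm.seed,
            },
            "ensemble": {
                "tanh_scale": self.ensemble.tanh_scale,
                "weight_ni": self.ensemble.weight_ni,
            },
            "eval": vars(self.eval),
        }
        blob = json.dumps(cfg, sort_keys=True)
        return {
            "config": cfg,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "input_sha256": checksums,
        }
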