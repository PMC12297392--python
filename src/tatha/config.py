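"""Run configuration: one YAML file covering every pipeline stage.

Each section maps onto the dataclass of its module (preprocess, tnet,
loss, train, ensemble, synth) and is validated at load time; a sha256
digest of the canonical serialization identifies the configuration in run
logs and ensemble manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .losses import LossParams
from .preprocess import ClaheParams, DiffusionParams, PreprocessConfig
from .synth import PhantomSpec
from .tnet import TNetConfig
from .training import TrainConfig


@dataclass
class EnsembleConfig:
    n_extractors: int = 3
    tau: float = 10.0

    def validate(self) -> None:
        if self.n_extractors < 1:
            raise ValueError("n_extractors must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass
class RunConfig:
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    tnet: TNetConfig = field(default_factory=TNetConfig)
    loss: LossParams = field(default_factory=LossParams)
    train: TrainConfig = field(default_factory=TrainConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    synth: PhantomSpec = field(default_factory=PhantomSpec)

    def validate(self) -> None:
        self.preprocess.diffusion.validate()
        self.preprocess.clahe.validate()
        self.tnet.validate()
        self.loss.validate()
        self.train.validate()
        self.ensemble.validate()
        self.synth.validate()

    def as_dict(self) -> dict:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, tuple):
                return list(o)
            return o
        d = {name: enc(getattr(self, name))
             for name in ("seed", "preprocess", "tnet", "loss",
                          "train", "ensemble", "synth")}
        return d

    @property
    def digest(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in data.items():
        if k not in fields:
            raise ValueError(f"unknown {cls.__name__} field: {k}")
        ftype = fields[k].type
        if isinstance(v, dict):
            sub = {"diffusion": DiffusionParams, "clahe": ClaheParams,
                   "loss": LossParams}.get(k)
            v = _build(sub, v) if sub else v
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; missing sections take
    their documented defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    sections = {"preprocess": PreprocessConfig, "tnet": TNetConfig,
                "loss": LossParams, "train": TrainConfig,
                "ensemble": EnsembleConfig, "synth": PhantomSpec}
    kwargs = {}
    for name, cls in sections.items():
        if name in data:
            kwargs[name] = _build(cls, data.pop(name))
    if "seed" in data:
        kwargs["seed"] = int(data.pop("seed"))
    if data:
        raise ValueError(f"unknown config sections: {sorted(data)}")
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.as_dict(), sort_keys=False))
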