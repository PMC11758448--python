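"""Run configuration: one YAML file drives every pipeline stage.

Every stochastic component derives its seed deterministically from
``global_seed`` so a completed run is replayable bit for bit (in
single-threaded mode) from its config file alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .model import ModelConfig
from .phantom import PhantomConfig
from .preprocess import PreprocSpec
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]


def _build(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise KeyError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preproc: PreprocSpec | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_cases: int = 20
    output_dir: str = "runs/out"
    global_seed: int = 0

    def seeded(self, stage: str) -> int:
        """Deterministic per-stage child seed (kept below 2**31)."""
        import zlib
        import numpy as np
        ss = np.random.SeedSequence([self.global_seed,
                                     zlib.crc32(stage.encode())])
        return int(ss.generate_state(1)[0] % (2 ** 31))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(
        phantom=_build(PhantomConfig, raw.get("phantom", {})),
        preproc=(_build(PreprocSpec, raw["preproc"]) if "preproc" in raw else None),
        model=_build(ModelConfig, raw.get("model", {})),
        train=_build(TrainConfig, raw.get("train", {})),
        n_cases=int(raw.get("n_cases", 20)),
        output_dir=str(raw.get("output_dir", "runs/out")),
        global_seed=int(raw.get("global_seed", 0)))


def save_config(config: RunConfig, path: str | Path) -> None:
    data = {
        "phantom": asdict(config.phantom),
        "model": asdict(config.model),
        "train": asdict(config.train),
        "n_cases": config.n_cases,
        "output_dir": config.output_dir,
        "global_seed": config.global_seed,
    }
    if config.preproc is not None:
        data["preproc"] = asdict(config.preproc)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
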