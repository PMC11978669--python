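"""Pipeline configuration: every stage's tunables in one dataclass, YAML-round-trippable."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .cvae import CVAEConfig


@dataclass
class PipelineConfig:
    # preprocessing
    target_fs: float = 2560.0
    filter_mode: str = "continuous"      # or "per_segment"
    # STE initial detector
    ste_k: float = 5.0                   # SD weight; the screening stage is
    ste_frame_ms: float = 10.0           # deliberately sensitivity-first
    ste_min_consecutive: int = 3
    ste_trim_fraction: float = 0.02
    # time-frequency imaging
    tfm_gamma: float = 3.0
    tfm_beta: float = 20.0
    tfm_voices: int = 16
    tfm_freq_range: tuple[float, float] = (60.0, 600.0)
    # auto-encoder
    cvae: CVAEConfig = field(default_factory=CVAEConfig)
    # clustering / class assignment
    cluster_method: str = "fcm"
    cluster_k: int = 4
    fcm_m: float = 2.0
    cluster_seed: int = 0
    # evaluation: the first-three-frames centre rule can sit several tens of
    # ms early on long events, so matching uses 100 ms (still unambiguous at
    # the generator's 300 ms minimum event spacing)
    match_tol_s: float = 0.1

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["tfm_freq_range"] = list(self.tfm_freq_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "cvae" in kwargs and isinstance(kwargs["cvae"], dict):
            kwargs["cvae"] = CVAEConfig(**kwargs["cvae"])
        if "tfm_freq_range" in kwargs:
            kwargs["tfm_freq_range"] = tuple(kwargs["tfm_freq_range"])
        return cls(**kwargs)
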