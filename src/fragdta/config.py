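"""Run configuration: one structured, human-editable YAML file covering
every architectural and training parameter, with the published architecture
as defaults (GIN: 5 layers, hidden size 60; CNNs: 3 layers, filters
32/64/128, kernels 5/5/3; predictor 512/128/1; K = 64 fragments; 64 drug
rows), plus the two ablation switches (no pretraining, 1D convolutions).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .infograph import EncoderConfig
from .model import CNNConfig, PredictorConfig, TrainOptions
from .segmentation import WindowConfig


@dataclass(frozen=True)
class PretrainOptions:
    epochs: int = 20
    batch_size: int = 32
    lr: float = 1e-3


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    drug_rows: int = 64
    window: WindowConfig = field(default_factory=WindowConfig)
    drug_encoder: EncoderConfig = field(default_factory=EncoderConfig)
    target_encoder: EncoderConfig = field(default_factory=EncoderConfig)
    drug_cnn: CNNConfig = field(default_factory=CNNConfig)
    target_cnn: CNNConfig = field(default_factory=CNNConfig)
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    pretrain: PretrainOptions = field(default_factory=PretrainOptions)
    train: TrainOptions = field(default_factory=TrainOptions)
    no_pretrain: bool = False      # ablation: randomly initialized encoders
    use_1d_cnn: bool = False       # ablation: convolve along rows only
    fragment_graphs: str = "residue"   # "residue" chain | "peptide" atom-level

    def __post_init__(self):
        if self.fragment_graphs not in ("residue", "peptide"):
            raise ValueError("fragment_graphs must be 'residue' or 'peptide'")

    def with_ablations(self) -> "RunConfig":
        """Apply the 1D-CNN switch to both CNN configs."""
        if not self.use_1d_cnn:
            return self
        return replace(
            self,
            drug_cnn=replace(self.drug_cnn, use_1d=True),
            target_cnn=replace(self.target_cnn, use_1d=True),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def tup(x):
            return tuple(tuple(v) if isinstance(v, list) else v for v in x) \
                if isinstance(x, list) else x

        kwargs: dict = {}
        for key, sub in (("window", WindowConfig), ("drug_encoder", EncoderConfig),
                         ("target_encoder", EncoderConfig), ("drug_cnn", CNNConfig),
                         ("target_cnn", CNNConfig), ("predictor", PredictorConfig),
                         ("pretrain", PretrainOptions), ("train", TrainOptions)):
            if key in d:
                section = {k: tup(v) for k, v in dict(d[key]).items()}
                kwargs[key] = sub(**section)
        for key in ("seed", "drug_rows", "no_pretrain", "use_1d_cnn", "fragment_graphs"):
            if key in d:
                kwargs[key] = d[key]
        unknown = set(d) - set(kwargs)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(Path(path)) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        try:
            return cls.from_dict(data)
        except (TypeError, ValueError) as e:
            raise ValueError(f"{path}: invalid config ({e})") from e

    def save(self, path) -> None:
        with open(Path(path), "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
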