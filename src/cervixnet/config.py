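"""Nested pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .features import feature_matrix_shape
from .gabor import GaborParams
from .network import BranchSpec, NetworkConfig
from .segmentation import StructuringElement


@dataclass(frozen=True)
class DnrfConfig:
    threshold: float = 20.0  # HM cutoff on the 0-255 scale (~8% of range)
    window: int = 11
    avg_window: int = 3
    hm_mode: str = "mad"


@dataclass(frozen=True)
class FeatureConfig:
    grid: tuple[int, int] = (16, 16)   # per-channel block-average grid (G, N)
    ltp_t: float = 5.0
    glcm_levels: int = 32
    glcm_offset: tuple[int, int] = (-1, 1)
    lbp_rule: str = "inverted"
    nsct_dirs: tuple[int, int] = (4, 2)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    lr: float = 1e-3
    batch_size: int = 16
    seed: int = 0


@dataclass(frozen=True)
class SegmentationConfig:
    se: StructuringElement = StructuringElement(shape="disk", radius=3)
    source: str = "gci"  # {"gci", "raw"}: which map is Otsu-binarized


@dataclass(frozen=True)
class SyntheticConfig:
    size: tuple[int, int] = (128, 128)
    noise_p: float = 0.05


@dataclass(frozen=True)
class PipelineConfig:
    version: str = "1"
    seed: int = 0
    dnrf: DnrfConfig = field(default_factory=DnrfConfig)
    gabor: GaborParams = field(default_factory=GaborParams)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    network: NetworkConfig | None = None  # derived from features when None
    train: TrainConfig = field(default_factory=TrainConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def network_config(self) -> NetworkConfig:
        if self.network is not None:
            return self.network
        return NetworkConfig(
            input_shape=feature_matrix_shape(self.features.grid, self.features.nsct_dirs),
            seed=self.train.seed,
        )


_TUPLE_FIELDS = {
    "grid", "glcm_offset", "nsct_dirs", "size", "conv_filters",
    "pool_positions", "dense_sizes", "input_shape",
}


def _restore(cls, data):
    if data is None:
        return None
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in (
            "dnrf", "gabor", "features", "train", "segmentation", "synthetic", "se",
            "ill1", "ill2", "network",
        ):
            sub = {
                "dnrf": DnrfConfig, "gabor": GaborParams, "features": FeatureConfig,
                "train": TrainConfig, "segmentation": SegmentationConfig,
                "synthetic": SyntheticConfig, "se": StructuringElement,
                "ill1": BranchSpec, "ill2": BranchSpec, "network": NetworkConfig,
            }[f.name]
            kwargs[f.name] = _restore(sub, v)
        elif f.name in _TUPLE_FIELDS and v is not None:
            kwargs[f.name] = tuple(v)
        else:
            kwargs[f.name] = v
    return cls(**kwargs)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def to_dict(cfg: PipelineConfig) -> dict:
    return _plain(dataclasses.asdict(cfg))


def from_dict(data: dict) -> PipelineConfig:
    return _restore(PipelineConfig, data)


def save_yaml(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=True)


def load_yaml(path) -> PipelineConfig:
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh))
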