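"""CervixNet: a dual-branch convolutional classifier for feature matrices.

The (M, N) feature matrix enters two parallel convolutional branches as a
single-channel plane.  Internal layering level 1 (ILL-1) carries a *high*
filter count, ILL-2 a deliberately *low* one; each branch is four stride-1
convolutions with ReLU, max-pooled (2x2, stride 2) after the second and
fourth convolution.  The branch outputs — spatially identical, differing
only in channel count — are concatenated along the channel axis by the
feature concatenator (FC), compressed once more by a 2x2 max pool
("Maxpool23"), flattened, and passed through three dense layers with
*unbiased* neurons (no bias terms anywhere in the network).  The single
sigmoid output is thresholded into {healthy, cancer}: cancer iff
score >= decision_threshold.

Training is binary cross-entropy with Adam; weight initialization and
shuffling are fully seeded, so training is reproducible bit-for-bit on a
fixed platform.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import _nn
from .features import FeatureMatrix

HEALTHY, CANCER = "healthy", "cancer"


@dataclass(frozen=True)
class BranchSpec:
    conv_filters: tuple[int, int, int, int]
    kernel_size: int
    pool_positions: tuple[int, int] = (2, 4)  # pool after these convs (1-based)
    pool_size: int = 2
    activation: str = "relu"

    def validate(self) -> None:
        if len(self.conv_filters) != 4:
            raise ValueError("a branch has exactly four convolutional layers")
        if tuple(self.pool_positions) != (2, 4) or self.pool_size != 2:
            raise ValueError("pooling is fixed at 2x2 after conv2 and conv4")
        if self.activation != "relu":
            raise ValueError("only relu activations are supported")
        if self.kernel_size % 2 == 0 or self.kernel_size < 3:
            raise ValueError("kernel size must be odd and >= 3")


@dataclass(frozen=True)
class NetworkConfig:
    input_shape: tuple[int, int]
    ill1: BranchSpec = BranchSpec(conv_filters=(16, 24, 32, 48), kernel_size=5)
    ill2: BranchSpec = BranchSpec(conv_filters=(4, 6, 8, 12), kernel_size=7)
    dense_sizes: tuple[int, int, int] = (256, 64, 1)
    dense_bias: bool = False
    decision_threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        self.ill1.validate()
        self.ill2.validate()
        if not all(a > b for a, b in zip(self.ill1.conv_filters, self.ill2.conv_filters)):
            raise ValueError("ILL-1 filter counts must exceed ILL-2's elementwise")
        if len(self.dense_sizes) != 3 or self.dense_sizes[-1] != 1:
            raise ValueError("exactly three dense layers ending in one output unit")
        if self.dense_bias:
            raise ValueError("dense layers are unbiased by construction")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must lie in (0, 1)")


@dataclass
class ClassLabel:
    value: str
    score: float


@dataclass
class TrainHistory:
    losses: list[float] = field(default_factory=list)


def _branch(spec: BranchSpec, rng: np.random.Generator, dtype) -> _nn.Sequential:
    f = spec.conv_filters
    k = spec.kernel_size
    return _nn.Sequential(
        _nn.Conv2D(1, f[0], k, rng, dtype), _nn.ReLU(),
        _nn.Conv2D(f[0], f[1], k, rng, dtype), _nn.ReLU(), _nn.MaxPool2x2(),
        _nn.Conv2D(f[1], f[2], k, rng, dtype), _nn.ReLU(),
        _nn.Conv2D(f[2], f[3], k, rng, dtype), _nn.ReLU(), _nn.MaxPool2x2(),
    )


class Network:
    """A built (possibly trained) CervixNet instance."""

    def __init__(self, config: NetworkConfig, dtype=np.float32):
        config.validate()
        self.config = config
        self.dtype = dtype
        self.trained = False
        rng = np.random.default_rng(config.seed)
        self.ill1 = _branch(config.ill1, rng, dtype)
        self.ill2 = _branch(config.ill2, rng, dtype)

        m, n = config.input_shape
        h, w = m // 2 // 2 // 2, n // 2 // 2 // 2  # two branch pools + Maxpool23
        if h < 1 or w < 1:
            raise ValueError(f"input shape {config.input_shape} too small for three pooling stages")
        flat = (config.ill1.conv_filters[-1] + config.ill2.conv_filters[-1]) * h * w
        d1, d2, d3 = config.dense_sizes
        self.trunk = _nn.Sequential(
            _nn.MaxPool2x2(), _nn.Flatten(),
            _nn.Dense(flat, d1, rng, dtype), _nn.ReLU(),
            _nn.Dense(d1, d2, rng, dtype), _nn.ReLU(),
            _nn.Dense(d2, d3, rng, dtype),
        )

    # -- parameter bookkeeping ------------------------------------------------

    def named_params(self) -> dict[str, np.ndarray]:
        out = {}
        out.update(self.ill1.named_params("ill1."))
        out.update(self.ill2.named_params("ill2."))
        out.update(self.trunk.named_params("trunk."))
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out = {}
        out.update(self.ill1.named_grads("ill1."))
        out.update(self.ill2.named_grads("ill2."))
        out.update(self.trunk.named_grads("trunk."))
        return out

    def parameter_count(self) -> int:
        return sum(p.size for p in self.named_params().values())

    def state_hash(self) -> str:
        """Deterministic digest of configuration + all weights."""
        h = hashlib.sha256(json.dumps(asdict(self.config), sort_keys=True).encode())
        for name in sorted(self.named_params()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.named_params()[name]).tobytes())
        return h.hexdigest()

    # -- forward / backward ---------------------------------------------------

    def _logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        a = self.ill1.forward(x, train=train)
        b = self.ill2.forward(x, train=train)
        self._split = a.shape[1]
        fc = np.concatenate([a, b], axis=1)  # feature concatenator
        return self.trunk.forward(fc, train=train)

    def _backward(self, dz: np.ndarray) -> None:
        dfc = self.trunk.backward(dz.astype(self.dtype))
        self.ill1.backward(dfc[:, : self._split])
        self.ill2.backward(dfc[:, self._split :])

    def scores(self, fms: np.ndarray) -> np.ndarray:
        """Sigmoid scores for a batch of feature matrices (B, M, N)."""
        x = np.asarray(fms, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != tuple(self.config.input_shape):
            raise ValueError(f"feature matrix shape {x.shape[1:]} != configured {self.config.input_shape}")
        z = self._logits(x[:, None, :, :], train=False)
        return _nn.sigmoid(z[:, 0])

    def forward(self, fm: FeatureMatrix | np.ndarray) -> ClassLabel:
        values = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm)
        score = float(self.scores(values[None])[0])
        value = CANCER if score >= self.config.decision_threshold else HEALTHY
        return ClassLabel(value=value, score=score)

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        cfg = json.dumps(asdict(self.config), sort_keys=True)
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
                 __trained__=np.array(self.trained), **self.named_params())

    @classmethod
    def load(cls, path) -> "Network":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            cfg["ill1"] = BranchSpec(**{**cfg["ill1"], "conv_filters": tuple(cfg["ill1"]["conv_filters"]),
                                        "pool_positions": tuple(cfg["ill1"]["pool_positions"])})
            cfg["ill2"] = BranchSpec(**{**cfg["ill2"], "conv_filters": tuple(cfg["ill2"]["conv_filters"]),
                                        "pool_positions": tuple(cfg["ill2"]["pool_positions"])})
            cfg["input_shape"] = tuple(cfg["input_shape"])
            cfg["dense_sizes"] = tuple(cfg["dense_sizes"])
            net = cls(NetworkConfig(**cfg))
            params = net.named_params()
            for name, p in params.items():
                p[...] = data[name]
            net.trained = bool(data["__trained__"])
        return net


def build(config: NetworkConfig, dtype=np.float32) -> Network:
    return Network(config, dtype=dtype)


def train(
    net: Network,
    fms: np.ndarray,
    labels: np.ndarray,
    epochs: int = 30,
    lr: float = 1e-3,
    batch_size: int = 16,
    seed: int = 0,
) -> TrainHistory:
    """Train in place with Adam on binary cross-entropy.

    ``labels`` are {0 (healthy), 1 (cancer)}.  Both classes must be present.
    Returns the per-epoch mean loss history; ``epochs=0`` leaves the weights
    untouched.
    """
    x = np.asarray(fms, dtype=net.dtype)
    y = np.asarray(labels, dtype=np.float64)
    if x.ndim != 3 or x.shape[0] != y.shape[0]:
        raise ValueError("fms must be (B, M, N) with one label per matrix")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(seed)
    opt = _nn.Adam(net.named_params(), lr=lr)
    history = TrainHistory()
    for _ in range(epochs):
        order = rng.permutation(x.shape[0])
        losses = []
        for start in range(0, x.shape[0], batch_size):
            sel = order[start : start + batch_size]
            z = net._logits(x[sel][:, None, :, :], train=True)
            loss, dz = _nn.bce_with_logits(z[:, 0], y[sel])
            net._backward(dz[:, None])
            opt.step(net.named_grads())
            losses.append(loss)
        history.losses.append(float(np.mean(losses)))
    if epochs > 0:
        net.trained = True
    return history
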