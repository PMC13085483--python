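"""The enhanced U-Net: three-level encoder, 512-filter bottleneck, skip decoder.

Architecture (defaults):

* encoder: 3 blocks of [3×3 conv → BN → ReLU] ×2 with 64/128/256 filters,
  each followed by 2×2 max-pooling and dropout (rate 0.3);
* bottleneck: the same double-conv with 512 filters (dropout configurable);
* decoder: 2×2 transposed convolution, concatenation with the matching
  encoder feature map, then a double-conv;
* head: 1×1 convolution with a sigmoid, yielding a per-pixel lesion
  probability map the same spatial size as the input.

Filter widths are configurable so the identical topology can run at desk
scale (e.g. 8/16/32 with a 64-filter bottleneck).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from mammoseg.nn.layers import (
    F32,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    MaxPool2d,
    Param,
    ReLU,
)

_PROB_EPS = 1e-6  # keeps the sigmoid output in the open interval (0, 1)


@dataclass(frozen=True)
class UNetConfig:
    input_side: int = 224
    encoder_filters: tuple[int, ...] = (64, 128, 256)
    bottleneck_filters: int = 512
    dropout_rate: float = 0.3
    kernel_size: int = 3
    pool_size: int = 2
    bottleneck_dropout: bool = True
    init_seed: int = 0

    def __post_init__(self):
        ef = tuple(self.encoder_filters)
        object.__setattr__(self, "encoder_filters", ef)
        if any(b <= a for a, b in zip(ef, ef[1:])):
            raise ValueError("encoder_filters must be strictly increasing")
        if self.pool_size != 2:
            raise ValueError("only pool_size=2 is supported")
        depth = len(ef)
        if self.input_side % (2 ** depth) != 0:
            raise ValueError(
                f"input_side={self.input_side} not divisible by 2^{depth}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def depth(self) -> int:
        return len(self.encoder_filters)


class _DoubleConv:
    """conv → BN → ReLU, twice (the classic U-Net block)."""

    def __init__(self, name: str, c_in: int, c_out: int, k: int, rng):
        self.conv1 = Conv2d(f"{name}.conv1", c_in, c_out, k, rng)
        self.bn1 = BatchNorm2d(f"{name}.bn1", c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(f"{name}.conv2", c_out, c_out, k, rng)
        self.bn2 = BatchNorm2d(f"{name}.bn2", c_out)
        self.relu2 = ReLU()

    def params(self) -> list[Param]:
        return (self.conv1.params() + self.bn1.params()
                + self.conv2.params() + self.bn2.params())

    def bns(self) -> list[BatchNorm2d]:
        return [self.bn1, self.bn2]

    def forward(self, x, train):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        return self.relu2.forward(self.bn2.forward(self.conv2.forward(h, train), train), train)

    def backward(self, d):
        d = self.conv2.backward(self.bn2.backward(self.relu2.backward(d)))
        return self.conv1.backward(self.bn1.backward(self.relu1.backward(d)))


class UNet:
    """A built network: the spec's ModelHandle (config + layers + manifest)."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        k = config.kernel_size
        f = config.encoder_filters
        self.enc_blocks: list[_DoubleConv] = []
        self.pools: list[MaxPool2d] = []
        self.drops: list[Dropout] = []
        c_in = 1
        for i, c in enumerate(f, start=1):
            self.enc_blocks.append(_DoubleConv(f"enc{i}", c_in, c, k, rng))
            self.pools.append(MaxPool2d())
            self.drops.append(Dropout(config.dropout_rate))
            c_in = c
        self.bottleneck = _DoubleConv("bottleneck", c_in, config.bottleneck_filters, k, rng)
        self.bottleneck_drop = Dropout(
            config.dropout_rate if config.bottleneck_dropout else 0.0)
        self.ups: list[ConvTranspose2d] = []
        self.dec_blocks: list[_DoubleConv] = []
        c_prev = config.bottleneck_filters
        for i, c in zip(range(len(f), 0, -1), reversed(f)):
            self.ups.append(ConvTranspose2d(f"dec{i}.up", c_prev, c, rng))
            self.dec_blocks.append(_DoubleConv(f"dec{i}", 2 * c, c, k, rng))
            c_prev = c
        self.head = Conv2d("head", f[0], 1, 1, rng)
        self._cache = None

    # ------------------------------------------------------------------ params
    def params(self) -> list[Param]:
        out: list[Param] = []
        for b in self.enc_blocks:
            out += b.params()
        out += self.bottleneck.params()
        for up, b in zip(self.ups, self.dec_blocks):
            out += up.params() + b.params()
        out += self.head.params()
        return out

    def _bns(self) -> list[BatchNorm2d]:
        out: list[BatchNorm2d] = []
        for b in self.enc_blocks:
            out += b.bns()
        out += self.bottleneck.bns()
        for b in self.dec_blocks:
            out += b.bns()
        return out

    def parameter_manifest(self) -> list[dict]:
        return [{"name": p.name, "shape": tuple(p.value.shape), "n_params": p.size}
                for p in self.params()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for bn in self._bns():
            state[f"{bn.name}.running_mean"] = bn.running_mean.copy()
            state[f"{bn.name}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name!r} in state dict")
            if state[p.name].shape != p.value.shape:
                raise ValueError(f"shape mismatch for {p.name!r}")
            p.value[...] = state[p.name]
        for bn in self._bns():
            bn.running_mean[...] = state[f"{bn.name}.running_mean"]
            bn.running_var[...] = state[f"{bn.name}.running_var"]

    # ----------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Map ``(N, 1, S, S)`` inputs to ``(N, 1, S, S)`` probabilities."""
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, S, S) input, got {x.shape}")
        s = self.config.input_side
        if x.shape[2] != s or x.shape[3] != s:
            raise ValueError(f"expected {s}x{s} input, got {x.shape[2]}x{x.shape[3]}")
        if train and self.config.dropout_rate > 0 and rng is None:
            raise ValueError("training-mode forward requires an rng for dropout")
        x = np.ascontiguousarray(x, dtype=F32)
        skips = []
        h = x
        for blk, pool, drop in zip(self.enc_blocks, self.pools, self.drops):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
            h = drop.forward(h, train, rng)
        h = self.bottleneck.forward(h, train)
        h = self.bottleneck_drop.forward(h, train, rng)
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up.forward(h, train)
            h = np.concatenate([skip, h], axis=1)
            h = blk.forward(h, train)
        logits = self.head.forward(h, train)
        prob = np.clip(expit(logits), _PROB_EPS, 1.0 - _PROB_EPS).astype(F32)
        if train:
            self._cache = prob
        return prob

    def backward(self, dprob: np.ndarray) -> None:
        """Backpropagate d(loss)/d(probability map) from a training forward."""
        if self._cache is None:
            raise RuntimeError("backward called without a training-mode forward")
        p = self._cache
        d = (dprob * p * (1.0 - p)).astype(F32)
        d = self.head.backward(d)
        # decoder backward: last applied block first
        dskips: list[np.ndarray | None] = [None] * len(self.dec_blocks)
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            d = self.dec_blocks[i].backward(d)
            c = self.ups[i].c_out
            dskips[i] = d[:, :c]
            d = self.ups[i].backward(d[:, c:])
        d = self.bottleneck_drop.backward(d)
        d = self.bottleneck.backward(d)
        for lvl in range(len(self.enc_blocks) - 1, -1, -1):
            d = self.drops[lvl].backward(d)
            d = self.pools[lvl].backward(d)
            # decoder block j consumes the skip from encoder level depth-1-j
            d = d + dskips[len(self.enc_blocks) - 1 - lvl]
            d = self.enc_blocks[lvl].backward(d)
        self._cache = None

    # --------------------------------------------------------------- persist
    def save(self, path) -> None:
        state = self.state_dict()
        cfg = {
            "input_side": self.config.input_side,
            "encoder_filters": list(self.config.encoder_filters),
            "bottleneck_filters": self.config.bottleneck_filters,
            "dropout_rate": self.config.dropout_rate,
            "kernel_size": self.config.kernel_size,
            "pool_size": self.config.pool_size,
            "bottleneck_dropout": self.config.bottleneck_dropout,
            "init_seed": self.config.init_seed,
        }
        np.savez_compressed(path, __config__=np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path) -> "UNet":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            cfg["encoder_filters"] = tuple(cfg["encoder_filters"])
            model = cls(UNetConfig(**cfg))
            model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
        return model


def build_unet(config: UNetConfig) -> UNet:
    """Construct the network; raises at build time on invalid geometry."""
    return UNet(config)


def transfer_encoder(source: UNet, target: UNet) -> tuple[UNet, list[str]]:
    """Copy encoder + bottleneck weights from ``source`` into ``target``.

    Decoder and head parameters of ``target`` are left untouched. Returns the
    target and the list of copied entries (the transfer report).
    """
    if source.config.encoder_filters != target.config.encoder_filters or \
            source.config.bottleneck_filters != target.config.bottleneck_filters or \
            source.config.kernel_size != target.config.kernel_size:
        src = {m["name"]: m["shape"] for m in source.parameter_manifest()}
        tgt = {m["name"]: m["shape"] for m in target.parameter_manifest()}
        for name in src:
            if name.startswith(("enc", "bottleneck")) and src[name] != tgt.get(name):
                raise ValueError(
                    f"encoder architecture mismatch at layer {name!r}: "
                    f"{src[name]} vs {tgt.get(name)}")
        raise ValueError("encoder architecture mismatch")
    src_state = source.state_dict()
    copied = [k for k in src_state if k.startswith(("enc", "bottleneck"))]
    partial = {k: src_state[k] for k in copied}
    for p in target.params():
        if p.name in partial:
            p.value[...] = partial[p.name]
    for bn in target._bns():
        rm, rv = f"{bn.name}.running_mean", f"{bn.name}.running_var"
        if rm in partial:
            bn.running_mean[...] = partial[rm]
            bn.running_var[...] = partial[rv]
    return target, sorted(copied)


def predict_mask(model: UNet, image: np.ndarray, threshold: float = 0.5
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Inference on one image or a batch: (probability map, binary mask).

    Dropout is disabled (inference mode) and batch norm uses running
    statistics, so repeated calls are deterministic.
    """
    single = image.ndim == 2
    x = image[None, None] if single else image
    prob = model.forward(x, train=False)
    binary = (prob > threshold).astype(np.uint8)
    if single:
        return prob[0, 0], binary[0, 0]
    return prob, binary
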