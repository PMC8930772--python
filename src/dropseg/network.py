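"""Residual U-Net emitting seed, bandwidth and offset maps.

A compact CPU implementation: encoder/decoder with residual blocks at
every scale, batch normalization after every convolution, 2x average
pooling / nearest upsampling between scales, and a 1x1 head with four
output channels — seed logit, raw bandwidth, and the two offset
components.  The head maps raw outputs to their ranges via sigmoid
(seed) and softplus (bandwidth); offsets are unconstrained and
zero-initialized, so at initialization the embedding of every pixel is
its own coordinate and the predicted bandwidth is ``init_bandwidth``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .maps import PredictionMaps

__all__ = ["NetworkSpec", "EmbedNet"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class NetworkSpec:
    depth: int = 3
    base_channels: int = 16
    in_channels: int = 1
    init_bandwidth: float = 0.08  # in normalized coordinate units

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be positive")


class _Conv:
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), (cout, cin, k, k))
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]


class _BatchNorm:
    def __init__(self, channels: int):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        c = x.shape[1]
        shape = (1, c, 1, 1)
        if training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += _BN_MOMENTUM * (
                mu.data.reshape(c) - self.running_mean
            )
            self.running_var += _BN_MOMENTUM * (
                var.data.reshape(c) - self.running_var
            )
            inv = (var + _BN_EPS) ** -0.5
            y = xc * inv
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            inv = Tensor(1.0 / np.sqrt(self.running_var.reshape(shape) + _BN_EPS))
            y = (x - mu) * inv
        return y * self.gamma.reshape(shape) + self.beta.reshape(shape)

    def params(self):
        return [self.gamma, self.beta]


class _ResBlock:
    """conv-bn-relu-conv-bn with an additive shortcut (1x1 projection
    when the channel count changes), relu after the sum."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = _Conv(cin, cout, 3, rng)
        self.bn1 = _BatchNorm(cout)
        self.conv2 = _Conv(cout, cout, 3, rng)
        self.bn2 = _BatchNorm(cout)
        self.proj = _Conv(cin, cout, 1, rng) if cin != cout else None

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h = ag.relu(self.bn1(self.conv1(x), training))
        h = self.bn2(self.conv2(h), training)
        s = self.proj(x) if self.proj is not None else x
        return ag.relu(h + s)

    def params(self):
        out = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out

    def bn_layers(self):
        return [self.bn1, self.bn2]


def _inv_softplus(y: float) -> float:
    return math.log(math.expm1(y))


class EmbedNet:
    def __init__(self, spec: NetworkSpec | None = None, seed: int = 0):
        self.spec = spec or NetworkSpec()
        rng = np.random.default_rng(seed)
        ch = [self.spec.base_channels * (1 << i) for i in range(self.spec.depth)]
        self.enc = []
        cin = self.spec.in_channels
        for c in ch:
            self.enc.append(_ResBlock(cin, c, rng))
            cin = c
        self.reduce = []  # 1x1 convs before adding skip connections
        self.dec = []
        for i in range(self.spec.depth - 2, -1, -1):
            self.reduce.append(_Conv(ch[i + 1], ch[i], 1, rng))
            self.dec.append(_ResBlock(ch[i], ch[i], rng))
        self.head = _Conv(ch[0], 4, 1, rng)
        # small head so initial predictions sit at the biases
        self.head.w.data *= 0.01
        self.head.b.data[:] = np.array(
            [-1.0, _inv_softplus(self.spec.init_bandwidth), 0.0, 0.0], dtype=np.float32
        )

    # -- parameter plumbing --------------------------------------------------
    def params(self) -> list[Tensor]:
        out = []
        for blk in self.enc + self.dec:
            out += blk.params()
        for conv in self.reduce:
            out += conv.params()
        out += self.head.params()
        return out

    def _bn_layers(self):
        out = []
        for blk in self.enc + self.dec:
            out += blk.bn_layers()
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.params()):
            state[f"p{i}"] = p.data.copy()
        for i, bn in enumerate(self._bn_layers()):
            state[f"rm{i}"] = bn.running_mean.copy()
            state[f"rv{i}"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.data = state[f"p{i}"].astype(np.float32).copy()
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean = state[f"rm{i}"].astype(np.float32).copy()
            bn.running_var = state[f"rv{i}"].astype(np.float32).copy()

    def save(self, path, extra: dict | None = None) -> None:
        meta = {f"spec_{k}": v for k, v in asdict(self.spec).items()}
        if extra:
            meta.update({f"extra_{k}": v for k, v in extra.items()})
        np.savez(path, **self.state_dict(), **meta)

    @classmethod
    def load(cls, path) -> tuple["EmbedNet", dict]:
        data = np.load(path)
        spec = NetworkSpec(
            depth=int(data["spec_depth"]),
            base_channels=int(data["spec_base_channels"]),
            in_channels=int(data["spec_in_channels"]),
            init_bandwidth=float(data["spec_init_bandwidth"]),
        )
        net = cls(spec)
        net.load_state_dict({k: data[k] for k in data.files if k[0] in "pr" and not k.startswith("spec")})
        extra = {k[6:]: data[k] for k in data.files if k.startswith("extra_")}
        return net, extra

    # -- forward -------------------------------------------------------------
    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        """(N, C, H, W) -> (N, 4, H, W); H, W divisible by 2^(depth-1)."""
        skips = []
        h = x
        for i, blk in enumerate(self.enc):
            h = blk(h, training)
            if i < len(self.enc) - 1:
                skips.append(h)
                h = ag.avgpool2(h)
        for conv, blk, skip in zip(self.reduce, self.dec, reversed(skips)):
            h = ag.upsample2(h)
            h = conv(h) + skip
            h = blk(h, training)
        return self.head(h)

    def output_to_maps(self, out: np.ndarray, coord_scale: float) -> PredictionMaps:
        """Convert one sample's raw head output (4, H, W) to maps."""
        seed = 1.0 / (1.0 + np.exp(-out[0]))
        bandwidth = np.logaddexp(0.0, out[1]) + 1e-4
        return PredictionMaps(
            seed=seed,
            bandwidth=bandwidth,
            offsets=out[2:4].astype(np.float64),
            coord_scale=coord_scale,
        )

    def predict_maps(self, image: np.ndarray, coord_scale: float) -> PredictionMaps:
        """Run inference on a single 2D image (padded to a valid size)."""
        x = normalize_image(image)
        h, w = x.shape
        mult = 1 << (self.spec.depth - 1)
        ph = (-h) % mult
        pw = (-w) % mult
        if ph or pw:
            x = np.pad(x, ((0, ph), (0, pw)), mode="reflect")
        out = self.forward(Tensor(x[None, None]), training=False).numpy()[0]
        out = out[:, :h, :w]
        return self.output_to_maps(out, coord_scale)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Standardize an intensity image to zero mean, unit variance."""
    x = np.asarray(image, dtype=np.float32)
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)
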