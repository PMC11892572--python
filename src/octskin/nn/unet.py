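"""U-Net encoder–decoder for 5-class voxelwise segmentation, in 2D and 3D.

The 2D network takes B-scan blocks (256x512 by default) and the 3D variant
takes 256x64x64 sub-volumes; 2D operations are replaced by their 3D analogues.
Five encoder stages of conv3 -> batch norm -> ReLU -> conv3 -> ReLU generate
32, 64, 128, 256, 512 feature maps at full width, each followed by 2x
max-pooling; the symmetric decoder upsamples with transposed convolutions,
concatenates the skip connection from the matching encoder stage, and a final
1x1 convolution emits one raw confidence channel per class.  No softmax is
applied inside the network — blending and argmax happen downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import BatchNorm, Conv1x1, ConvND, ConvTranspose, MaxPool, ReLU

__all__ = [
    "UNetConfig", "UNet", "build_unet", "classify", "softmax",
    "cross_entropy", "Adam", "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class UNetConfig:
    dims: int = 2
    n_stages: int = 5
    base_features: int = 32
    n_classes: int = 5
    in_channels: int = 1
    width_multiplier: float = 1.0
    norm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if not (0 < self.width_multiplier <= 1):
            raise ValueError("width_multiplier must lie in (0, 1]")
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")

    def features(self, stage: int) -> int:
        """Feature count of a 1-based encoder stage."""
        return max(1, round(self.base_features * 2 ** (stage - 1) * self.width_multiplier))

    @property
    def divisor(self) -> int:
        return 2 ** (self.n_stages - 1)

    def to_dict(self) -> dict:
        return {
            "dims": self.dims,
            "n_stages": self.n_stages,
            "base_features": self.base_features,
            "n_classes": self.n_classes,
            "in_channels": self.in_channels,
            "width_multiplier": self.width_multiplier,
            "norm": self.norm,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UNetConfig":
        return cls(**d)


class _DoubleConv:
    """conv3 -> (batch norm) -> ReLU -> conv3 -> ReLU."""

    def __init__(self, in_c, out_c, dims, rng, norm=True):
        self.conv1 = ConvND(in_c, out_c, dims, rng)
        self.bn = BatchNorm(out_c) if norm else None
        self.relu1 = ReLU()
        self.conv2 = ConvND(out_c, out_c, dims, rng)
        self.relu2 = ReLU()

    def forward(self, x, train=True):
        x = self.conv1.forward(x, train)
        if self.bn is not None:
            x = self.bn.forward(x, train)
        x = self.relu1.forward(x, train)
        x = self.conv2.forward(x, train)
        return self.relu2.forward(x, train)

    def backward(self, dy):
        dy = self.relu2.backward(dy)
        dy = self.conv2.backward(dy)
        dy = self.relu1.backward(dy)
        if self.bn is not None:
            dy = self.bn.backward(dy)
        return self.conv1.backward(dy)

    def layers(self):
        out = [self.conv1, self.conv2]
        if self.bn is not None:
            out.append(self.bn)
        return out


class UNet:
    """Symmetric encoder–decoder with skip connections.

    Built through :func:`build_unet`; ``forward`` maps ``(N, in_c, *S)`` to
    ``(N, n_classes, *S)`` with every spatial dim preserved.
    """

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, S = config.dims, config.n_stages
        feats = [config.features(s) for s in range(1, S + 1)]
        self.enc = []
        in_c = config.in_channels
        for f in feats:
            self.enc.append(_DoubleConv(in_c, f, d, rng, config.norm))
            in_c = f
        self.pools = [MaxPool(d) for _ in range(S - 1)]
        self.ups = []
        self.dec = []
        for s in range(S - 2, -1, -1):
            self.ups.append(ConvTranspose(feats[s + 1], feats[s], d, rng))
            self.dec.append(_DoubleConv(2 * feats[s], feats[s], d, rng, config.norm))
        self.head = Conv1x1(feats[0], config.n_classes, rng)

    # -- plumbing ---------------------------------------------------------
    def _layers(self):
        out = []
        for blk in self.enc + self.dec:
            out.extend(blk.layers())
        out.extend(self.ups)
        out.append(self.head)
        return out

    def parameters(self):
        params, grads = [], []
        for layer in self._layers():
            params.extend(layer.params())
            grads.extend(layer.grads())
        return params, grads

    def zero_grad(self):
        for layer in self._layers():
            for g in layer.grads():
                g[...] = 0.0

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()[0]))

    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != self.config.dims + 2:
            raise ValueError(
                f"expected {self.config.dims + 2}D input (N, C, *spatial), got {x.ndim}D"
            )
        if x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} channel(s)")
        dv = self.config.divisor
        if any(s % dv for s in x.shape[2:]):
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by {dv} "
                f"for {self.config.n_stages} stages"
            )

    # -- passes -----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        self._check_shape(x)
        skips = []
        for i, blk in enumerate(self.enc):
            x = blk.forward(x, train)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x, train)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dscores: np.ndarray) -> None:
        dy = self.head.backward(dscores)
        n_skip = len(self.enc) - 1
        dskips = [None] * n_skip
        for j in range(len(self.dec) - 1, -1, -1):
            dy = self.dec[j].backward(dy)
            skip_idx = n_skip - 1 - j
            f = self.enc[skip_idx].conv2.out_c
            dskips[skip_idx] = dy[:, :f]
            dy = self.ups[j].backward(dy[:, f:])
        for i in range(len(self.enc) - 1, -1, -1):
            if i < n_skip:
                dy = self.pools[i].backward(dy)
                dy = dy + dskips[i]
            dy = self.enc[i].backward(dy)


def build_unet(config: UNetConfig) -> UNet:
    """Construct a U-Net from its configuration."""
    return UNet(config)


def classify(scores: np.ndarray, class_axis: int = 0) -> np.ndarray:
    """Argmax over class channels, mapped to labels 1..n_classes.

    Ties break toward the lowest class index.
    """
    return (np.argmax(scores, axis=class_axis) + 1).astype(np.uint8)


def softmax(scores: np.ndarray, axis: int = 1) -> np.ndarray:
    m = scores.max(axis=axis, keepdims=True)
    e = np.exp(scores - m)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(scores: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean voxelwise softmax cross-entropy and its gradient w.r.t. scores.

    ``target`` holds class labels 1..n_classes with the class axis removed.
    """
    p = softmax(scores, axis=1)
    t = np.asarray(target, dtype=np.int64) - 1
    n_vox = t.size
    idx = np.expand_dims(t, 1)
    picked = np.take_along_axis(p, idx, axis=1)
    loss = float(-np.log(np.clip(picked, 1e-12, None)).sum() / n_vox)
    grad = p.copy()
    np.put_along_axis(grad, idx, picked - 1.0, axis=1)
    return loss, (grad / n_vox).astype(np.float32)


def save_checkpoint(net: UNet, path) -> None:
    """Write weights plus the embedded UNetConfig to an .npz checkpoint."""
    import json

    params, _ = net.parameters()
    arrays = {f"p{i}": p for i, p in enumerate(params)}
    bn_state = {}
    for i, layer in enumerate(net._layers()):
        if isinstance(layer, BatchNorm):
            bn_state[f"rm{i}"] = layer.running_mean
            bn_state[f"rv{i}"] = layer.running_var
    np.savez(
        path,
        config=np.frombuffer(json.dumps(net.config.to_dict()).encode(), dtype=np.uint8),
        **arrays,
        **bn_state,
    )


def load_checkpoint(path) -> UNet:
    """Rebuild a U-Net from a checkpoint written by :func:`save_checkpoint`."""
    import json

    with np.load(path) as f:
        config = UNetConfig.from_dict(json.loads(bytes(f["config"]).decode()))
        net = UNet(config)
        params, _ = net.parameters()
        for i, p in enumerate(params):
            p[...] = f[f"p{i}"]
        for i, layer in enumerate(net._layers()):
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = f[f"rm{i}"]
                layer.running_var[...] = f[f"rv{i}"]
    return net


class Adam:
    """Adam optimizer; moving-average coefficients betas=(0.9, 0.98)."""

    def __init__(self, params, grads, lr=0.001, betas=(0.9, 0.98), eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0.0
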