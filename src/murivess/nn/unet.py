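"""Shallow two-level 3D U-Net for 32-cubed patch segmentation.

The network has one encoder level, a bottleneck reached through a single
2x max-pool, and one decoder level fed by 2x upsampling plus a skip
concatenation — i.e. an encoding and a decoding path of two levels each.
Every convolution is 3x3x3, stride 1, zero same-padding, followed by
batch normalisation and ReLU; the head is a 1-channel convolution with a
sigmoid, so the output is a voxelwise vessel probability of the same
shape as the input.

The published description of this architecture fixes kernel, stride,
depth, normalisation, activations and the total trainable-parameter
budget (831,105) but not the layer widths.  The reference widths used
here — 80 encoder, 91 bottleneck, 41 decoder filters — are recovered by
:func:`enumerate_configs_matching`, which exhaustively enumerates the
width space against that budget; see ``docs/methods.md`` for the
tie-breaking rule among exact matches.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from murivess.nn.layers import (
    Adam,
    BatchNorm3d,
    Conv3d,
    MaxPool3d,
    ReLU,
    Sigmoid,
    UpsampleNearest3d,
)

__all__ = [
    "UNetConfig",
    "REFERENCE_CONFIG",
    "UNet3D",
    "build_unet",
    "count_parameters",
    "config_parameter_count",
    "enumerate_configs_matching",
    "predict_patches",
]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyper-parameters of the shallow U-Net.

    ``base_filters``/``bottleneck_filters``/``decoder_filters`` are the
    convolution widths of the encoder level, the bottleneck and the
    decoder level.  ``upsample`` is ``"nearest"`` (parameter-free) or
    ``"transposed-conv"`` (learned 2x2x2 stride-2 kernel mapping to
    ``decoder_filters`` channels).  ``final_kernel`` is the head kernel
    edge (1 or 3).
    """

    in_channels: int = 1
    base_filters: int = 80
    bottleneck_filters: int = 91
    decoder_filters: int = 41
    convs_per_block: int = 2
    upsample: str = "nearest"
    final_kernel: int = 1

    def __post_init__(self):
        if min(self.base_filters, self.bottleneck_filters, self.decoder_filters) < 1:
            raise ValueError("filter counts must be positive")
        if self.upsample not in ("nearest", "transposed-conv"):
            raise ValueError(f"unknown upsample mode {self.upsample!r}")
        if self.final_kernel not in (1, 3):
            raise ValueError("final_kernel must be 1 or 3")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "UNetConfig":
        return cls(**json.loads(text))


#: Widths fixed by exhaustive enumeration against the 831,105-parameter budget.
REFERENCE_CONFIG = UNetConfig()


class TransposedConv3d(Conv3d):
    """2x2x2 stride-2 learned upsampling (non-overlapping windows)."""

    def __init__(self, in_channels: int, out_channels: int, rng=None):
        rng = rng or np.random.default_rng()
        self.cin = in_channels
        self.cout = out_channels
        self.k = 2
        fan_in = in_channels
        self.weight = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), (in_channels, out_channels, 2, 2, 2)
        ).astype(np.float32)
        self.bias = np.zeros(out_channels, dtype=np.float32)
        self.grads = {"weight": np.zeros_like(self.weight), "bias": np.zeros_like(self.bias)}

    def forward(self, x):
        self._x = x
        n, c, d, h, w = x.shape
        y = np.einsum("ncdhw,cfijk->nfdihjwk", x, self.weight, optimize=True)
        y = y.reshape(n, self.cout, d * 2, h * 2, w * 2)
        return y + self.bias.reshape(1, -1, 1, 1, 1)

    def backward(self, dy):
        n, f, d2, h2, w2 = dy.shape
        d, h, w = d2 // 2, h2 // 2, w2 // 2
        dyr = dy.reshape(n, f, d, 2, h, 2, w, 2)
        self.grads["bias"] += dy.sum(axis=(0, 2, 3, 4))
        self.grads["weight"] += np.einsum(
            "ncdhw,nfdihjwk->cfijk", self._x, dyr, optimize=True
        )
        dx = np.einsum("nfdihjwk,cfijk->ncdhw", dyr, self.weight, optimize=True)
        self._x = None
        return np.ascontiguousarray(dx)


class UNet3D:
    """The network graph with explicit forward/backward passes.

    Input/output tensors are ``(N, 1, D, H, W)`` with spatial dims
    divisible by 2; the model is fully convolutional, so any such shape
    is accepted.
    """

    def __init__(self, config: UNetConfig = REFERENCE_CONFIG, seed: int | None = None):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config

        def block(cin, width):
            seq = []
            for _ in range(c.convs_per_block):
                seq += [Conv3d(cin, width, 3, rng), BatchNorm3d(width), ReLU()]
                cin = width
            return seq

        self.encoder = block(c.in_channels, c.base_filters)
        self.pool = MaxPool3d()
        self.bottleneck = block(c.base_filters, c.bottleneck_filters)
        if c.upsample == "nearest":
            self.up = UpsampleNearest3d()
            up_out = c.bottleneck_filters
        else:
            self.up = TransposedConv3d(c.bottleneck_filters, c.decoder_filters, rng)
            up_out = c.decoder_filters
        self._up_out = up_out
        self.decoder = block(up_out + c.base_filters, c.decoder_filters)
        self.head = Conv3d(c.decoder_filters, 1, c.final_kernel, rng)
        # prior-probability initialisation of the head bias: start the
        # sigmoid output near the foreground prior (~1%) so the focal loss
        # concentrates on vessel voxels from the first step instead of
        # spending its budget pushing the dominant background down
        prior = 0.01
        self.head.bias[:] = -np.log((1 - prior) / prior)
        self.sigmoid = Sigmoid()

    # -- plumbing ---------------------------------------------------------
    def layers(self):
        out = list(self.encoder) + [self.pool] + list(self.bottleneck)
        out.append(self.up)
        out += list(self.decoder) + [self.head, self.sigmoid]
        return out

    def train(self):
        for layer in self.layers():
            layer.training = True

    def eval(self):
        for layer in self.layers():
            layer.training = False

    # -- computation ------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        for n in x.shape[2:]:
            if n % 2 != 0:
                raise ValueError("spatial dimensions must be divisible by 2")
        e = x
        for layer in self.encoder:
            e = layer.forward(e)
        b = self.pool.forward(e)
        for layer in self.bottleneck:
            b = layer.forward(b)
        u = self.up.forward(b)
        d = np.concatenate([u, e], axis=1)
        for layer in self.decoder:
            d = layer.forward(d)
        return self.sigmoid.forward(self.head.forward(d))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = self.head.backward(self.sigmoid.backward(dy))
        for layer in reversed(self.decoder):
            g = layer.backward(g)
        g_up = g[:, : self._up_out]
        g_skip = g[:, self._up_out :]
        g = self.up.backward(np.ascontiguousarray(g_up))
        for layer in reversed(self.bottleneck):
            g = layer.backward(g)
        g = self.pool.backward(g)
        g = g + g_skip
        for layer in reversed(self.encoder):
            g = layer.backward(g)
        return g

    def make_optimizer(self, lr: float = 1e-4) -> Adam:
        return Adam(self.layers(), lr=lr)

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers()):
            for name, arr in layer.params().items():
                state[f"{i}.{name}"] = arr.copy()
            if isinstance(layer, BatchNorm3d):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers()):
            for name in layer.params():
                layer.params()[name][...] = state[f"{i}.{name}"]
            if isinstance(layer, BatchNorm3d):
                layer.running_mean[...] = state[f"{i}.running_mean"]
                layer.running_var[...] = state[f"{i}.running_var"]

    def save(self, path) -> None:
        np.savez(path, __config__=self.config.to_json(), **self.state_dict())

    @classmethod
    def load(cls, path) -> "UNet3D":
        with np.load(path, allow_pickle=False) as data:
            config = UNetConfig.from_json(str(data["__config__"]))
            model = cls(config)
            state = {k: data[k] for k in data.files if k != "__config__"}
        model.load_state_dict(state)
        return model


def build_unet(config: UNetConfig = REFERENCE_CONFIG, seed: int | None = None) -> UNet3D:
    """Instantiate the network with seeded He-normal weight init."""
    return UNet3D(config, seed=seed)


def count_parameters(model: UNet3D) -> int:
    """Number of trainable parameters (conv weights/biases, BN scale/shift).

    Batch-norm running statistics are not trainable and are excluded.
    """
    return int(sum(arr.size for layer in model.layers() for arr in layer.params().values()))


def predict_patches(model: UNet3D, patchset, batch_size: int = 8):
    """Voxelwise vessel probabilities for every patch, order preserved.

    Inference runs in evaluation mode (batch norm uses running
    statistics), so identical patches yield identical outputs.
    """
    from murivess.preprocess import PatchSet

    model.eval()
    out = []
    for i in range(0, len(patchset.patches), batch_size):
        batch = patchset.patches[i : i + batch_size]
        x = np.stack([np.asarray(p, dtype=np.float32) for p in batch])[:, None]
        prob = model.forward(x)
        out.extend(prob[j, 0] for j in range(len(batch)))
    return PatchSet(patches=out, grid_shape=patchset.grid_shape, geometry=patchset.geometry)


def config_parameter_count(config: UNetConfig) -> int:
    """Closed-form trainable-parameter count for a configuration."""

    def conv(cin, cout, k=3):
        return k**3 * cin * cout + cout

    c = config
    total = 0
    cin = c.in_channels
    for _ in range(c.convs_per_block):
        total += conv(cin, c.base_filters) + 2 * c.base_filters
        cin = c.base_filters
    for _ in range(c.convs_per_block):
        total += conv(cin, c.bottleneck_filters) + 2 * c.bottleneck_filters
        cin = c.bottleneck_filters
    if c.upsample == "transposed-conv":
        total += 8 * cin * c.decoder_filters + c.decoder_filters
        cin = c.decoder_filters
    cin += c.base_filters
    for _ in range(c.convs_per_block):
        total += conv(cin, c.decoder_filters) + 2 * c.decoder_filters
        cin = c.decoder_filters
    total += conv(cin, 1, c.final_kernel)
    return total


def enumerate_configs_matching(
    target_count: int,
    base_filters=range(1, 257),
    bottleneck_filters=range(1, 513),
    convs_per_block=(1, 2, 3),
    upsample=("nearest", "transposed-conv"),
    final_kernel=(1, 3),
    n_nearest: int = 3,
) -> tuple[list[UNetConfig], list[tuple[UNetConfig, int]]]:
    """Exhaustively enumerate configurations with an exact parameter count.

    For every combination of the discrete fields the parameter total is a
    quadratic polynomial in the decoder width, so the decoder width is
    solved for in closed form rather than scanned — the enumeration over
    the full documented space is exact and fast.  Returns the list of
    matching configs and, as a diagnostic, the ``n_nearest`` closest
    misses with their counts (useful when the list is empty).
    """
    matches: list[UNetConfig] = []
    nearest: list[tuple[int, UNetConfig]] = []

    def consider(cfg: UNetConfig):
        n = config_parameter_count(cfg)
        if n == target_count:
            matches.append(cfg)
        else:
            nearest.append((abs(n - target_count), cfg))

    for convs in convs_per_block:
        for up in upsample:
            for fk in final_kernel:
                for A in base_filters:
                    for B in bottleneck_filters:
                        # total(C) = alpha*C^2 + beta*C + gamma
                        enc = 27 * 1 * A + A + (convs - 1) * (27 * A * A + A) + 2 * convs * A
                        enc += 27 * A * B + B + (convs - 1) * (27 * B * B + B) + 2 * convs * B
                        if up == "nearest":
                            alpha = 27 * (convs - 1)
                            beta = 27 * (B + A) + 2 + (convs - 1) + 2 * convs + fk**3
                            gamma = enc + 1
                        else:
                            alpha = 27 * convs
                            beta = 8 * B + 2 + 27 * A + (convs - 1) + 2 * convs + fk**3
                            gamma = enc + 1
                        rem = target_count - gamma
                        candidates = set()
                        if alpha == 0:
                            if rem > 0 and rem % beta == 0:
                                candidates.add(rem // beta)
                            candidates.add(max(1, round(rem / beta)))
                        else:
                            disc = beta * beta + 4 * alpha * rem
                            if disc >= 0:
                                root = (-beta + disc**0.5) / (2 * alpha)
                                for C in (int(root), int(root) + 1):
                                    if C >= 1:
                                        candidates.add(C)
                        for C in candidates:
                            if C < 1:
                                continue
                            consider(
                                UNetConfig(
                                    base_filters=A,
                                    bottleneck_filters=B,
                                    decoder_filters=int(C),
                                    convs_per_block=convs,
                                    upsample=up,
                                    final_kernel=fk,
                                )
                            )
    nearest.sort(key=lambda t: t[0])
    report = [(cfg, config_parameter_count(cfg)) for _, cfg in nearest[:n_nearest]]
    return matches, report
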