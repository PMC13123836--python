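"""The map-to-map CNN: seven hidden convolutional layers with skip connections.

The topology is a small U-Net: two encoder convolutions with 2x2 average
pooling after each, two middle convolutions at quarter resolution, then a
decoder that upsamples (nearest-neighbour) and adds the matching-width
encoder activation back in before each decoder convolution.  Dropout is
applied after every hidden layer except the last; the output layer is a
linear convolution to a single channel.

Two presets are provided: ``"reduced"`` (~2e5 weights, for the 256 x 100
grid) and ``"full"`` (~4.5e6 weights, for the 512 x 200 grid).  Both spatial
input dimensions must be divisible by 4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from . import layers as L

__all__ = ["ArchConfig", "UNet"]


@dataclass
class ArchConfig:
    """Widths and kernel sizes of the seven hidden layers plus output.

    ``widths = (c1, c2, cm)``: encoder/decoder channel counts at full and
    half resolution, and the middle width at quarter resolution.  ``kernels``
    lists the square kernel size of each of the 8 convolutions in order
    (enc1, enc2, mid1, mid2, dec1, dec2, dec3, out).
    """

    widths: tuple = (16, 24, 80)
    kernels: tuple = (3, 5, 7, 7, 5, 3, 3, 3)
    dropout_rate: float = 0.30

    def __post_init__(self) -> None:
        if len(self.widths) != 3 or len(self.kernels) != 8:
            raise ValueError("ArchConfig needs 3 widths and 8 kernel sizes")
        if any(k % 2 == 0 for k in self.kernels):
            raise ValueError("kernel sizes must be odd")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @classmethod
    def preset(cls, name: str) -> "ArchConfig":
        if name == "reduced":
            return cls(widths=(16, 24, 80), kernels=(3, 5, 7, 7, 5, 3, 3, 3))
        if name == "full":
            return cls(widths=(64, 128, 256), kernels=(9, 9, 7, 7, 7, 9, 9, 3))
        raise ValueError(f"unknown architecture preset {name!r}")

    @property
    def layer_channels(self) -> list:
        """(cin, cout) per convolution in order."""
        c1, c2, cm = self.widths
        return [
            (2, c1), (c1, c2), (c2, cm), (cm, c2),
            (c2, c1), (c1, c1), (c1, c1), (c1, 1),
        ]

    def n_weights(self) -> int:
        n = 0
        for (cin, cout), k in zip(self.layer_channels, self.kernels):
            n += cin * cout * k * k + cout
        return n

    def receptive_field(self) -> tuple:
        """(rf_h, rf_c) in full-resolution pixels (both axes treated alike)."""
        # scale factor of each conv: enc1 @1, enc2 @2, mid @4, dec1 @2, rest @1
        scales = (1, 2, 4, 4, 2, 1, 1, 1)
        rf = 1
        for k, s in zip(self.kernels, scales):
            rf += (k - 1) * s
        return rf, rf

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchConfig":
        d = dict(d)
        d["widths"] = tuple(d["widths"])
        d["kernels"] = tuple(d["kernels"])
        return cls(**d)


_LAYER_NAMES = ["enc1", "enc2", "mid1", "mid2", "dec1", "dec2", "dec3", "out"]


class UNet:
    """Forward/backward implementation of the seven-hidden-layer network."""

    def __init__(self, arch: ArchConfig, rng: np.random.Generator | int = 0):
        self.arch = arch
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.params: dict[str, np.ndarray] = {}
        for name, (cin, cout), k in zip(
            _LAYER_NAMES, arch.layer_channels, arch.kernels
        ):
            fan_in = cin * k * k
            std = np.sqrt(2.0 / fan_in)
            self.params[f"{name}.w"] = rng.normal(
                0.0, std, size=(cout, cin, k, k)
            ).astype(np.float32)
            self.params[f"{name}.b"] = np.zeros(cout, dtype=np.float32)

    @property
    def n_weights(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def check_receptive_field(self, n_offsets: int, min_arm: int | None = None):
        """Warn when the 13C-axis receptive field cannot span an X-arm."""
        rf_c = self.arch.receptive_field()[1]
        min_arm = n_offsets // 2 if min_arm is None else min_arm
        if rf_c < min_arm:
            warnings.warn(
                f"receptive field along the 13C axis ({rf_c} px) is smaller "
                f"than the widest expected X-arm ({min_arm} px); the network "
                "may not localize peaks from far off-resonance features",
                stacklevel=2,
            )

    # -- forward / backward ---------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ):
        """x: channel-major (2, B, H, W) float32 -> (B, H, W); H, W % 4 == 0.

        ``train=True`` (or an explicit ``dropout_rng``) activates dropout
        after hidden layers 1-6 and returns a cache for :meth:`backward`.
        """
        p = self.params
        rate = self.arch.dropout_rate if (train or dropout_rng is not None) else 0.0
        rng = dropout_rng or np.random.default_rng(0)
        cache: dict = {}

        def conv_relu_drop(name, x, drop):
            y, cv = L.conv2d_forward(x, p[f"{name}.w"], p[f"{name}.b"])
            a, rl = L.relu_forward(y)
            if drop and rate > 0:
                a, mask = L.dropout_forward(a, rate, rng)
            else:
                mask = None
            cache[name] = (cv, rl, mask)
            return a

        e1 = conv_relu_drop("enc1", x, True)                 # (c1, B, H, W)
        p1, cache["pool1"] = L.avgpool2_forward(e1)
        e2 = conv_relu_drop("enc2", p1, True)                # (c2, B, H/2, W/2)
        p2, cache["pool2"] = L.avgpool2_forward(e2)
        m1 = conv_relu_drop("mid1", p2, True)                # (cm, B, H/4, W/4)
        m2 = conv_relu_drop("mid2", m1, True)                # (c2, B, H/4, W/4)
        u1, cache["up1"] = L.upsample2_forward(m2)
        d1 = conv_relu_drop("dec1", u1 + e2, True)           # (c1, B, H/2, W/2)
        u2, cache["up2"] = L.upsample2_forward(d1)
        d2 = conv_relu_drop("dec2", u2 + e1, True)           # (c1, B, H, W)
        d3 = conv_relu_drop("dec3", d2, False)               # last hidden: no dropout
        y, cv = L.conv2d_forward(d3, p["out.w"], p["out.b"])
        cache["out"] = (cv, None, None)
        out = y[0]                                           # (B, H, W)
        return (out, cache) if train else out

    def backward(self, dy: np.ndarray, cache: dict) -> dict:
        """dy: (B, H, W) gradient of the loss wrt the output map.

        The skip additions route gradient both into the upsample path and
        directly into the encoder activations; the encoder conv backprops
        receive the sum of the pooled-path and skip-path gradients.
        """
        grads: dict[str, np.ndarray] = {}

        def conv_back(name, da):
            cv, rl, mask = cache[name]
            if name != "out":
                da = L.dropout_backward(da, mask)
                da = L.relu_backward(da, rl)
            dx, dw, db = L.conv2d_backward(da, cv)
            grads[f"{name}.w"] = dw
            grads[f"{name}.b"] = db
            return dx

        d = conv_back("out", dy[None].astype(np.float32))
        d = conv_back("dec3", d)
        d = conv_back("dec2", d)
        d_skip_e1 = d                       # gradient into e1 via the skip add
        d = L.upsample2_backward(d, cache["up2"])
        d = conv_back("dec1", d)
        d_skip_e2 = d                       # gradient into e2 via the skip add
        d = L.upsample2_backward(d, cache["up1"])
        d = conv_back("mid2", d)
        d = conv_back("mid1", d)
        d = L.avgpool2_backward(d, cache["pool2"])
        d = conv_back("enc2", d + d_skip_e2)
        d = L.avgpool2_backward(d, cache["pool1"])
        conv_back("enc1", d + d_skip_e1)
        return grads

    # -- persistence ----------------------------------------------------------

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32)
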