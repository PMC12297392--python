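"""T-Net: dilated-convolution encoder-decoder with channel attention.

The building unit is the T-block: two parallel 3x3 convolutions over the
same input -- one standard, one dilated (rate 2) -- concatenated
channelwise, then batch-normalized and ReLU-activated.  Five T-blocks with
2x2 max pooling form the encoder (filters 64, 128, 256, 512, 1024, each
block doubling its nominal width through the concatenation); a
squeeze-excite style channel-attention module (global average + max
pooling through a shared ratio-8 bottleneck, sigmoid gate) recalibrates
the 2048-channel bottleneck; the decoder applies two transposed-convolution
blocks with skip connections from the matching encoder stages.

Two heads are provided.  ``table4_strict`` terminates exactly where the
published layer enumeration does -- a parameter-free sigmoid projection
(channel average) at quarter resolution -- and exists so the build can be
audited row by row against that enumeration.  ``full_resolution`` (the
training default) completes the last T-block, upsamples twice, and applies
a 1x1 convolution + sigmoid to emit a full-size probability map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn


def conv_param_count(kernel: int, c_in: int, c_out: int, bias: bool = True) -> int:
    """Analytic parameter count of a KxK convolution: K^2*c_in*c_out (+c_out)."""
    if min(kernel, c_in, c_out) <= 0:
        raise ValueError("kernel, c_in, c_out must be positive")
    return kernel * kernel * c_in * c_out + (c_out if bias else 0)


@dataclass(frozen=True)
class LayerDescriptor:
    """One enumerated layer: its shape, parameter count and fan-in.

    ``param_count`` follows the model-summary convention that batch-norm
    rows count 4*C (including the two non-trainable moving statistics).
    """

    name: str
    output_shape: tuple
    param_count: int
    connections: tuple


@dataclass
class TBlockSpec:
    in_channels: int
    filters: int
    kernel: int = 3
    dilation: int = 2

    def validate(self) -> None:
        if self.filters <= 0 or self.dilation < 1 or self.in_channels <= 0:
            raise ValueError(f"invalid T-block spec {self}")


@dataclass
class ChannelAttentionSpec:
    channels: int
    ratio: int = 8

    def validate(self) -> None:
        if self.channels % self.ratio != 0:
            raise ValueError(
                f"channels {self.channels} not divisible by ratio {self.ratio}")


@dataclass
class TNetConfig:
    """Declarative architecture description.

    ``encoder_filters`` must double at every level; the input edge must be
    square and divisible by 2**(levels-1) so every pooling stage is exact.
    """

    input_size: int = 256
    encoder_filters: tuple = (64, 128, 256, 512, 1024)
    attention_ratio: int = 8
    dilation: int = 2
    output_mode: str = "full_resolution"  # or "table4_strict"
    seed: int = 0

    def validate(self) -> None:
        f = self.encoder_filters
        if len(f) < 3 or any(f[i + 1] != 2 * f[i] for i in range(len(f) - 1)):
            raise ValueError("encoder_filters must double at each level")
        if self.input_size % 2 ** (len(f) - 1) != 0:
            raise ValueError(
                f"input size {self.input_size} not divisible by "
                f"{2 ** (len(f) - 1)}")
        if (2 * f[-1]) % self.attention_ratio != 0:
            raise ValueError("bottleneck width not divisible by attention ratio")
        if self.output_mode not in ("table4_strict", "full_resolution"):
            raise ValueError(f"unknown output_mode {self.output_mode}")


class TNet:
    """Built network plus its layer registry and attention tap point."""

    def __init__(self, config: TNetConfig):
        config.validate()
        self.config = config
        self.net = nn.Network("Input")
        self._build()

    # -- construction --------------------------------------------------
    def _build(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        net = self.net
        net.add(nn.Input("Input", (cfg.input_size, cfg.input_size, 1)))

        filters = cfg.encoder_filters
        levels = len(filters)
        prev = "Input"
        c_prev = 1
        conv_idx = 1
        relu_names = []
        for lvl, f in enumerate(filters, start=1):
            prev, c_prev, conv_idx = self._t_block(
                prev, c_prev, f, lvl, conv_idx, rng)
            relu_names.append(prev)
            if lvl < levels:
                net.add(nn.MaxPool2(f"MaxPool{lvl}", [prev]))
                prev = f"MaxPool{lvl}"

        # channel attention on the bottleneck
        c_bottleneck = 2 * filters[-1]
        ChannelAttentionSpec(c_bottleneck, cfg.attention_ratio).validate()
        bottleneck_relu = prev
        net.add(nn.GlobalAvgPool("GlobalAvgPool", [prev]))
        net.add(nn.GlobalMaxPool("GlobalMaxPool", [prev]))
        hidden = c_bottleneck // cfg.attention_ratio
        net.add(nn.SharedDense("Dense", ["GlobalAvgPool", "GlobalMaxPool"],
                               c_bottleneck, hidden, activation="relu", rng=rng))
        net.add(nn.SharedDense("Dense2", ["Dense"], hidden, c_bottleneck,
                               activation=None, rng=rng))
        net.add(nn.AddPaths("Add", ["Dense2"]))
        net.add(nn.Sigmoid("Sigmoid", ["Add"]))
        net.add(nn.ChannelScale("Mul", [bottleneck_relu, "Sigmoid"]))
        self.attention_gate = "Sigmoid"
        prev, c_prev = "Mul", c_bottleneck

        # two decoder blocks with skips from the two deepest pooled stages
        concat_idx = levels + 1
        bn_idx = levels + 1
        for d in (1, 2):
            skip_relu = relu_names[levels - 1 - d]
            skip_c = 2 * filters[levels - 1 - d]  # T-block concat width there
            f = filters[levels - 1 - d]
            net.add(nn.ConvTranspose2D(f"UpConv{d}", [prev], c_prev, f, rng=rng))
            net.add(nn.Concat(f"Concat{concat_idx}", [f"UpConv{d}", skip_relu]))
            cat = f"Concat{concat_idx}"
            concat_idx += 1
            c_cat = f + skip_c
            net.add(nn.Conv2D(f"Conv{conv_idx}", [cat], c_cat, f,
                              dilation=1, rng=rng))
            net.add(nn.Conv2D(f"Conv{conv_idx + 1}", [cat], c_cat, f,
                              dilation=self.config.dilation, rng=rng))
            if d == 1:
                net.add(nn.Concat(f"Concat{concat_idx}",
                                  [f"Conv{conv_idx}", f"Conv{conv_idx + 1}"]))
                net.add(nn.BatchNorm(f"BN{bn_idx}", [f"Concat{concat_idx}"], 2 * f))
                net.add(nn.ReLU(f"ReLU{bn_idx}", [f"BN{bn_idx}"]))
                prev, c_prev = f"ReLU{bn_idx}", 2 * f
                concat_idx += 1
                bn_idx += 1
            else:
                last_pair = (f"Conv{conv_idx}", f"Conv{conv_idx + 1}")
                last_f = f
            conv_idx += 2

        if cfg.output_mode == "table4_strict":
            # terminate exactly as the published enumeration does: a
            # parameter-free sigmoid projection of the last convolution
            net.add(nn.ChannelMeanSigmoid("Output", [last_pair[1]]))
        else:
            # complete the final T-block, then upsample back to input size
            net.add(nn.Concat(f"Concat{concat_idx}", list(last_pair)))
            net.add(nn.BatchNorm(f"BN{bn_idx}", [f"Concat{concat_idx}"], 2 * last_f))
            net.add(nn.ReLU(f"ReLU{bn_idx}", [f"BN{bn_idx}"]))
            net.add(nn.UpSample2("UpSample1", [f"ReLU{bn_idx}"]))
            net.add(nn.UpSample2("UpSample2", ["UpSample1"]))
            net.add(nn.Conv2D("ConvHead", ["UpSample2"], 2 * last_f, 1,
                              kernel=1, rng=rng))
            net.add(nn.Sigmoid("Output", ["ConvHead"]))

    def _t_block(self, prev: str, c_in: int, f: int, lvl: int,
                 conv_idx: int, rng) -> tuple[str, int, int]:
        """Both branches read the block input; concat doubles the width."""
        TBlockSpec(c_in, f, dilation=self.config.dilation).validate()
        net = self.net
        net.add(nn.Conv2D(f"Conv{conv_idx}", [prev], c_in, f, dilation=1, rng=rng))
        net.add(nn.Conv2D(f"Conv{conv_idx + 1}", [prev], c_in, f,
                          dilation=self.config.dilation, rng=rng))
        net.add(nn.Concat(f"Concat{lvl}", [f"Conv{conv_idx}", f"Conv{conv_idx + 1}"]))
        net.add(nn.BatchNorm(f"BN{lvl}", [f"Concat{lvl}"], 2 * f))
        net.add(nn.ReLU(f"ReLU{lvl}", [f"BN{lvl}"]))
        return f"ReLU{lvl}", 2 * f, conv_idx + 2

    # -- inference -----------------------------------------------------
    def predict(self, images: np.ndarray, training: bool = False) -> np.ndarray:
        """Forward pass; accepts (H,W), (N,H,W) or (N,H,W,1)."""
        x = np.asarray(images, dtype=np.float32)
        squeeze = x.ndim == 2
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1] != self.config.input_size or x.shape[2] != self.config.input_size:
            raise ValueError(
                f"input spatial shape {x.shape[1:3]} does not match "
                f"configured size {self.config.input_size}")
        out = self.net.forward(x, training=training)
        return out[0] if squeeze else out

    def attention_map(self, img: np.ndarray) -> np.ndarray:
        """Mean channel-attention gate, broadcast to input resolution.

        The gate is a per-channel multiplier in [0,1]; averaging over
        channels yields one attention level per image, rendered as a map
        at input resolution for overlay display.
        """
        self.predict(img)
        gate = self.net.layer_output(self.attention_gate)  # (N, C)
        level = gate.mean(axis=-1)
        size = self.config.input_size
        maps = np.broadcast_to(level[:, None, None], (len(level), size, size))
        return maps[0].copy() if np.asarray(img).ndim == 2 else maps.copy()

    # -- introspection -------------------------------------------------
    def enumerate_layers(self) -> list[LayerDescriptor]:
        out = []
        for name, layer in self.net.layers.items():
            shape = (None,) + tuple(int(s) for s in layer.output_shape)
            out.append(LayerDescriptor(
                name=name, output_shape=shape,
                param_count=layer.param_count(),
                connections=tuple(layer.inputs)))
        return out

    def total_params(self) -> int:
        return sum(d.param_count for d in self.enumerate_layers())

    def save(self, path) -> None:
        self.net.save(path)

    def load(self, path) -> None:
        self.net.load(path)


def build_tnet(config: TNetConfig | None = None) -> TNet:
    return TNet(config or TNetConfig())


# ---------------------------------------------------------------------------
# reference enumeration for the canonical 256x256 build
# ---------------------------------------------------------------------------

# Published layer-by-layer summary of the canonical T-Net (input 256x256x1,
# encoder filters 64..1024, strict head).  Shape None entries are rows whose
# printed shape is inconsistent with their printed parameter count (the
# Dense row prints the post-bottleneck width but the first shared layer's
# parameters); those shapes are not compared.
TABLE4_REFERENCE: list[tuple[str, tuple | None, int]] = [
    ("Input", (None, 256, 256, 1), 0),
    ("Conv1", (None, 256, 256, 64), 640),
    ("Conv2", (None, 256, 256, 64), 640),
    ("Concat1", (None, 256, 256, 128), 0),
    ("BN1", (None, 256, 256, 128), 512),
    ("ReLU1", (None, 256, 256, 128), 0),
    ("MaxPool1", (None, 128, 128, 128), 0),
    ("Conv3", (None, 128, 128, 128), 147584),
    ("Conv4", (None, 128, 128, 128), 147584),
    ("Concat2", (None, 128, 128, 256), 0),
    ("BN2", (None, 128, 128, 256), 1024),
    ("ReLU2", (None, 128, 128, 256), 0),
    ("MaxPool2", (None, 64, 64, 256), 0),
    ("Conv5", (None, 64, 64, 256), 590080),
    ("Conv6", (None, 64, 64, 256), 590080),
    ("Concat3", (None, 64, 64, 512), 0),
    ("BN3", (None, 64, 64, 512), 2048),
    ("ReLU3", (None, 64, 64, 512), 0),
    ("MaxPool3", (None, 32, 32, 512), 0),
    ("Conv7", (None, 32, 32, 512), 2359808),
    ("Conv8", (None, 32, 32, 512), 2359808),
    ("Concat4", (None, 32, 32, 1024), 0),
    ("BN4", (None, 32, 32, 1024), 4096),
    ("ReLU4", (None, 32, 32, 1024), 0),
    ("MaxPool4", (None, 16, 16, 1024), 0),
    ("Conv9", (None, 16, 16, 1024), 9438208),
    ("Conv10", (None, 16, 16, 1024), 9438208),
    ("Concat5", (None, 16, 16, 2048), 0),
    ("BN5", (None, 16, 16, 2048), 8192),
    ("ReLU5", (None, 16, 16, 2048), 0),
    ("GlobalAvgPool", (None, 2048), 0),
    ("GlobalMaxPool", (None, 2048), 0),
    ("Dense", None, 524544),
    ("Add", (None, 2048), 0),
    ("Mul", (None, 16, 16, 2048), 0),
    ("UpConv1", (None, 32, 32, 512), 9437696),
    ("Concat6", (None, 32, 32, 1536), 0),
    ("Conv11", (None, 32, 32, 512), 7078400),
    ("Conv12", (None, 32, 32, 512), 7078400),
    ("Concat7", (None, 32, 32, 1024), 0),
    ("BN6", (None, 32, 32, 1024), 4096),
    ("ReLU6", (None, 32, 32, 1024), 0),
    ("UpConv2", (None, 64, 64, 256), 2359552),
    ("Concat8", (None, 64, 64, 768), 0),
    ("Conv13", (None, 64, 64, 256), 1769728),
    ("Conv14", (None, 64, 64, 256), 1769728),
    ("Output", (None, 64, 64, 1), 0),
]


def verify_table4(tnet: TNet | None = None) -> list[str]:
    """Audit the strict build against the reference enumeration.

    Returns a list of human-readable mismatch strings (empty = pass).
    Rows the reference omits (the second shared dense layer, the explicit
    sigmoid) are allowed; every reference row must exist with the exact
    printed parameter count and, where consistent, output shape.
    """
    if tnet is None:
        tnet = build_tnet(TNetConfig(output_mode="table4_strict"))
    built = {d.name: d for d in tnet.enumerate_layers()}
    problems = []
    for name, shape, params in TABLE4_REFERENCE:
        if name not in built:
            problems.append(f"missing layer {name}")
            continue
        d = built[name]
        if d.param_count != params:
            problems.append(
                f"{name}: param count {d.param_count} != {params}")
        if shape is not None and tuple(d.output_shape) != shape:
            problems.append(
                f"{name}: output shape {d.output_shape} != {shape}")
    return problems
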