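"""HRU-Net: ResNet-50 encoder with per-block channel reduction, hybrid
atrous convolution (HAC) modules on the high-level layers, and a
U-Net-style skip-concatenation decoder ending in a two-class softmax.

Architecture summary (input H x W grayscale, H and W divisible by 32):

    stem  7x7/2 conv          -> H/2,  64 ch   -> 1x1 reduce ->  32
    res1  3 bottlenecks       -> H/4,  256     -> 1x1 reduce ->  64
    res2  4 bottlenecks /2    -> H/8,  512     -> 1x1 reduce ->  96
    res3  6 bottlenecks /2    -> H/16, 1024    -> 1x1 reduce -> 128
    res4  3 bottlenecks /2    -> H/32, 2048    -> 1x1 reduce -> 128

HAC modules (parallel dilated 3x3 convs at rates 1,2,3,5 plus a cascaded
rate-1->2->3 chain, channel-preserving) are applied to the reduced
features at configurable positions, by default the three deepest layers
res2/res3/res4.  The decoder upsamples 2x per stage with bilinear
interpolation, concatenates the reduced skip feature, and applies two
3x3 conv/BN/ReLU; a final 1x1 conv plus softmax yields the per-pixel
class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import (Adam, BatchNorm2d, Conv2d, MaxPool2d, Module, ReLU,
                 Sequential, UpsampleBilinear2x, softmax_channels)

__all__ = [
    "HACSpec", "ModelConfig", "EncoderPyramid", "HRUNet",
    "atrous_conv_value", "receptive_field", "build_hac", "build_hrunet",
    "load_pretrained_encoder", "save_encoder_weights", "encoder_state_dict",
    "model_state_dict", "save_model", "load_model",
    "HAC_PLACEMENT_ORDER", "hac_placement_for_count",
]

# deepest-first order in which HAC modules are added for the ablation sweep
HAC_PLACEMENT_ORDER = ("res4", "res3", "res2", "res1", "conv_block", "input")

# Table-style encoder contract: (pre-reduction channels, reduced channels)
ENCODER_CHANNELS = {
    "conv_block": (64, 32),
    "res1": (256, 64),
    "res2": (512, 96),
    "res3": (1024, 128),
    "res4": (2048, 128),
}


# --------------------------------------------------------------------------
# dilated-convolution arithmetic
# --------------------------------------------------------------------------

def atrous_conv_value(grid: np.ndarray, center: tuple[int, int],
                      kernel: np.ndarray, rate: int) -> float:
    """Value of a single dilated cross-correlation tap sum at ``center``.

    The K x K kernel taps are spaced ``rate`` pixels apart around the
    center; taps falling outside the grid contribute zero (zero
    padding).  With rate 1 this is a standard convolution output pixel.
    """
    kernel = np.asarray(kernel, dtype=np.float64)
    K = kernel.shape[0]
    if kernel.ndim != 2 or kernel.shape[0] != kernel.shape[1]:
        raise ValueError(f"kernel must be square, got shape {kernel.shape}")
    if K % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {K}")
    if rate < 1:
        raise ValueError(f"atrous rate must be >= 1, got {rate}")
    grid = np.asarray(grid, dtype=np.float64)
    m, n = center
    H, W = grid.shape
    acc = 0.0
    c = (K + 1) // 2
    for i in range(1, K + 1):
        for j in range(1, K + 1):
            r_idx = m - rate * c + rate * i
            c_idx = n - rate * c + rate * j
            if 0 <= r_idx < H and 0 <= c_idx < W:
                acc += grid[r_idx, c_idx] * kernel[i - 1, j - 1]
    return float(acc)


def receptive_field(kernels, rates) -> int:
    """Receptive field of a stride-1 stack of dilated convolutions.

    RF = 1 + sum_i rate_i * (K_i - 1).  E.g. three 3x3 convs at rates
    1, 2, 3 see a 13 x 13 input window.
    """
    kernels, rates = list(kernels), list(rates)
    if not kernels or not rates:
        raise ValueError("kernels and rates must be non-empty")
    if len(kernels) != len(rates):
        raise ValueError("kernels and rates must have equal length")
    if any(k < 1 for k in kernels) or any(r < 1 for r in rates):
        raise ValueError("kernel sizes and rates must be >= 1")
    return 1 + sum(r * (k - 1) for k, r in zip(kernels, rates))


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HACSpec:
    """Rates of the parallel branches and of the cascaded chain."""

    parallel_rates: tuple[int, ...] = (1, 2, 3, 5)
    cascade_rates: tuple[int, ...] = (1, 2, 3)
    kernel: int = 3

    def __post_init__(self):
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError(f"kernel must be odd and >= 1, got {self.kernel}")
        if any(r < 1 for r in self.parallel_rates + self.cascade_rates):
            raise ValueError("all atrous rates must be >= 1")
        if not self.parallel_rates and not self.cascade_rates:
            raise ValueError("HACSpec needs at least one branch")

    @property
    def n_branches(self) -> int:
        return len(self.parallel_rates) + (1 if self.cascade_rates else 0)

    def cascade_receptive_field(self) -> int:
        return receptive_field([self.kernel] * len(self.cascade_rates),
                               self.cascade_rates)


@dataclass(frozen=True)
class ModelConfig:
    in_height: int = 128
    in_width: int = 128
    n_classes: int = 2
    hac_placement: tuple[str, ...] = ("res4", "res3", "res2")
    pretrained: bool = False
    reduced_channels: tuple[int, int, int, int, int] = (32, 64, 96, 128, 128)
    hac: HACSpec = field(default_factory=HACSpec)
    seed: int = 0

    def __post_init__(self):
        if self.in_height % 32 or self.in_width % 32:
            raise ValueError("input size must be divisible by 32, got "
                             f"{self.in_height}x{self.in_width}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        bad = set(self.hac_placement) - set(HAC_PLACEMENT_ORDER)
        if bad:
            raise ValueError(f"unknown HAC placement(s) {sorted(bad)}; "
                             f"valid: {HAC_PLACEMENT_ORDER}")
        if len(self.reduced_channels) != 5:
            raise ValueError("reduced_channels must list 5 per-block counts")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hac_placement"] = list(self.hac_placement)
        d["reduced_channels"] = list(self.reduced_channels)
        d["hac"] = {"parallel_rates": list(self.hac.parallel_rates),
                    "cascade_rates": list(self.hac.cascade_rates),
                    "kernel": self.hac.kernel}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "hac" in d and isinstance(d["hac"], dict):
            h = d["hac"]
            d["hac"] = HACSpec(tuple(h.get("parallel_rates", (1, 2, 3, 5))),
                               tuple(h.get("cascade_rates", (1, 2, 3))),
                               h.get("kernel", 3))
        for key in ("hac_placement", "reduced_channels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def hac_placement_for_count(n: int) -> tuple[str, ...]:
    """First ``n`` positions of the deepest-first placement order."""
    if not 0 <= n <= len(HAC_PLACEMENT_ORDER):
        raise ValueError(f"HAC count must be in 0..{len(HAC_PLACEMENT_ORDER)}, got {n}")
    return HAC_PLACEMENT_ORDER[:n]


@dataclass
class EncoderPyramid:
    """Reduced encoder features at the five skip levels."""

    conv_block: np.ndarray  # (B, 32, H/2, W/2)
    res1: np.ndarray        # (B, 64, H/4, W/4)
    res2: np.ndarray        # (B, 96, H/8, W/8)
    res3: np.ndarray        # (B, 128, H/16, W/16)
    res4: np.ndarray        # (B, 128, H/32, W/32)


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------

class ConvBNReLU(Sequential):
    def __init__(self, cin, cout, k, stride=1, dilation=1, rng=None):
        super().__init__(Conv2d(cin, cout, k, stride=stride, dilation=dilation, rng=rng),
                         BatchNorm2d(cout), ReLU())


class Bottleneck(Module):
    """ResNet bottleneck: 1x1 down, 3x3, 1x1 up, residual add, ReLU."""

    def __init__(self, cin, cmid, cout, stride=1, rng=None):
        self.conv1 = Conv2d(cin, cmid, 1, rng=rng)
        self.bn1 = BatchNorm2d(cmid)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cmid, cmid, 3, stride=stride, rng=rng)
        self.bn2 = BatchNorm2d(cmid)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(cmid, cout, 1, rng=rng)
        self.bn3 = BatchNorm2d(cout)
        self.relu_out = ReLU()
        if stride != 1 or cin != cout:
            self.down_conv = Conv2d(cin, cout, 1, stride=stride, padding=0, rng=rng)
            self.down_bn = BatchNorm2d(cout)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x, training=False):
        h = self.relu1(self.bn1(self.conv1(x, training), training), training)
        h = self.relu2(self.bn2(self.conv2(h, training), training), training)
        h = self.bn3(self.conv3(h, training), training)
        sc = x if self.down_conv is None else \
            self.down_bn(self.down_conv(x, training), training)
        return self.relu_out(h + sc, training)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dh = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(self.relu2.backward(
                self.conv3.backward(self.bn3.backward(d))))))))
        if self.down_conv is None:
            dsc = d
        else:
            dsc = self.down_conv.backward(self.down_bn.backward(d))
        return dh + dsc


class ResNet50Encoder(Module):
    """Stock ResNet-50 trunk emitting the five raw feature maps.

    Grayscale inputs are replicated to three channels before the stem so
    that ImageNet-shaped pretrained weights remain loadable.
    """

    BLOCKS = {"res1": 3, "res2": 4, "res3": 6, "res4": 3}

    def __init__(self, rng=None):
        self.conv1 = Conv2d(3, 64, 7, stride=2, padding=3, rng=rng)
        self.bn1 = BatchNorm2d(64)
        self.relu1 = ReLU()
        self.maxpool = MaxPool2d(3, 2, 1)
        self.res1 = self._make_layer(64, 64, 256, 3, stride=1, rng=rng)
        self.res2 = self._make_layer(256, 128, 512, 4, stride=2, rng=rng)
        self.res3 = self._make_layer(512, 256, 1024, 6, stride=2, rng=rng)
        self.res4 = self._make_layer(1024, 512, 2048, 3, stride=2, rng=rng)

    @staticmethod
    def _make_layer(cin, cmid, cout, n_blocks, stride, rng):
        blocks = [Bottleneck(cin, cmid, cout, stride=stride, rng=rng)]
        blocks += [Bottleneck(cout, cmid, cout, rng=rng) for _ in range(n_blocks - 1)]
        return Sequential(*blocks)

    def forward(self, x, training=False):
        if x.shape[1] == 1:
            x = np.repeat(x, 3, axis=1)
        elif x.shape[1] != 3:
            raise ValueError(f"expected 1- or 3-channel input, got {x.shape[1]}")
        c = self.relu1(self.bn1(self.conv1(x, training), training), training)
        p = self.maxpool(c, training)
        f1 = self.res1(p, training=training)
        f2 = self.res2(f1, training=training)
        f3 = self.res3(f2, training=training)
        f4 = self.res4(f3, training=training)
        return {"conv_block": c, "res1": f1, "res2": f2, "res3": f3, "res4": f4}

    def backward(self, grads: dict):
        """Backprop given gradients w.r.t. each emitted feature map."""
        d3 = self.res4.backward(grads["res4"]) + grads["res3"]
        d2 = self.res3.backward(d3) + grads["res2"]
        d1 = self.res2.backward(d2) + grads["res1"]
        dp = self.res1.backward(d1)
        dc = self.maxpool.backward(dp) + grads["conv_block"]
        dx = self.conv1.backward(self.bn1.backward(self.relu1.backward(dc)))
        return dx


class HACBlock(Module):
    """Hybrid atrous convolutions: parallel dilated branches plus one
    cascaded chain, fused back to the input channel count.

    Each parallel branch is a 3x3 conv at its rate followed by BN/ReLU;
    the cascade chains conv/BN/ReLU at its rates in order.  Branch
    outputs are concatenated along channels and fused by a 1x1
    conv/BN/ReLU, so the block is channel- and resolution-preserving and
    can be dropped in at any pyramid level.
    """

    def __init__(self, spec: HACSpec, channels: int, rng=None):
        if channels < 1:
            raise ValueError("channels must be >= 1")
        self.spec = spec
        k = spec.kernel
        self.branches = [ConvBNReLU(channels, channels, k, dilation=r, rng=rng)
                         for r in spec.parallel_rates]
        if spec.cascade_rates:
            self.cascade = Sequential(*[ConvBNReLU(channels, channels, k,
                                                   dilation=r, rng=rng)
                                        for r in spec.cascade_rates])
        else:
            self.cascade = None
        n = spec.n_branches
        self.fuse = ConvBNReLU(n * channels, channels, 1, rng=rng)
        self._channels = channels

    def forward(self, x, training=False):
        outs = [b(x, training=training) for b in self.branches]
        if self.cascade is not None:
            outs.append(self.cascade(x, training=training))
        cat = np.concatenate(outs, axis=1)
        return self.fuse(cat, training=training)

    def backward(self, dy):
        dcat = self.fuse.backward(dy)
        C = self._channels
        parts = [dcat[:, i * C:(i + 1) * C] for i in range(self.spec.n_branches)]
        dx = np.zeros_like(parts[0])
        for b, part in zip(self.branches, parts):
            dx += b.backward(np.ascontiguousarray(part))
        if self.cascade is not None:
            dx += self.cascade.backward(np.ascontiguousarray(parts[-1]))
        return dx


def build_hac(spec: HACSpec, channels: int,
              rng: np.random.Generator | None = None) -> HACBlock:
    """Channel-preserving HAC block for a ``channels``-deep feature grid."""
    return HACBlock(spec, channels, rng=rng or np.random.default_rng(0))


class DecoderStage(Module):
    """2x bilinear upsample, concat skip, two 3x3 conv/BN/ReLU."""

    def __init__(self, cin_deep, cin_skip, cout, rng=None):
        self.up = UpsampleBilinear2x()
        self.conv = Sequential(ConvBNReLU(cin_deep + cin_skip, cout, 3, rng=rng),
                               ConvBNReLU(cout, cout, 3, rng=rng))
        self._split = None

    def forward(self, deep, skip, training=False):
        u = self.up(deep, training)
        cat = np.concatenate([u, skip], axis=1)
        self._split = u.shape[1]
        return self.conv(cat, training=training)

    def backward(self, dy):
        dcat = self.conv.backward(dy)
        s = self._split
        d_deep = self.up.backward(np.ascontiguousarray(dcat[:, :s]))
        d_skip = np.ascontiguousarray(dcat[:, s:])
        return d_deep, d_skip


SKIP_ORDER = ("res3", "res2", "res1", "conv_block")  # decoder traversal order


class HRUNet(Module):
    """Full segmentation network mapping (B, 1, H, W) to (B, C, H, W) logits."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = ResNet50Encoder(rng=rng)
        rc = dict(zip(("conv_block", "res1", "res2", "res3", "res4"),
                      config.reduced_channels))
        self.reduced_channels = rc
        self.reducers = {name: ConvBNReLU(ENCODER_CHANNELS[name][0], rc[name], 1, rng=rng)
                         for name in ENCODER_CHANNELS}
        self.hacs = {name: HACBlock(config.hac, rc[name], rng=rng)
                     for name in config.hac_placement if name != "input"}
        widths = {"res3": rc["res3"], "res2": rc["res2"],
                  "res1": rc["res1"], "conv_block": rc["conv_block"]}
        self.stages = []
        deep_c = rc["res4"]
        for name in SKIP_ORDER:
            stage = DecoderStage(deep_c, rc[name], widths[name], rng=rng)
            self.stages.append(stage)
            deep_c = widths[name]
        self.final_up = UpsampleBilinear2x()
        self.final_conv = Sequential(ConvBNReLU(deep_c, deep_c, 3, rng=rng),
                                     ConvBNReLU(deep_c, deep_c, 3, rng=rng))
        if "input" in config.hac_placement:
            self.hac_input = HACBlock(config.hac, deep_c, rng=rng)
        else:
            self.hac_input = None
        self.head = Conv2d(deep_c, config.n_classes, 1, bias=True, rng=rng)

    # named_params does not traverse dicts; expose reducers/hacs as lists
    def named_params(self, prefix: str = ""):
        yield from super().named_params(prefix)
        for group, members in (("reducers", self.reducers), ("hacs", self.hacs)):
            for name, mod in members.items():
                yield from mod.named_params(prefix=f"{prefix}{group}.{name}.")

    def named_modules(self, prefix: str = ""):
        yield from super().named_modules(prefix)
        for group, members in (("reducers", self.reducers), ("hacs", self.hacs)):
            for name, mod in members.items():
                yield f"{prefix}{group}.{name}", mod
                yield from mod.named_modules(prefix=f"{prefix}{group}.{name}.")

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        H, W = x.shape[2:]
        if H % 32 or W % 32:
            raise ValueError(f"input size must be divisible by 32, got {H}x{W}")
        return x

    def encoder_features(self, x, training=False) -> EncoderPyramid:
        """Reduced (post-1x1) skip features, before any HAC."""
        x = self._check_input(x)
        raw = self.encoder(x, training=training)
        red = {k: self.reducers[k](v, training=training) for k, v in raw.items()}
        return EncoderPyramid(**red)

    def forward(self, x, training=False):
        x = self._check_input(x)
        raw = self.encoder(x, training=training)
        red = {k: self.reducers[k](v, training=training) for k, v in raw.items()}
        for name, hac in self.hacs.items():
            red[name] = hac(red[name], training=training)
        f = red["res4"]
        for stage, name in zip(self.stages, SKIP_ORDER):
            f = stage.forward(f, red[name], training=training)
        f = self.final_up(f, training)
        f = self.final_conv(f, training=training)
        if self.hac_input is not None:
            f = self.hac_input(f, training=training)
        return self.head(f, training)

    def backward(self, dlogits):
        d = self.head.backward(dlogits)
        if self.hac_input is not None:
            d = self.hac_input.backward(d)
        d = self.final_conv.backward(d)
        d = self.final_up.backward(d)
        skip_grads = {}
        for stage, name in zip(reversed(self.stages), reversed(SKIP_ORDER)):
            d, d_skip = stage.backward(d)
            skip_grads[name] = d_skip
        skip_grads["res4"] = d
        for name in list(skip_grads):
            if name in self.hacs:
                skip_grads[name] = self.hacs[name].backward(skip_grads[name])
        raw_grads = {name: self.reducers[name].backward(g)
                     for name, g in skip_grads.items()}
        return self.encoder.backward(raw_grads)

    def predict_proba(self, x) -> np.ndarray:
        """(B, C, H, W) softmax probability maps (inference mode)."""
        return softmax_channels(self.forward(x, training=False))

    def predict_mask(self, x) -> np.ndarray:
        """(B, H, W) arg-max class labels."""
        return self.predict_proba(x).argmax(axis=1).astype(np.uint8)


def build_hrunet(config: ModelConfig | None = None, **overrides) -> HRUNet:
    """Construct an HRU-Net (random init; see ``load_pretrained_encoder``)."""
    if config is None:
        config = ModelConfig(**overrides)
    elif overrides:
        config = ModelConfig(**{**config.to_dict(), **overrides})
    return HRUNet(config)


# --------------------------------------------------------------------------
# checkpointing and encoder weight transfer
# --------------------------------------------------------------------------

def model_state_dict(model: HRUNet) -> dict[str, np.ndarray]:
    state = {name: p.value.copy() for name, p in model.named_params()}
    for name, mod in model.named_modules():
        if isinstance(mod, BatchNorm2d):
            state[f"{name}.running_mean"] = mod.running_mean.copy()
            state[f"{name}.running_var"] = mod.running_var.copy()
    return state


def save_model(model: HRUNet, path) -> None:
    """Serialize config + all parameters and BN statistics to one .npz."""
    import json
    np.savez(path, __config__=np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8),
        **model_state_dict(model))


def load_model(path) -> HRUNet:
    import json
    with np.load(path) as npz:
        cfg = ModelConfig.from_dict(json.loads(bytes(npz["__config__"]).decode()))
        weights = {k: npz[k] for k in npz.files if k != "__config__"}
    model = HRUNet(cfg)
    for name, p in model.named_params():
        p.value[...] = weights[name].astype(np.float32)
    for name, mod in model.named_modules():
        if isinstance(mod, BatchNorm2d):
            mod.running_mean = weights[f"{name}.running_mean"].astype(np.float32).copy()
            mod.running_var = weights[f"{name}.running_var"].astype(np.float32).copy()
    return model


# --------------------------------------------------------------------------
# encoder weight transfer
# --------------------------------------------------------------------------

def encoder_state_dict(model: HRUNet) -> dict[str, np.ndarray]:
    """All encoder parameters plus batch-norm running statistics."""
    state = {name: p.value.copy() for name, p in model.encoder.named_params()}
    for name, mod in model.encoder.named_modules():
        if isinstance(mod, BatchNorm2d):
            state[f"{name}.running_mean"] = mod.running_mean.copy()
            state[f"{name}.running_var"] = mod.running_var.copy()
    return state


def save_encoder_weights(model: HRUNet, path) -> None:
    np.savez(path, **encoder_state_dict(model))


def load_pretrained_encoder(model: HRUNet, weights_source=None) -> HRUNet:
    """Initialize the encoder from a saved weight set; fine-tuning keeps
    every parameter trainable.

    ``weights_source`` may be a path to an ``.npz`` file or a mapping of
    parameter name to array (names as produced by
    :func:`encoder_state_dict`).  ``None`` leaves the seeded random
    initialization in place — the documented offline fallback when no
    pretrained weights are available.  Shape-incompatible or missing
    entries raise a single error listing every mismatch.
    """
    if weights_source is None:
        return model
    if isinstance(weights_source, (str, Path)):
        with np.load(weights_source) as npz:
            weights = {k: npz[k] for k in npz.files}
    else:
        weights = dict(weights_source)

    problems = []
    params = dict(model.encoder.named_params())
    for name, p in params.items():
        if name not in weights:
            problems.append(f"missing: {name} {p.shape}")
        elif tuple(weights[name].shape) != tuple(p.shape):
            problems.append(f"shape mismatch: {name} expected {tuple(p.shape)} "
                            f"got {tuple(weights[name].shape)}")
    if problems:
        raise ValueError("cannot load encoder weights:\n  " + "\n  ".join(problems))
    for name, p in params.items():
        p.value[...] = weights[name].astype(np.float32)
    for name, mod in model.encoder.named_modules():
        if isinstance(mod, BatchNorm2d):
            for stat in ("running_mean", "running_var"):
                key = f"{name}.{stat}"
                if key in weights:
                    setattr(mod, stat, weights[key].astype(np.float32).copy())
    return model
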