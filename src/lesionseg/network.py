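"""The RatLesNetV2 architecture and static analyses of it.

The network is a 3D residual encoder-decoder: an initial 3^3
convolution lifts the input to the encoder width, each encoder level
applies a residual block followed by 2x2x2 max pooling, a bridge block
sits at the bottom, and each decoder level upsamples by trilinear
interpolation, concatenates the same-level encoder output (doubling the
channel count — hence the decoder width is twice the encoder width),
reduces channels with a 1^3 bottleneck, and applies another residual
block.  A final 1^3 bottleneck maps to two classes and a per-voxel
softmax yields the probability map.  Blocks use the pre-activation
order ReLU -> BatchNorm -> Conv.  No transposed convolutions are used.

Ablation variants are plain configuration changes: ``levels=2`` halves
the receptive field, ``encoder_width`` 28/36 shrinks/grows the model,
and ``block_type="densenet"`` swaps residual blocks for concatenative
ones whose growth rate can be matched to the baseline parameter count
with :func:`match_parameters`.

Inputs whose spatial dimensions are not divisible by ``2**levels`` are
zero-padded on entry and cropped on exit, so the network maps any
volume to an equally-shaped probability map.

:func:`receptive_field` computes the theoretical receptive field by
exact per-axis dependency propagation through the layer graph (branch
joins take the union), which the test suite checks against a
brute-force input-perturbation oracle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field

import numpy as np

from lesionseg.engine import Adam, BatchNorm3d, Conv3d, MaxPool2, Param, ReLU, TrilinearUp2
from lesionseg.errors import InvalidConfigError

__all__ = [
    "NetworkConfig",
    "RatLesNetV2",
    "build_network",
    "receptive_field",
    "count_parameters",
    "match_parameters",
]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``decoder_width`` is fixed at twice ``encoder_width`` by the
    concatenation of skip connections; it is stored for clarity and
    validated rather than set independently.
    """

    levels: int = 3
    encoder_width: int = 32
    decoder_width: int | None = None
    block_type: str = "resnet"
    blocks_per_stage: int = 1
    in_channels: int = 1
    out_classes: int = 2
    growth_rate: int | None = None  # densenet only; default encoder_width // 2

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise InvalidConfigError("levels must be >= 1")
        if self.encoder_width < 1 or self.blocks_per_stage < 1:
            raise InvalidConfigError("widths and blocks_per_stage must be >= 1")
        if self.decoder_width is None:
            self.decoder_width = 2 * self.encoder_width
        if self.decoder_width != 2 * self.encoder_width:
            raise InvalidConfigError(
                "decoder_width must equal 2 * encoder_width (skip concatenation)"
            )
        if self.block_type not in ("resnet", "densenet"):
            raise InvalidConfigError(f"unknown block_type {self.block_type!r}")
        if self.block_type == "densenet":
            if self.growth_rate is None:
                self.growth_rate = max(1, self.encoder_width // 2)
            if self.growth_rate < 1:
                raise InvalidConfigError("growth_rate must be >= 1")
        if self.out_classes != 2:
            raise InvalidConfigError("only two-class (lesion / non-lesion) output is supported")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# blocks


class _ConvUnit:
    """Pre-activation unit: ReLU -> BatchNorm -> Conv(k)."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        self.relu = ReLU()
        self.bn = BatchNorm3d(in_ch)
        self.conv = Conv3d(in_ch, out_ch, k, rng)

    def parameters(self) -> list[Param]:
        return self.bn.parameters() + self.conv.parameters()

    def forward(self, x, training):
        return self.conv.forward(self.bn.forward(self.relu.forward(x, training), training), training)

    def backward(self, gy):
        return self.relu.backward(self.bn.backward(self.conv.backward(gy)))


class ResNetBlock:
    """Two ReLU->BatchNorm->Conv3 stacks with an identity shortcut."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.u1 = _ConvUnit(channels, channels, 3, rng)
        self.u2 = _ConvUnit(channels, channels, 3, rng)

    def parameters(self) -> list[Param]:
        return self.u1.parameters() + self.u2.parameters()

    def forward(self, x, training):
        return x + self.u2.forward(self.u1.forward(x, training), training)

    def backward(self, gy):
        return gy + self.u1.backward(self.u2.backward(gy))

    # (kernel sizes along the main path, for receptive-field analysis)
    conv_kernels = (3, 3)


class DenseNetBlock:
    """Concatenative block: two growth units, then a 1^3 transition back.

    Each unit maps the accumulated feature stack to ``growth`` new
    channels which are concatenated on; a final 1^3 convolution returns
    to the block's nominal channel count so the surrounding topology is
    unchanged.
    """

    def __init__(self, channels: int, growth: int, rng: np.random.Generator):
        self.channels, self.growth = channels, growth
        self.u1 = _ConvUnit(channels, growth, 3, rng)
        self.u2 = _ConvUnit(channels + growth, growth, 3, rng)
        self.transition = _ConvUnit(channels + 2 * growth, channels, 1, rng)

    def parameters(self) -> list[Param]:
        return self.u1.parameters() + self.u2.parameters() + self.transition.parameters()

    def forward(self, x, training):
        g1 = self.u1.forward(x, training)
        x1 = np.concatenate([x, g1], axis=0)
        g2 = self.u2.forward(x1, training)
        x2 = np.concatenate([x1, g2], axis=0)
        return self.transition.forward(x2, training)

    def backward(self, gy):
        c, g = self.channels, self.growth
        gx2 = self.transition.backward(gy)
        gx1 = gx2[: c + g].copy()
        gx1 += self.u2.backward(gx2[c + g :])
        gx = gx1[:c].copy()
        gx += self.u1.backward(gx1[c:])
        return gx

    conv_kernels = (3, 3, 1)


def _make_block(config: NetworkConfig, rng: np.random.Generator):
    if config.block_type == "resnet":
        return ResNetBlock(config.encoder_width, rng)
    return DenseNetBlock(config.encoder_width, config.growth_rate, rng)


# ---------------------------------------------------------------------------
# the model


@dataclass
class _Level:
    blocks: list
    pool: MaxPool2 | None = None


class RatLesNetV2:
    """Residual encoder-decoder for two-class 3D segmentation.

    Operates on single volumes shaped ``(D, H, W)`` (a channel axis is
    added internally).  :meth:`forward_logits` returns the two-channel
    logit field, :meth:`predict_probs` the softmax probability field.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        ew = config.encoder_width
        self.conv_in = Conv3d(config.in_channels, ew, 3, rng)
        self.encoder: list[_Level] = []
        for _ in range(config.levels):
            blocks = [_make_block(config, rng) for _ in range(config.blocks_per_stage)]
            self.encoder.append(_Level(blocks=blocks, pool=MaxPool2()))
        self.bridge = [_make_block(config, rng) for _ in range(config.blocks_per_stage)]
        self.decoder = []
        for _ in range(config.levels):
            self.decoder.append(
                {
                    "up": TrilinearUp2(),
                    "bottleneck": _ConvUnit(2 * ew, ew, 1, rng),
                    "blocks": [_make_block(config, rng) for _ in range(config.blocks_per_stage)],
                }
            )
        self.head = _ConvUnit(ew, config.out_classes, 1, rng)
        self._pad_cache = None
        self._skip_shapes = None

    # -- parameters -------------------------------------------------------

    def parameters(self) -> list[Param]:
        params = self.conv_in.parameters()
        for lvl in self.encoder:
            for b in lvl.blocks:
                params += b.parameters()
        for b in self.bridge:
            params += b.parameters()
        for d in self.decoder:
            params += d["bottleneck"].parameters()
            for b in d["blocks"]:
                params += b.parameters()
        params += self.head.parameters()
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value.copy() for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._batchnorms()):
            state[f"bn_{i}_mean"] = bn.running_mean.copy()
            state[f"bn_{i}_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.value[...] = state[f"param_{i}"]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = state[f"bn_{i}_mean"]
            bn.running_var[...] = state[f"bn_{i}_var"]

    def _batchnorms(self) -> list[BatchNorm3d]:
        bns = []

        def collect_unit(u: _ConvUnit):
            bns.append(u.bn)

        for lvl in self.encoder:
            for b in lvl.blocks:
                self._collect_block_bns(b, bns)
        for b in self.bridge:
            self._collect_block_bns(b, bns)
        for d in self.decoder:
            collect_unit(d["bottleneck"])
            for b in d["blocks"]:
                self._collect_block_bns(b, bns)
        collect_unit(self.head)
        return bns

    @staticmethod
    def _collect_block_bns(block, bns):
        if isinstance(block, ResNetBlock):
            bns += [block.u1.bn, block.u2.bn]
        else:
            bns += [block.u1.bn, block.u2.bn, block.transition.bn]

    # -- forward / backward ----------------------------------------------

    def _pad_input(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        div = 2**self.config.levels
        pads = [(0, (-s) % div) for s in x.shape[1:]]
        if any(p[1] for p in pads):
            x = np.pad(x, [(0, 0)] + pads)
        return x, tuple(p[1] for p in pads)

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Two-channel logits for one volume ``(D, H, W)`` or ``(C, D, H, W)``."""
        if x.ndim == 3:
            x = x[None]
        if x.shape[0] != self.config.in_channels:
            raise InvalidConfigError(
                f"expected {self.config.in_channels} input channel(s), got {x.shape[0]}"
            )
        orig_shape = x.shape[1:]
        x, pad = self._pad_input(x.astype(np.float32))
        self._pad_cache = (orig_shape, pad)

        x = self.conv_in.forward(x, training)
        skips = []
        for lvl in self.encoder:
            for b in lvl.blocks:
                x = b.forward(x, training)
            skips.append(x)
            x = lvl.pool.forward(x, training)
        for b in self.bridge:
            x = b.forward(x, training)
        for d, skip in zip(self.decoder, reversed(skips)):
            x = d["up"].forward(x, training)
            x = np.concatenate([x, skip], axis=0)
            x = d["bottleneck"].forward(x, training)
            for b in d["blocks"]:
                x = b.forward(x, training)
        z = self.head.forward(x, training)
        d0, h0, w0 = orig_shape
        return z[:, :d0, :h0, :w0]

    def backward(self, gz: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the (cropped) logits."""
        orig_shape, pad = self._pad_cache
        full = tuple(s + p for s, p in zip(orig_shape, pad))
        if any(pad):
            g = np.zeros((gz.shape[0],) + full, dtype=np.float32)
            g[:, : orig_shape[0], : orig_shape[1], : orig_shape[2]] = gz
            gz = g
        g = self.head.backward(gz)
        ew = self.config.encoder_width
        skip_grads = []
        for d in reversed(self.decoder):
            for b in reversed(d["blocks"]):
                g = b.backward(g)
            g = d["bottleneck"].backward(g)
            skip_grads.append(g[ew:].copy())
            g = d["up"].backward(np.ascontiguousarray(g[:ew]))
        for b in reversed(self.bridge):
            g = b.backward(g)
        # skip_grads[i] is the gradient for skips[i]; walk the encoder deepest-first
        for lvl, sg in zip(reversed(self.encoder), reversed(skip_grads)):
            g = lvl.pool.backward(g)
            g = g + sg
            for b in reversed(lvl.blocks):
                g = b.backward(g)
        self.conv_in.backward(g)

    def predict_probs(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Per-voxel class probabilities ``(out_classes, D, H, W)`` (softmax)."""
        z = self.forward_logits(x, training)
        z = z - z.max(axis=0, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=0, keepdims=True)


def build_network(config: NetworkConfig, seed: int = 0) -> RatLesNetV2:
    """Instantiate the architecture for a configuration."""
    return RatLesNetV2(config, seed=seed)


# ---------------------------------------------------------------------------
# static analyses


def count_parameters(model: RatLesNetV2) -> int:
    """Exact number of trainable scalars (conv kernels, biases, BN affine)."""
    return int(sum(p.value.size for p in model.parameters()))


def _block_kernels(config: NetworkConfig) -> list[int]:
    if config.block_type == "resnet":
        return [3, 3]
    return [3, 3, 1]


def _back_conv(s: set[int], k: int) -> set[int]:
    r = (k - 1) // 2
    return {i + d for i in s for d in range(-r, r + 1)}


def _back_block(s: set[int], config: NetworkConfig) -> set[int]:
    for k in _block_kernels(config):
        s = _back_conv(s, k)
    return s


def _back_pool(s: set[int]) -> set[int]:
    return {2 * i + j for i in s for j in (0, 1)}


def _back_up(s: set[int]) -> set[int]:
    # cell-centered 2x upsampling: output o reads floor(o/2 - 0.25) and +1
    out = set()
    for o in s:
        i0 = (o - 1) // 2 if o % 2 else o // 2 - 1
        out |= {i0, i0 + 1}
    return out


def _input_support(config: NetworkConfig, out_index: int) -> set[int]:
    """Indices of the (1D) input axis that influence one output index."""

    def through_encoder_prefix(s: set[int], level: int) -> set[int]:
        # backward from the skip tensor at `level` (output of that level's
        # blocks) down to the input: blocks_level, pool below, ..., blocks_0,
        # and finally the initial lifting convolution.
        for l in range(level, -1, -1):
            for _ in range(config.blocks_per_stage):
                s = _back_block(s, config)
            if l > 0:
                s = _back_pool(s)
        return _back_conv(s, 3)

    s = {out_index}  # head conv is 1^3: no growth
    support: set[int] = set()
    # decoder, walked backward from the full-resolution end: stage at
    # resolution level 0 first, then deeper stages
    for level in range(config.levels):
        for _ in range(config.blocks_per_stage):
            s = _back_block(s, config)
        # bottleneck is 1^3: no growth; the concat joins the skip branch here
        support |= through_encoder_prefix(set(s), level)
        s = _back_up(s)
    # s is now at the bridge output
    for _ in range(config.blocks_per_stage):
        s = _back_block(s, config)
    # encoder backward from the bridge input: pool, blocks, ... to the input
    for l in range(config.levels - 1, -1, -1):
        s = _back_pool(s)
        for _ in range(config.blocks_per_stage):
            s = _back_block(s, config)
        # pools between shallower levels are handled by the next iteration's
        # _back_pool call; level 0 connects straight to the lifting conv
    support |= _back_conv(s, 3)
    return support


def receptive_field(model: RatLesNetV2 | NetworkConfig) -> tuple[int, int, int]:
    """Theoretical receptive-field edge length per spatial axis.

    Computed by exact dependency propagation: starting from a single
    output voxel, each layer maps the current index set to the input
    indices it reads (convolution of kernel ``k`` dilates by
    ``(k-1)/2`` on each side, pooling doubles indices, upsampling
    halves them, branch joins take the union).  The extent is maximized
    over output positions to absorb the parity dependence introduced by
    upsampling.  All kernels are cubic, so the three axes agree.
    """
    config = model.config if isinstance(model, RatLesNetV2) else model
    best = 0
    for out_index in range(2**config.levels):
        support = _input_support(config, out_index)
        best = max(best, max(support) - min(support) + 1)
    return (best, best, best)


def match_parameters(
    variant: NetworkConfig, reference: RatLesNetV2, max_width: int = 96
) -> NetworkConfig:
    """Adjust a variant's free width knob to match a reference's parameter count.

    For ``densenet`` variants the growth rate is scanned; otherwise the
    encoder width is scanned (the decoder width follows as twice the
    encoder width).  Returns the closest-count configuration; the
    residual mismatch is available by re-counting.
    """
    target = count_parameters(reference)
    best_cfg, best_err = variant, None
    knob = "growth_rate" if variant.block_type == "densenet" else "encoder_width"
    for width in range(1, max_width + 1):
        fields = asdict(variant)
        fields[knob] = width
        if knob == "encoder_width":
            fields["decoder_width"] = 2 * width
        try:
            cfg = NetworkConfig(**fields)
        except InvalidConfigError:
            continue
        err = abs(count_parameters(build_network(cfg)) - target)
        if best_err is None or err < best_err:
            best_cfg, best_err = cfg, err
    return best_cfg
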