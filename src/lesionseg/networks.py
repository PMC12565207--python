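"""Declarative network specs and the two segmentation architectures.

``EfficientNetUNet3D`` is an inverted-bottleneck encoder–decoder: a 3x3x3
stem, four stride-2 depthwise MBConv3D encoder stages, an MBConv3D
bottleneck, and four decoder stages of trilinear 2x upsampling, a 1x1x1
channel-mapping convolution, skip concatenation and an MBConv3D refinement
block with spatial dropout.  ``UNet3DBaseline`` is the classic double-conv
U-Net with max pooling and transposed-convolution upsampling.  Both end in a
1x1x1 convolution and a sigmoid, producing voxel-wise lesion probabilities.

Convolutions followed by batch normalization carry no bias term; the only
biased convolution is the 1x1x1 head.  Parameter counts quoted anywhere in
the docs follow from that convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MultiModalVolume
from .nn.layers import (
    EVAL,
    BatchNorm3d,
    Conv3d,
    ConvTranspose3d,
    DoubleConv3d,
    Layer,
    MaxPool3d,
    MBConv3d,
    Mode,
    ReLU,
    Sequential,
    Sigmoid,
    SpatialDropout3d,
    Swish,
    walk_layers,
)

VARIANTS = ("efficientnet3d_unet", "unet3d_baseline")


@dataclass(frozen=True)
class MBConvSpec:
    """Declarative description of one MBConv3D block."""

    in_channels: int
    out_channels: int
    stride: int = 1
    expansion_factor: int = 1

    def __post_init__(self) -> None:
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.expansion_factor < 1:
            raise ValueError("expansion factor must be >= 1")

    @property
    def use_residual(self) -> bool:
        return self.stride == 1 and self.in_channels == self.out_channels


def build_mbconv3d(spec: MBConvSpec, rng: np.random.Generator | None = None) -> MBConv3d:
    """Instantiate an MBConv3D block (expansion -> depthwise 3x3x3 -> projection)."""
    return MBConv3d(
        spec.in_channels,
        spec.out_channels,
        stride=spec.stride,
        expansion=spec.expansion_factor,
        rng=rng or np.random.default_rng(0),
    )


@dataclass(frozen=True)
class NetworkSpec:
    """Channel ladder and regularization of either architecture.

    The default EfficientNet3D-UNet ladder is stem 32, encoder
    [32, 48, 64, 96] (stride-2 depthwise stages), bottleneck 256 and decoder
    [160, 96, 64, 48] at expansion factor 1; the baseline follows the classic
    [64, 128, 256, 512] double-conv ladder with a 512-channel bottleneck.
    """

    variant: str = "efficientnet3d_unet"
    stem_channels: int = 32
    encoder_channels: tuple[int, int, int, int] = (32, 48, 64, 96)
    bottleneck_channels: int = 256
    decoder_channels: tuple[int, int, int, int] = (160, 96, 64, 48)
    dropout_rate: float = 0.25
    expansion_factor: int = 1
    in_channels: int = 3
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if len(self.encoder_channels) != 4 or len(self.decoder_channels) != 4:
            raise ValueError("encoder/decoder ladders must have 4 stages")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @classmethod
    def efficientnet_default(cls) -> "NetworkSpec":
        return cls()

    @classmethod
    def baseline_default(cls) -> "NetworkSpec":
        return cls(
            variant="unet3d_baseline",
            stem_channels=32,
            encoder_channels=(64, 128, 256, 512),
            bottleneck_channels=512,
            decoder_channels=(256, 128, 64, 32),
            dropout_rate=0.2,
        )

    @classmethod
    def baseline_text_341(cls) -> "NetworkSpec":
        """Alternate baseline reading: a 256-channel double-conv bottleneck."""
        return cls(
            variant="unet3d_baseline",
            stem_channels=32,
            encoder_channels=(64, 128, 256, 512),
            bottleneck_channels=256,
            decoder_channels=(256, 128, 64, 32),
            dropout_rate=0.2,
        )

    @classmethod
    def tiny(cls, variant: str = "efficientnet3d_unet") -> "NetworkSpec":
        """Reduced-width ladder for CPU-scale studies and tests."""
        if variant == "efficientnet3d_unet":
            return cls(stem_channels=8, encoder_channels=(8, 12, 16, 24),
                       bottleneck_channels=32, decoder_channels=(24, 16, 12, 8))
        return cls(variant="unet3d_baseline", stem_channels=8,
                   encoder_channels=(8, 12, 16, 24), bottleneck_channels=24,
                   decoder_channels=(24, 16, 12, 8), dropout_rate=0.2)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "stem_channels": self.stem_channels,
            "encoder_channels": list(self.encoder_channels),
            "bottleneck_channels": self.bottleneck_channels,
            "decoder_channels": list(self.decoder_channels),
            "dropout_rate": self.dropout_rate,
            "expansion_factor": self.expansion_factor,
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        d["encoder_channels"] = tuple(d["encoder_channels"])
        d["decoder_channels"] = tuple(d["decoder_channels"])
        return cls(**d)


class _SegmentationModel(Layer):
    """Shared plumbing: spatial contract, parameter counting, state dicts."""

    spec: NetworkSpec
    divisor = 16  # four stride-2 stages

    def _check_spatial(self, x: np.ndarray) -> None:
        spatial = x.shape[2:]
        bad = [s for s in spatial if s % self.divisor]
        if bad:
            raise ValueError(
                f"spatial dims {spatial} must be divisible by {self.divisor} "
                "(four stride-2 stages)"
            )

    def batchnorms(self):
        return [l for l in walk_layers(self) if isinstance(l, BatchNorm3d)]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.data for i, p in enumerate(self.params())}
        for i, bn in enumerate(self.batchnorms()):
            state[f"bn_{i}_mean"] = bn.running_mean
            state[f"bn_{i}_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            arr = np.asarray(state[f"param_{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"param_{i}: shape {arr.shape} != {p.data.shape}")
            p.data[...] = arr.astype(p.data.dtype)
        for i, bn in enumerate(self.batchnorms()):
            bn.running_mean = np.asarray(state[f"bn_{i}_mean"], dtype=np.float64).copy()
            bn.running_var = np.asarray(state[f"bn_{i}_var"], dtype=np.float64).copy()


class EfficientNetUNet3D(_SegmentationModel):
    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        if spec.variant != "efficientnet3d_unet":
            raise ValueError(f"spec variant is {spec.variant!r}")
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = spec
        self.stem = Sequential(
            Conv3d(ch.in_channels, ch.stem_channels, k=3, rng=rng, dtype=dtype),
            BatchNorm3d(ch.stem_channels, dtype=dtype), Swish(),
        )
        enc_in = [ch.stem_channels] + list(ch.encoder_channels[:-1])
        self.encoders = [
            MBConv3d(cin, cout, stride=2, expansion=ch.expansion_factor, rng=rng, dtype=dtype)
            for cin, cout in zip(enc_in, ch.encoder_channels)
        ]
        self.bottleneck = MBConv3d(
            ch.encoder_channels[-1], ch.bottleneck_channels,
            expansion=ch.expansion_factor, rng=rng, dtype=dtype,
        )
        # skips, deep to shallow: enc3 out, enc2 out, enc1 out, stem out
        skip_ch = [ch.encoder_channels[2], ch.encoder_channels[1],
                   ch.encoder_channels[0], ch.stem_channels]
        dec_in = [ch.bottleneck_channels] + list(ch.decoder_channels[:-1])
        from .nn.layers import TrilinearUpsample2x

        self.ups = [TrilinearUpsample2x() for _ in range(4)]
        self.pre_convs = [
            Conv3d(cin, cout, k=1, rng=rng, dtype=dtype)
            for cin, cout in zip(dec_in, ch.decoder_channels)
        ]
        self.dec_blocks = [
            MBConv3d(cout + sk, cout, expansion=ch.expansion_factor, rng=rng, dtype=dtype)
            for cout, sk in zip(ch.decoder_channels, skip_ch)
        ]
        self.dropouts = [SpatialDropout3d(ch.dropout_rate) for _ in range(4)]
        self.head = Conv3d(ch.decoder_channels[-1], ch.out_channels, k=1,
                           bias=True, rng=rng, dtype=dtype)
        self.sigmoid = Sigmoid()

    def children(self):
        return ([self.stem] + self.encoders + [self.bottleneck] + self.ups
                + self.pre_convs + self.dec_blocks + self.dropouts
                + [self.head, self.sigmoid])

    def params(self):
        for layer in self.children():
            yield from layer.params()

    def forward(self, x, mode: Mode = EVAL):
        self._check_spatial(x)
        s = self.stem.forward(x, mode)
        enc_outs = [s]
        h = s
        for block in self.encoders:
            h = block.forward(h, mode)
            enc_outs.append(h)
        h = self.bottleneck.forward(h, mode)
        skips = [enc_outs[3], enc_outs[2], enc_outs[1], enc_outs[0]]
        self._split = []
        for up, pre, block, drop, skip in zip(
            self.ups, self.pre_convs, self.dec_blocks, self.dropouts, skips
        ):
            h = up.forward(h, mode)
            h = pre.forward(h, mode)
            self._split.append(h.shape[1])
            h = np.concatenate([h, skip], axis=1)
            h = block.forward(h, mode)
            h = drop.forward(h, mode)
        logits = self.head.forward(h, mode)
        return self.sigmoid.forward(logits, mode)

    def backward(self, gy):
        g = self.sigmoid.backward(gy)
        g = self.head.backward(g)
        skip_grads = []
        for up, pre, block, drop, split in zip(
            reversed(self.ups), reversed(self.pre_convs),
            reversed(self.dec_blocks), reversed(self.dropouts),
            reversed(self._split),
        ):
            g = drop.backward(g)
            g = block.backward(g)
            skip_grads.append(g[:, split:])
            g = pre.backward(np.ascontiguousarray(g[:, :split]))
            g = up.backward(g)
        # skip_grads order (by append): [stem, enc1, enc2, enc3] outputs
        g = self.bottleneck.backward(g)
        for i, block in enumerate(reversed(self.encoders)):
            g = block.backward(g)
            g = g + skip_grads[3 - i]  # enc3, enc2, enc1, then stem
        return self.stem.backward(g)


class UNet3DBaseline(_SegmentationModel):
    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        if spec.variant != "unet3d_baseline":
            raise ValueError(f"spec variant is {spec.variant!r}")
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = spec
        self.stem = Sequential(
            Conv3d(ch.in_channels, ch.stem_channels, k=3, rng=rng, dtype=dtype),
            BatchNorm3d(ch.stem_channels, dtype=dtype), ReLU(),
        )
        enc_in = [ch.stem_channels] + list(ch.encoder_channels[:-1])
        self.encoders = [
            DoubleConv3d(cin, cout, rng=rng, dtype=dtype)
            for cin, cout in zip(enc_in, ch.encoder_channels)
        ]
        self.pools = [MaxPool3d() for _ in range(4)]
        self.bottleneck = DoubleConv3d(
            ch.encoder_channels[-1], ch.bottleneck_channels, rng=rng, dtype=dtype
        )
        skip_ch = [ch.encoder_channels[3], ch.encoder_channels[2],
                   ch.encoder_channels[1], ch.encoder_channels[0]]
        dec_in = [ch.bottleneck_channels] + list(ch.decoder_channels[:-1])
        self.upconvs = [
            ConvTranspose3d(cin, cout, rng=rng, dtype=dtype)
            for cin, cout in zip(dec_in, ch.decoder_channels)
        ]
        self.dec_blocks = [
            DoubleConv3d(cout + sk, cout, rng=rng, dtype=dtype)
            for cout, sk in zip(ch.decoder_channels, skip_ch)
        ]
        self.dropouts = [SpatialDropout3d(ch.dropout_rate) for _ in range(4)]
        self.head = Conv3d(ch.decoder_channels[-1], ch.out_channels, k=1,
                           bias=True, rng=rng, dtype=dtype)
        self.sigmoid = Sigmoid()

    def children(self):
        return ([self.stem] + self.encoders + self.pools + [self.bottleneck]
                + self.upconvs + self.dec_blocks + self.dropouts
                + [self.head, self.sigmoid])

    def params(self):
        for layer in self.children():
            yield from layer.params()

    def forward(self, x, mode: Mode = EVAL):
        self._check_spatial(x)
        h = self.stem.forward(x, mode)
        skips = []
        for block, pool in zip(self.encoders, self.pools):
            h = block.forward(h, mode)
            skips.append(h)
            h = pool.forward(h, mode)
        h = self.bottleneck.forward(h, mode)
        self._split = []
        for up, block, drop, skip in zip(
            self.upconvs, self.dec_blocks, self.dropouts, reversed(skips)
        ):
            h = up.forward(h, mode)
            self._split.append(h.shape[1])
            h = np.concatenate([h, skip], axis=1)
            h = block.forward(h, mode)
            h = drop.forward(h, mode)
        logits = self.head.forward(h, mode)
        return self.sigmoid.forward(logits, mode)

    def backward(self, gy):
        g = self.sigmoid.backward(gy)
        g = self.head.backward(g)
        skip_grads = []
        for up, block, drop, split in zip(
            reversed(self.upconvs), reversed(self.dec_blocks),
            reversed(self.dropouts), reversed(self._split),
        ):
            g = drop.backward(g)
            g = block.backward(g)
            skip_grads.append(g[:, split:])  # deepest last
            g = up.backward(np.ascontiguousarray(g[:, :split]))
        g = self.bottleneck.backward(g)
        # skip_grads appended shallow-first: [enc1, enc2, enc3, enc4] skips
        for pool, block, skip_grad in zip(
            reversed(self.pools), reversed(self.encoders), reversed(skip_grads)
        ):
            g = pool.backward(g)
            g = g + skip_grad
            g = block.backward(g)
        return self.stem.backward(g)


def build_network(spec: NetworkSpec, seed: int = 0, dtype=np.float32) -> _SegmentationModel:
    """Construct either architecture from its spec with seed-deterministic init."""
    if spec.variant == "efficientnet3d_unet":
        return EfficientNetUNet3D(spec, seed=seed, dtype=dtype)
    return UNet3DBaseline(spec, seed=seed, dtype=dtype)


def count_trainable_parameters(network: Layer) -> int:
    """Sum of all trainable tensor sizes (batch-norm affine terms included)."""
    return int(sum(p.size for p in network.params()))


@dataclass(frozen=True)
class PredictionVolume:
    """Voxel-wise lesion probabilities aligned to the input volume."""

    probs: np.ndarray
    spacing: tuple[float, float, float]


def predict_patch(network: _SegmentationModel, patch_image: np.ndarray,
                  mode: Mode = EVAL) -> np.ndarray:
    """Probability map for one ``[3, s, s, s]`` patch (eval mode by default)."""
    x = np.asarray(patch_image, dtype=np.float32)[None]
    return network.forward(x, mode)[0, 0]


def sliding_window_predict(
    network: _SegmentationModel,
    volume: MultiModalVolume,
    patch_size: int = 64,
    overlap: float = 0.5,
    mode: Mode = EVAL,
) -> PredictionVolume:
    """Tile the volume with overlapping windows and average their probabilities.

    The volume is zero-padded so every axis admits at least one full window
    and windows at stride ``patch_size * (1 - overlap)`` cover it completely;
    each voxel's probability is the uniform mean over the windows containing
    it, and the padding is cropped away at the end.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    stride = max(1, int(round(patch_size * (1.0 - overlap))))
    x = np.asarray(volume.channels, dtype=np.float32)
    spatial = x.shape[1:]
    padded = []
    for s in spatial:
        if s <= patch_size:
            padded.append(patch_size)
        else:
            padded.append(patch_size + int(np.ceil((s - patch_size) / stride)) * stride)
    pad = [(0, ps - s) for s, ps in zip(spatial, padded)]
    xp = np.pad(x, [(0, 0)] + pad)
    acc = np.zeros(padded, dtype=np.float64)
    weight = np.zeros(padded, dtype=np.float64)
    starts = [range(0, ps - patch_size + 1, stride) for ps in padded]
    for d0 in starts[0]:
        for h0 in starts[1]:
            for w0 in starts[2]:
                sl = (slice(d0, d0 + patch_size), slice(h0, h0 + patch_size),
                      slice(w0, w0 + patch_size))
                probs = network.forward(xp[(slice(None),) + sl][None], mode)[0, 0]
                acc[sl] += probs
                weight[sl] += 1.0
    probs = acc / weight
    crop = tuple(slice(0, s) for s in spatial)
    return PredictionVolume(probs=probs[crop], spacing=volume.spacing)
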