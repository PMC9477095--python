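"""The three model components and their forward contracts.

* :class:`ReconstructionNet` (R) — multi-branch encoder, converter
  (batch-norm stage + residual latent stage), single decoder.  Maps the
  source-modality slices, conditioned on the target modality's mask
  vector, to the target-modality slice and exposes its decoder feature
  maps for the feature-guidance loss.
* :class:`AuxiliaryNet` (P) — the same architecture with the branches
  merged into one: an autoencoder trained on the target modality only,
  whose decoder features act as the teacher signal for R's decoder.
* :class:`Discriminator` (D) — a PatchGAN conditioned on the mask
  vector, emitting a 2D patch-score map (logits; probabilities are formed
  in the loss layer).

Architecture defaults: each encoder branch is a 7x7 stride-1 convolution
followed by two 3x3 stride-2 convolutions (channels c, 2c, 4c); the
converter applies batch normalization to the concatenated branch+mask
features, fuses them to 4c with a 1x1 convolution, and runs six residual
blocks of the form Conv-BN-ReLU-BN; the decoder is two 3x3 stride-2
transposed convolutions and a 7x7 tanh output convolution — so the
decoder has three layers and the feature stack has length three.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .image_io import ImageSlice
from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    LeakyReLU,
    Module,
    ReLU,
    ResidualBlock,
    Sequential,
    Tanh,
)

__all__ = [
    "NetworkConfig",
    "MaskVector",
    "FeatureStack",
    "ReconstructionNet",
    "AuxiliaryNet",
    "Discriminator",
    "forward_reconstruction",
    "forward_auxiliary",
    "forward_discriminator",
    "count_parameters",
]


@dataclasses.dataclass(frozen=True)
class NetworkConfig:
    n_input_branches: int = 2
    base_channels: int = 32
    n_residual_blocks: int = 6
    n_encoder_convs_per_branch: int = 3
    n_decoder_layers: int = 3
    patch_receptive_field: int = 70
    n_modalities_total: int = 3

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, int) and v <= 0:
                raise ValueError(f"{f.name} must be positive")


@dataclasses.dataclass
class MaskVector:
    """One spatially constant plane per modality; exactly one plane is hot."""

    target_index: int
    n_modalities: int
    height: int
    width: int

    def __post_init__(self):
        if not 0 <= self.target_index < self.n_modalities:
            raise ValueError("target_index out of range")

    def planes(self, height: int | None = None, width: int | None = None) -> np.ndarray:
        """(n_modalities, H, W) stack; broadcastable to any spatial size."""
        h = height if height is not None else self.height
        w = width if width is not None else self.width
        planes = np.zeros((self.n_modalities, h, w), dtype=np.float32)
        planes[self.target_index] = 1.0
        return planes


@dataclasses.dataclass
class FeatureStack:
    """Ordered per-decoder-layer feature maps (each C x H x W per sample)."""

    features: list[np.ndarray]
    source: str  # "De_R" or "De_P"

    def __len__(self):
        return len(self.features)

    def shapes(self):
        return [f.shape for f in self.features]


class _Decoder(Module):
    """Decoder with per-layer output capture for the feature stack."""

    def __init__(self, c: int, rng):
        self.layers = [
            Sequential(
                ConvTranspose2d(4 * c, 2 * c, 3, 2, 1, 1, rng=rng), BatchNorm2d(2 * c), ReLU()
            ),
            Sequential(
                ConvTranspose2d(2 * c, c, 3, 2, 1, 1, rng=rng), BatchNorm2d(c), ReLU()
            ),
            Sequential(Conv2d(c, 1, 7, 1, 3, rng=rng), Tanh()),
        ]

    def children(self):
        return self.layers

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        feats = []
        for layer in self.layers:
            x = layer.forward(x)
            feats.append(x)
        self._feats = feats
        return x

    def backward(self, dy, dfeats: list[np.ndarray] | None = None):
        """Backward with optional extra gradients injected at each layer output."""
        for i in reversed(range(len(self.layers))):
            if dfeats is not None and dfeats[i] is not None:
                dy = dy + dfeats[i]
            dy = self.layers[i].backward(dy)
        return dy


def _encoder_branch(c: int, rng) -> Sequential:
    return Sequential(
        Conv2d(1, c, 7, 1, 3, rng=rng),
        BatchNorm2d(c),
        ReLU(),
        Conv2d(c, 2 * c, 3, 2, 1, rng=rng),
        BatchNorm2d(2 * c),
        ReLU(),
        Conv2d(2 * c, 4 * c, 3, 2, 1, rng=rng),
        BatchNorm2d(4 * c),
        ReLU(),
    )


class ReconstructionNet(Module):
    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        c = config.base_channels
        self.branches = [_encoder_branch(c, rng) for _ in range(config.n_input_branches)]
        fused_in = 4 * c * config.n_input_branches + config.n_modalities_total
        self.converter = Sequential(
            BatchNorm2d(fused_in),
            Conv2d(fused_in, 4 * c, 1, 1, 0, rng=rng),
            *[ResidualBlock(4 * c, rng=rng) for _ in range(config.n_residual_blocks)],
        )
        self.decoder = _Decoder(c, rng)

    def children(self):
        return [*self.branches, self.converter, self.decoder]

    def params(self):
        out = []
        for child in self.children():
            out.extend(child.params())
        return out

    def encoder_params(self):
        out = []
        for b in self.branches:
            out.extend(b.params())
        return out

    def decoder_params(self):
        return self.decoder.params()

    def forward(self, sources: np.ndarray, mask_planes: np.ndarray):
        """sources: (n_branches, N, 1, H, W); mask_planes: (M, h, w) at any scale.

        Returns (output (N,1,H,W), list of per-layer decoder features).
        """
        if sources.shape[0] != len(self.branches):
            raise ValueError(
                f"got {sources.shape[0]} sources for {len(self.branches)} encoder branches"
            )
        encoded = [b.forward(sources[i]) for i, b in enumerate(self.branches)]
        n, _, fh, fw = encoded[0].shape
        m = np.broadcast_to(
            mask_planes[:, :1, :1] if mask_planes.shape[1:] != (fh, fw) else mask_planes,
            (mask_planes.shape[0], fh, fw),
        )
        m = np.broadcast_to(m[None], (n, *m.shape)).astype(np.float32)
        fused = np.concatenate([*encoded, m], axis=1)
        self._n_mask = mask_planes.shape[0]
        self._enc_channels = [e.shape[1] for e in encoded]
        latent = self.converter.forward(np.ascontiguousarray(fused))
        y = self.decoder.forward(latent)
        return y, list(self.decoder._feats)

    def backward(self, dy, dfeats=None):
        dlatent = self.decoder.backward(dy, dfeats)
        dfused = self.converter.backward(dlatent)
        # split channel gradient back to branches; mask gradient is discarded
        ofs = 0
        for b, ch in zip(self.branches, self._enc_channels):
            b.backward(np.ascontiguousarray(dfused[:, ofs : ofs + ch]))
            ofs += ch


class AuxiliaryNet(Module):
    """Single-branch autoencoder with the same converter/decoder structure."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        c = config.base_channels
        self.encoder = _encoder_branch(c, rng)
        self.converter = Sequential(
            BatchNorm2d(4 * c),
            Conv2d(4 * c, 4 * c, 1, 1, 0, rng=rng),
            *[ResidualBlock(4 * c, rng=rng) for _ in range(config.n_residual_blocks)],
        )
        self.decoder = _Decoder(c, rng)

    def children(self):
        return [self.encoder, self.converter, self.decoder]

    def params(self):
        out = []
        for child in self.children():
            out.extend(child.params())
        return out

    def forward(self, target: np.ndarray):
        """target: (N, 1, H, W) -> (reconstruction, decoder features, latent)."""
        latent = self.converter.forward(self.encoder.forward(target))
        y = self.decoder.forward(latent)
        return y, list(self.decoder._feats), latent

    def backward(self, dy, dfeats=None):
        dlatent = self.decoder.backward(dy, dfeats)
        self.encoder.backward(self.converter.backward(dlatent))


class Discriminator(Module):
    """70x70 PatchGAN over image + mask channels; outputs a logit patch map."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        c = config.base_channels
        ch_in = 1 + config.n_modalities_total
        self.body = Sequential(
            Conv2d(ch_in, c, 4, 2, 1, rng=rng),
            LeakyReLU(0.2),
            Conv2d(c, 2 * c, 4, 2, 1, rng=rng),
            BatchNorm2d(2 * c),
            LeakyReLU(0.2),
            Conv2d(2 * c, 4 * c, 4, 2, 1, rng=rng),
            BatchNorm2d(4 * c),
            LeakyReLU(0.2),
            Conv2d(4 * c, 8 * c, 4, 1, 1, rng=rng),
            BatchNorm2d(8 * c),
            LeakyReLU(0.2),
            Conv2d(8 * c, 1, 4, 1, 1, rng=rng),
        )

    def children(self):
        return [self.body]

    def params(self):
        return self.body.params()

    def forward(self, image: np.ndarray, mask_planes: np.ndarray):
        """image: (N, 1, H, W); mask_planes: (M, H, W) -> logit map (N, 1, h', w')."""
        n, _, h, w = image.shape
        if mask_planes.shape[1:] != (h, w):
            raise ValueError("mask planes must match the image spatial size")
        m = np.broadcast_to(mask_planes[None], (n, *mask_planes.shape)).astype(np.float32)
        x = np.ascontiguousarray(np.concatenate([image, m], axis=1))
        return self.body.forward(x)

    def backward(self, dy):
        dx = self.body.backward(dy)
        return dx[:, :1]  # image-channel gradient only


def forward_reconstruction(
    sources: list[ImageSlice], target_mask: MaskVector, net: ReconstructionNet
) -> tuple[ImageSlice, FeatureStack]:
    """Single-sample forward pass through R on normalized slices."""
    if len(sources) != net.config.n_input_branches:
        raise ValueError(
            f"{len(sources)} sources but network has {net.config.n_input_branches} branches"
        )
    shapes = {s.shape for s in sources}
    if len(shapes) != 1:
        raise ValueError("all sources must share one spatial size")
    for s in sources:
        if s.intensity_domain != "normalized":
            raise ValueError("sources must be normalized to [-1, 1]")
    x = np.stack([s.pixels[None, None].astype(np.float32) for s in sources])
    y, feats = net.forward(x, target_mask.planes())
    out = ImageSlice(
        pixels=y[0, 0],
        intensity_domain="normalized",
        modality_name=None,
        subject_id=sources[0].subject_id,
        slice_index=sources[0].slice_index,
    )
    return out, FeatureStack(features=[f[0] for f in feats], source="De_R")


def forward_auxiliary(target: ImageSlice, net: AuxiliaryNet):
    if target.intensity_domain != "normalized":
        raise ValueError("target must be normalized to [-1, 1]")
    y, feats, latent = net.forward(target.pixels[None, None].astype(np.float32))
    out = target.with_pixels(y[0, 0], "normalized")
    return out, FeatureStack(features=[f[0] for f in feats], source="De_P"), latent[0]


def forward_discriminator(image: ImageSlice, mask: MaskVector, net: Discriminator) -> np.ndarray:
    if image.intensity_domain != "normalized":
        raise ValueError("image must be normalized to [-1, 1]")
    logits = net.forward(image.pixels[None, None].astype(np.float32), mask.planes())
    return logits[0, 0]


def count_parameters(net: Module) -> int:
    return net.n_params()
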