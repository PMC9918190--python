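"""Network architectures: lid classifier, U-Net segmenter, VAE-GAN parts.

All models are resolution-agnostic convolutional networks built on the
package's own autodiff stack.  ``base_width`` scales every channel count, so
the same topologies run as width-reduced "toy" variants for CPU-scale
experiments (the default here) or wider for larger budgets.

* ``LidClassifier`` - a residual-block image classifier with a binary head
  (upper vs lower eyelid), a width-reduced take on the standard 18-layer
  residual topology.
* ``UNetSegmenter`` - an encoder of residual blocks (the 34-layer-residual
  family of backbones, width-reduced) with two decoders sharing it: a
  segmentation decoder with skip connections producing the per-pixel
  foreground probability, and a cascaded reconstruction decoder producing
  an estimate of the input image.  The reconstruction error gives the
  encoder an extra gradient signal for feature fidelity.
* ``MaskEncoder`` / ``MaskDecoder`` / ``Discriminator`` - the three parts of
  the VAE-GAN shape prior over tarsus masks.
"""

from __future__ import annotations

import numpy as np

from .nn import (
    Conv2d,
    GlobalAvgPool,
    Linear,
    Module,
    ResidualBlock,
    Sequential,
    Tensor,
    UpsampleConv,
    concat,
    crop2d,
)

__all__ = ["LidClassifier", "UNetSegmenter", "MaskEncoder", "MaskDecoder", "Discriminator"]


def _to_nchw(x) -> Tensor:
    """Accept (H,W), (N,H,W) or (N,1,H,W) arrays/tensors as NCHW tensors."""
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    elif arr.ndim != 4:
        raise ValueError(f"expected 2-4 dims, got {arr.ndim}")
    return Tensor(arr)


def _pad_to_multiple(arr: np.ndarray, m: int) -> np.ndarray:
    """Edge-pad the two trailing dims up to the next multiple of m."""
    H, W = arr.shape[-2:]
    ph, pw = (-H) % m, (-W) % m
    if ph == 0 and pw == 0:
        return arr
    pad = [(0, 0)] * (arr.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(arr, pad, mode="edge")


class LidClassifier(Module):
    """Residual conv-net with a binary (upper/lower) classification head."""

    def __init__(self, base_width: int = 8, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        w = base_width
        self.stem = Conv2d(1, w, 3, stride=2, rng=rng)
        self.blocks = Sequential(
            ResidualBlock(w, w, rng=rng),
            ResidualBlock(w, 2 * w, stride=2, rng=rng),
            ResidualBlock(2 * w, 2 * w, rng=rng),
            ResidualBlock(2 * w, 4 * w, stride=2, rng=rng),
        )
        self.pool = GlobalAvgPool()
        self.head = Linear(4 * w, 2, rng=rng)

    def forward(self, x) -> Tensor:
        """Return logits of shape (N, 2); column 0 = upper, 1 = lower."""
        # center intensities around 0 for better conditioning
        h = self.stem(_to_nchw(x) + (-0.5)).relu()
        return self.head(self.pool(self.blocks(h)))


class _SegDecoderStage(Module):
    def __init__(self, cin: int, cskip: int, cout: int, rng):
        self.up = UpsampleConv(cin, cout, rng=rng)
        self.fuse = Conv2d(cout + cskip, cout, 3, rng=rng)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        h = self.up(x).relu()
        if h.shape[2:] != skip.shape[2:]:
            h = crop2d(h, skip.shape[2], skip.shape[3])
        return self.fuse(concat([h, skip], axis=1)).relu()


class UNetSegmenter(Module):
    """U-Net with a residual encoder and two decoder heads.

    The segmentation decoder uses skip connections from the encoder stages;
    the reconstruction decoder is cascaded after the shared encoder without
    skips (so reconstruction cannot bypass the bottleneck).  Both heads end
    in a sigmoid: the first is the foreground probability map, the second an
    intensity image in [0, 1].
    """

    def __init__(self, base_width: int = 8, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        w = base_width
        self.stem = Conv2d(1, w, 3, rng=rng)
        self.enc1 = ResidualBlock(w, w, rng=rng)  # full resolution
        self.enc2 = ResidualBlock(w, 2 * w, stride=2, rng=rng)  # 1/2
        self.enc3 = ResidualBlock(2 * w, 4 * w, stride=2, rng=rng)  # 1/4
        self.bottleneck = ResidualBlock(4 * w, 4 * w, rng=rng)

        self.seg_up1 = _SegDecoderStage(4 * w, 2 * w, 2 * w, rng)
        self.seg_up2 = _SegDecoderStage(2 * w, w, w, rng)
        self.seg_head = Conv2d(w, 1, 1, pad=0, rng=rng)

        self.rec_up1 = UpsampleConv(4 * w, 2 * w, rng=rng)
        self.rec_up2 = UpsampleConv(2 * w, w, rng=rng)
        self.rec_head = Conv2d(w, 1, 1, pad=0, rng=rng)

    def forward(self, x) -> tuple[Tensor, Tensor]:
        """Return (seg_prob, reconstruction), both NCHW at the input size."""
        x = _to_nchw(x)
        N, C, H, W = x.shape
        padded = _pad_to_multiple(x.data, 4)
        x = Tensor(padded, requires_grad=x.requires_grad)
        e1 = self.enc1(self.stem(x).relu())
        e2 = self.enc2(e1)
        e3 = self.bottleneck(self.enc3(e2))

        s = self.seg_up1(e3, e2)
        s = self.seg_up2(s, e1)
        seg = self.seg_head(s).sigmoid()

        r = self.rec_up1(e3).relu()
        r = self.rec_up2(r).relu()
        rec = self.rec_head(r).sigmoid()
        if seg.shape[2:] != (H, W):
            seg = crop2d(seg, H, W)
            rec = crop2d(rec, H, W)
        return seg, rec


class MaskEncoder(Module):
    """Strided conv encoder of a binary mask into a Gaussian latent code."""

    def __init__(self, input_shape: tuple[int, int], latent_dim: int = 16,
                 base_width: int = 8, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        H, W = input_shape
        if H % 8 or W % 8:
            raise ValueError(f"mask encoder input ({H},{W}) must be divisible by 8")
        w = base_width
        self.input_shape = (H, W)
        self.latent_dim = latent_dim
        self.conv = Sequential(
            Conv2d(1, w, 3, stride=2, rng=rng),
            _LeakyWrap(),
            Conv2d(w, 2 * w, 3, stride=2, rng=rng),
            _LeakyWrap(),
            Conv2d(2 * w, 4 * w, 3, stride=2, rng=rng),
            _LeakyWrap(),
        )
        self.feat_dim = 4 * w * (H // 8) * (W // 8)
        self.fc = Linear(self.feat_dim, 2 * latent_dim, rng=rng)

    def forward(self, x) -> tuple[Tensor, Tensor]:
        x = _to_nchw(x)
        if x.shape[2:] != self.input_shape:
            raise ValueError(
                f"mask of spatial size {x.shape[2:]} does not match encoder input "
                f"{self.input_shape}"
            )
        h = self.conv(x)
        out = self.fc(h.reshape(x.shape[0], -1))
        mean = Tensor(out.data[:, : self.latent_dim], _parents=(out,))
        logvar = Tensor(out.data[:, self.latent_dim :], _parents=(out,))

        d = self.latent_dim

        def bwd_mean(g, out=out, d=d):
            full = np.zeros_like(out.data)
            full[:, :d] = g
            out._accum(full)

        def bwd_logvar(g, out=out, d=d):
            full = np.zeros_like(out.data)
            full[:, d:] = g
            out._accum(full)

        mean._backward = bwd_mean
        logvar._backward = bwd_logvar
        return mean, logvar


class _LeakyWrap(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(0.2)


class MaskDecoder(Module):
    """Decode a latent vector into a mask probability grid (the generator G)."""

    def __init__(self, output_shape: tuple[int, int], latent_dim: int = 16,
                 base_width: int = 8, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        H, W = output_shape
        if H % 8 or W % 8:
            raise ValueError(f"mask decoder output ({H},{W}) must be divisible by 8")
        w = base_width
        self.output_shape = (H, W)
        self.latent_dim = latent_dim
        self.w0 = 4 * w
        self.h8, self.w8 = H // 8, W // 8
        self.fc = Linear(latent_dim, self.w0 * self.h8 * self.w8, rng=rng)
        self.up = Sequential(
            UpsampleConv(4 * w, 2 * w, rng=rng), _ReluWrap(),
            UpsampleConv(2 * w, w, rng=rng), _ReluWrap(),
            UpsampleConv(w, w, rng=rng), _ReluWrap(),
        )
        self.head = Conv2d(w, 1, 1, pad=0, rng=rng)

    def forward(self, z) -> Tensor:
        if not isinstance(z, Tensor):
            z = Tensor(np.atleast_2d(np.asarray(z, dtype=np.float64)))
        if z.shape[-1] != self.latent_dim:
            raise ValueError(f"latent vector length {z.shape[-1]} != {self.latent_dim}")
        h = self.fc(z).relu().reshape(z.shape[0], self.w0, self.h8, self.w8)
        return self.head(self.up(h)).sigmoid()


class _ReluWrap(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Discriminator(Module):
    """Small strided conv classifier scoring how "real tarsus"-like a mask is."""

    def __init__(self, input_shape: tuple[int, int], base_width: int = 8,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        w = base_width
        self.input_shape = tuple(input_shape)
        self.conv = Sequential(
            Conv2d(1, w, 3, stride=2, rng=rng), _LeakyWrap(),
            Conv2d(w, 2 * w, 3, stride=2, rng=rng), _LeakyWrap(),
            Conv2d(2 * w, 4 * w, 3, stride=2, rng=rng), _LeakyWrap(),
        )
        self.pool = GlobalAvgPool()
        self.head = Linear(4 * w, 1, rng=rng)

    def forward(self, x) -> Tensor:
        """Return per-sample scores in (0, 1), shape (N, 1)."""
        x = _to_nchw(x)
        if x.shape[2:] != self.input_shape:
            raise ValueError(
                f"input spatial size {x.shape[2:]} does not match discriminator "
                f"input {self.input_shape}"
            )
        return self.head(self.pool(self.conv(x))).sigmoid()

    def freeze(self) -> "Discriminator":
        """Stop gradient accumulation into the discriminator's parameters."""
        for p in self.parameters():
            p.requires_grad = False
        return self
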