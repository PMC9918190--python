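"""VAE-GAN shape prior over tarsus masks.

The tarsal plate has a stereotyped shape: a smooth convex band whose height
differs between upper and lower eyelids.  This module learns that shape
distribution from expert (or synthetic ground-truth) binary masks and
exports the *discriminator* as a frozen shape critic for segmenter training.

The model is a variational autoencoder whose decoder doubles as a GAN
generator: the encoder maps a mask to a Gaussian latent code (mean, logvar),
the reparameterized code z = mean + exp(logvar/2) * eps is decoded back into
a mask probability grid, and a discriminator D learns to tell expert masks
("real") from decoded ones ("fake").  Training alternates three updates:

1. VAE step - per-pixel binary cross-entropy reconstruction + KL divergence
   to the standard normal prior (weight beta = 1), on encoder + decoder.
2. Discriminator step - logistic loss, real vs. decoded masks.
3. Generator step - non-saturating adversarial loss -log D(decoded), on the
   decoder.

Through this adversarial game D becomes sensitive to the specific shape of
the tarsus: it ranks intact band-shaped masks above noise or hole-punched
masks, which is exactly the signal the segmenter borrows as a shape
constraint.  After export, D's parameters are frozen: segmenter training
backpropagates *through* D into the predicted mask but never updates D.

Because upper and lower lids have distinct morphology, a separate prior per
lid side is trained and selected by the lid classifier at inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .models import Discriminator, MaskDecoder, MaskEncoder
from .nn import RMSprop, Tensor, exponential_lr

__all__ = [
    "LatentCode",
    "ShapePriorConfig",
    "ShapePriorParams",
    "kl_divergence",
    "reparameterize",
    "encode_mask",
    "decode_latent",
    "discriminate",
    "train_shape_prior",
]

LOGVAR_FLOOR = -10.0
LOGVAR_CEIL = 10.0


@dataclass(frozen=True)
class LatentCode:
    """Gaussian posterior over the latent shape space: N(mean, diag exp(logvar))."""

    mean: np.ndarray
    logvar: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=np.float64))
        object.__setattr__(self, "logvar", np.asarray(self.logvar, dtype=np.float64))
        if self.mean.shape != self.logvar.shape:
            raise ValueError("mean and logvar must share shape")
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.logvar))):
            raise ValueError("latent code entries must be finite")


@dataclass
class ShapePriorConfig:
    input_shape: tuple[int, int] = (64, 128)
    latent_dim: int = 16
    base_width: int = 8
    steps: int = 200
    batch_size: int = 8
    lr: float = 1e-3
    lr_gamma: float = 0.98
    seed: int = 0


@dataclass
class ShapePriorParams:
    """Trained encoder/decoder/discriminator parameters plus loss history."""

    encoder: MaskEncoder
    decoder: MaskDecoder
    discriminator: Discriminator
    config: ShapePriorConfig
    history: list[dict] = field(default_factory=list)

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim

    def frozen_discriminator(self) -> Discriminator:
        """The shape critic with gradient accumulation disabled."""
        return self.discriminator.freeze()

    # -- checkpointing -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "encoder.npz", **self.encoder.state_dict())
        np.savez(path / "decoder.npz", **self.decoder.state_dict())
        np.savez(path / "discriminator.npz", **self.discriminator.state_dict())
        meta = {
            "input_shape": list(self.config.input_shape),
            "latent_dim": self.config.latent_dim,
            "base_width": self.config.base_width,
            "steps": self.config.steps,
            "batch_size": self.config.batch_size,
            "lr": self.config.lr,
            "lr_gamma": self.config.lr_gamma,
            "seed": self.config.seed,
            "history": self.history,
        }
        (path / "config.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ShapePriorParams":
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        config = ShapePriorConfig(
            input_shape=tuple(meta["input_shape"]),
            latent_dim=meta["latent_dim"],
            base_width=meta["base_width"],
            steps=meta["steps"],
            batch_size=meta["batch_size"],
            lr=meta["lr"],
            lr_gamma=meta["lr_gamma"],
            seed=meta["seed"],
        )
        params = _build_parts(config)
        for part, fname in [
            (params.encoder, "encoder.npz"),
            (params.decoder, "decoder.npz"),
            (params.discriminator, "discriminator.npz"),
        ]:
            with np.load(path / fname) as data:
                part.load_state_dict(dict(data))
        params.history = meta["history"]
        return params


def _build_parts(config: ShapePriorConfig) -> ShapePriorParams:
    rng = np.random.default_rng([config.seed, 0x5AFE])
    enc = MaskEncoder(config.input_shape, config.latent_dim, config.base_width, rng)
    dec = MaskDecoder(config.input_shape, config.latent_dim, config.base_width, rng)
    disc = Discriminator(config.input_shape, config.base_width, rng)
    return ShapePriorParams(enc, dec, disc, config)


# ---------------------------------------------------------------------------
# core operations


def kl_divergence(code: LatentCode) -> float:
    """KL( N(mean, diag exp(logvar)) || N(0, I) ), summed over dimensions."""
    m, lv = code.mean, code.logvar
    return float(-0.5 * np.sum(1.0 + lv - m**2 - np.exp(lv)))


def reparameterize(code: LatentCode, rng: np.random.Generator) -> np.ndarray:
    """Sample z = mean + exp(logvar/2) * eps with eps ~ N(0, I)."""
    lv = np.clip(code.logvar, LOGVAR_FLOOR, LOGVAR_CEIL)
    eps = rng.standard_normal(code.mean.shape)
    return code.mean + np.exp(lv / 2.0) * eps


def encode_mask(mask: np.ndarray, params: ShapePriorParams) -> LatentCode:
    """Deterministically encode one binary mask into its latent code."""
    mean, logvar = params.encoder(np.asarray(mask, dtype=np.float64))
    lv = np.clip(logvar.data[0], LOGVAR_FLOOR, LOGVAR_CEIL)
    return LatentCode(mean=mean.data[0], logvar=lv)


def decode_latent(z: np.ndarray, params: ShapePriorParams) -> np.ndarray:
    """Decode a latent vector into a mask probability grid in (0, 1)."""
    out = params.decoder(np.asarray(z, dtype=np.float64))
    return out.data[0, 0]


def discriminate(mask_prob: np.ndarray, params: ShapePriorParams) -> float:
    """Score a mask (probability grid in [0, 1]) for tarsus-shape realism."""
    grid = np.asarray(mask_prob, dtype=np.float64)
    if grid.min() < 0 or grid.max() > 1:
        raise ValueError("discriminator input must lie in [0, 1]")
    return float(params.discriminator(grid).data[0, 0])


# ---------------------------------------------------------------------------
# training


def _bce(p: Tensor, target: np.ndarray) -> Tensor:
    pc = p.clamp(1e-7, 1.0 - 1e-7)
    t = Tensor(target)
    return -(t * pc.log() + (1.0 - t) * (1.0 - pc).log()).sum()


def _kl_tensor(mean: Tensor, logvar: Tensor) -> Tensor:
    lv = logvar.clamp(LOGVAR_FLOOR, LOGVAR_CEIL)
    return (-0.5) * (1.0 + lv - mean**2 - lv.exp()).sum()


def train_shape_prior(
    gt_masks: Sequence[np.ndarray],
    config: ShapePriorConfig | None = None,
) -> ShapePriorParams:
    """Train the VAE-GAN on ground-truth tarsus masks.

    Requires at least 8 masks, all at ``config.input_shape``.  Returns the
    trained parts with a per-step loss history (VAE reconstruction, KL,
    discriminator loss, generator adversarial loss).  Fully deterministic
    given ``config.seed``.
    """
    config = config or ShapePriorConfig()
    masks = [np.asarray(m, dtype=np.float64) for m in gt_masks]
    if len(masks) == 0:
        raise ValueError("training set of masks is empty")
    if len(masks) < 8:
        raise ValueError(f"need >= 8 masks to train the shape prior, got {len(masks)}")
    for m in masks:
        if m.shape != tuple(config.input_shape):
            raise ValueError(
                f"mask shape {m.shape} does not match configured input "
                f"{config.input_shape}"
            )
    stack = np.stack(masks)[:, None]  # (M,1,H,W)

    params = _build_parts(config)
    enc, dec, disc = params.encoder, params.decoder, params.discriminator
    rng = np.random.default_rng([config.seed, 0x7EA1])
    vae_params = enc.parameters() + dec.parameters()
    opt_vae = RMSprop(vae_params, lr=config.lr)
    opt_disc = RMSprop(disc.parameters(), lr=config.lr)
    opt_gen = RMSprop(dec.parameters(), lr=config.lr)

    n = stack.shape[0]
    steps_per_epoch = max(1, n // config.batch_size)
    for step in range(config.steps):
        epoch = step // steps_per_epoch
        lr = exponential_lr(epoch, config.lr, config.lr_gamma)
        opt_vae.lr = opt_disc.lr = opt_gen.lr = lr
        idx = rng.choice(n, size=min(config.batch_size, n), replace=False)
        real = stack[idx]
        b = real.shape[0]
        npix = real[0].size

        # (a) VAE step: reconstruction BCE + KL
        x = Tensor(real)
        mean, logvar = enc(x)
        eps = rng.standard_normal(mean.shape)
        z = mean + (logvar.clamp(LOGVAR_FLOOR, LOGVAR_CEIL) * 0.5).exp() * Tensor(eps)
        recon = dec(z)
        loss_rec = _bce(recon, real) * (1.0 / (b * npix))
        loss_kl = _kl_tensor(mean, logvar) * (1.0 / (b * npix))
        loss_vae = loss_rec + loss_kl
        opt_vae.zero_grad()
        loss_vae.backward()
        opt_vae.step()

        # (b) discriminator step on real vs decoded ("fake") masks
        z_prior = rng.standard_normal((b, config.latent_dim))
        fake = dec(Tensor(z_prior)).detach()
        d_real = disc(Tensor(real)).clamp(1e-7, 1 - 1e-7)
        d_fake = disc(fake).clamp(1e-7, 1 - 1e-7)
        loss_d = (-(d_real.log()) - (1.0 - d_fake).log()).mean()
        opt_disc.zero_grad()
        loss_d.backward()
        opt_disc.step()

        # (c) generator adversarial step (non-saturating): -log D(G(z))
        fake2 = dec(Tensor(z_prior))
        d_fake2 = disc(fake2).clamp(1e-7, 1 - 1e-7)
        loss_g = -(d_fake2.log()).mean()
        opt_gen.zero_grad()
        disc.zero_grad()
        loss_g.backward()
        opt_gen.step()  # decoder only; discriminator untouched

        params.history.append(
            {
                "step": step,
                "lr": lr,
                "vae_recon": float(loss_rec.item()),
                "kl": float(loss_kl.item()),
                "disc": float(loss_d.item()),
                "gen": float(loss_g.item()),
            }
        )
    return params
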