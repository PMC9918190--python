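"""Lid classifier and U-Net segmenter training under the composite loss.

The segmenter is trained to minimise

    Loss = lambda1 * RL(I, I_re) + lambda2 * DcL(I_seg, I_gt) + lambda3 * DL(I_seg)

where RL is the mean absolute reconstruction error between the input image
and the cascaded decoder's output, DcL is the soft Dice loss between the
predicted probability map and the ground-truth mask, and DL = -log D(I_seg)
is the shape-constraint term scored by the frozen VAE-GAN discriminator.
Default weights (0.1, 1.0, 0.05) let the Dice term dominate while the
reconstruction and shape terms regularise the encoder and the predicted
geometry respectively.

Training uses an exponentially decayed learning rate starting at 0.001 and
a momentum-free adaptive optimizer; every run is deterministic given its
seed.  The returned parameters are the best-validation checkpoint
(cross-entropy accuracy for the classifier, Dice for the segmenter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .image import LID_SIDES
from .models import Discriminator, LidClassifier, UNetSegmenter
from .nn import Adam, RMSprop, Tensor, exponential_lr
from .synthetic import SyntheticSample

__all__ = [
    "LossWeights",
    "TrainConfig",
    "SegOutput",
    "reconstruction_loss",
    "dice_loss",
    "discriminator_shape_loss",
    "combined_loss",
    "lr_schedule",
    "classify_lid",
    "segment",
    "train_classifier",
    "train_segmenter",
]

DICE_EPS = 1e-6
_D_CLAMP = (1e-7, 1.0 - 1e-7)


@dataclass(frozen=True)
class LossWeights:
    """Weights (lambda1, lambda2, lambda3) of the RL, DcL and DL terms."""

    lambda1: float = 0.1
    lambda2: float = 1.0
    lambda3: float = 0.05

    def __post_init__(self) -> None:
        for name, v in (("lambda1", self.lambda1), ("lambda2", self.lambda2),
                        ("lambda3", self.lambda3)):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class TrainConfig:
    initial_lr: float = 1e-3
    lr_gamma: float = 0.98
    epochs: int = 5
    batch_size: int = 8
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    base_width: int = 8
    optimizer: str = "adam"  # or "rmsprop"

    def __post_init__(self) -> None:
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if not 0 < self.lr_gamma <= 1:
            raise ValueError("lr_gamma must lie in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class SegOutput:
    """Per-pixel foreground probabilities plus the reconstructed input."""

    seg_prob: np.ndarray
    reconstruction: np.ndarray

    def __post_init__(self) -> None:
        self.seg_prob = np.asarray(self.seg_prob, dtype=np.float64)
        self.reconstruction = np.asarray(self.reconstruction, dtype=np.float64)
        if self.seg_prob.shape != self.reconstruction.shape:
            raise ValueError("seg_prob and reconstruction must share shape")


# ---------------------------------------------------------------------------
# loss terms (accept numpy arrays or autograd tensors)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _same_shape(a: Tensor, b: Tensor, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what}: shape mismatch {a.shape} vs {b.shape}")


def _mae(image, reconstruction) -> Tensor:
    i, r = _as_tensor(image), _as_tensor(reconstruction)
    _same_shape(i, r, "reconstruction_loss")
    d = i - r
    return (((d * d) + 1e-12) ** 0.5).mean()


def dice_loss(seg_prob, gt_mask):
    """Soft Dice loss: 1 - (2 sum(p*g) + eps) / (sum(p) + sum(g) + eps)."""
    p, g = _as_tensor(seg_prob), _as_tensor(gt_mask)
    _same_shape(p, g, "dice_loss")
    inter = (p * g).sum()
    denom = p.sum() + g.sum()
    return 1.0 - (2.0 * inter + DICE_EPS) / (denom + DICE_EPS)


def discriminator_shape_loss(seg_prob, discriminator: Discriminator):
    """DL: -log D(seg_prob) under the frozen shape-prior discriminator."""
    p = _as_tensor(seg_prob)
    score = discriminator(p if p.ndim == 4 else p.reshape(1, 1, *p.shape))
    return -(score.clamp(*_D_CLAMP).log()).mean()


def combined_loss(image, out: SegOutput | tuple, gt_mask, weights: LossWeights,
                  discriminator: Discriminator | None = None):
    """The weighted composite loss; the DL term requires a discriminator."""
    if not isinstance(weights, LossWeights):
        weights = LossWeights(*weights)
    if isinstance(out, SegOutput):
        seg, rec = out.seg_prob, out.reconstruction
    else:
        seg, rec = out
    total = weights.lambda1 * _mae(image, rec) + weights.lambda2 * dice_loss(seg, gt_mask)
    if weights.lambda3 > 0:
        if discriminator is None:
            raise ValueError("lambda3 > 0 requires a shape-prior discriminator")
        total = total + weights.lambda3 * discriminator_shape_loss(seg, discriminator)
    return total


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Exponentially decayed learning rate for a given epoch."""
    return exponential_lr(epoch, config.initial_lr, config.lr_gamma)


def reconstruction_loss(image, reconstruction):
    """RL: mean absolute difference between the input and its reconstruction.

    Implemented with a smoothed absolute value (sqrt(d^2 + 1e-12)) so the
    loss stays differentiable at zero error; the smoothing is far below any
    tolerance of interest when evaluating on plain arrays.
    """
    return _mae(image, reconstruction)


# ---------------------------------------------------------------------------
# classifier


@dataclass
class ClassifierModel:
    net: LidClassifier
    history: list[dict] = field(default_factory=list)

    def state_dict(self):
        return self.net.state_dict()


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def classify_lid(image: np.ndarray, model: ClassifierModel) -> tuple[str, float]:
    """Classify a preprocessed image as upper or lower eyelid.

    Returns the argmax label and its softmax probability.
    """
    logits = model.net(np.asarray(image, dtype=np.float64)).data
    probs = _softmax(logits)[0]
    k = int(np.argmax(probs))
    return LID_SIDES[k], float(probs[k])


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    n, k = logits.shape
    m = Tensor(logits.data.max(axis=1, keepdims=True))  # detached max for stability
    shifted = logits - m
    log_z = (shifted.exp().sum(axis=1, keepdims=True)).log()
    log_p = shifted - log_z
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    return -(log_p * Tensor(onehot)).sum() * (1.0 / n)


def _label_index(sample) -> int:
    side = sample.lid_side if hasattr(sample, "lid_side") else sample[1]
    return LID_SIDES.index(side)


def _sample_image(sample) -> np.ndarray:
    if isinstance(sample, SyntheticSample):
        return sample.image.pixels
    if hasattr(sample, "pixels"):
        return sample.pixels
    return np.asarray(sample[0], dtype=np.float64)


def _make_optimizer(params, config: TrainConfig):
    if config.optimizer == "adam":
        return Adam(params, lr=config.initial_lr)
    return RMSprop(params, lr=config.initial_lr)


def train_classifier(
    train_set: Sequence,
    val_set: Sequence,
    config: TrainConfig | None = None,
) -> ClassifierModel:
    """Train the eyelid-side classifier with cross-entropy.

    Samples are ``SyntheticSample`` objects or ``(image, lid_side)`` pairs.
    Returns the best-validation-accuracy checkpoint with per-epoch history.
    """
    config = config or TrainConfig()
    labels = [_label_index(s) for s in train_set]
    if len(set(labels)) < 2:
        raise ValueError("training set must contain both upper and lower lids")
    images = np.stack([_sample_image(s) for s in train_set])[:, None]
    y = np.asarray(labels)
    val_images = np.stack([_sample_image(s) for s in val_set])[:, None]
    val_y = np.asarray([_label_index(s) for s in val_set])

    rng = np.random.default_rng([config.seed, 0xC1A5])
    net = LidClassifier(base_width=config.base_width,
                        rng=np.random.default_rng([config.seed, 0x11D]))
    opt = _make_optimizer(net.parameters(), config)
    model = ClassifierModel(net=net)
    best_acc, best_state = -1.0, net.state_dict()
    n = images.shape[0]
    for epoch in range(config.epochs):
        opt.lr = lr_schedule(epoch, config)
        order = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = net(Tensor(images[idx]))
            loss = _cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            nb += 1
        val_logits = net(Tensor(val_images)).data
        val_acc = float((val_logits.argmax(axis=1) == val_y).mean())
        model.history.append(
            {"epoch": epoch, "lr": opt.lr, "train_loss": epoch_loss / nb,
             "val_accuracy": val_acc}
        )
        if val_acc > best_acc:
            best_acc, best_state = val_acc, net.state_dict()
    net.load_state_dict(best_state)
    return model


# ---------------------------------------------------------------------------
# segmenter


@dataclass
class SegmenterModel:
    net: UNetSegmenter
    target: str  # "tarsus" or "gland"
    history: list[dict] = field(default_factory=list)

    def state_dict(self):
        return self.net.state_dict()


def segment(image: np.ndarray, model: SegmenterModel) -> SegOutput:
    """Run the segmenter on one preprocessed image."""
    seg, rec = model.net(np.asarray(image, dtype=np.float64))
    return SegOutput(seg_prob=seg.data[0, 0], reconstruction=rec.data[0, 0])


def _target_mask(sample: SyntheticSample, target: str) -> np.ndarray:
    if target == "tarsus":
        return sample.tarsus_mask
    if target == "gland":
        return sample.gland_mask
    raise ValueError(f"unknown segmentation target {target!r}")


def _val_dice(net: UNetSegmenter, images: np.ndarray, masks: np.ndarray,
              threshold: float = 0.5) -> float:
    seg, _ = net(Tensor(images))
    pred = seg.data[:, 0] >= threshold
    gt = masks.astype(bool)
    tp = np.sum(pred & gt)
    return float(2 * tp / (2 * tp + np.sum(pred & ~gt) + np.sum(~pred & gt) + DICE_EPS))


def train_segmenter(
    train_set: Sequence[SyntheticSample],
    val_set: Sequence[SyntheticSample],
    target: str = "tarsus",
    shape_prior: Discriminator | None = None,
    config: TrainConfig | None = None,
) -> SegmenterModel:
    """Train the U-Net under the composite loss.

    ``shape_prior`` is the frozen discriminator exported by the VAE-GAN; when
    omitted the DL weight is forced to 0 and training uses RL + DcL only.
    The discriminator's parameters are never updated (frozen contract).
    Returns the best-validation-Dice checkpoint.
    """
    config = config or TrainConfig()
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    images = np.stack([_sample_image(s) for s in train_set])[:, None]
    masks = np.stack([_target_mask(s, target) for s in train_set]).astype(np.float64)
    val_images = np.stack([_sample_image(s) for s in val_set])[:, None]
    val_masks = np.stack([_target_mask(s, target) for s in val_set])

    weights = config.weights
    if shape_prior is None:
        weights = replace(weights, lambda3=0.0)
    else:
        shape_prior.freeze()

    rng = np.random.default_rng([config.seed, 0x5E6])
    net = UNetSegmenter(base_width=config.base_width,
                        rng=np.random.default_rng([config.seed, 0x04E7]))
    opt = _make_optimizer(net.parameters(), config)
    model = SegmenterModel(net=net, target=target)
    best_dice, best_state = -1.0, net.state_dict()
    n = images.shape[0]
    for epoch in range(config.epochs):
        opt.lr = lr_schedule(epoch, config)
        order = rng.permutation(n)
        epoch_loss, nb = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x = Tensor(images[idx])
            seg, rec = net(x)
            loss = weights.lambda1 * _mae(x, rec) + weights.lambda2 * dice_loss(
                seg, Tensor(masks[idx][:, None])
            )
            if weights.lambda3 > 0:
                loss = loss + weights.lambda3 * discriminator_shape_loss(seg, shape_prior)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            nb += 1
        vd = _val_dice(net, val_images, val_masks)
        model.history.append(
            {"epoch": epoch, "lr": opt.lr, "train_loss": epoch_loss / nb, "val_dice": vd}
        )
        if vd > best_dice:
            best_dice, best_state = vd, net.state_dict()
    net.load_state_dict(best_state)
    return model
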