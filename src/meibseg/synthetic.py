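"""Parametric synthetic meibograph: images with exact ground-truth masks.

Infrared meibography of an everted eyelid shows the tarsal plate as a bright
elliptical band against a darker background, with the meibomian glands as
still-brighter, roughly vertical, slightly tortuous stripes inside it.  This
module renders that scene from explicit parameters and returns the *exact*
tarsus and gland masks alongside the image, so segmentation and evaluation
code can be exercised without any clinical data.

Two design rules shape the generator:

* Geometry is specified in coordinates relative to the image, so a
  64 x 128 test-scale scene and a 420 x 890 full-scale scene depict the same
  anatomy.
* Imaging artifacts - specular highlights from the tear film and occluding
  eyelashes - are composited onto the image *after* the masks are fixed.
  Ground truth always describes the underlying anatomy; the "hard"
  difficulty is therefore a controlled robustness probe.

Upper eyelids carry a taller tarsal band than lower eyelids (as in real
anatomy), which makes the lid side geometrically recoverable and gives the
eyelid-side classifier a well-posed task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import LID_SIDES, LOWER, UPPER, MeibographyImage

__all__ = [
    "SceneParams",
    "SyntheticSample",
    "sample_scene_params",
    "render_sample",
    "generate_cohort",
    "DIFFICULTIES",
]

DIFFICULTIES = ("easy", "hard")

# Relative vertical semi-axis ranges; disjoint so a band-height threshold
# separates the classes perfectly (classifier ground truth is recoverable).
_UPPER_SEMI_H = (0.32, 0.40)
_LOWER_SEMI_H = (0.18, 0.25)
BAND_HEIGHT_THRESHOLD_REL = 0.57  # fraction of image height; between 2*0.25 and 2*0.32


class GeometryError(ValueError):
    """Scene geometry does not fit inside the image."""


@dataclass(frozen=True)
class SceneParams:
    """Full description of one synthetic meibography scene.

    Geometry fields are fractions of the image dimensions; pixel values are
    exposed through the ``*_px`` properties so the same parameters render
    consistently at any resolution.
    """

    lid_side: str
    image_height: int = 420
    image_width: int = 890
    tarsus_center_rel: tuple[float, float] = (0.5, 0.5)  # (row, col) fractions
    tarsus_axes_rel: tuple[float, float] = (0.35, 0.42)  # (semi-h/H, semi-w/W)
    gland_count: int = 12
    gland_width_rel: float = 0.022  # stripe width as a fraction of image width
    gland_tortuosity: float = 0.5  # sinusoid amplitude relative to gland spacing
    atrophy_fraction: float = 0.0  # fraction of each gland's length removed
    highlight_count: int = 0
    eyelash_count: int = 0
    noise_sigma: float = 0.01  # additive Gaussian noise, intensity units
    seed: int = 0  # drives texture and artifact placement

    def __post_init__(self) -> None:
        if self.lid_side not in LID_SIDES:
            raise ValueError(f"lid_side must be one of {LID_SIDES}, got {self.lid_side!r}")
        if self.gland_count < 0:
            raise ValueError("gland_count must be >= 0")
        if not 0.0 <= self.atrophy_fraction <= 1.0:
            raise ValueError("atrophy_fraction must lie in [0, 1]")
        if self.gland_tortuosity < 0:
            raise ValueError("gland_tortuosity must be >= 0")
        cy, cx = self.tarsus_center_rel
        ay, ax = self.tarsus_axes_rel
        if not (0 < ay < 0.5 and 0 < ax < 0.5):
            raise GeometryError(f"tarsus semi-axes {self.tarsus_axes_rel} must lie in (0, 0.5)")
        if cy - ay < 0 or cy + ay > 1 or cx - ax < 0 or cx + ax > 1:
            raise GeometryError(
                f"tarsus band (center {self.tarsus_center_rel}, axes {self.tarsus_axes_rel}) "
                "exceeds the image bounds"
            )

    # -- pixel-space accessors --------------------------------------------

    @property
    def tarsus_center(self) -> tuple[float, float]:
        return (self.tarsus_center_rel[0] * self.image_height,
                self.tarsus_center_rel[1] * self.image_width)

    @property
    def tarsus_axes(self) -> tuple[float, float]:
        return (self.tarsus_axes_rel[0] * self.image_height,
                self.tarsus_axes_rel[1] * self.image_width)

    @property
    def gland_width_px(self) -> float:
        return max(1.0, self.gland_width_rel * self.image_width)

    def expected_gland_fraction(self) -> float:
        """Analytic |gland| / |tarsus| implied by the parameters.

        Treats each gland as a constant-width vertical stripe clipped to the
        ellipse: area ~ width * chord length at the stripe's column.  Atrophy
        removes a proportional share of each stripe's length.
        """
        if self.gland_count == 0:
            return 0.0
        ay, ax = self.tarsus_axes
        u = _gland_column_positions(self.gland_count)
        chords = 2.0 * ay * np.sqrt(np.clip(1.0 - u**2, 0.0, None))
        stripe_area = self.gland_width_px * chords.sum()
        tarsus_area = np.pi * ay * ax
        return float((1.0 - self.atrophy_fraction) * stripe_area / tarsus_area)


@dataclass
class SyntheticSample:
    """A rendered image plus its exact ground truth."""

    image: MeibographyImage
    tarsus_mask: np.ndarray
    gland_mask: np.ndarray
    params: SceneParams
    patient_id: str = "synthetic"

    @property
    def lid_side(self) -> str:
        return self.image.lid_side

    def __post_init__(self) -> None:
        self.tarsus_mask = np.asarray(self.tarsus_mask, dtype=bool)
        self.gland_mask = np.asarray(self.gland_mask, dtype=bool)
        if self.tarsus_mask.shape != self.image.pixels.shape:
            raise ValueError("tarsus mask and image dimensions differ")
        if self.gland_mask.shape != self.image.pixels.shape:
            raise ValueError("gland mask and image dimensions differ")
        if np.any(self.gland_mask & ~self.tarsus_mask):
            raise ValueError("gland mask must be contained in the tarsus mask")


def _gland_column_positions(count: int) -> np.ndarray:
    """Even gland placement across the inner 85% of the ellipse width."""
    return np.linspace(-0.85, 0.85, count) if count > 1 else np.array([0.0])


def sample_scene_params(
    rng_seed: int,
    lid_side: str,
    difficulty: str = "easy",
    image_height: int = 420,
    image_width: int = 890,
) -> SceneParams:
    """Draw a random but reproducible scene for one lid side.

    ``easy`` scenes have no artifacts and little noise; ``hard`` scenes add
    specular tear-film highlights and occluding eyelashes plus stronger
    sensor noise.  The draw is a pure function of (seed, side, difficulty).
    """
    if lid_side not in LID_SIDES:
        raise ValueError(f"unknown lid_side {lid_side!r}; expected one of {LID_SIDES}")
    if difficulty not in DIFFICULTIES:
        raise ValueError(f"unknown difficulty {difficulty!r}; expected one of {DIFFICULTIES}")
    rng = np.random.default_rng(
        [int(rng_seed), LID_SIDES.index(lid_side), DIFFICULTIES.index(difficulty)]
    )
    lo, hi = _UPPER_SEMI_H if lid_side == UPPER else _LOWER_SEMI_H
    semi_h = rng.uniform(lo, hi)
    semi_w = rng.uniform(0.38, 0.45)
    center = (0.5 + rng.uniform(-0.03, 0.03), 0.5 + rng.uniform(-0.02, 0.02))
    hard = difficulty == "hard"
    return SceneParams(
        lid_side=lid_side,
        image_height=image_height,
        image_width=image_width,
        tarsus_center_rel=center,
        tarsus_axes_rel=(semi_h, semi_w),
        gland_count=int(rng.integers(10, 17)),
        gland_width_rel=rng.uniform(0.018, 0.026),
        gland_tortuosity=rng.uniform(0.2, 0.8),
        atrophy_fraction=rng.uniform(0.0, 0.3),
        highlight_count=int(rng.integers(2, 5)) if hard else 0,
        eyelash_count=int(rng.integers(3, 7)) if hard else 0,
        noise_sigma=0.04 if hard else 0.01,
        seed=int(rng.integers(2**31)),
    )


def _ellipse_mask(H: int, W: int, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[0:H, 0:W]
    cy, cx = center
    ay, ax = axes
    return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0


def _render_glands(params: SceneParams, tarsus: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    H, W = params.image_height, params.image_width
    cy, cx = params.tarsus_center
    ay, ax = params.tarsus_axes
    rr, cc = np.mgrid[0:H, 0:W]
    mask = np.zeros((H, W), dtype=bool)
    if params.gland_count == 0:
        return mask
    positions = _gland_column_positions(params.gland_count)
    spacing = (1.7 * ax) / max(params.gland_count, 1)
    half_w = params.gland_width_px / 2.0
    for u in positions:
        phase = rng.uniform(0, 2 * np.pi)
        amp = params.gland_tortuosity * spacing * 0.35
        center_col = cx + u * ax + amp * np.sin(2 * np.pi * 1.5 * rr / H + phase)
        stripe = (np.abs(cc - center_col) <= half_w) & tarsus
        if params.atrophy_fraction > 0 and stripe.any():
            rows = np.where(stripe.any(axis=1))[0]
            rmin, rmax = rows[0], rows[-1]
            # atrophy shortens the gland from the lid-margin (bottom) end
            keep_until = rmin + (1.0 - params.atrophy_fraction) * (rmax - rmin + 1)
            stripe &= rr < keep_until
        mask |= stripe
    return mask


def _composite_artifacts(image: np.ndarray, params: SceneParams, tarsus: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    H, W = image.shape
    rr, cc = np.mgrid[0:H, 0:W]
    cy, cx = params.tarsus_center
    ay, ax = params.tarsus_axes
    for _ in range(params.highlight_count):
        # specular tear-film reflection: bright round blob inside the band
        hr = cy + rng.uniform(-0.6, 0.6) * ay
        hc = cx + rng.uniform(-0.7, 0.7) * ax
        radius = rng.uniform(0.03, 0.07) * H
        blob = np.exp(-(((rr - hr) ** 2 + (cc - hc) ** 2) / (2 * radius**2)))
        image = np.maximum(image, 0.97 * blob)
    for _ in range(params.eyelash_count):
        # eyelash: thin dark near-vertical parabolic streak across the band
        c0 = rng.uniform(0.1, 0.9) * W
        slope = rng.uniform(-0.35, 0.35)
        curv = rng.uniform(-0.4, 0.4) / H
        width = max(1.0, 0.012 * W)
        center_col = c0 + slope * (rr - cy) + curv * (rr - cy) ** 2
        streak = np.abs(cc - center_col) <= width / 2.0
        image = np.where(streak, 0.06, image)
    return image


def render_sample(params: SceneParams, patient_id: str = "synthetic") -> SyntheticSample:
    """Render a scene into an image plus exact tarsus/gland masks.

    Intensity ordering is enforced by construction: glands brighter than the
    tarsus background, tarsus brighter than the surround.  Artifacts and
    noise are composited after the masks are fixed, so they occlude the
    image but never edit the ground truth.
    """
    H, W = params.image_height, params.image_width
    rng = np.random.default_rng([params.seed, 0x5CE11E])
    tarsus = _ellipse_mask(H, W, params.tarsus_center, params.tarsus_axes)
    glands = _render_glands(params, tarsus, rng)

    image = np.full((H, W), 0.15)
    image[tarsus] = 0.45
    image[glands] = 0.80
    # low-frequency biological texture, then a slight optical blur
    texture = gaussian_filter(rng.normal(0.0, 1.0, (H, W)), sigma=max(2.0, H / 16))
    tex_amp = texture.std()
    if tex_amp > 0:
        image = image + 0.03 * texture / tex_amp
    image = gaussian_filter(image, sigma=0.6)
    image = _composite_artifacts(image, params, tarsus, rng)
    if params.noise_sigma > 0:
        image = image + rng.normal(0.0, params.noise_sigma, (H, W))
    image = np.clip(image, 0.0, 1.0)

    return SyntheticSample(
        image=MeibographyImage(image, params.lid_side, patient_id),
        tarsus_mask=tarsus,
        gland_mask=glands,
        params=params,
        patient_id=patient_id,
    )


def generate_cohort(
    n_patients: int,
    images_per_patient: int,
    seed: int,
    difficulty: str = "easy",
    image_height: int = 420,
    image_width: int = 890,
) -> list[SyntheticSample]:
    """Generate a patient-structured cohort of synthetic samples.

    Lid side alternates with the flat sample index so both classes always
    appear in near-equal numbers; all of a patient's images share one
    patient_id, which the splitter uses to keep patients in a single set.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    if images_per_patient < 1:
        raise ValueError(f"images_per_patient must be >= 1, got {images_per_patient}")
    if difficulty not in DIFFICULTIES:
        raise ValueError(f"unknown difficulty {difficulty!r}; expected one of {DIFFICULTIES}")
    samples: list[SyntheticSample] = []
    for i in range(n_patients):
        patient_id = f"P{i:04d}"
        for j in range(images_per_patient):
            flat = i * images_per_patient + j
            side = UPPER if flat % 2 == 0 else LOWER
            sub_seed = int(np.random.default_rng([int(seed), flat]).integers(2**31))
            params = sample_scene_params(
                sub_seed, side, difficulty,
                image_height=image_height, image_width=image_width,
            )
            samples.append(render_sample(params, patient_id=patient_id))
    return samples


def band_height_lid_rule(tarsus_mask: np.ndarray) -> str:
    """Classify lid side from band height alone (the geometric ground rule).

    The tallest column of the tarsus mask, as a fraction of image height,
    exceeds ``BAND_HEIGHT_THRESHOLD_REL`` only for upper lids.
    """
    H = tarsus_mask.shape[0]
    heights = tarsus_mask.sum(axis=0)
    return UPPER if heights.max() / H > BAND_HEIGHT_THRESHOLD_REL else LOWER
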