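"""Data handling: annotation rasterization, cropping, smoothing,
normalization, the 16-fold augmentation, and leakage-free patient splits.

The pipeline mirrors routine meibography preprocessing: frames are cropped
to the 420 x 890 region of interest (stripping device/personal margins),
smoothed with a small edge-preserving bilateral filter, max-min normalized
to [0, 1], and expanded 16-fold by the full on/off product of four
augmentations (horizontal flip, brightness/contrast jitter, low-frequency
lighting, additive Gaussian noise).  Patients are never split across the
train/validation/test sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "AugmentToggles",
    "SplitAssignment",
    "rasterize_annotations",
    "crop_to_roi",
    "bilateral_smooth",
    "minmax_normalize",
    "augment_16",
    "split_by_patient",
    "CROP_HEIGHT",
    "CROP_WIDTH",
]

CROP_HEIGHT = 420
CROP_WIDTH = 890

SPLIT_NAMES = ("train", "val", "test")


# ---------------------------------------------------------------------------
# annotations


@dataclass
class AnnotationSet:
    """Expert polygon annotations for one image.

    ``tarsus_polygon`` outlines the tarsal plate; ``gland_polygons`` holds
    one closed contour per meibomian gland.  Vertices are (x, y) =
    (column, row) pixel coordinates, as produced by COCO-style lasso
    annotation tools.
    """

    tarsus_polygon: np.ndarray
    gland_polygons: list[np.ndarray]
    image_id: str = ""

    def __post_init__(self) -> None:
        self.tarsus_polygon = _as_polygon(self.tarsus_polygon)
        self.gland_polygons = [_as_polygon(p) for p in self.gland_polygons]


def _as_polygon(vertices) -> np.ndarray:
    arr = np.asarray(vertices, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError(
            f"polygon must be an (n>=3, 2) vertex array, got shape {arr.shape}"
        )
    return arr


def _fill_polygon(vertices: np.ndarray, height: int, width: int) -> np.ndarray:
    """Even-odd polygon fill sampled at integer pixel centers.

    A pixel is set when its center (row r, col c) lies strictly inside the
    polygon by the even-odd (ray crossing) rule, or exactly on an edge:
    boundary pixels belong to the region, so an axis-aligned rectangle with
    corners (2,2)-(5,4) covers the full 4 x 3 = 12 pixel block.
    """
    verts = np.asarray(vertices, dtype=np.float64)
    # physical image extent under the pixel-center convention
    oob = (
        (verts[:, 0] < -0.5) | (verts[:, 0] > width - 0.5)
        | (verts[:, 1] < -0.5) | (verts[:, 1] > height - 0.5)
    )
    if oob.any():
        logger.warning(
            "polygon has %d vertices outside the %dx%d image; clipping",
            int(oob.sum()), height, width,
        )
        verts = verts.copy()
        verts[:, 0] = np.clip(verts[:, 0], -0.5, width - 0.5)
        verts[:, 1] = np.clip(verts[:, 1], -0.5, height - 0.5)

    rr, cc = np.mgrid[0:height, 0:width]
    px = cc.ravel().astype(np.float64)  # x = column of the pixel center
    py = rr.ravel().astype(np.float64)  # y = row
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    x1s, y1s = verts[:, 0], verts[:, 1]
    x2s, y2s = np.roll(x1s, -1), np.roll(y1s, -1)
    eps = 1e-9
    for x1, y1, x2, y2 in zip(x1s, y1s, x2s, y2s):
        crosses = (y1 > py) != (y2 > py)
        if np.any(crosses):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (px < x_at)
        # point-on-segment test
        dx, dy = x2 - x1, y2 - y1
        seg_len2 = dx * dx + dy * dy
        if seg_len2 < eps:
            on_edge |= (np.abs(px - x1) < eps) & (np.abs(py - y1) < eps)
            continue
        t = ((px - x1) * dx + (py - y1) * dy) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        dist2 = (px - (x1 + t * dx)) ** 2 + (py - (y1 + t * dy)) ** 2
        on_edge |= dist2 < 1e-18
    return (inside | on_edge).reshape(height, width)


def rasterize_annotations(
    ann: AnnotationSet, height: int, width: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize polygon annotations into tarsus and gland masks.

    The gland mask is the union of all per-gland polygons; both masks use
    even-odd fill at pixel centers with boundary pixels included.
    """
    if height <= 0 or width <= 0:
        raise ValueError(f"mask dimensions must be positive, got {height}x{width}")
    tarsus = _fill_polygon(ann.tarsus_polygon, height, width)
    gland = np.zeros((height, width), dtype=bool)
    for poly in ann.gland_polygons:
        gland |= _fill_polygon(poly, height, width)
    return tarsus, gland


# ---------------------------------------------------------------------------
# intensity pipeline


def crop_to_roi(
    raw_image: np.ndarray,
    row_offset: int,
    col_offset: int,
    out_height: int = CROP_HEIGHT,
    out_width: int = CROP_WIDTH,
) -> np.ndarray:
    """Extract the region of interest as an exact window copy (no resampling)."""
    raw = np.asarray(raw_image)
    H, W = raw.shape[:2]
    if row_offset < 0 or col_offset < 0 or row_offset + out_height > H or col_offset + out_width > W:
        raise ValueError(
            f"crop window {out_height}x{out_width} at offset "
            f"({row_offset}, {col_offset}) exceeds image of size {H}x{W}"
        )
    return raw[row_offset : row_offset + out_height, col_offset : col_offset + out_width].copy()


def bilateral_smooth(
    image: np.ndarray,
    kernel_size: int = 3,
    sigma_color: float = 0.1,
    sigma_space: float = 1.0,
) -> np.ndarray:
    """Edge-preserving bilateral filter with replicated borders.

    Each output pixel is the weighted mean of its k x k neighbourhood, with
    weights the product of a spatial Gaussian (sigma_space, in pixels) and a
    range Gaussian on intensity difference (sigma_color, intensity units).
    Being a convex combination of neighbour intensities, the output stays in
    [0, 1] and constants are preserved exactly.
    """
    if kernel_size % 2 == 0 or kernel_size < 1:
        raise ValueError(f"kernel_size must be odd and positive, got {kernel_size}")
    img = np.asarray(image, dtype=np.float64)
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("bilateral_smooth expects intensities in [0, 1]")
    r = kernel_size // 2
    padded = np.pad(img, r, mode="edge")
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    H, W = img.shape
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            neigh = padded[r + dy : r + dy + H, r + dx : r + dx + W]
            w_spatial = np.exp(-(dy * dy + dx * dx) / (2.0 * sigma_space**2))
            w_range = np.exp(-((neigh - img) ** 2) / (2.0 * sigma_color**2))
            w = w_spatial * w_range
            num += w * neigh
            den += w
    return num / den


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Max-min normalization to [0, 1]; constant images map to all zeros."""
    img = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class AugmentToggles:
    """On/off switches for the four augmentation operations of one variant."""

    horizontal_flip: bool = False
    color_jitter: bool = False
    random_lighting: bool = False
    gaussian_noise: bool = False

    @staticmethod
    def full_set() -> list["AugmentToggles"]:
        """All 2^4 = 16 combinations, identity first."""
        return [
            AugmentToggles(*bits)
            for bits in product([False, True], repeat=4)
        ]


def augment_16(
    image: np.ndarray,
    masks: Mapping[str, np.ndarray],
    seed: int,
    noise_sigma: float = 0.02,
) -> list[tuple[np.ndarray, dict[str, np.ndarray], AugmentToggles]]:
    """Expand one sample into the 16 on/off combinations of four augmentations.

    Geometric ops (horizontal flip) apply to image and masks alike;
    photometric ops (jitter, lighting, noise) touch the image only.  The
    random draws behind the photometric ops are made once from ``seed``, so
    the variant set is deterministic and the all-off variant is bit-identical
    to the input.
    """
    img = np.asarray(image, dtype=np.float64)
    mask_dict = {k: np.asarray(v) for k, v in masks.items()}
    for name, m in mask_dict.items():
        if m.shape != img.shape:
            raise ValueError(
                f"mask {name!r} shape {m.shape} does not match image shape {img.shape}"
            )
    rng = np.random.default_rng([int(seed), 0xA06])
    brightness = rng.uniform(-0.12, 0.12)
    contrast = rng.uniform(0.8, 1.2)
    grad_r, grad_c = rng.uniform(-0.3, 0.3, size=2)
    noise_field = rng.normal(0.0, noise_sigma, img.shape)
    H, W = img.shape
    rr, cc = np.mgrid[0:H, 0:W]
    lighting = 1.0 + grad_r * (rr / max(H - 1, 1) - 0.5) + grad_c * (cc / max(W - 1, 1) - 0.5)

    out = []
    for toggles in AugmentToggles.full_set():
        v = img
        vmasks = mask_dict
        if toggles.horizontal_flip:
            v = v[:, ::-1]
            vmasks = {k: m[:, ::-1] for k, m in vmasks.items()}
        if toggles.color_jitter:
            v = np.clip((v - 0.5) * contrast + 0.5 + brightness, 0.0, 1.0)
        if toggles.random_lighting:
            v = np.clip(v * lighting, 0.0, 1.0)
        if toggles.gaussian_noise:
            v = np.clip(v + noise_field, 0.0, 1.0)
        out.append((v.copy(), {k: m.copy() for k, m in vmasks.items()}, toggles))
    return out


# ---------------------------------------------------------------------------
# patient-level splitting


@dataclass
class SplitAssignment:
    """Mapping from patient_id to one of train/val/test."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]

    def patients(self, split: str) -> set[str]:
        return {p for p, s in self.assignment.items() if s == split}

    def split_of(self, patient_id: str) -> str:
        return self.assignment[patient_id]


def split_by_patient(
    patient_ids: Iterable[str] | Sequence,
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10),
    seed: int = 0,
) -> SplitAssignment:
    """Assign whole patients to train/val/test at the target image fractions.

    Accepts one entry per image: either a patient-id string or any object
    with a ``patient_id`` attribute.  Patients are shuffled, then assigned
    greedily: each patient goes to the set with the largest remaining image
    deficit (largest-remainder allocation), so no patient straddles sets and
    realized image fractions stay within one patient's worth of the targets.
    """
    if len(fractions) != 3:
        raise ValueError("fractions must be a (train, val, test) triple")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions} (sum {sum(fractions)})")
    ids = [
        p if isinstance(p, str) else getattr(p, "patient_id")
        for p in patient_ids
    ]
    counts: dict[str, int] = {}
    for pid in ids:
        counts[pid] = counts.get(pid, 0) + 1
    if len(counts) < 3:
        raise ValueError(f"need at least 3 patients to split, got {len(counts)}")
    patients = sorted(counts)
    rng = np.random.default_rng(seed)
    rng.shuffle(patients)
    total = len(ids)
    deficits = [f * total for f in fractions]
    assignment: dict[str, str] = {}
    for pid in patients:
        k = int(np.argmax(deficits))  # ties break train > val > test
        assignment[pid] = SPLIT_NAMES[k]
        deficits[k] -= counts[pid]
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions))
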