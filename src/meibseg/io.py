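"""Reading and writing images, masks, COCO-style annotations and manifests.

Images travel as 8-bit grayscale PNG/TIFF; masks as 0/255 PNG.  Polygon
annotations use the COCO JSON layout (``images`` and ``annotations`` arrays,
``segmentation`` as flat [x1, y1, x2, y2, ...] sequences) with two
categories: tarsus (id 1) and gland (id 2).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage import measure

from .preprocessing import AnnotationSet
from .synthetic import SyntheticSample

__all__ = [
    "save_image",
    "load_image",
    "save_mask",
    "load_mask",
    "write_cohort",
    "read_coco_annotations",
    "write_coco_annotations",
]

TARSUS_CATEGORY = 1
GLAND_CATEGORY = 2


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0,1] float image as 8-bit grayscale PNG/TIFF."""
    arr = np.asarray(image, dtype=np.float64)
    Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(path)


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale image into a [0,1] float array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64) / 255.0


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray(np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8),
                    mode="L").save(path)


def load_mask(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) >= 128


def write_cohort(samples: Sequence[SyntheticSample], out_dir: str | Path,
                 coco: bool = False) -> Path:
    """Write images, masks and a JSON manifest; optionally COCO polygons.

    Returns the manifest path.  Layout: ``images/{i:04d}.png``,
    ``masks/{i:04d}_tarsus.png``, ``masks/{i:04d}_gland.png``.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(samples):
        img_rel = f"images/{i:04d}.png"
        t_rel = f"masks/{i:04d}_tarsus.png"
        g_rel = f"masks/{i:04d}_gland.png"
        save_image(out / img_rel, s.image.pixels)
        save_mask(out / t_rel, s.tarsus_mask)
        save_mask(out / g_rel, s.gland_mask)
        entries.append(
            {
                "image_id": f"{i:04d}",
                "patient_id": s.patient_id,
                "lid_side": s.lid_side,
                "image": img_rel,
                "tarsus_mask": t_rel,
                "gland_mask": g_rel,
            }
        )
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({"samples": entries}, indent=2))
    if coco:
        anns = [mask_annotations(s, f"{i:04d}") for i, s in enumerate(samples)]
        write_coco_annotations(out / "annotations.json", anns,
                               [s.image.pixels.shape for s in samples])
    return manifest


# ---------------------------------------------------------------------------
# COCO-style polygons


def _mask_to_polygons(mask: np.ndarray) -> list[np.ndarray]:
    """Trace a binary mask into (x, y) polygon contours."""
    polys = []
    for contour in measure.find_contours(mask.astype(float), 0.5):
        if contour.shape[0] < 3:
            continue
        # find_contours yields (row, col); COCO wants (x, y) = (col, row)
        polys.append(contour[:, ::-1])
    return polys


def mask_annotations(sample: SyntheticSample, image_id: str) -> AnnotationSet:
    """Build an AnnotationSet by tracing the sample's ground-truth masks."""
    tarsus_polys = _mask_to_polygons(sample.tarsus_mask)
    if not tarsus_polys:
        raise ValueError("tarsus mask traced to no contour")
    tarsus = max(tarsus_polys, key=len)
    glands = _mask_to_polygons(sample.gland_mask)
    return AnnotationSet(tarsus_polygon=tarsus, gland_polygons=glands, image_id=image_id)


def write_coco_annotations(path: str | Path, annotation_sets: Sequence[AnnotationSet],
                           image_shapes: Sequence[tuple[int, int]]) -> None:
    images, annotations = [], []
    ann_id = 1
    for idx, (ann, shape) in enumerate(zip(annotation_sets, image_shapes)):
        images.append(
            {"id": idx, "file_name": f"{ann.image_id}.png",
             "height": int(shape[0]), "width": int(shape[1])}
        )
        polys = [(TARSUS_CATEGORY, ann.tarsus_polygon)] + [
            (GLAND_CATEGORY, p) for p in ann.gland_polygons
        ]
        for cat, poly in polys:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": idx,
                    "category_id": cat,
                    "segmentation": [np.asarray(poly, dtype=float).ravel().tolist()],
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [
            {"id": TARSUS_CATEGORY, "name": "tarsus"},
            {"id": GLAND_CATEGORY, "name": "gland"},
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_coco_annotations(path: str | Path) -> list[AnnotationSet]:
    """Parse COCO polygon JSON into one AnnotationSet per image."""
    doc = json.loads(Path(path).read_text())
    by_image: dict[int, dict] = {
        img["id"]: {"file_name": img.get("file_name", str(img["id"])),
                    "tarsus": None, "glands": []}
        for img in doc["images"]
    }
    for ann in doc["annotations"]:
        seg = ann["segmentation"][0]
        poly = np.asarray(seg, dtype=np.float64).reshape(-1, 2)
        slot = by_image[ann["image_id"]]
        if ann["category_id"] == TARSUS_CATEGORY:
            slot["tarsus"] = poly
        else:
            slot["glands"].append(poly)
    out = []
    for img_id in sorted(by_image):
        slot = by_image[img_id]
        if slot["tarsus"] is None:
            raise ValueError(f"image {img_id} has no tarsus annotation")
        out.append(
            AnnotationSet(
                tarsus_polygon=slot["tarsus"],
                gland_polygons=slot["glands"],
                image_id=Path(slot["file_name"]).stem,
            )
        )
    return out
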