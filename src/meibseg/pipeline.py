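"""End-to-end inference: classify the lid, then segment with lid-specific models.

The full pipeline mirrors clinical use: a preprocessed meibography image is
first routed by the upper/lower classifier, then the matching tarsus and
gland segmenters produce masks, the gland mask is clipped to the tarsus, and
the gland-area-to-tarsus-area ratio (whose complement is the gland loss
proportion) is computed.  When ground truth is supplied, per-image pixel
metrics are attached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .evaluation import MetricsReport, confusion, gland_area_ratio, metrics
from .image import LID_SIDES
from .models import LidClassifier, UNetSegmenter
from .segmentation import ClassifierModel, SegmenterModel, classify_lid, segment

__all__ = ["ModelBundle", "PipelineResult", "predict_pipeline"]

ROLES = ("classifier", "upper-tarsus", "lower-tarsus", "upper-gland", "lower-gland")


@dataclass
class ModelBundle:
    """Trained models for every pipeline role.

    Roles: ``classifier`` plus one (lid side x target) segmenter each:
    upper-tarsus, lower-tarsus, upper-gland, lower-gland.
    """

    classifier: ClassifierModel
    segmenters: dict[str, SegmenterModel] = field(default_factory=dict)

    def require(self, role: str):
        if role == "classifier":
            return self.classifier
        if role not in self.segmenters:
            raise KeyError(f"model bundle is missing role {role!r}")
        return self.segmenters[role]

    # -- persistence -------------------------------------------------------

    def save(self, out_dir: str | Path, base_width: int,
             classifier_base_width: int | None = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "classifier.npz", **self.classifier.net.state_dict())
        for role, model in self.segmenters.items():
            np.savez(out / f"{role}.npz", **model.net.state_dict())
        manifest = {
            "base_width": base_width,
            "classifier_base_width": classifier_base_width or base_width,
            "roles": {"classifier": "classifier.npz",
                      **{r: f"{r}.npz" for r in self.segmenters}},
        }
        (out / "bundle.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "ModelBundle":
        path = Path(in_dir)
        manifest = json.loads((path / "bundle.json").read_text())
        w = manifest["base_width"]
        clf_w = manifest.get("classifier_base_width", w)
        clf = ClassifierModel(net=LidClassifier(base_width=clf_w))
        with np.load(path / manifest["roles"]["classifier"]) as data:
            clf.net.load_state_dict(dict(data))
        segmenters = {}
        for role, fname in manifest["roles"].items():
            if role == "classifier":
                continue
            target = role.split("-")[1]
            model = SegmenterModel(net=UNetSegmenter(base_width=w), target=target)
            with np.load(path / fname) as data:
                model.net.load_state_dict(dict(data))
            segmenters[role] = model
        return cls(classifier=clf, segmenters=segmenters)


@dataclass
class PipelineResult:
    lid_side: str
    lid_probability: float
    tarsus_mask: np.ndarray
    gland_mask: np.ndarray
    gland_area_ratio: float
    tarsus_metrics: MetricsReport | None = None
    gland_metrics: MetricsReport | None = None


def predict_pipeline(
    image: np.ndarray,
    bundle: ModelBundle,
    threshold: float = 0.5,
    ground_truth: Mapping[str, np.ndarray] | None = None,
) -> PipelineResult:
    """Run classifier -> lid-specific tarsus & gland segmentation -> ratio.

    ``ground_truth`` may carry "tarsus" / "gland" masks to attach per-image
    metrics.  The gland mask is always clipped to the tarsus mask before the
    area ratio is computed.
    """
    img = np.asarray(image, dtype=np.float64)
    side, prob = classify_lid(img, bundle.require("classifier"))
    assert side in LID_SIDES
    tarsus_out = segment(img, bundle.require(f"{side}-tarsus"))
    gland_out = segment(img, bundle.require(f"{side}-gland"))
    tarsus_mask = tarsus_out.seg_prob >= threshold
    gland_mask = (gland_out.seg_prob >= threshold) & tarsus_mask
    ratio = (
        gland_area_ratio(gland_mask, tarsus_mask) if tarsus_mask.any() else float("nan")
    )
    result = PipelineResult(
        lid_side=side,
        lid_probability=prob,
        tarsus_mask=tarsus_mask,
        gland_mask=gland_mask,
        gland_area_ratio=ratio,
    )
    if ground_truth:
        if "tarsus" in ground_truth:
            result.tarsus_metrics = metrics(confusion(tarsus_mask, ground_truth["tarsus"]))
        if "gland" in ground_truth:
            result.gland_metrics = metrics(confusion(gland_mask, ground_truth["gland"]))
    return result
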