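"""Core image container shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

UPPER = "upper"
LOWER = "lower"
LID_SIDES = (UPPER, LOWER)


@dataclass
class MeibographyImage:
    """An 8-bit-derived grayscale meibography frame in [0, 1].

    Attributes
    ----------
    pixels : float array (H, W), intensities in [0, 1]
    lid_side : "upper" or "lower" (everted upper or lower eyelid)
    patient_id : identifier used for leakage-free patient-level splitting
    """

    pixels: np.ndarray
    lid_side: str
    patient_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected 2-D grayscale image, got ndim={self.pixels.ndim}")
        if self.lid_side not in LID_SIDES:
            raise ValueError(f"lid_side must be one of {LID_SIDES}, got {self.lid_side!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
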