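"""ROI contrast metrics and Bland-Altman agreement statistics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = ["ROISpec", "ContrastReport", "roi_cr", "roi_cnr", "bland_altman"]


@dataclass
class ROISpec:
    """A named region of interest given as a boolean mask."""

    name: str
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.name!r} is empty")

    @classmethod
    def from_box(cls, name: str, shape, box) -> "ROISpec":
        """Build from a box spec ((x0,x1),(y0,y1),(z0,z1))."""
        mask = np.zeros(shape, dtype=bool)
        sl = tuple(slice(a, b) for a, b in box)
        mask[sl] = True
        return cls(name, mask)


@dataclass
class ContrastReport:
    cr: float | None
    cnr: float | None
    roi_a: str
    roi_b: str
    noise_roi: str = ""
    image_tag: str = ""


def _mask_of(roi) -> np.ndarray:
    return roi.mask if isinstance(roi, ROISpec) else np.asarray(roi, dtype=bool)


def _name_of(roi, default: str) -> str:
    return roi.name if isinstance(roi, ROISpec) else default


def roi_cr(image: np.ndarray, roi_a, roi_b) -> float:
    """Contrast ratio mean(A)/mean(B) on a display-normalized image.

    Intended for display-normalized PSIR volumes (values in [0, 1], nulled
    tissue at 0.5), where the ratio of ROI means is scale-meaningful.
    """
    ma = _mask_of(roi_a)
    mb = _mask_of(roi_b)
    if not ma.any() or not mb.any():
        raise ValueError("ROIs must be nonempty")
    mean_b = float(image[mb].mean())
    if mean_b == 0:
        raise ValueError("undefined contrast ratio: mean of roi_b is zero")
    return float(image[ma].mean()) / mean_b


def roi_cnr(image: np.ndarray, roi_a, roi_b, noise_roi) -> float:
    """Contrast-to-noise ratio (mean(A) - mean(B)) / std(noise ROI)."""
    ma = _mask_of(roi_a)
    mb = _mask_of(roi_b)
    mn = _mask_of(noise_roi)
    sd = float(np.std(image[mn], ddof=1))
    if sd == 0:
        raise ValueError("noise ROI has zero standard deviation")
    return (float(image[ma].mean()) - float(image[mb].mean())) / sd


class BlandAltman(NamedTuple):
    bias: float
    loa_low: float
    loa_high: float


def bland_altman(x, y) -> BlandAltman:
    """Bland-Altman agreement: bias and 95% limits of agreement.

    d = x - y; bias = mean(d); limits = bias +/- 1.96 * sample std(d).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D sequences")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd)
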