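"""Pixel classification, morphological mask refinement, and evaluation.

The raw mask marks every pixel whose HSI value falls inside the
discriminating ellipsoid.  Stained smears produce broken and speckled raw
masks, so refinement applies, in order: dilation, closing, a median
filter, hole filling, and removal of all but the largest connected
component.  Structuring-element sizes default to the smallest standard
choices (3x3 square for dilation/closing, 7x7 median) and are
configurable.

Segmentation quality is scored per pixel:

    sensitivity = TP / (TP + FN)      specificity = TN / (TN + FP)

A rate whose denominator is zero is defined as 1 (nothing to find is
vacuously found).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .color_model import rgb_to_hsi
from .discriminating_region import EllipsoidRegion, membership_image

__all__ = [
    "BinaryMask", "SegmentationMetrics", "classify_pixels", "refine_mask",
    "segment_cell", "evaluate_segmentation",
]


@dataclass
class BinaryMask:
    """A per-pixel cell/background labeling.

    ``provenance`` records where the mask came from: ``"raw"`` (pixel
    classification), ``"refined"`` (after morphology) or
    ``"ground-truth"``.
    """

    pixels: np.ndarray
    provenance: str = "raw"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2-D boolean array")

    @property
    def shape(self):
        return self.pixels.shape

    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass
class SegmentationMetrics:
    """Pixel-level confusion counts and the derived rates."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        }


def classify_pixels(hsi: np.ndarray, region: EllipsoidRegion) -> BinaryMask:
    """Label pixels whose ellipsoid membership value is <= 1 as cell.

    Parameters
    ----------
    hsi : (H, W, 3) array
        Image already converted to the HSI convention the region was
        fitted under.
    """
    values = membership_image(region, hsi)
    return BinaryMask(values <= 1.0, provenance="raw")


def refine_mask(raw: BinaryMask, dilation_size: int = 3, closing_size: int = 3,
                median_size: int = 7, fill_holes: bool = True) -> BinaryMask:
    """Clean a raw mask into (at most) one solid cell component.

    Applies, in order: square dilation, square closing, median filter,
    hole filling, then keeps only the largest 8-connected component.
    Returns an all-false mask if nothing survives.
    """
    m = raw.pixels
    if m.any():
        m = morphology.dilation(m, morphology.footprint_rectangle((dilation_size,) * 2))
        m = morphology.closing(m, morphology.footprint_rectangle((closing_size,) * 2))
        m = ndimage.median_filter(m, size=median_size)
        if fill_holes:
            m = ndimage.binary_fill_holes(m)
    if m.any():
        labels, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
            m = labels == (int(np.argmax(sizes)) + 1)
        if fill_holes:
            m = ndimage.binary_fill_holes(m)
    return BinaryMask(m, provenance="refined")


def segment_cell(img: np.ndarray, region: EllipsoidRegion,
                 **refine_kwargs) -> tuple[BinaryMask, np.ndarray]:
    """Segment one white blood cell from an RGB smear image.

    Runs rgb_to_hsi -> classify_pixels -> refine_mask, then crops the
    image to the bounding box of the refined mask (the full image when
    the mask is empty).

    Returns
    -------
    (BinaryMask, cropped RGB array)
    """
    hsi = rgb_to_hsi(img)
    raw = classify_pixels(hsi, region)
    refined = refine_mask(raw, **refine_kwargs)
    if refined.pixels.any():
        rows = np.flatnonzero(refined.pixels.any(axis=1))
        cols = np.flatnonzero(refined.pixels.any(axis=0))
        crop = np.asarray(img)[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    else:
        crop = np.asarray(img)
    return refined, crop


def evaluate_segmentation(pred: BinaryMask, truth: BinaryMask) -> SegmentationMetrics:
    """Pixel-count confusion matrix plus sensitivity and specificity.

    A rate with a zero denominator is defined as 1.0.

    Raises
    ------
    ValueError
        If the two masks differ in shape.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p, t = pred.pixels, truth.pixels
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    sens = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    spec = tn / (tn + fp) if (tn + fp) > 0 else 1.0
    return SegmentationMetrics(tp=tp, fp=fp, tn=tn, fn=fn,
                               sensitivity=sens, specificity=spec)
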