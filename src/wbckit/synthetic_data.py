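"""Synthetic smear scenes, HSI pixel samples, and labeled feature sets.

Stained-smear scenes are emulated at the level the segmentation pipeline
cares about: a pale, lightly jittered background; one or more elliptical
cells whose per-pixel HSI tones are drawn from inside a known ellipsoidal
tone region (so the ground-truth mask is exact by construction); optional
"granules" — small disks of off-region red tone inside the cell that mimic
the basophil failure mode, where dense granulation hides cell tone from a
color-based segmenter; and optional speckle noise, isolated cell-tone
pixels scattered over the background.  Everything is bit-exact
reproducible from (spec, seed).

The feature-set generator makes 5 Gaussian clusters in the 20-feature
space with controllable centroid separation (in units of the per-feature
standard deviation), mapped onto physically plausible feature scales
(positive areas, LDP frequencies inside [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .color_model import hsi_to_rgb
from .discriminating_region import (
    EllipsoidRegion, PixelSampleSet, membership_image,
)
from .segmentation import BinaryMask
from .classifiers import CLASS_LABELS
from .features import FEATURE_NAMES

__all__ = [
    "SyntheticSceneSpec", "SyntheticScene", "default_scene_region",
    "generate_scene", "sample_region_pixels", "generate_feature_dataset",
]


def default_scene_region() -> EllipsoidRegion:
    """A plausible nucleus-tone ellipsoid in the package's HSI convention.

    Centered on a purple stain tone (H = 290 deg, S = 0.45, I = 0.40)
    with hue spread of about 20 degrees and a mild rotation in the
    saturation-intensity plane, emulating the correlated S/I cluster of
    stained chromatin.
    """
    theta = np.radians(30.0)
    rotation = np.array([
        [1.0, 0.0, 0.0],
        [0.0, np.cos(theta), np.sin(theta)],
        [0.0, -np.sin(theta), np.cos(theta)],
    ])
    preimage = np.array([290.0, 0.45, 0.40])
    semi = np.array([20.0, 0.15, 0.08])
    return EllipsoidRegion(rotation=rotation, center=rotation @ preimage,
                           semi_axes=semi,
                           convention_tag="gw-degrees-unit")


@dataclass
class SyntheticSceneSpec:
    """Parameters fully determining one synthetic smear scene.

    ``cells`` is a list of ellipses ((row, col) center, (a, b) semi-axes
    in pixels, rotation in radians).  ``tone_quantile`` caps the
    ellipsoid membership value of sampled cell tones; ``granule_density``
    is the expected number of granule disks per 100 cell pixels;
    ``speckle_fraction`` is the fraction of background pixels replaced by
    isolated cell-tone speckles.
    """

    size: tuple = (120, 120)
    cells: tuple = (((60.0, 60.0), (22.0, 18.0), 0.5),)
    tone_region: EllipsoidRegion = field(default_factory=default_scene_region)
    tone_quantile: float = 0.7
    background_rgb: tuple = (235.0, 228.0, 232.0)
    background_jitter: float = 6.0
    speckle_fraction: float = 0.01
    granule_density: float = 0.0
    granule_rgb: tuple = (170.0, 40.0, 70.0)
    granule_radius: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.tone_quantile <= 1.0):
            raise ValueError("tone_quantile must lie in (0, 1]")
        if not (0.0 <= self.speckle_fraction <= 0.2):
            raise ValueError("speckle_fraction must lie in [0, 0.2]")
        h, w = self.size
        for (cy, cx), (a, b), _ in self.cells:
            r = max(a, b)
            if cy - r < 0 or cx - r < 0 or cy + r >= h or cx + r >= w:
                raise ValueError("cell ellipse does not fit inside the image")


@dataclass
class SyntheticScene:
    """A generated scene: RGB image, exact truth mask, and its spec."""

    image: np.ndarray
    truth: BinaryMask
    spec: SyntheticSceneSpec
    cell_tone_hsi: np.ndarray = None    # HSI tones placed in cells, pre-granule


def _sample_inside(region: EllipsoidRegion, n: int, quantile: float,
                   rng: np.random.Generator) -> np.ndarray:
    """n HSI triples with membership value <= quantile.

    Draws from a Gaussian in the rotated frame (per-axis sigma =
    semi-axis / 2) truncated to the membership-<=-quantile ellipsoid.
    Sampling is exact and O(n): a uniform direction times a radius from
    the inverse CDF of the chi(3) distribution truncated at 2*sqrt(q),
    which stays fast even as the quantile approaches zero.
    """
    from scipy import stats

    cap = 2.0 * np.sqrt(quantile)
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    radii = stats.chi.ppf(rng.uniform(0.0, stats.chi.cdf(cap, df=3), size=n),
                          df=3)
    y = u * radii[:, None] * (region.semi_axes / 2.0)
    return (region.center + y) @ region.rotation


def _ellipse_mask(shape, center, axes, angle) -> np.ndarray:
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    dy, dx = rows - center[0], cols - center[1]
    c, s = np.cos(angle), np.sin(angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def generate_scene(spec: SyntheticSceneSpec) -> SyntheticScene:
    """Render a scene deterministically from its spec.

    Cell pixels receive RGB tones converted from HSI samples whose
    membership value under ``spec.tone_region`` is at most
    ``spec.tone_quantile``; granules and speckles are injected afterward,
    so ``cell_tone_hsi`` records the clean tones.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    img = np.asarray(spec.background_rgb, dtype=np.float64) + rng.uniform(
        -spec.background_jitter, spec.background_jitter, size=(h, w, 3))

    truth = np.zeros((h, w), dtype=bool)
    for center, axes, angle in spec.cells:
        truth |= _ellipse_mask((h, w), center, axes, angle)

    n_cell = int(truth.sum())
    tones = np.empty((0, 3))
    if n_cell:
        tones = _sample_inside(spec.tone_region, n_cell, spec.tone_quantile, rng)
        img[truth] = hsi_to_rgb(tones)

    # granules: off-region disks inside the cell (basophil-like occlusion)
    if n_cell and spec.granule_density > 0:
        n_gran = rng.poisson(spec.granule_density * n_cell / 100.0)
        cell_rows, cell_cols = np.nonzero(truth)
        if n_gran > 0:
            pick = rng.integers(0, n_cell, size=n_gran)
            for gy, gx in zip(cell_rows[pick], cell_cols[pick]):
                disk = _ellipse_mask((h, w), (gy, gx),
                                     (spec.granule_radius, spec.granule_radius), 0.0)
                disk &= truth
                jitter = rng.uniform(-10, 10, size=3)
                img[disk] = np.clip(np.asarray(spec.granule_rgb) + jitter, 0, 255)

    # speckle: isolated cell-tone pixels on the background
    if spec.speckle_fraction > 0:
        bg_rows, bg_cols = np.nonzero(~truth)
        n_bg = bg_rows.size
        n_spk = int(round(spec.speckle_fraction * n_bg))
        if n_spk > 0:
            pick = rng.choice(n_bg, size=n_spk, replace=False)
            spk = _sample_inside(spec.tone_region, n_spk, spec.tone_quantile, rng)
            img[bg_rows[pick], bg_cols[pick]] = hsi_to_rgb(spk)

    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SyntheticScene(image=image,
                          truth=BinaryMask(truth, provenance="ground-truth"),
                          spec=spec, cell_tone_hsi=tones)


def sample_region_pixels(region: EllipsoidRegion, n: int,
                         quantile: float = 0.9, seed: int = 0) -> PixelSampleSet:
    """Draw n HSI pixel samples from inside a tone region.

    Emulates collecting cell pixels from expert-segmented images: every
    returned triple has membership value at most ``quantile``.  As the
    quantile approaches zero the samples collapse onto the pre-image of
    the region center.
    """
    if n < 4:
        raise ValueError("need n >= 4 samples")
    rng = np.random.default_rng(seed)
    samples = _sample_inside(region, n, quantile, rng)
    return PixelSampleSet(samples=samples, source_label=f"synthetic-q{quantile}")


# plausible per-feature location/scale for the 20-feature space
_FEATURE_LOC = np.array([3000.0, 12.0, 45.0, 60.0, 0.004, 0.003]
                        + [0.12] * 14)
_FEATURE_SCALE = np.array([250.0, 3.0, 4.0, 6.0, 0.0008, 0.0006]
                          + [0.012] * 14)


def generate_feature_dataset(n_per_class: int = 50, separation: float = 5.0,
                             seed: int = 0):
    """Five Gaussian clusters in the 20-feature space.

    Each cluster centroid lies at distance ``separation`` (in units of
    the per-feature standard deviation) from the shared feature-space
    center, along mutually orthogonal directions, so pairwise centroid
    distances are ``separation * sqrt(2)``.  The latent standard-normal
    draws are mapped onto plausible feature scales, so areas stay
    positive and LDP frequencies stay inside [0, 1].

    Returns
    -------
    (X, y) : ((5 * n_per_class, 20) float array, object array of labels)
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    n_feat = len(FEATURE_NAMES)
    # 5 orthonormal centroid directions at radius `separation`
    q, _ = np.linalg.qr(rng.standard_normal((n_feat, 5)))
    centroids = separation * q.T                       # (5, 20)

    X = np.empty((5 * n_per_class, n_feat))
    y = np.empty(5 * n_per_class, dtype=object)
    for k, cls in enumerate(CLASS_LABELS):
        z = centroids[k] + rng.standard_normal((n_per_class, n_feat))
        sl = slice(k * n_per_class, (k + 1) * n_per_class)
        X[sl] = _FEATURE_LOC + _FEATURE_SCALE * z
        y[sl] = cls
    X[:, 0] = np.maximum(X[:, 0], 1.0)                 # area > 0
    X[:, 1:6] = np.maximum(X[:, 1:6], 0.0)             # variances, comp >= 0
    X[:, 6:] = np.clip(X[:, 6:], 0.0, 1.0)             # ldp in [0, 1]
    return X, y
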