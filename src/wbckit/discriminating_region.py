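"""Ellipsoidal discriminating regions of white-blood-cell tones in HSI space.

A stained leukocyte's nucleus and granular cytoplasm occupy a compact,
obliquely oriented cluster in the HSI color space.  The cluster is modeled
as a rotated ellipsoid: a 3x3 rotation matrix ``R`` aligns the principal
axes of the pixel cloud with the coordinate axes, and a pixel (H, S, I)
belongs to the region iff

    (H' - C_H)^2 / r_H^2 + (S' - C_S)^2 / r_S^2 + (I' - C_I)^2 / r_I^2 <= 1

where (H', S', I') = R (H, S, I), (C_H, C_S, C_I) is the center in rotated
coordinates and (r_H, r_S, r_I) are the semi-axes.  ``membership`` returns
the left-hand side; values <= 1 are claimed cell pixels.

Fitting uses PCA on labeled cell-pixel samples; semi-axes are set by a
per-axis quantile rule followed by a global bisection so that a requested
fraction of the samples falls inside the ellipsoid.

Two literature presets are shipped verbatim for two staining protocols
(May Grünwald Giemsa and Wright).  Their source does not state the HSI
channel scaling they were fitted under, so they carry
``convention_tag="paper-unknown"`` and are stored exactly as printed
(their rotation matrices are not orthonormal to printed precision).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EllipsoidRegion", "PixelSampleSet", "fit_region", "membership",
    "membership_image", "preset_region", "save_region", "load_region",
]


@dataclass
class EllipsoidRegion:
    """A rotated ellipsoid in HSI space.

    Attributes
    ----------
    rotation : (3, 3) array
        Rotation matrix; rows are the principal axes.
    center : (3,) array
        Ellipsoid center in *rotated* coordinates.
    semi_axes : (3,) array
        Strictly positive semi-axis lengths (r_H, r_S, r_I).
    convention_tag : str
        Label of the HSI scaling convention the region was fitted under.
    """

    rotation: np.ndarray
    center: np.ndarray
    semi_axes: np.ndarray
    convention_tag: str = "gw-degrees-unit"

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        self.semi_axes = np.asarray(self.semi_axes, dtype=np.float64).reshape(3)
        if not np.all(self.semi_axes > 0):
            raise ValueError("semi-axes must be strictly positive")

    @property
    def center_preimage(self) -> np.ndarray:
        """The HSI triple that maps onto the center (membership 0).

        Computed with the true inverse rather than the transpose so it is
        exact even for the shipped presets, whose printed matrices are
        not orthonormal to printed precision.
        """
        return np.linalg.solve(self.rotation, self.center)


@dataclass
class PixelSampleSet:
    """Labeled HSI pixel samples used for region fitting."""

    samples: np.ndarray
    source_label: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an N x 3 array of HSI triples")
        if self.samples.shape[0] < 4:
            raise ValueError("need at least 4 samples for a non-degenerate fit")


def membership(region: EllipsoidRegion, hsi) -> float:
    """Evaluate the ellipsoid quadratic form at one HSI triple.

    Returns the nonnegative left-hand side of the region inequality; the
    pixel is claimed a cell pixel iff the value is <= 1.  The value is 0
    exactly at the pre-image of the center.
    """
    v = region.rotation @ np.asarray(hsi, dtype=np.float64).reshape(3)
    d = (v - region.center) / region.semi_axes
    return float(d @ d)


def membership_image(region: EllipsoidRegion, hsi: np.ndarray) -> np.ndarray:
    """Vectorized membership over an (..., 3) array of HSI triples."""
    arr = np.asarray(hsi, dtype=np.float64)
    v = arr @ region.rotation.T
    d = (v - region.center) / region.semi_axes
    return np.einsum("...i,...i->...", d, d)


def fit_region(samples: PixelSampleSet, coverage: float = 0.975,
               tol: float = 0.005) -> EllipsoidRegion:
    """Fit a rotated ellipsoid to cell-pixel samples by PCA.

    The rotation is the transposed eigenvector matrix of the sample
    covariance (rows = principal axes, sorted by descending eigenvalue,
    each row's sign fixed so its largest-magnitude entry is positive).
    Semi-axes start from the per-axis ``coverage**(1/3)`` quantile of the
    absolute projected deviation and are then scaled by a single global
    factor, found by bisection, so that the fraction of samples inside the
    ellipsoid matches ``coverage`` to within ``tol``.

    Parameters
    ----------
    samples : PixelSampleSet
        At least 4 HSI triples with full-rank covariance.
    coverage : float in (0, 1]
        Target fraction of samples with membership <= 1.

    Raises
    ------
    ValueError
        If coverage is outside (0, 1] or the sample covariance is
        rank-deficient (degenerate cloud).
    """
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must lie in (0, 1]")
    x = samples.samples
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    if np.linalg.matrix_rank(cov, tol=1e-12 * max(1.0, np.abs(cov).max())) < 3:
        raise ValueError("degenerate samples: covariance is rank-deficient")

    evals, evecs = np.linalg.eigh(cov)        # ascending
    order = np.argsort(evals)[::-1]
    rotation = evecs[:, order].T              # rows = principal axes
    # sign rule: largest-magnitude entry of each row positive.  This may
    # yield a left-handed frame, which is still a valid orthonormal change
    # of basis for the quadratic form.
    for k in range(3):
        j = np.argmax(np.abs(rotation[k]))
        if rotation[k, j] < 0:
            rotation[k] = -rotation[k]

    center = rotation @ mean
    proj = x @ rotation.T - center            # centered rotated coordinates
    q = coverage ** (1.0 / 3.0)
    base = np.quantile(np.abs(proj), q, axis=0)
    base = np.maximum(base, 1e-12)

    def inside_frac(scale: float) -> float:
        d = proj / (base * scale)
        return float(np.mean(np.einsum("ij,ij->i", d, d) <= 1.0))

    lo, hi = 1e-6, 1.0
    while inside_frac(hi) < coverage and hi < 1e6:
        hi *= 2.0
    scale = hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f = inside_frac(mid)
        if abs(f - coverage) <= tol:
            scale = mid
            break
        if f < coverage:
            lo = mid
        else:
            hi = mid
        scale = hi
    return EllipsoidRegion(rotation=rotation, center=center,
                           semi_axes=base * scale)


# Published discriminating regions for the two staining protocols.  The
# constants are reproduced verbatim; the HSI scaling they assume is not
# recoverable, hence the "paper-unknown" tag.
_PRESETS = {
    1: dict(
        rotation=[[-0.6590, 0.3518, -0.7135],
                  [0.7527, 0.5438, 0.3711],
                  [-0.2574, 0.7620, 0.5943]],
        center=[6.042, 2.916, 0.252],
        semi_axes=[52.645, 17.274, 11.154],
    ),
    2: dict(
        rotation=[[-0.3683, 0.5550, -0.7459],
                  [0.8238, 0.5667, 0.0149],
                  [-0.4309, 0.6090, 0.6659]],
        center=[-16.433, -0.0512, -8.735],
        semi_axes=[56.761, 40.027, 21.894],
    ),
}


def preset_region(dataset_id: int) -> EllipsoidRegion:
    """Return the published discriminating region for data set 1 or 2.

    Data set 1 covers May Grünwald Giemsa staining, data set 2 Wright
    staining.  Constants are stored exactly as printed in the source;
    ``convention_tag`` is ``"paper-unknown"`` because the HSI scaling
    used to fit them was never stated.
    """
    if dataset_id not in _PRESETS:
        raise ValueError(f"dataset_id must be 1 or 2, got {dataset_id!r}")
    p = _PRESETS[dataset_id]
    return EllipsoidRegion(rotation=p["rotation"], center=p["center"],
                           semi_axes=p["semi_axes"],
                           convention_tag="paper-unknown")


def save_region(region: EllipsoidRegion, path) -> None:
    """Serialize a region to JSON at full double precision."""
    doc = {
        "rotation": region.rotation.tolist(),
        "center": region.center.tolist(),
        "semi_axes": region.semi_axes.tolist(),
        "convention_tag": region.convention_tag,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_region(path) -> EllipsoidRegion:
    """Load a region written by :func:`save_region`.

    Raises
    ------
    ValueError
        If the file is not valid JSON or a required field is missing.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed region file {path!r}: {exc}") from exc
    missing = {"rotation", "center", "semi_axes"} - set(doc)
    if missing:
        raise ValueError(f"region file {path!r} missing fields: {sorted(missing)}")
    return EllipsoidRegion(rotation=doc["rotation"], center=doc["center"],
                           semi_axes=doc["semi_axes"],
                           convention_tag=doc.get("convention_tag", "unknown"))
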