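"""Image I/O and RGB <-> HSI conversion.

One scaling convention is used everywhere downstream: hue in degrees on
[0, 360), saturation and intensity on [0, 1].  The conversion is the
classical arccos (chromatic-angle) HSI model:

    I = (R + G + B) / (3 * 255)
    S = 1 - min(R, G, B) / mean(R, G, B)        (S := 0 when mean = 0)
    H = theta            if B <= G
      = 360 - theta      if B >  G
    theta = arccos( ((R-G) + (R-B)) / 2 / sqrt((R-G)^2 + (R-B)(G-B)) )

Achromatic pixels (S = 0) get H := 0 by convention so the conversion is
total and deterministic.  All arithmetic is double precision; H/S/I are
never quantized.
"""

from __future__ import annotations

import numpy as np
from PIL import Image


def read_image(path) -> np.ndarray:
    """Read a raster image (PNG/TIFF/BMP...) as an H x W x 3 uint8 array.

    Palette and RGBA images are converted to RGB.  Grayscale is expanded
    to three identical channels.

    Raises
    ------
    OSError
        If the file does not exist, is truncated, or is not a supported
        raster format.
    """
    with Image.open(path) as im:
        rgb = im.convert("RGB")
        arr = np.asarray(rgb, dtype=np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise OSError(f"{path!r} did not decode to an RGB image")
    return arr


def write_image(path, pixels: np.ndarray) -> None:
    """Write an H x W x 3 array (values in [0, 255]) or an H x W boolean
    mask (written as 0/255 grayscale) as an 8-bit image."""
    arr = np.asarray(pixels)
    if arr.dtype == bool:
        arr = (arr.astype(np.uint8)) * 255
        Image.fromarray(arr, mode="L").save(path)
        return
    arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)
    return


def rgb_to_hsi(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image (channels in [0, 255]) to HSI.

    Parameters
    ----------
    img : (H, W, 3) array
        RGB channels in [0, 255] (integer or real).

    Returns
    -------
    (H, W, 3) float64 array with hue in degrees [0, 360), saturation and
    intensity in [0, 1].
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB array")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    total = r + g + b

    intensity = total / (3.0 * 255.0)

    minimum = np.minimum(np.minimum(r, g), b)
    with np.errstate(divide="ignore", invalid="ignore"):
        saturation = np.where(total > 0, 1.0 - 3.0 * minimum / total, 0.0)
    saturation = np.clip(saturation, 0.0, 1.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.where(den > 0, num / den, 1.0)
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    hue = np.where(b > g, 360.0 - theta, theta)
    # achromatic convention, and keep the half-open range
    hue = np.where(saturation == 0.0, 0.0, hue)
    hue = np.where(hue >= 360.0, 0.0, hue)

    return np.stack([hue, saturation, intensity], axis=-1)


def hsi_to_rgb(hsi: np.ndarray) -> np.ndarray:
    """Invert the arccos HSI model back to RGB in [0, 255] (float64).

    Uses the standard sector construction: the hue circle splits into the
    RG (0-120 deg), GB (120-240 deg) and BR (240-360 deg) sectors, and in
    each sector one channel equals I(1-S) while the leading channel is
    I(1 + S cos(h) / cos(60 - h)).
    """
    arr = np.asarray(hsi, dtype=np.float64)
    h = np.mod(arr[..., 0], 360.0)
    s = np.clip(arr[..., 1], 0.0, 1.0)
    i = np.clip(arr[..., 2], 0.0, 1.0)

    r = np.empty_like(i)
    g = np.empty_like(i)
    b = np.empty_like(i)

    def sector(hh):
        rad = np.radians(hh)
        lead = i * (1.0 + s * np.cos(rad) / np.cos(np.radians(60.0) - rad))
        low = i * (1.0 - s)
        return lead, low

    m0 = h < 120.0
    m1 = (h >= 120.0) & (h < 240.0)
    m2 = h >= 240.0

    lead, low = sector(h)
    r[m0], b[m0] = lead[m0], low[m0]
    g[m0] = 3.0 * i[m0] - (r[m0] + b[m0])

    lead, low = sector(h - 120.0)
    g[m1], r[m1] = lead[m1], low[m1]
    b[m1] = 3.0 * i[m1] - (r[m1] + g[m1])

    lead, low = sector(h - 240.0)
    b[m2], g[m2] = lead[m2], low[m2]
    r[m2] = 3.0 * i[m2] - (g[m2] + b[m2])

    rgb = np.stack([r, g, b], axis=-1) * 255.0
    return np.clip(rgb, 0.0, 255.0)
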