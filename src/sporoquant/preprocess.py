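"""Background correction: blank subtraction and rolling-ball flattening.

Macroscopic scans are corrected by subtracting a blank scan of the empty
apparatus (clamped at zero, never wrapped). Microscopic patches are
flattened with Sternberg's rolling-ball background, realised as a grayscale
opening with a ball-shaped structuring element; large radii use the standard
shrink/enlarge speed-up, with the output forced below the input so the
defining inequality ``background <= image`` holds exactly.

Bright particles on a dark background are assumed throughout; invert first
for the opposite polarity.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage import transform

from .image import GrayImage

logger = logging.getLogger(__name__)


def _ball_opening(img: np.ndarray, radius: float) -> np.ndarray:
    """Grayscale opening with a ball structuring function of given radius.

    Erosion then dilation with the ball's upper surface b(y) = sqrt(r² − |y|²)
    traces the hull a ball of that radius reaches rolling under the
    intensity surface — the Sternberg rolling-ball background.
    """
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = yy**2 + xx**2
    footprint = d2 <= radius**2
    heights = np.sqrt(np.maximum(radius**2 - d2, 0.0))
    eroded = ndi.grey_erosion(img.astype(float), footprint=footprint, structure=heights,
                              mode="nearest")
    return ndi.grey_dilation(eroded, footprint=footprint, structure=heights, mode="nearest")


def subtract_blank(sample: GrayImage, blank: GrayImage) -> GrayImage:
    """Pixelwise ``max(sample - blank, 0)``.

    Mirrors the "Subtract" mode of common image calculators: the result is
    clamped at zero rather than wrapping around the 8-bit range.
    """
    if sample.shape != blank.shape:
        raise ValueError(
            f"sample shape {sample.shape} and blank shape {blank.shape} do not match"
        )
    diff = sample.pixels.astype(np.int16) - blank.pixels.astype(np.int16)
    out = np.clip(diff, 0, 255).astype(np.uint8)
    return GrayImage(out, scale_um_per_px=sample.scale_um_per_px, provenance="blank-subtracted")


def invert(img: GrayImage) -> GrayImage:
    """255 - pixels, for dark-particles-on-bright-background inputs."""
    return img.with_pixels(255 - img.pixels, provenance=img.provenance + "+inverted")


def _shrink_factor(radius_px: float) -> int:
    # standard speed-up ladder: small radii exact, large radii on a
    # downsampled copy with a proportionally smaller ball
    if radius_px <= 16:
        return 1
    if radius_px <= 32:
        return 2
    if radius_px <= 100:
        return 4
    return 8


def rolling_ball_background(
    img: GrayImage, radius_px: float, shrink: int | None = None
) -> tuple[GrayImage, GrayImage]:
    """Estimate a smooth background by the rolling-ball algorithm.

    A ball of the given radius is rolled under the intensity surface; the
    hull it traces is the background. Subtracting it flattens uneven
    illumination while leaving particles smaller than the ball intact.

    Parameters
    ----------
    img
        Input image (bright particles on dark background).
    radius_px
        Ball radius in pixels; >= 1. Choose it clearly larger than the
        particles of interest (a common rule is ~3x the particle diameter).
    shrink
        Integer downsampling factor for the fast path; ``None`` selects it
        automatically from the radius (1 for radius <= 16, i.e. exact).

    Returns
    -------
    (background, corrected)
        Both 8-bit; ``background <= img`` pixelwise and
        ``corrected = clip(img - background, 0, 255)``.
    """
    if not radius_px >= 1:
        raise ValueError(f"radius_px must be >= 1, got {radius_px}")
    px = img.pixels
    h, w = px.shape
    if radius_px >= h and radius_px >= w:
        logger.warning(
            "rolling-ball radius %.1f exceeds image size %dx%d; "
            "background degenerates to the global minimum",
            radius_px, h, w,
        )
        bg = np.full_like(px, px.min())
    else:
        s = _shrink_factor(radius_px) if shrink is None else int(shrink)
        if s <= 1:
            bg = _ball_opening(px, radius_px)
        else:
            small = transform.resize(
                px.astype(float), (max(1, h // s), max(1, w // s)),
                order=1, anti_aliasing=True, preserve_range=True,
            )
            bg_small = _ball_opening(small, max(1.0, radius_px / s))
            bg = transform.resize(bg_small, (h, w), order=1, preserve_range=True)
        bg = np.minimum(np.clip(np.rint(bg), 0, 255).astype(np.uint8), px)
    corrected = (px.astype(np.int16) - bg.astype(np.int16)).clip(0, 255).astype(np.uint8)
    background = GrayImage(bg, scale_um_per_px=img.scale_um_per_px, provenance="rolling-ball-background")
    out = GrayImage(corrected, scale_um_per_px=img.scale_um_per_px, provenance="rolling-ball-corrected")
    return background, out
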