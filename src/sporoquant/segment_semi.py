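"""Semi-automatic conidia counting (SACC).

The operator (or a batch parameter file) supplies two numbers per patch: an
intensity threshold ``t`` separating conidia from background, and a
``prominence`` controlling how many local intensity maxima count as
conidia. Maxima seed a marker-controlled watershed on the inverted
intensity, so fused clusters are split at intensity saddles rather than by
shape alone — the reason the semi-automatic route resolves clusters that
the automatic one merges.

Prominence semantics: a maximum's prominence is its height above the
highest saddle connecting it to higher terrain, evaluated within the
above-threshold region only (pixels below ``t`` are treated as level 0).
A maximum is reported when its prominence is >= the requested value; the
highest point of each connected above-threshold region has no higher
neighbour, so its prominence is its own height. Plateau maxima contribute a
single representative point: the plateau centroid rounded toward the
top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import segmentation

from ._peaks import prominent_max_regions
from .image import GrayImage
from .segment_auto import AccConfig, ParticleSet, analyze_particles

_N8 = np.ones((3, 3), dtype=int)


@dataclass
class MaximaSet:
    """Detected local maxima: one row per (x, y, intensity, prominence)."""

    points: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["x_px", "y_px", "intensity", "prominence"])
    )
    threshold: int = 0
    prominence: float = 1.0

    @property
    def count(self) -> int:
        return len(self.points)


def apply_threshold(img: GrayImage, t: int) -> GrayImage:
    """Mark pixels below ``t`` as background (0); others keep their value."""
    if not 0 <= t <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {t}")
    out = np.where(img.pixels >= t, img.pixels, 0).astype(np.uint8)
    return GrayImage(out, scale_um_per_px=img.scale_um_per_px, provenance="thresholded")


def find_maxima(img: GrayImage, t: int, prominence: float) -> MaximaSet:
    """Detect local intensity maxima with at least the given prominence.

    Lower prominence yields more maxima, higher prominence fewer; the count
    is non-increasing in ``prominence``. Implemented by h-maxima transform
    (morphological reconstruction) on the thresholded image.
    """
    if not prominence > 0:
        raise ValueError(f"prominence must be positive, got {prominence}")
    if not 0 <= t <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {t}")
    f = np.where(img.pixels >= t, img.pixels.astype(float), 0.0)
    if not (f > 0).any():
        return MaximaSet(threshold=t, prominence=prominence)
    # pixel values are integers, so dynamics are too: shifting the cut by
    # half a gray level turns the strict criterion into the inclusive
    # "prominence >= requested" one
    peaks = prominent_max_regions(f, prominence - 0.5)
    peaks &= f > 0
    if not peaks.any():
        # every peak merged into one flood level (reconstruction constant):
        # keep a single representative top plateau per connected region
        comps, nc = ndi.label(f > 0, structure=_N8)
        for i in range(1, nc + 1):
            comp = comps == i
            plateaus, _ = ndi.label(comp & (f == f[comp].max()), structure=_N8)
            first = plateaus.ravel()[np.flatnonzero(plateaus.ravel())[0]]
            peaks |= plateaus == first
    labels, n = ndi.label(peaks, structure=_N8)
    rows = []
    for i in range(1, n + 1):
        ys, xs = np.nonzero(labels == i)
        # plateau representative: centroid rounded toward the top-left
        y = int(np.floor(ys.mean()))
        x = int(np.floor(xs.mean()))
        peak_val = int(img.pixels[ys, xs].max())
        if peak_val < prominence:
            # the top of an above-threshold region: its prominence is its
            # own height over the masked floor, so it fails the criterion
            continue
        rows.append(dict(x_px=x, y_px=y, intensity=peak_val, prominence=float(prominence)))
    points = pd.DataFrame(rows, columns=["x_px", "y_px", "intensity", "prominence"])
    points = points.sort_values(["y_px", "x_px"], ignore_index=True)
    return MaximaSet(points=points, threshold=t, prominence=prominence)


def segment_from_maxima(img: GrayImage, maxima: MaximaSet) -> np.ndarray:
    """Marker-controlled watershed of the above-threshold region.

    Each maximum seeds one catchment basin on the inverted intensity
    surface, restricted to pixels >= the maxima set's threshold; basin
    boundary lines are left unlabelled so touching labels remain distinct.
    Returns an int label image with one label per marker (0 = background).
    """
    h, w = img.shape
    mask = img.pixels >= maxima.threshold
    # the thresholded region may include t == 0 background; treat gray 0 as
    # background only when the threshold itself is 0 and nothing else exists
    markers = np.zeros((h, w), dtype=np.int32)
    for i, row in maxima.points.iterrows():
        y, x = int(row["y_px"]), int(row["x_px"])
        if not (0 <= y < h and 0 <= x < w):
            raise ValueError(f"maximum at ({x}, {y}) lies outside the {w}x{h} image")
        markers[y, x] = i + 1
    if maxima.count == 0:
        return np.zeros((h, w), dtype=np.int32)
    labels = segmentation.watershed(
        255 - img.pixels.astype(np.int16), markers=markers, mask=mask, watershed_line=True
    )
    return labels.astype(np.int32)


def count_semi(
    patch: GrayImage,
    t: int,
    prominence: float,
    config: AccConfig | None = None,
    smooth_sigma: float = 1.0,
) -> ParticleSet:
    """Run the full semi-automatic counting chain on one patch.

    threshold → prominence-filtered maxima → marker watershed → particle
    analysis (same filters as the automatic route). ``t`` and ``prominence``
    are echoed into ``result.params``.

    A light Gaussian pre-smooth (``smooth_sigma``, in px; 0 disables)
    suppresses single-pixel sensor-noise maxima so a prominence chosen for
    the particles' intensity structure is not swamped by noise peaks — the
    batch stand-in for the operator visually tuning the prominence per
    image.
    """
    cfg = config or AccConfig()
    d = cfg.derived(patch.scale_um_per_px)
    work = patch
    if smooth_sigma > 0:
        work = GrayImage.from_float(
            ndi.gaussian_filter(patch.pixels.astype(float), smooth_sigma),
            scale_um_per_px=patch.scale_um_per_px,
            provenance=patch.provenance + "+smoothed",
        )
    maxima = find_maxima(work, t, prominence)
    labels = segment_from_maxima(work, maxima)
    result = analyze_particles(
        labels,
        min_area_px=d["min_area_px"],
        max_area_px=d["max_area_px"],
        min_circularity=cfg.min_circularity,
        exclude_edge_particles=cfg.exclude_edge_particles,
        scale_um_per_px=patch.scale_um_per_px,
    )
    result.params.update(threshold=t, prominence=prominence, n_maxima=maxima.count)
    return result
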