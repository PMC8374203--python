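"""Automatic conidia counting (ACC).

Fixed pipeline: rolling-ball background subtraction → intensity threshold →
distance-transform watershed with an adjustable merge tolerance → particle
analysis with size/shape filters. No per-image operator input is required;
every parameter is recorded in the result so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, segmentation

from ._peaks import prominent_max_regions
from .image import GrayImage
from .preprocess import rolling_ball_background

PARTICLE_PROPS = ["label", "area_px", "area_um2", "centroid_y", "centroid_x",
                  "equivalent_diameter_px", "circularity"]


@dataclass
class BinaryMask:
    """Thresholding result: candidate conidium pixels plus the rule used."""

    mask: np.ndarray           # 2-D bool
    threshold: float           # gray level actually applied
    method: str                # "otsu" | "fixed:t" | "percentile:p"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")


@dataclass
class ParticleSet:
    """Per-particle measurements and the particle count for one patch."""

    particles: pd.DataFrame
    patch_area_cm2: float | None = None
    params: dict = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.particles)

    def density(self) -> float:
        """Conidia per cm²; requires patch area metadata."""
        from .calibrate import density_from_count

        if self.patch_area_cm2 is None:
            raise ValueError("patch has no physical area (missing scale metadata)")
        return density_from_count(self.count, self.patch_area_cm2)


@dataclass
class AccConfig:
    """Tunable parameters of the automatic pipeline.

    Size-dependent defaults (rolling-ball radius, area filters) derive from
    the expected conidium axes so the pipeline adapts to the image scale:
    rolling-ball radius 3× the expected major axis, minimum particle area
    25 % of the expected conidium area, maximum 10×.
    """

    expected_conidium_axes_um: tuple[float, float] = (20.0, 14.0)
    rolling_ball_radius_px: float | None = None
    threshold_method: str = "otsu"
    merge_tolerance: float = 0.5
    min_area_fraction: float = 0.25
    max_area_factor: float = 10.0
    min_circularity: float = 0.0
    exclude_edge_particles: bool = False
    apply_rolling_ball: bool = True
    # automatic thresholds always "find" a split, even on particle-free
    # noise; a threshold below this floor means background only
    min_threshold: float = 25.0

    def derived(self, scale_um_per_px: float | None) -> dict:
        scale = 1.0 if scale_um_per_px is None else scale_um_per_px
        sa = self.expected_conidium_axes_um[0] / 2.0 / scale
        sb = self.expected_conidium_axes_um[1] / 2.0 / scale
        area = np.pi * sa * sb
        radius = self.rolling_ball_radius_px
        if radius is None:
            radius = 3.0 * (2 * sa)
        return dict(
            rolling_ball_radius_px=float(radius),
            min_area_px=int(round(self.min_area_fraction * area)),
            max_area_px=int(round(self.max_area_factor * area)),
        )


def binarize(img: GrayImage, method: str = "otsu") -> BinaryMask:
    """Threshold a background-corrected patch into a candidate-conidium mask.

    ``method`` is one of ``"otsu"`` (automatic, bimodal histogram),
    ``"fixed:<t>"`` (explicit gray level) or ``"percentile:<p>"`` (threshold
    at the p-th intensity percentile). The mask is true where intensity is
    greater than or equal to the threshold.
    """
    px = img.pixels
    if method == "otsu":
        if px.min() == px.max():
            raise ValueError("otsu thresholding is undefined on a constant image")
        # threshold_otsu returns the upper edge of the background class;
        # foreground is strictly above it, so apply t+1 with >= semantics
        t = float(filters.threshold_otsu(px)) + 1.0
    elif method.startswith("fixed:"):
        t = float(method.split(":", 1)[1])
        if not 0 <= t <= 255:
            raise ValueError(f"fixed threshold must be in [0, 255], got {t}")
    elif method.startswith("percentile:"):
        p = float(method.split(":", 1)[1])
        if not 0 <= p <= 100:
            raise ValueError(f"percentile must be in [0, 100], got {p}")
        t = float(np.percentile(px, p))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return BinaryMask(mask=px >= t, threshold=t, method=method)


def adjustable_watershed(mask: np.ndarray | BinaryMask, merge_tolerance: float = 0.5) -> np.ndarray:
    """Split touching particles by a distance-transform watershed.

    The Euclidean distance map of the foreground is flooded from its local
    maxima; catchment basins whose maxima rise less than ``merge_tolerance``
    above the saddle towards a deeper basin are merged (h-maxima marker
    suppression), which is the single "sensitivity" knob of the adjustable
    watershed. Watershed-line pixels are left as background, so touching
    labels stay separated in the binary sense.

    Returns an int label image (0 = background).
    """
    if isinstance(mask, BinaryMask):
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    if merge_tolerance < 0:
        raise ValueError("merge_tolerance must be non-negative")
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    peaks = prominent_max_regions(dist, merge_tolerance) & mask
    # a tolerance above every peak height leaves a component markerless;
    # merging "everything" still means one basin per connected blob
    s8 = np.ones((3, 3), dtype=int)
    comps, nc = ndi.label(mask, structure=s8)
    marked = np.unique(comps[peaks])
    for i in np.setdiff1d(np.arange(1, nc + 1), marked):
        # one marker only: equal-height tops may be disjoint pixels, and
        # splitting a fully-merged blob would defeat the merge
        flat = np.where((comps == i).ravel(), dist.ravel(), -1.0)
        peaks.ravel()[int(flat.argmax())] = True
    markers, _ = ndi.label(peaks, structure=s8)
    labels = segmentation.watershed(-dist, markers=markers, mask=mask, watershed_line=True)
    return labels.astype(np.int32)


def analyze_particles(
    labels: np.ndarray,
    min_area_px: int = 0,
    max_area_px: int | None = None,
    min_circularity: float = 0.0,
    exclude_edge_particles: bool = False,
    scale_um_per_px: float | None = None,
) -> ParticleSet:
    """Measure labelled particles and apply size/shape filters.

    Circularity is the shape factor 4πA/P² (1 for a perfect disk), capped at
    1.0 to absorb discrete-perimeter overshoot on very small particles.
    Particles outside [min_area_px, max_area_px], below ``min_circularity``,
    or touching the image border (when ``exclude_edge_particles``) are
    dropped.
    """
    if max_area_px is not None and min_area_px > max_area_px:
        raise ValueError(f"min_area_px {min_area_px} exceeds max_area_px {max_area_px}")
    labels = np.asarray(labels)
    rows = []
    h, w = labels.shape
    for rp in measure.regionprops(labels):
        area = int(rp.area)
        if area < min_area_px:
            continue
        if max_area_px is not None and area > max_area_px:
            continue
        perim = float(rp.perimeter)
        circ = 1.0 if perim == 0 else min(1.0, 4 * np.pi * area / perim**2)
        if circ < min_circularity:
            continue
        if exclude_edge_particles:
            r0, c0, r1, c1 = rp.bbox
            if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
                continue
        cy, cx = rp.centroid
        rows.append(
            dict(
                label=int(rp.label),
                area_px=area,
                area_um2=area * scale_um_per_px**2 if scale_um_per_px else np.nan,
                centroid_y=cy,
                centroid_x=cx,
                equivalent_diameter_px=float(rp.equivalent_diameter_area),
                circularity=circ,
            )
        )
    df = pd.DataFrame(rows, columns=PARTICLE_PROPS)
    area_cm2 = None
    if scale_um_per_px:
        area_cm2 = (h * scale_um_per_px * 1e-4) * (w * scale_um_per_px * 1e-4)
    return ParticleSet(
        particles=df,
        patch_area_cm2=area_cm2,
        params=dict(
            min_area_px=min_area_px,
            max_area_px=max_area_px,
            min_circularity=min_circularity,
            exclude_edge_particles=exclude_edge_particles,
        ),
    )


def count_auto(patch: GrayImage, config: AccConfig | None = None) -> ParticleSet:
    """Run the full automatic counting chain on one patch.

    rolling-ball correction → threshold → adjustable watershed → particle
    analysis. Deterministic: identical input and configuration give an
    identical :class:`ParticleSet`; all effective parameters are recorded in
    ``result.params``.
    """
    cfg = config or AccConfig()
    d = cfg.derived(patch.scale_um_per_px)
    img = patch
    if cfg.apply_rolling_ball:
        _, img = rolling_ball_background(patch, d["rolling_ball_radius_px"])
    bin_mask = binarize(img, cfg.threshold_method)
    if bin_mask.threshold < cfg.min_threshold:
        bin_mask = BinaryMask(
            mask=np.zeros_like(bin_mask.mask), threshold=bin_mask.threshold,
            method=bin_mask.method + " (below noise floor)",
        )
    labels = adjustable_watershed(bin_mask, cfg.merge_tolerance)
    result = analyze_particles(
        labels,
        min_area_px=d["min_area_px"],
        max_area_px=d["max_area_px"],
        min_circularity=cfg.min_circularity,
        exclude_edge_particles=cfg.exclude_edge_particles,
        scale_um_per_px=patch.scale_um_per_px,
    )
    result.params.update(
        threshold_method=cfg.threshold_method,
        threshold_used=bin_mask.threshold,
        merge_tolerance=cfg.merge_tolerance,
        rolling_ball_radius_px=d["rolling_ball_radius_px"] if cfg.apply_rolling_ball else None,
    )
    return result
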