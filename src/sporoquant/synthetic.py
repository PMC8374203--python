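"""Ground-truthed synthetic scenes for the conidia-quantification pipeline.

Three generators cover the data the method consumes:

* :func:`generate_micro_scene` — a bright-field-like patch of bright,
  roughly elliptical conidia on a dark background, with optional touching
  clusters, germ tubes, and secondary conidia accompanied by faint remnants
  of their collapsed primaries. Every rendered particle is recorded in a
  ground-truth table, so segmentation accuracy can be scored exactly.
* :func:`generate_macro_zone` — a macroscopic sporulation-zone scan whose
  per-cell mean gray value is the inverse of the linear gray↔density map,
  plus seeded Gaussian noise.
* :func:`generate_calibration_set` — paired (gray value, conidia density)
  points scattered around a known line, emulating the statistical structure
  of a counted calibration data set.

Conidia are rendered as filled ellipses with a parabolic "dome" profile
(brightest at the centre, dimmer at the rim), which mimics the lensing of a
spherical spore in bright field and gives touching conidia a genuine
intensity saddle. All randomness flows from a single integer seed; equal
seeds give bit-identical images and truth tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import draw

from .image import GrayImage

logger = logging.getLogger(__name__)

PARTICLE_COLUMNS = ["particle_id", "x_px", "y_px", "type", "germ_tube", "cluster_id"]


class PlacementError(RuntimeError):
    """Raised when conidia cannot be placed without overlap within the retry budget."""


@dataclass
class SceneParams:
    """Parameters of one synthetic microscopic patch.

    Defaults describe the regime the counting pipeline is designed for:
    500 × 500 µm patches at 1 µm/px, pear-shaped conidia idealised as
    20 × 14 µm ellipses, bright particles (~180) on a dark background (~10)
    with mild sensor noise and optical blur.
    """

    patch_size_px: tuple[int, int] = (500, 500)
    scale_um_per_px: float = 1.0
    n_conidia: int = 50
    conidium_axes_um: tuple[float, float] = (20.0, 14.0)
    intensity_mean: float = 180.0
    intensity_sd: float = 15.0
    cluster_fraction: float = 0.0
    cluster_size_range: tuple[int, int] = (2, 4)
    germinated_fraction: float = 0.0
    secondary_fraction: float = 0.0
    remnant_intensity_factor: float = 0.2
    background_level: float = 10.0
    noise_sd: float = 5.0
    blur_sigma_px: float = 1.0
    dome_falloff: float = 0.4   # relative intensity drop centre -> rim
    max_place_attempts: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cluster_fraction", "germinated_fraction", "secondary_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.remnant_intensity_factor < 1.0:
            raise ValueError("remnant_intensity_factor must be in (0, 1): remnants are strictly fainter")
        if self.conidium_axes_um[0] < self.conidium_axes_um[1]:
            raise ValueError("conidium_axes_um must be (major, minor)")
        if self.n_conidia < 0:
            raise ValueError("n_conidia must be non-negative")
        if self.cluster_size_range[0] < 2:
            raise ValueError("cluster_size_range minimum is 2 (a cluster has >= 2 members)")
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be positive")
        if self.noise_sd < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise_sd and blur_sigma_px must be non-negative")
        if not 0.0 <= self.dome_falloff < 1.0:
            raise ValueError("dome_falloff must be in [0, 1)")
        for v in (self.intensity_mean, self.background_level):
            if not 0.0 <= v <= 255.0:
                raise ValueError("intensity levels must be in [0, 255]")


@dataclass
class GroundTruth:
    """Per-particle truth table for a generated scene.

    One row per rendered particle: primary and secondary conidia are
    countable; remnants of collapsed primaries are rendered but are not
    conidia and are excluded from the count.
    """

    particles: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=PARTICLE_COLUMNS)
    )

    @property
    def true_count(self) -> int:
        """Number of countable conidia (primary + secondary, remnants excluded)."""
        if len(self.particles) == 0:
            return 0
        return int((self.particles["type"] != "remnant").sum())

    def to_csv(self, path) -> None:
        self.particles.to_csv(path, index=False)


@dataclass
class _Particle:
    y: float
    x: float
    semi_major: float
    semi_minor: float
    theta: float
    intensity: float
    ptype: str = "primary"
    germ_tube: bool = False
    cluster_id: int | None = None


def _support_radius(semi_major: float, semi_minor: float, theta: float, direction: float) -> float:
    """Half-extent of an ellipse along a direction (support function)."""
    phi = direction - theta
    return float(np.hypot(semi_major * np.cos(phi), semi_minor * np.sin(phi)))


def _too_close(y, x, r, placed: list[_Particle], cluster_id=None, margin: float = 1.0) -> bool:
    for p in placed:
        if cluster_id is not None and p.cluster_id == cluster_id:
            continue
        if np.hypot(p.y - y, p.x - x) < p.semi_major + r + margin:
            return True
    return False


def _place_free(rng, shape, sa, placed, attempts, cluster_id=None) -> tuple[float, float]:
    h, w = shape
    m = sa + 3.0  # keep whole particle inside the frame
    if 2 * m >= h or 2 * m >= w:
        raise PlacementError(f"patch {shape} too small for particles of semi-major {sa:.1f} px")
    for _ in range(attempts):
        y = rng.uniform(m, h - m)
        x = rng.uniform(m, w - m)
        if not _too_close(y, x, sa, placed, cluster_id=cluster_id):
            return y, x
    raise PlacementError(
        f"could not place a particle after {attempts} attempts; "
        "density too high for the patch size"
    )


def generate_micro_scene(params: SceneParams) -> tuple[GrayImage, GroundTruth]:
    """Render one microscopic patch and its ground-truth particle table.

    ``params.n_conidia`` countable conidia are placed: a ``cluster_fraction``
    share in touching clusters (pairwise overlap 20–50 % of the minor axis,
    shallow enough that a watershed split is geometrically possible), the
    rest disjoint. A ``secondary_fraction`` share is marked secondary and
    receives an adjacent remnant ellipse at ``remnant_intensity_factor``
    times the conidium intensity; a ``germinated_fraction`` share grows a
    thin germ tube (width 0.25× minor axis, length 1–2× major axis).

    Raises
    ------
    PlacementError
        If non-overlapping placement fails within ``max_place_attempts``
        tries per particle (density too high for the patch).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.patch_size_px
    scale = params.scale_um_per_px
    sa = params.conidium_axes_um[0] / 2.0 / scale
    sb = params.conidium_axes_um[1] / 2.0 / scale

    n = params.n_conidia
    particles: list[_Particle] = []

    def draw_intensity() -> float:
        return float(np.clip(rng.normal(params.intensity_mean, params.intensity_sd), 1.0, 255.0))

    # partition countable conidia into clusters and singletons
    n_clustered_target = int(round(n * params.cluster_fraction))
    cluster_sizes: list[int] = []
    remaining = n_clustered_target
    lo, hi = params.cluster_size_range
    while remaining >= 2:
        size = int(rng.integers(lo, hi + 1))
        size = min(size, remaining)
        if size < 2:
            break
        cluster_sizes.append(size)
        remaining -= size
    n_single = n - sum(cluster_sizes)

    cid = 0
    for size in cluster_sizes:
        cid += 1
        th = rng.uniform(0, np.pi)
        y0, x0 = _place_free(
            rng, (h, w), sa + 2 * sb, particles, params.max_place_attempts, cluster_id=cid
        )
        seed_p = _Particle(y0, x0, sa, sb, th, draw_intensity(), cluster_id=cid)
        particles.append(seed_p)
        anchors = [seed_p]
        for _ in range(size - 1):
            placed_ok = False
            for _ in range(params.max_place_attempts):
                anchor = anchors[int(rng.integers(0, len(anchors)))]
                direction = rng.uniform(0, 2 * np.pi)
                th2 = rng.uniform(0, np.pi)
                overlap = rng.uniform(0.2, 0.5) * (2 * sb)
                d = (
                    _support_radius(sa, sb, anchor.theta, direction)
                    + _support_radius(sa, sb, th2, direction)
                    - overlap
                )
                y = anchor.y + d * np.sin(direction)
                x = anchor.x + d * np.cos(direction)
                if not (sa + 3 <= y <= h - sa - 3 and sa + 3 <= x <= w - sa - 3):
                    continue
                if _too_close(y, x, sa, particles, cluster_id=cid):
                    continue
                p = _Particle(y, x, sa, sb, th2, draw_intensity(), cluster_id=cid)
                particles.append(p)
                anchors.append(p)
                placed_ok = True
                break
            if not placed_ok:
                raise PlacementError(
                    f"could not place cluster member after {params.max_place_attempts} attempts"
                )

    for _ in range(n_single):
        th = rng.uniform(0, np.pi)
        y, x = _place_free(rng, (h, w), sa, particles, params.max_place_attempts)
        particles.append(_Particle(y, x, sa, sb, th, draw_intensity()))

    # secondary conidia (+ faint remnants) and germ tubes, assigned among
    # singletons so cluster geometry stays controlled
    singles = [p for p in particles if p.cluster_id is None]
    singles = [singles[i] for i in rng.permutation(len(singles))]
    n_secondary = int(round(n * params.secondary_fraction))
    remnants: list[_Particle] = []
    for p in singles[:n_secondary]:
        p.ptype = "secondary"
        for _ in range(params.max_place_attempts):
            direction = rng.uniform(0, 2 * np.pi)
            th_r = rng.uniform(0, np.pi)
            d = (
                _support_radius(p.semi_major, p.semi_minor, p.theta, direction)
                + _support_radius(sa, sb, th_r, direction)
                + 2.0  # small gap: remnant lies beside, not fused to, the secondary
            )
            y = p.y + d * np.sin(direction)
            x = p.x + d * np.cos(direction)
            if not (sa + 3 <= y <= h - sa - 3 and sa + 3 <= x <= w - sa - 3):
                continue
            others = [q for q in particles + remnants if q is not p]
            if _too_close(y, x, sa, others):
                continue
            remnants.append(
                _Particle(
                    y, x, sa, sb, th_r,
                    params.remnant_intensity_factor * p.intensity,
                    ptype="remnant",
                )
            )
            break
        else:
            raise PlacementError("could not place a primary-conidium remnant")

    n_germ = int(round(n * params.germinated_fraction))
    germ_candidates = [p for p in singles[n_secondary:]]
    tubes: list[tuple[_Particle, float, float]] = []  # (owner, length, direction)
    for p in germ_candidates[:n_germ]:
        p.germ_tube = True
        length = rng.uniform(1.0, 2.0) * (2 * sa)
        direction = p.theta + rng.choice([0.0, np.pi])  # grows from a pole
        tubes.append((p, length, direction))

    # ---- render -------------------------------------------------------
    canvas = np.full((h, w), float(params.background_level))
    yy, xx = np.mgrid[0:h, 0:w]

    def paint_ellipse(p: _Particle) -> None:
        r0 = max(0, int(np.floor(p.y - p.semi_major - 1)))
        r1 = min(h, int(np.ceil(p.y + p.semi_major + 2)))
        c0 = max(0, int(np.floor(p.x - p.semi_major - 1)))
        c1 = min(w, int(np.ceil(p.x + p.semi_major + 2)))
        ys = yy[r0:r1, c0:c1] - p.y
        xs = xx[r0:r1, c0:c1] - p.x
        u = xs * np.cos(p.theta) + ys * np.sin(p.theta)
        v = -xs * np.sin(p.theta) + ys * np.cos(p.theta)
        rho2 = (u / p.semi_major) ** 2 + (v / p.semi_minor) ** 2
        inside = rho2 <= 1.0
        dome = p.intensity * (1.0 - params.dome_falloff * rho2)
        region = canvas[r0:r1, c0:c1]
        region[inside] = np.maximum(region[inside], dome[inside])

    for p in particles + remnants:
        paint_ellipse(p)

    for p, length, direction in tubes:
        half_w = 0.25 * (2 * p.semi_minor) / 2.0
        start = _support_radius(p.semi_major, p.semi_minor, p.theta, direction) - 1.0
        ys_line = p.y + np.array([start, start + length]) * np.sin(direction)
        xs_line = p.x + np.array([start, start + length]) * np.cos(direction)
        # rectangle as a polygon around the tube axis
        ny, nx = np.cos(direction), -np.sin(direction)
        poly_r = np.array([ys_line[0] + half_w * ny, ys_line[1] + half_w * ny,
                           ys_line[1] - half_w * ny, ys_line[0] - half_w * ny])
        poly_c = np.array([xs_line[0] + half_w * nx, xs_line[1] + half_w * nx,
                           xs_line[1] - half_w * nx, xs_line[0] - half_w * nx])
        rr, cc = draw.polygon(poly_r, poly_c, shape=(h, w))
        canvas[rr, cc] = np.maximum(canvas[rr, cc], 0.9 * p.intensity)

    if params.blur_sigma_px > 0:
        canvas = gaussian_filter(canvas, params.blur_sigma_px)
    if params.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, params.noise_sd, canvas.shape)

    img = GrayImage.from_float(canvas, scale_um_per_px=scale, provenance="synthetic")

    rows = []
    for i, p in enumerate(particles + remnants):
        rows.append(
            dict(
                particle_id=i,
                x_px=p.x,
                y_px=p.y,
                type=p.ptype,
                germ_tube=p.germ_tube,
                cluster_id=p.cluster_id if p.cluster_id is not None else pd.NA,
            )
        )
    table = pd.DataFrame(rows, columns=PARTICLE_COLUMNS)
    return img, GroundTruth(table)


def truth_mask(params: SceneParams, truth: GroundTruth, include_remnants: bool = True) -> np.ndarray:
    """Boolean ground-truth foreground mask (unblurred ellipse footprints).

    Re-renders the ellipse footprints from the truth table; germ tubes are
    not included (they are appendages, not particle bodies).
    """
    h, w = params.patch_size_px
    # footprints only need centre + axes; orientation is not stored in the
    # truth table, so this helper re-renders axis-aligned bounding ellipses
    # with the same area, adequate for area-level comparisons.
    sa = params.conidium_axes_um[0] / 2.0 / params.scale_um_per_px
    sb = params.conidium_axes_um[1] / 2.0 / params.scale_um_per_px
    r_eq = float(np.sqrt(sa * sb))
    mask = np.zeros((h, w), dtype=bool)
    for _, row in truth.particles.iterrows():
        if not include_remnants and row["type"] == "remnant":
            continue
        rr, cc = draw.disk((row["y_px"], row["x_px"]), r_eq, shape=(h, w))
        mask[rr, cc] = True
    return mask


def generate_macro_zone(
    density_field: np.ndarray,
    optics_slope: float,
    optics_intercept: float,
    noise_sd_gray: float = 0.0,
    seed: int = 0,
    cell_px: int = 50,
    scale_um_per_px: float | None = None,
) -> GrayImage:
    """Render a macroscopic sporulation zone from a per-cell density field.

    Inverts the linear calibration ``C = a·g + b``: each grid cell of
    ``density_field`` (conidia·cm⁻²) is painted uniformly at gray
    ``g = (C - b)/a`` plus seeded per-cell Gaussian noise, then clipped to
    the 8-bit range.

    Parameters
    ----------
    density_field
        2-D array of non-negative conidia densities, one value per grid cell.
    optics_slope, optics_intercept
        Slope a (> 0) and intercept b of the forward gray→density map.
    noise_sd_gray
        Standard deviation of the per-cell gray noise.
    cell_px
        Edge length of one rendered grid cell in pixels.
    """
    field_arr = np.asarray(density_field, dtype=float)
    if field_arr.ndim != 2:
        raise ValueError("density_field must be 2-D (one value per grid cell)")
    if not optics_slope > 0:
        raise ValueError("optics_slope must be positive")
    if (field_arr < 0).any():
        raise ValueError("densities must be non-negative")
    rng = np.random.default_rng(seed)
    target = (field_arr - optics_intercept) / optics_slope
    if noise_sd_gray > 0:
        target = target + rng.normal(0.0, noise_sd_gray, target.shape)
    clipped = (target < 0) | (target > 255)
    if clipped.mean() > 0.05:
        logger.warning(
            "%.1f%% of grid cells have target gray outside [0, 255] and were clipped",
            100 * clipped.mean(),
        )
    img = np.kron(target, np.ones((cell_px, cell_px)))
    return GrayImage.from_float(img, scale_um_per_px=scale_um_per_px, provenance="synthetic")


@dataclass
class CalibrationSetParams:
    """Parameters of a synthetic (gray value, density) calibration set.

    Defaults mirror a realistic counted set: 25 grid cells spanning gray
    values 50–175, densities scattered with sd 15 000 conidia·cm⁻² around a
    line with slope 1250 conidia·cm⁻²·gray⁻¹ and intercept −100 conidia·cm⁻².
    """

    n_points: int = 25
    g_range: tuple[float, float] = (50.0, 175.0)
    true_slope: float = 1250.0
    true_intercept: float = -100.0
    noise_sd: float = 15000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if not (0 <= self.g_range[0] < self.g_range[1] <= 255):
            raise ValueError("g_range must be an ordered pair within [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_calibration_set(params: CalibrationSetParams) -> list[tuple[float, float]]:
    """Draw seeded (g, C) pairs: g ~ U(g_range), C = a·g + b + N(0, noise_sd)."""
    rng = np.random.default_rng(params.seed)
    g = rng.uniform(params.g_range[0], params.g_range[1], params.n_points)
    c = params.true_slope * g + params.true_intercept
    if params.noise_sd > 0:
        c = c + rng.normal(0.0, params.noise_sd, params.n_points)
    return list(zip(g.tolist(), c.tolist()))
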