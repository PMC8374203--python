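"""Linear gray-value ↔ conidia-density calibration with error bands.

The core of the fast quantification route: counted densities C (conidia
per cm²) from a set of grid cells are regressed on the cells' mean gray
values g,

    C = a·g + b,

by ordinary least squares. Afterwards a gray value alone predicts a
density, with an uncertainty band of half-width

    E(g) = E_a·g + E_b,

the worst-case combination of a slope error E_a and an intercept error
E_b. In ``fit`` mode these are the OLS standard errors (σ_a, σ_b); in
``expanded`` mode they are inflated errors (Δ_a, Δ_b) chosen so the band
covers a target fraction of observed points — trading precision for
coverage. In expanded mode the band is drawn around the slope-only central
line a·g (the intercept, small against the band width, is dropped), which
reproduces the conventional printed form of such expanded calibrations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats


def density_from_count(count: int, patch_area_cm2: float) -> float:
    """Conidia density C = count / area, in conidia per cm²."""
    if not patch_area_cm2 > 0:
        raise ValueError(f"patch area must be positive, got {patch_area_cm2}")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / patch_area_cm2


@dataclass
class CalibrationModel:
    """Fitted linear calibration C = slope·g + intercept with error band."""

    slope: float                      # conidia·cm⁻²·gray⁻¹
    intercept: float                  # conidia·cm⁻²
    slope_err: float = 0.0            # σ_a, OLS standard error
    intercept_err: float = 0.0        # σ_b
    r_squared: float = 1.0
    n_points: int = 3
    band_mode: str = "fit"            # "fit" | "expanded"
    slope_err_expanded: float | None = None      # Δ_a
    intercept_err_expanded: float | None = None  # Δ_b
    expansion_factor: float | None = None        # k with (Δa, Δb) = k·(σa, σb), if derived
    residual_sd: float | None = None  # for the conventional prediction interval
    g_mean: float | None = None
    g_ss: float | None = None         # Σ (g_i - ḡ)²

    def __post_init__(self) -> None:
        if self.band_mode not in ("fit", "expanded"):
            raise ValueError(f"band_mode must be 'fit' or 'expanded', got {self.band_mode!r}")
        for v in (self.slope_err, self.intercept_err):
            if v < 0:
                raise ValueError("standard errors must be non-negative")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_points < 3:
            raise ValueError("a calibration needs at least 3 points")
        if self.band_mode == "expanded":
            if self.slope_err_expanded is None or self.intercept_err_expanded is None:
                raise ValueError("expanded mode requires (slope_err_expanded, intercept_err_expanded)")
            if self.slope_err_expanded < 0 or self.intercept_err_expanded < 0:
                raise ValueError("expanded errors must be non-negative")

    # -- serialisation ---------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationModel":
        try:
            is_file = Path(str(source)).exists()
        except OSError:
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        return cls(**json.loads(text))


@dataclass
class PredictionBand:
    """Predicted density interval for one gray value."""

    g: float
    central: float
    lower: float
    upper: float
    floored: bool = False   # lower bound was clipped at 0

    def __post_init__(self) -> None:
        if not self.lower <= self.central + 1e-9 or not self.central <= self.upper + 1e-9:
            # central may sit below a floored lower bound; that is flagged
            if not self.floored:
                raise ValueError("band must satisfy lower <= central <= upper")


def fit_linear(points: list[tuple[float, float]]) -> CalibrationModel:
    """Ordinary least squares fit of density on gray value.

    Returns the slope/intercept with their standard errors, R², and the
    ancillary statistics needed for a conventional prediction interval.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (g, C) points")
    g, c = pts[:, 0], pts[:, 1]
    if np.ptp(g) == 0:
        raise ValueError("gray values are all equal; slope is undetermined")
    res = stats.linregress(g, c)
    n = len(g)
    resid = c - (res.slope * g + res.intercept)
    dof = n - 2
    residual_sd = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else 0.0
    ss_tot = ((c - c.mean()) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else float(res.rvalue**2)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_err=float(res.stderr),
        intercept_err=float(res.intercept_stderr),
        r_squared=min(1.0, r2),
        n_points=n,
        band_mode="fit",
        residual_sd=residual_sd,
        g_mean=float(g.mean()),
        g_ss=float(((g - g.mean()) ** 2).sum()),
    )


def predict_band(model: CalibrationModel, g: float) -> PredictionBand:
    """Density band at gray value g: central ± (E_a·g + E_b).

    ``fit`` mode: central a·g + b, errors (σ_a, σ_b). ``expanded`` mode:
    central a·g, errors (Δ_a, Δ_b). Negative lower bounds are floored at 0
    and flagged — densities are physical counts.
    """
    if not 0 <= g <= 255:
        raise ValueError(f"gray value must be in [0, 255], got {g}")
    if model.band_mode == "fit":
        central = model.slope * g + model.intercept
        ea, eb = model.slope_err, model.intercept_err
    else:
        central = model.slope * g
        ea, eb = model.slope_err_expanded, model.intercept_err_expanded
    half = ea * g + eb
    lower, upper = central - half, central + half
    floored = lower < 0
    return PredictionBand(g=g, central=central, lower=max(0.0, lower), upper=upper, floored=floored)


def prediction_interval(model: CalibrationModel, g: float, level: float = 0.95) -> PredictionBand:
    """Conventional OLS prediction interval for a new observation at g.

    Alternative to the worst-case band of :func:`predict_band`; requires a
    model produced by :func:`fit_linear` (residual statistics present).
    """
    if model.residual_sd is None or model.g_mean is None or model.g_ss is None:
        raise ValueError("model lacks residual statistics; fit it with fit_linear")
    central = model.slope * g + model.intercept
    n = model.n_points
    se = model.residual_sd * np.sqrt(1 + 1 / n + (g - model.g_mean) ** 2 / model.g_ss)
    tcrit = stats.t.ppf(0.5 + level / 2, df=n - 2)
    half = float(tcrit * se)
    lower = central - half
    return PredictionBand(
        g=g, central=central, lower=max(0.0, lower), upper=central + half, floored=lower < 0
    )


def coverage_fraction(model: CalibrationModel, points: list[tuple[float, float]]) -> float:
    """Fraction of (g, C) points lying inside the model's band."""
    pts = list(points)
    if not pts:
        raise ValueError("coverage is undefined for an empty point set")
    inside = 0
    for g, c in pts:
        band = predict_band(model, g)
        if band.lower <= c <= band.upper:
            inside += 1
    return inside / len(pts)


def with_expanded_errors(
    model: CalibrationModel, slope_err_expanded: float, intercept_err_expanded: float
) -> CalibrationModel:
    """Copy of a model in expanded mode with explicitly chosen (Δ_a, Δ_b)."""
    return CalibrationModel(
        slope=model.slope,
        intercept=model.intercept,
        slope_err=model.slope_err,
        intercept_err=model.intercept_err,
        r_squared=model.r_squared,
        n_points=model.n_points,
        band_mode="expanded",
        slope_err_expanded=slope_err_expanded,
        intercept_err_expanded=intercept_err_expanded,
        residual_sd=model.residual_sd,
        g_mean=model.g_mean,
        g_ss=model.g_ss,
    )


def expand_band(
    model: CalibrationModel,
    points: list[tuple[float, float]],
    target_coverage: float,
    rel_tol: float = 1e-3,
) -> CalibrationModel:
    """Inflate the error band until it covers ``target_coverage`` of the points.

    Finds the smallest multiplier k >= 1 (bisection to ``rel_tol`` relative
    tolerance) such that the band with errors (k·σ_a, k·σ_b) contains at
    least the target fraction of points, and returns the model in expanded
    mode. If k = 1 already suffices, no expansion takes place.
    """
    if not 0 < target_coverage <= 1:
        raise ValueError("target_coverage must be in (0, 1]")
    pts = list(points)
    if not pts:
        raise ValueError("cannot expand a band against an empty point set")

    def cov(k: float) -> float:
        m = with_expanded_errors(model, k * model.slope_err, k * model.intercept_err)
        return coverage_fraction(m, pts)

    if cov(1.0) >= target_coverage:
        out = with_expanded_errors(model, model.slope_err, model.intercept_err)
        out.expansion_factor = 1.0
        return out
    lo, hi = 1.0, 2.0
    max_hi = 1e9
    while cov(hi) < target_coverage:
        hi *= 2.0
        if hi > max_hi:
            raise ValueError(
                "target coverage unreachable: band width does not grow enough "
                "(zero error at some gray values?)"
            )
    while (hi - lo) / hi > rel_tol:
        mid = 0.5 * (lo + hi)
        if cov(mid) >= target_coverage:
            hi = mid
        else:
            lo = mid
    out = with_expanded_errors(model, hi * model.slope_err, hi * model.intercept_err)
    out.expansion_factor = hi
    return out
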