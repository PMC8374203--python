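"""Pseudo-coloring of sporulation zones into six discrete shades.

The 8-bit gray range is partitioned into six bands; every pixel takes its
band's display color, and a legend maps each band to the density interval
predicted by a calibration model at the band's gray edges. The default
palette samples the perceptually uniform viridis map dark-to-bright; any
six-color palette can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib import colormaps

from .calibrate import CalibrationModel, predict_band
from .image import GrayImage

N_SHADES = 6


def default_palette() -> list[tuple[int, int, int]]:
    """Six viridis samples, dark (low gray) to bright (high gray)."""
    cmap = colormaps["viridis"]
    return [tuple(int(round(255 * v)) for v in cmap(x)[:3]) for x in np.linspace(0, 1, N_SHADES)]


@dataclass
class ShadeBand:
    """One gray band: inclusive gray interval, color, predicted densities."""

    index: int
    g_lo: int
    g_hi: int                       # inclusive upper edge
    color: tuple[int, int, int]
    density_lo: float | None = None
    density_hi: float | None = None


@dataclass
class ShadeLegend:
    bands: list[ShadeBand] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    band=b.index, g_lo=b.g_lo, g_hi=b.g_hi,
                    r=b.color[0], g=b.color[1], b=b.color[2],
                    density_lo=b.density_lo, density_hi=b.density_hi,
                )
                for b in self.bands
            ]
        )


def _band_edges() -> list[tuple[int, int]]:
    # band i covers gray values with floor(g*6/255) == i, i.e. the half-open
    # real interval [i*255/6, (i+1)*255/6); on integers that is
    # [ceil(i*255/6), ceil((i+1)*255/6) - 1] inclusive
    edges = []
    for i in range(N_SHADES):
        lo = -(-i * 255 // 6)
        hi = -(-(i + 1) * 255 // 6) - 1 if i < N_SHADES - 1 else 255
        edges.append((lo, hi))
    return edges


def six_shades(
    image: GrayImage, palette: list[tuple[int, int, int]] | None = None
) -> tuple[np.ndarray, ShadeLegend]:
    """Map each pixel to one of six colors by its gray band.

    Returns the RGB uint8 image and the legend of bands (densities not yet
    annotated). The mapping is a pure function of the gray value, so
    recoloring the same image twice is bitwise identical.
    """
    pal = default_palette() if palette is None else list(palette)
    if len(pal) != N_SHADES:
        raise ValueError(f"palette must have exactly {N_SHADES} colors, got {len(pal)}")
    idx = np.minimum(image.pixels.astype(np.int32) * N_SHADES // 255, N_SHADES - 1)
    lut = np.asarray(pal, dtype=np.uint8)
    rgb = lut[idx]
    legend = ShadeLegend(
        [ShadeBand(index=i, g_lo=lo, g_hi=hi, color=tuple(pal[i])) for i, (lo, hi) in enumerate(_band_edges())]
    )
    return rgb, legend


def annotate_legend(legend: ShadeLegend, model: CalibrationModel) -> ShadeLegend:
    """Attach predicted density intervals to each band.

    A band's interval runs from the model's lower bound at its low gray
    edge to the upper bound at its high gray edge, in the model's band
    mode (fit or expanded).
    """
    bands = []
    for b in legend.bands:
        lo_band = predict_band(model, b.g_lo)
        hi_band = predict_band(model, b.g_hi)
        bands.append(
            ShadeBand(
                index=b.index, g_lo=b.g_lo, g_hi=b.g_hi, color=b.color,
                density_lo=lo_band.lower, density_hi=hi_band.upper,
            )
        )
    return ShadeLegend(bands)
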