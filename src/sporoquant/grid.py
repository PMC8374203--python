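"""Digital grid over a macroscopic sporulation-zone image.

The macroscopic scan is divided into square cells matching the physical
grid under the collection surface (2.5 × 2.5 mm in the reference setup);
each cell's mean gray value is the fast quantification parameter, and the
cell interiors are what gets cropped for microscopic counting.

Conventions: 0-based row-major cell indices, origin at the image top-left,
half-open pixel intervals [start, end); partial cells at the right/bottom
edge are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import GrayImage


@dataclass
class GridSpec:
    """A regular grid of square cells in pixel coordinates."""

    origin_px: tuple[int, int]          # (row, col) of the first cell's top-left
    cell_px: int
    cell_mm: float
    n_rows: int
    n_cols: int
    scale_um_per_px: float

    def cell_bounds(self, row: int, col: int) -> tuple[int, int, int, int]:
        """(r0, c0, r1, c1) half-open pixel bounds of one cell."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"cell ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        r0 = self.origin_px[0] + row * self.cell_px
        c0 = self.origin_px[1] + col * self.cell_px
        return r0, c0, r0 + self.cell_px, c0 + self.cell_px


@dataclass
class GridCellMeasurement:
    """One grid cell: index, pixel bounds, mean gray, optional density link."""

    row: int
    col: int
    bounds: tuple[int, int, int, int]   # (r0, c0, r1, c1), half-open
    mean_gray: float
    density: float | None = None        # conidia per cm², when counted
    patch_id: str | None = None


def make_grid(
    image: GrayImage, cell_size_mm: float, origin_px: tuple[int, int] = (0, 0)
) -> GridSpec:
    """Fit the maximal grid of whole cells onto an image with scale metadata.

    The cell edge in pixels is ``round(cell_size_mm * 1000 / scale)``;
    cells that would not fit completely are discarded.
    """
    if image.scale_um_per_px is None:
        raise ValueError("image needs scale_um_per_px metadata to lay out a physical grid")
    if not cell_size_mm > 0:
        raise ValueError("cell size must be positive")
    cell_px = int(round(cell_size_mm * 1000.0 / image.scale_um_per_px))
    if cell_px < 2:
        raise ValueError(f"grid cell of {cell_size_mm} mm is {cell_px} px — below the 2 px minimum")
    h, w = image.shape
    r0, c0 = origin_px
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError(f"origin {origin_px} outside image of shape {(h, w)}")
    n_rows = (h - r0) // cell_px
    n_cols = (w - c0) // cell_px
    return GridSpec(
        origin_px=(r0, c0),
        cell_px=cell_px,
        cell_mm=cell_size_mm,
        n_rows=n_rows,
        n_cols=n_cols,
        scale_um_per_px=image.scale_um_per_px,
    )


def mean_gray_per_cell(image: GrayImage, grid: GridSpec) -> list[GridCellMeasurement]:
    """Arithmetic mean gray value g of every grid cell (one record per cell)."""
    out = []
    px = image.pixels
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            r0, c0, r1, c1 = grid.cell_bounds(row, col)
            g = float(px[r0:r1, c0:c1].mean())
            out.append(GridCellMeasurement(row=row, col=col, bounds=(r0, c0, r1, c1), mean_gray=g))
    return out


def crop_cell_interior(
    image: GrayImage, grid: GridSpec, cell: tuple[int, int], margin_px: int = 0
) -> GrayImage:
    """Extract one cell's pixels, shrunk by ``margin_px`` on every side.

    This is the patch handed to the microscopic counting pipelines; scale
    metadata is carried over.
    """
    if margin_px < 0 or 2 * margin_px >= grid.cell_px:
        raise ValueError(f"margin {margin_px} px must satisfy 0 <= margin < half cell size")
    r0, c0, r1, c1 = grid.cell_bounds(*cell)
    sub = image.pixels[r0 + margin_px : r1 - margin_px, c0 + margin_px : c1 - margin_px]
    return GrayImage(sub.copy(), scale_um_per_px=image.scale_um_per_px, provenance=image.provenance)


def select_cells_with_particles(
    measurements: list[GridCellMeasurement], min_g: float
) -> list[GridCellMeasurement]:
    """Keep cells whose mean gray reaches ``min_g``.

    On a blank-subtracted scan an empty cell averages near 0, so a small
    ``min_g`` acts as a proxy for "cell contains particles"; the threshold
    is an explicit parameter rather than a visual judgement.
    """
    return [m for m in measurements if m.mean_gray >= min_g]
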