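"""8-bit grayscale image container with physical scale metadata.

All pipeline stages exchange :class:`GrayImage` objects: a 2-D uint8 raster
plus an optional micrometre-per-pixel scale and a provenance tag recording
which corrections have been applied.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile


@dataclass
class GrayImage:
    """Single-channel 8-bit image.

    Parameters
    ----------
    pixels
        2-D array of integers in [0, 255]; stored as ``uint8``.
    scale_um_per_px
        Physical pixel size in micrometres, if known.
    provenance
        Free-text processing tag, e.g. ``"raw"``, ``"blank-subtracted"``,
        ``"rolling-ball-corrected"``, ``"synthetic"``.
    """

    pixels: np.ndarray
    scale_um_per_px: float | None = None
    provenance: str = "raw"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        if px.dtype != np.uint8:
            arr = np.asarray(px, dtype=float)
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("pixel values must lie in [0, 255] for an 8-bit image")
            if not np.allclose(arr, np.rint(arr)):
                raise ValueError("pixel values must be integers; quantize with GrayImage.from_float")
            px = arr.astype(np.uint8)
        self.pixels = px
        if self.scale_um_per_px is not None and not self.scale_um_per_px > 0:
            raise ValueError(f"scale_um_per_px must be positive, got {self.scale_um_per_px}")

    # -- basic geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def area_cm2(self) -> float:
        """Physical image area in cm²; requires scale metadata."""
        if self.scale_um_per_px is None:
            raise ValueError("image has no scale_um_per_px metadata")
        h, w = self.shape
        return (h * self.scale_um_per_px * 1e-4) * (w * self.scale_um_per_px * 1e-4)

    # -- construction / IO ----------------------------------------------

    @classmethod
    def from_float(
        cls,
        arr: np.ndarray,
        scale_um_per_px: float | None = None,
        provenance: str = "raw",
    ) -> "GrayImage":
        """Clip a float array to [0, 255], round to integers and wrap."""
        px = np.clip(np.rint(np.asarray(arr, dtype=float)), 0, 255).astype(np.uint8)
        return cls(px, scale_um_per_px=scale_um_per_px, provenance=provenance)

    def with_pixels(self, pixels: np.ndarray, provenance: str | None = None) -> "GrayImage":
        """Copy of this image with new pixel data (same scale)."""
        return dataclasses.replace(
            self, pixels=pixels, provenance=self.provenance if provenance is None else provenance
        )

    def save(self, path: str | Path) -> None:
        """Write as 8-bit TIFF or PNG depending on the file suffix."""
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            tifffile.imwrite(path, self.pixels)
        else:
            iio.imwrite(path, self.pixels)

    @classmethod
    def load(cls, path: str | Path, scale_um_per_px: float | None = None) -> "GrayImage":
        """Read an 8-bit grayscale TIFF/PNG; multi-channel input is rejected."""
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
        arr = np.asarray(arr)
        if arr.ndim == 3 and arr.shape[2] == 1:
            arr = arr[:, :, 0]
        if arr.ndim != 2:
            raise ValueError(f"{path} is not single-channel (shape {arr.shape})")
        if arr.dtype != np.uint8:
            raise ValueError(f"{path} is not 8-bit (dtype {arr.dtype})")
        return cls(arr, scale_um_per_px=scale_um_per_px, provenance="raw")
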