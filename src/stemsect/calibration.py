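"""Image loading and Hounsfield-unit calibration.

Micro-CT reconstructions arrive either as 16-bit TIFFs whose codes are
Hounsfield units (air = −1000, water = 0) or as already-calibrated 8-bit
rasters.  A fixed calibration window, wide enough to cover the HU range
of dried plant material, maps HU linearly onto [0, 255]; values outside
the window are attenuation saturations and are clamped, not rejected.

Rounding is nearest-integer with ties away from zero.  Coordinates are
(row, col), 0-based, row 0 at the top, throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

#: mm per pixel of the reference acquisition (13.55 µm).
DEFAULT_PIXEL_SIZE_MM = 0.01355


@dataclass(frozen=True)
class CalibrationRange:
    """HU window mapped linearly onto the 8-bit grey range."""

    hu_min: float = -1000.0
    hu_max: float = 9240.0

    def __post_init__(self) -> None:
        if not (self.hu_min < self.hu_max):
            raise ValueError(
                f"degenerate calibration range: hu_min={self.hu_min} must be "
                f"strictly below hu_max={self.hu_max}"
            )


@dataclass(frozen=True)
class SliceImage:
    """Calibrated 8-bit grayscale cross-section with physical scale."""

    pixels: np.ndarray
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("SliceImage requires a single-channel 2-D raster")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("grey levels must lie in [0, 255]")
            px = px.astype(np.uint8)
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def hu_to_gray(raw: np.ndarray, cal: CalibrationRange | None = None,
               pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM,
               source_id: str = "") -> SliceImage:
    """Map HU values linearly onto [0, 255].

    grey = round(255 · (clamp(hu) − hu_min) / (hu_max − hu_min)), with
    clamping to the calibration window before scaling and half-away-from-
    zero rounding.  The endpoints map exactly: hu_min → 0, hu_max → 255.
    """
    cal = cal or CalibrationRange()
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).all():
        raise ValueError("raw HU data must be finite")
    clamped = np.clip(raw, cal.hu_min, cal.hu_max)
    scaled = 255.0 * (clamped - cal.hu_min) / (cal.hu_max - cal.hu_min)
    grey = np.floor(scaled + 0.5).astype(np.uint8)  # scaled >= 0 everywhere
    return SliceImage(grey, pixel_size_mm=pixel_size_mm, source_id=source_id)


def load_slice(path: str | Path, pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM,
               cal: CalibrationRange | None = None) -> SliceImage:
    """Read a single-channel 8- or 16-bit TIFF/PNG cross-section.

    8-bit input passes through unchanged.  16-bit input is interpreted as
    HU codes and requires a :class:`CalibrationRange`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-channel image, got shape {data.shape}"
        )
    if data.dtype == np.uint8:
        return SliceImage(data, pixel_size_mm=pixel_size_mm, source_id=str(path))
    if data.dtype == np.uint16:
        if cal is None:
            raise ValueError(
                f"{path.name}: 16-bit input needs a CalibrationRange to map HU "
                "codes onto the 8-bit working range"
            )
        return hu_to_gray(data, cal, pixel_size_mm=pixel_size_mm,
                          source_id=str(path))
    raise ValueError(f"{path.name}: unsupported dtype {data.dtype}")


def save_slice(img: SliceImage, path: str | Path) -> None:
    """Write the 8-bit raster; TIFF via tifffile, PNG via imageio."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, img.pixels)
    else:
        iio.imwrite(path, img.pixels)
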