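"""Loading scanned pages and establishing physical calibration.

Drawings are collected on A4 paper and digitised on a flatbed scanner, so a
page either carries DPI metadata (PNG ``pHYs`` / TIFF resolution tags) or can
be calibrated by fitting the known A4 page width.  All downstream metrics are
expressed in centimetres via a single ``pixels_per_cm`` factor.

Conventions: images are stored row-major with row 0 at the top of the page
and rows increasing downward, so every "height" is a row extent and the crown
of a tree sits at smaller row indices than its trunk.  RGB scans are reduced
to grayscale by luminance weighting before any processing; the protocol uses
a dark pen on white paper, so hue carries no signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import CalibrationError, FormatError

#: A4 page dimensions in centimetres (portrait width, portrait height).
A4_WIDTH_CM = 21.0
A4_HEIGHT_CM = 29.7

CM_PER_INCH = 2.54


@dataclass
class RasterImage:
    """A scanned page: grayscale intensities plus optional physical metadata.

    Parameters
    ----------
    pixels
        2-D uint8 array, rows x cols, values in [0, 255].  0 is black ink,
        255 is white paper.
    dpi
        Dots per inch from the file's metadata, or ``None`` when the scan
        carries no physical resolution.
    source_path
        Where the image came from ("synthetic" for rendered fixtures).
    """

    pixels: np.ndarray
    dpi: float | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise FormatError(
                f"expected a non-empty 2-D intensity grid, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            lo, hi = float(self.pixels.min()), float(self.pixels.max())
            if lo < 0 or hi > 255:
                raise FormatError(f"intensities outside [0, 255]: min={lo}, max={hi}")
            self.pixels = self.pixels.astype(np.uint8)
        if self.dpi is not None:
            self.dpi = float(self.dpi)
            if not math.isfinite(self.dpi) or self.dpi <= 0:
                raise FormatError(f"dpi must be finite and positive, got {self.dpi}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class CalibrationParams:
    """Pixel-to-centimetre conversion and where it came from.

    ``source`` is one of ``"dpi-metadata"`` (derived from embedded scan
    resolution, pixels_per_cm = dpi / 2.54), ``"page-fit"`` (page width
    fitted to A4) or ``"manual"`` (user supplied).
    """

    pixels_per_cm: float
    source: str = "manual"

    def __post_init__(self) -> None:
        if not math.isfinite(self.pixels_per_cm) or self.pixels_per_cm <= 0:
            raise CalibrationError(
                f"pixels_per_cm must be finite and positive, got {self.pixels_per_cm}"
            )
        if self.source not in ("dpi-metadata", "page-fit", "manual"):
            raise CalibrationError(f"unknown calibration source {self.source!r}")

    @property
    def pixels_per_cm2(self) -> float:
        return self.pixels_per_cm**2


def load_image(path: str | Path) -> RasterImage:
    """Load a PNG/TIFF/JPEG scan as a grayscale :class:`RasterImage`.

    DPI metadata is read back when the file carries it.  Unreadable or
    truncated files raise :class:`OSError`; images with a zero dimension
    raise :class:`FormatError`.
    """
    path = Path(path)
    with Image.open(path) as img:
        dpi_info = img.info.get("dpi")
        if img.mode not in ("L", "I;16"):
            img = img.convert("L")  # ITU-R 601 luminance weighting
        arr = np.asarray(img)
    if arr.dtype != np.uint8:
        # 16-bit scans: rescale to 8-bit.
        arr = (arr.astype(np.float64) / max(arr.max(), 1) * 255).astype(np.uint8)
    dpi: float | None = None
    if dpi_info:
        try:
            dpi = float(dpi_info[0] if isinstance(dpi_info, (tuple, list)) else dpi_info)
        except (TypeError, ValueError):
            dpi = None
        if dpi is not None and (not math.isfinite(dpi) or dpi <= 0):
            dpi = None
    return RasterImage(pixels=arr, dpi=dpi, source_path=str(path))


def save_image(image: RasterImage, path: str | Path) -> None:
    """Write a grayscale image, embedding DPI metadata when present."""
    pil = Image.fromarray(image.pixels, mode="L")
    kwargs = {}
    if image.dpi is not None:
        kwargs["dpi"] = (image.dpi, image.dpi)
    pil.save(Path(path), **kwargs)


def derive_calibration(
    image: RasterImage,
    page_width_cm: float | None = None,
    *,
    strict: bool = False,
) -> CalibrationParams:
    """Establish ``pixels_per_cm`` for a scanned page.

    Preference order: embedded DPI metadata (pixels_per_cm = dpi / 2.54),
    then page-width fitting.  When ``page_width_cm`` is not given the page is
    assumed A4 and orientation is detected from the aspect ratio (portrait
    width 21.0 cm; landscape 29.7 cm).  ``strict=True`` disables page
    fitting so that a missing DPI is an error.
    """
    if image.dpi is not None:
        return CalibrationParams(pixels_per_cm=image.dpi / CM_PER_INCH, source="dpi-metadata")
    if strict and page_width_cm is None:
        raise CalibrationError(
            "image carries no DPI metadata and strict calibration forbids page fitting"
        )
    rows, cols = image.shape
    if page_width_cm is None:
        page_width_cm = A4_WIDTH_CM if rows >= cols else A4_HEIGHT_CM
    if page_width_cm <= 0:
        raise CalibrationError(f"page width must be positive, got {page_width_cm}")
    return CalibrationParams(pixels_per_cm=cols / page_width_cm, source="page-fit")
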