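"""From a grayscale page to a cleaned binary ink mask.

Binarisation uses Otsu's criterion (pen-on-paper pages are strongly bimodal,
ink being the darker class).  Cleaning removes scanner dust and — important
for this protocol, where participants write their age and sex on the page —
annotation text near the page margins.  Two independent defenses are applied:
a margin-band exclusion and, downstream, largest-component selection.

8-connectivity is used throughout so thin diagonal pen strokes stay connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing as _closing

from .errors import NoDrawingError, NoInkError
from .image_io import RasterImage

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


def _square(radius: int) -> np.ndarray:
    """Square closing footprint: unlike a disk, a radius-r square reliably
    bridges gaps up to 2r even in 1-px-thin strokes."""
    return np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)

#: Default speck threshold at 300 dpi; scaled by (pixels_per_cm / 118.11)^2
#: at other resolutions (~0.13 mm^2 of dust).
MIN_SPECK_PX_AT_300DPI = 25
REFERENCE_PPCM = 300 / 2.54


def scale_min_speck(pixels_per_cm: float, base: int = MIN_SPECK_PX_AT_300DPI) -> int:
    """Scale the dust-speck threshold to the page's actual resolution."""
    return max(2, round(base * (pixels_per_cm / REFERENCE_PPCM) ** 2))


@dataclass
class InkMask:
    """Binary ink mask congruent with its source image."""

    mask: np.ndarray
    threshold_used: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ink mask must be 2-D")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class ComponentMask:
    """A single connected component with its tight bounding box.

    ``bbox`` is (top_row, bottom_row, left_col, right_col), inclusive.
    """

    mask: np.ndarray
    pixel_count: int
    bbox: tuple[int, int, int, int]

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "ComponentMask":
        mask = np.asarray(mask, dtype=bool)
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        if rows.size == 0:
            raise NoDrawingError("empty component mask")
        return cls(
            mask=mask,
            pixel_count=int(mask.sum()),
            bbox=(int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1])),
        )


def binarize(image: RasterImage) -> InkMask:
    """Threshold a grayscale page with Otsu's criterion; ink = darker class.

    Raises :class:`NoInkError` for a zero-contrast page (a single intensity
    value admits no foreground/background split).
    """
    px = image.pixels
    if px.min() == px.max():
        raise NoInkError(f"no ink detected: page has uniform intensity {int(px.min())}")
    thr = float(threshold_otsu(px))
    mask = px <= thr  # skimage convention: the darker class sits at or below thr
    if not mask.any():
        raise NoInkError("no ink detected: no pixels at or below the Otsu threshold")
    return InkMask(mask=mask, threshold_used=thr, provenance={"method": "otsu"})


def clean_mask(
    ink: InkMask,
    min_speck_px: int = MIN_SPECK_PX_AT_300DPI,
    margin_frac: float = 0.08,
    closing_radius_px: int = 3,
) -> InkMask:
    """Remove dust specks and margin annotations, then close pen gaps.

    Components smaller than ``min_speck_px`` are dropped; components lying
    entirely within the outer ``margin_frac`` band of the page (where the
    protocol has participants write their age and sex) are dropped; the
    remainder is morphologically closed with a square of half-width
    ``closing_radius_px``
    to bridge pen skips.  An empty result raises :class:`NoDrawingError`.
    """
    mask = ink.mask
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        raise NoDrawingError("no drawing found: empty ink mask")
    counts = np.bincount(labels.ravel())
    keep = counts >= min_speck_px
    keep[0] = False

    if margin_frac > 0:
        h, w = mask.shape
        mh = int(round(margin_frac * h))
        mw = int(round(margin_frac * w))
        interior = np.zeros_like(mask)
        interior[mh : h - mh, mw : w - mw] = True
        # a component survives only if it has at least one interior pixel
        interior_labels = np.unique(labels[mask & interior])
        in_interior = np.zeros_like(keep)
        in_interior[interior_labels] = True
        keep &= in_interior

    cleaned = keep[labels]
    if closing_radius_px > 0:
        cleaned = _closing(cleaned, _square(closing_radius_px))
    if not cleaned.any():
        raise NoDrawingError("no drawing found: nothing survived cleaning")
    prov = dict(ink.provenance)
    prov.update(
        min_speck_px=int(min_speck_px),
        margin_frac=float(margin_frac),
        closing_radius_px=int(closing_radius_px),
    )
    return InkMask(mask=cleaned, threshold_used=ink.threshold_used, provenance=prov)


def largest_component(ink: InkMask) -> ComponentMask:
    """Select the dominant 8-connected component (the tree).

    Ties on pixel count are broken by topmost, then leftmost bounding box,
    which makes the selection deterministic.
    """
    labels, n = ndimage.label(ink.mask, structure=_EIGHT)
    if n == 0:
        raise NoDrawingError("no drawing found: empty ink mask")
    counts = np.bincount(labels.ravel())
    counts[0] = -1
    best = int(np.argmax(counts))
    max_count = counts[best]
    tied = np.flatnonzero(counts == max_count)
    if tied.size > 1:
        slices = ndimage.find_objects(labels)
        # (top row, left col) lexicographic tie-break
        best = min(tied, key=lambda lab: (slices[lab - 1][0].start, slices[lab - 1][1].start))
    return ComponentMask.from_mask(labels == best)
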