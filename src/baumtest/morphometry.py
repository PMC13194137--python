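"""Calibrated tree metrics: areas (cm²), heights and widths (cm).

Areas are filled-silhouette areas (pixel count / pixels_per_cm²), not
ink-stroke areas; heights are row extents of the crown/trunk/root row
partition, so component heights always sum to the total height; widths are
the maximum single-row horizontal extent of each component.  Totals are
derived from the components, never re-measured, which makes the additive
identities exact.

Interface values are rounded half-up to 2 decimals (matching the precision
clinical reports use); all internal arithmetic is unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import CalibrationError
from .image_io import CalibrationParams
from .segmentation import TreeSegmentation

AREA_FIELDS = ("crown_area_cm2", "trunk_area_cm2", "root_area_cm2", "total_area_cm2")
HEIGHT_FIELDS = ("crown_height_cm", "trunk_height_cm", "root_height_cm", "total_height_cm")
WIDTH_FIELDS = ("crown_width_cm", "trunk_width_cm", "total_width_cm")
METRIC_FIELDS = AREA_FIELDS + HEIGHT_FIELDS + WIDTH_FIELDS


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (numpy/python round are half-even)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TreeMetrics:
    """Calibrated morphometric features of one tree drawing.

    All areas in cm², lengths in cm.  ``total_area_cm2`` is the exact sum of
    the component areas; ``total_height_cm`` the sum of component heights;
    ``total_width_cm`` the maximum component width.
    """

    crown_area_cm2: float = 0.0
    trunk_area_cm2: float = 0.0
    root_area_cm2: float = 0.0
    total_area_cm2: float = 0.0
    crown_height_cm: float = 0.0
    trunk_height_cm: float = 0.0
    root_height_cm: float = 0.0
    total_height_cm: float = 0.0
    crown_width_cm: float = 0.0
    trunk_width_cm: float = 0.0
    total_width_cm: float = 0.0
    confidence_flags: frozenset[str] = frozenset()

    def as_dict(self, rounded: bool = True) -> dict[str, float | str]:
        """Metric values keyed by field name, 2-dp half-up when ``rounded``."""
        out: dict[str, float | str] = {}
        for name in METRIC_FIELDS:
            v = getattr(self, name)
            out[name] = round_half_up(v, 2) if rounded else v
        out["confidence_flags"] = ";".join(sorted(self.confidence_flags))
        return out


def _max_row_extent(mask: np.ndarray) -> int:
    """Maximum per-row horizontal extent (rightmost - leftmost + 1)."""
    rows_any = mask.any(axis=1)
    if not rows_any.any():
        return 0
    n_cols = mask.shape[1]
    sub = mask[rows_any]
    first = np.argmax(sub, axis=1)
    last = n_cols - 1 - np.argmax(sub[:, ::-1], axis=1)
    return int((last - first + 1).max())


def measure(segmentation: TreeSegmentation, cal: CalibrationParams) -> TreeMetrics:
    """Convert a segmentation into calibrated metrics.

    area = pixels / pixels_per_cm²; height = partition row extent /
    pixels_per_cm; width = max per-row extent / pixels_per_cm.  An empty
    component scores 0 on all its metrics.
    """
    ppcm = cal.pixels_per_cm
    if not np.isfinite(ppcm) or ppcm <= 0:
        raise CalibrationError(f"non-positive pixels_per_cm: {ppcm}")
    ppcm2 = ppcm * ppcm

    sil = segmentation.silhouette_mask
    rows = np.flatnonzero(sil.any(axis=1))
    if rows.size == 0:
        return TreeMetrics(confidence_flags=segmentation.flags)
    top, bottom = int(rows[0]), int(rows[-1])
    # clamp boundary rows into the silhouette's row range so the partition
    # heights are well defined even for crown-only / root-only degenerates
    ct = min(max(segmentation.crown_trunk_row, top), bottom + 1)
    tr = min(max(segmentation.trunk_root_row, ct), bottom + 1)

    crown_px = int(segmentation.crown_mask.sum())
    trunk_px = int(segmentation.trunk_mask.sum())
    root_px = int(segmentation.root_mask.sum())

    # a connected silhouette fills every row in [top, bottom], so each slab
    # is non-empty exactly when its component mask is
    crown_h = ct - top
    trunk_h = tr - ct
    root_h = bottom + 1 - tr

    crown_area = crown_px / ppcm2
    trunk_area = trunk_px / ppcm2
    root_area = root_px / ppcm2
    crown_w = _max_row_extent(segmentation.crown_mask) / ppcm
    trunk_w = _max_row_extent(segmentation.trunk_mask) / ppcm
    root_w = _max_row_extent(segmentation.root_mask) / ppcm

    return TreeMetrics(
        crown_area_cm2=crown_area,
        trunk_area_cm2=trunk_area,
        root_area_cm2=root_area,
        total_area_cm2=crown_area + trunk_area + root_area,
        crown_height_cm=crown_h / ppcm,
        trunk_height_cm=trunk_h / ppcm,
        root_height_cm=root_h / ppcm,
        total_height_cm=(crown_h + trunk_h + root_h) / ppcm,
        crown_width_cm=crown_w,
        trunk_width_cm=trunk_w,
        total_width_cm=max(crown_w, trunk_w, root_w),
        confidence_flags=segmentation.flags,
    )
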