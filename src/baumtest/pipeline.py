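"""Single-image and batch measurement pipelines.

One image flows load -> calibrate -> binarize -> clean -> largest component
-> fill -> boundaries -> segment -> measure.  Each stage failure is wrapped
in a :class:`PipelineError` carrying the stage name, so a batch run can log
"P0012: [binarize] no ink detected" and keep going.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .config import RunConfig
from .errors import BaumtestError, PipelineError, SchemaError
from .image_io import CalibrationParams, RasterImage, derive_calibration, load_image
from .ink_extraction import binarize, clean_mask, largest_component, scale_min_speck
from .morphometry import TreeMetrics, measure
from .segmentation import (
    TreeSegmentation,
    fill_silhouette,
    find_boundaries,
    segment_tree,
    width_profile,
)


@dataclass
class MeasureResult:
    """Everything one image yields: metrics, masks, and an audit trail."""

    metrics: TreeMetrics
    segmentation: TreeSegmentation
    calibration: CalibrationParams
    audit: dict


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise domain errors with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, BaumtestError) and not isinstance(
                exc, PipelineError
            ):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def measure_image(image: RasterImage, config: RunConfig | None = None) -> MeasureResult:
    """Run the full measurement pipeline on an in-memory page."""
    config = config or RunConfig()

    with _stage("calibrate"):
        if config.pixels_per_cm is not None:
            cal = CalibrationParams(pixels_per_cm=config.pixels_per_cm, source="manual")
        else:
            cal = derive_calibration(
                image, page_width_cm=config.page_width_cm, strict=config.strict_calibration
            )

    with _stage("binarize"):
        ink = binarize(image)

    min_speck = (
        config.min_speck_px
        if config.min_speck_px is not None
        else scale_min_speck(cal.pixels_per_cm)
    )
    with _stage("clean_mask"):
        cleaned = clean_mask(
            ink,
            min_speck_px=min_speck,
            margin_frac=config.margin_frac,
            closing_radius_px=config.closing_radius_px,
        )

    with _stage("largest_component"):
        component = largest_component(cleaned)

    with _stage("fill_silhouette"):
        silhouette = fill_silhouette(component, closing_radius_px=config.closing_radius_px)

    with _stage("segment"):
        profile = width_profile(silhouette, smooth_window_rows=config.smooth_window_rows)
        bounds = find_boundaries(
            profile, alpha=config.alpha, beta=config.beta, run_rows=config.run_rows
        )
        seg = segment_tree(silhouette, bounds)

    with _stage("measure"):
        metrics = measure(seg, cal)

    audit = {
        "source": image.source_path,
        "calibration": {"pixels_per_cm": cal.pixels_per_cm, "source": cal.source},
        "binarize": {"threshold": ink.threshold_used},
        "clean_mask": {
            "min_speck_px": min_speck,
            "margin_frac": config.margin_frac,
            "closing_radius_px": config.closing_radius_px,
        },
        "segment": {
            "alpha": config.alpha,
            "beta": config.beta,
            "smooth_window": profile.smooth_window,
            "crown_trunk_row": seg.crown_trunk_row,
            "trunk_root_row": seg.trunk_root_row,
            "flags": sorted(seg.flags),
        },
    }
    return MeasureResult(metrics=metrics, segmentation=seg, calibration=cal, audit=audit)


def measure_file(path: str | Path, config: RunConfig | None = None) -> MeasureResult:
    """Load an image file and measure it (stage errors carry the stage name)."""
    try:
        image = load_image(path)
    except (OSError, BaumtestError) as exc:
        raise PipelineError("load_image", str(exc)) from exc
    return measure_image(image, config)


# component colours for the audit overlay (RGB)
_OVERLAY_TINTS = {
    "crown": (60, 170, 60),
    "trunk": (170, 100, 40),
    "roots": (60, 90, 200),
}


def render_overlay(image: RasterImage, seg: TreeSegmentation) -> np.ndarray:
    """RGB review image with crown/trunk/root regions tinted."""
    base = np.stack([image.pixels] * 3, axis=-1).astype(np.float64)
    for name, mask in (
        ("crown", seg.crown_mask),
        ("trunk", seg.trunk_mask),
        ("roots", seg.root_mask),
    ):
        tint = np.array(_OVERLAY_TINTS[name], dtype=np.float64)
        base[mask] = 0.45 * base[mask] + 0.55 * tint
    return np.clip(base, 0, 255).astype(np.uint8)


def save_overlay(image: RasterImage, seg: TreeSegmentation, path: str | Path) -> None:
    Image.fromarray(render_overlay(image, seg)).save(Path(path))


def batch_measure(
    image_dir: str | Path,
    roster: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Measure every roster participant's image and join metrics to the roster.

    Images are looked up as ``<image_dir>/<id>.<ext>`` for common raster
    extensions.  Per-image failures are collected (id, stage, message) and
    the run continues; the output is ordered by participant id.  Zero
    matched images is an error.
    """
    if "id" not in roster.columns:
        raise SchemaError("roster lacks an 'id' column")
    image_dir = Path(image_dir)
    rows = []
    failures: list[dict] = []
    matched = 0
    for _, rec in roster.sort_values("id").iterrows():
        pid = str(rec["id"])
        path = None
        for ext in (".png", ".tif", ".tiff", ".jpg", ".jpeg"):
            cand = image_dir / f"{pid}{ext}"
            if cand.exists():
                path = cand
                break
        if path is None:
            failures.append({"id": pid, "stage": "lookup", "message": "no image file"})
            continue
        matched += 1
        try:
            result = measure_file(path, config)
        except PipelineError as exc:
            failures.append({"id": pid, "stage": exc.stage, "message": str(exc)})
            continue
        row = dict(rec)
        row.update(result.metrics.as_dict(rounded=True))
        rows.append(row)
    if matched == 0:
        raise SchemaError(f"no roster id matches an image in {image_dir}")
    return pd.DataFrame(rows), failures
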