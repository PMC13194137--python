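"""Synthetic tree drawings with analytic ground truth.

No public corpus of scanned tree drawings exists, so the test bed is a
renderer that draws what the protocol elicits — a pen drawing of a tree on a
white A4 page — from an explicit geometric specification: an ellipse crown
(optionally with a jittered boundary, stressing the boundary finder), a
trapezoid trunk, and optional triangular root flares.  Because the ink is
rasterised from the same geometry that defines the ground truth, every
rendered page comes with exact component masks and analytic metrics (ellipse
area pi*a*b, trapezoid area, triangle areas), which is what lets the
measurement pipeline be validated end to end.

A cohort generator layers the study's statistical structure on top: group
means and spreads of drawn area, depression (HDRS) and anxiety (HAMA) scale
scores, and a Gaussian-copula rank correlation between drawn area and HDRS.
All randomness flows from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon
from skimage.morphology import erosion as _erosion, disk

from .errors import GeometryError
from .image_io import A4_HEIGHT_CM, A4_WIDTH_CM, CM_PER_INCH, RasterImage, save_image
from .morphometry import TreeMetrics
from .segmentation import Boundaries, TreeSegmentation, segment_tree

# ---------------------------------------------------------------------------
# single-tree specification and renderer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticTreeSpec:
    """Geometry (in cm, on an A4 portrait page) of one synthetic drawing.

    The crown is an ellipse with semi-axes ``(crown_a_cm, crown_b_cm)``
    whose bottom point meets the trunk's top edge; ``crown_jitter`` is the
    relative amplitude of a smooth periodic perturbation of the crown
    boundary (tapered to zero at the trunk junction so the junction row
    stays well defined).  The trunk is a trapezoid; roots, when
    ``root_count > 0``, are disjoint triangular flares partitioning the
    trunk's bottom edge and fanning over ``root_spread_deg``.
    """

    center_x_cm: float = A4_WIDTH_CM / 2
    crown_top_cm: float = 6.0
    crown_a_cm: float = 3.0
    crown_b_cm: float = 2.5
    crown_jitter: float = 0.04
    trunk_top_width_cm: float = 0.9
    trunk_bottom_width_cm: float = 1.1
    trunk_height_cm: float = 4.0
    root_count: int = 0
    root_length_cm: float = 0.0
    root_spread_deg: float = 50.0
    style: str = "filled"  # "filled" | "outline"
    stroke_width_px: int = 3
    noise_sigma: float = 0.0
    annotation: bool = False
    annotation_pos: str = "bottom"
    dpi: float = 150.0
    seed: int = 0

    @property
    def pixels_per_cm(self) -> float:
        return self.dpi / CM_PER_INCH

    @property
    def junction_y_cm(self) -> float:
        """y (from page top) where crown bottom meets trunk top."""
        return self.crown_top_cm + 2 * self.crown_b_cm

    @property
    def trunk_bottom_y_cm(self) -> float:
        return self.junction_y_cm + self.trunk_height_cm

    def _root_angles(self) -> np.ndarray:
        if self.root_count <= 0:
            return np.empty(0)
        half = math.radians(self.root_spread_deg) / 2
        if self.root_count == 1:
            return np.array([0.0])
        return np.linspace(-half, half, self.root_count)

    @property
    def root_depth_cm(self) -> float:
        ang = self._root_angles()
        if ang.size == 0:
            return 0.0
        return float(self.root_length_cm * np.cos(ang).max())

    def validate(self) -> None:
        for name in (
            "crown_a_cm",
            "crown_b_cm",
            "trunk_top_width_cm",
            "trunk_bottom_width_cm",
            "trunk_height_cm",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.style not in ("filled", "outline"):
            raise GeometryError(f"unknown style {self.style!r}")
        ang = self._root_angles()
        lean = self.root_length_cm * math.sin(math.radians(self.root_spread_deg) / 2)
        half_w = max(self.crown_a_cm * (1 + self.crown_jitter),
                     self.trunk_bottom_width_cm / 2 + (lean if ang.size else 0.0))
        border = 0.5  # cm of clear page around the drawing
        if self.center_x_cm - half_w < border or self.center_x_cm + half_w > A4_WIDTH_CM - border:
            raise GeometryError("tree exceeds page width")
        top = self.crown_top_cm - self.crown_b_cm * self.crown_jitter
        bottom = self.trunk_bottom_y_cm + self.root_depth_cm
        if top < border or bottom > A4_HEIGHT_CM - border:
            raise GeometryError("tree exceeds page height")

    def ground_truth_metrics(self) -> TreeMetrics:
        """Analytic metrics implied by the specified geometry."""
        a, b = self.crown_a_cm, self.crown_b_cm
        wt, wb = self.trunk_top_width_cm, self.trunk_bottom_width_cm
        h = self.trunk_height_cm
        crown_area = math.pi * a * b
        trunk_area = (wt + wb) / 2 * h
        ang = self._root_angles()
        if ang.size:
            base_w = wb / self.root_count
            root_area = float((0.5 * base_w * self.root_length_cm * np.cos(ang)).sum())
            root_h = self.root_depth_cm
            lean = self.root_length_cm * math.sin(math.radians(self.root_spread_deg) / 2)
            root_w = max(wb, wb - base_w + 2 * lean)
        else:
            root_area = root_h = root_w = 0.0
        crown_w, trunk_w = 2 * a, max(wt, wb)
        return TreeMetrics(
            crown_area_cm2=crown_area,
            trunk_area_cm2=trunk_area,
            root_area_cm2=root_area,
            total_area_cm2=crown_area + trunk_area + root_area,
            crown_height_cm=2 * b,
            trunk_height_cm=h,
            root_height_cm=root_h,
            total_height_cm=2 * b + h + root_h,
            crown_width_cm=crown_w,
            trunk_width_cm=trunk_w,
            total_width_cm=max(crown_w, trunk_w, root_w),
        )


def _fill_poly(mask: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> None:
    rr, cc = draw_polygon(ys, xs, shape=mask.shape)
    mask[rr, cc] = True


def _crown_polygon(spec: SyntheticTreeSpec, rng: np.random.Generator, ppcm: float):
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    r = np.ones_like(theta)
    if spec.crown_jitter > 0:
        f = np.zeros_like(theta)
        for k in range(2, 8):  # smooth low-order harmonics
            amp = rng.normal(0, 1) / k
            phase = rng.uniform(0, 2 * np.pi)
            f += amp * np.cos(k * theta + phase)
        peak = np.abs(f).max()
        if peak > 0:
            f /= peak
        taper = (1 - np.cos(theta - np.pi / 2)) / 2  # 0 at the trunk junction
        r += spec.crown_jitter * f * taper
    cx = spec.center_x_cm * ppcm
    cy = (spec.crown_top_cm + spec.crown_b_cm) * ppcm
    xs = cx + spec.crown_a_cm * ppcm * r * np.cos(theta)
    ys = cy + spec.crown_b_cm * ppcm * r * np.sin(theta)
    return ys, xs


def _annotation_mask(spec: SyntheticTreeSpec, rng: np.random.Generator, shape) -> np.ndarray:
    """Pseudo-handwriting block (age/sex note) inside the page margin band."""
    H, W = shape
    mask = np.zeros(shape, dtype=bool)
    yc = 0.96 * H if spec.annotation_pos == "bottom" else 0.03 * H
    for _ in range(8):
        w = max(3, int(0.015 * W))
        x0 = int(rng.uniform(0.38 * W, 0.60 * W))
        y0 = int(yc + rng.integers(-int(0.004 * H) - 1, int(0.004 * H) + 2))
        t = max(1, spec.stroke_width_px - 1)
        mask[max(y0, 0) : min(y0 + t, H), max(x0, 0) : min(x0 + w, W)] = True
    return mask


def render(spec: SyntheticTreeSpec) -> tuple[RasterImage, TreeSegmentation, TreeMetrics]:
    """Rasterise a spec into (page image, ground-truth masks, true metrics).

    Deterministic given ``spec.seed``.  The ground-truth segmentation is the
    row partition of the rendered silhouette at the geometric junction rows,
    i.e. the same semantics the measurement pipeline uses; the ground-truth
    metrics are analytic (so rasterisation error is *not* baked into them).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ppcm = spec.pixels_per_cm
    W = round(A4_WIDTH_CM * ppcm)
    H = round(A4_HEIGHT_CM * ppcm)

    filled = np.zeros((H, W), dtype=bool)
    ys, xs = _crown_polygon(spec, rng, ppcm)
    _fill_poly(filled, ys, xs)

    cx = spec.center_x_cm * ppcm
    yj = spec.junction_y_cm * ppcm
    yb = spec.trunk_bottom_y_cm * ppcm
    wt2 = spec.trunk_top_width_cm * ppcm / 2
    wb2 = spec.trunk_bottom_width_cm * ppcm / 2
    overlap = 2.0  # px of hidden overlap so tangent parts stay connected
    _fill_poly(
        filled,
        np.array([yj - overlap, yj - overlap, yb, yb]),
        np.array([cx - wt2, cx + wt2, cx + wb2, cx - wb2]),
    )

    angles = spec._root_angles()
    if angles.size:
        base_w = 2 * wb2 / spec.root_count
        L = spec.root_length_cm * ppcm
        for i, ang in enumerate(angles):
            x0 = cx - wb2 + i * base_w
            x1 = x0 + base_w
            xa = (x0 + x1) / 2 + L * math.sin(ang)
            ya = yb + L * math.cos(ang)
            _fill_poly(
                filled,
                np.array([yb - overlap, yb - overlap, ya]),
                np.array([x0, x1, xa]),
            )

    if spec.style == "outline":
        ink = filled & ~_erosion(filled, disk(max(1, spec.stroke_width_px)))
    else:
        ink = filled
    if spec.annotation:
        ink = ink | _annotation_mask(spec, rng, (H, W))

    page = np.where(ink, 0.0, 255.0)
    if spec.noise_sigma > 0:
        page = page + rng.normal(0, spec.noise_sigma, size=page.shape)
    pixels = np.clip(np.rint(page), 0, 255).astype(np.uint8)
    image = RasterImage(pixels=pixels, dpi=spec.dpi, source_path="synthetic")

    rows = np.flatnonzero(filled.any(axis=1))
    bottom = int(rows[-1])
    ct_row = int(round(yj))
    tr_row = int(round(yb)) if angles.size else bottom + 1
    seg = segment_tree(filled, Boundaries(crown_trunk_row=ct_row, trunk_root_row=tr_row))
    return image, seg, spec.ground_truth_metrics()


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

EDUCATION_LEVELS = ("primary", "junior_high", "high_school", "college")


@dataclass(frozen=True)
class GroupSpec:
    """Marginal distributions of one study group."""

    n: int
    total_area_mean: float  # cm^2
    total_area_sd: float
    crown_frac: float  # crown share of total drawn area
    trunk_frac: float  # trunk share; remainder goes to roots
    hdrs_mean: float
    hdrs_sd: float
    hama_mean: float | None = None
    hama_sd: float | None = None
    age_mean: float = 40.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (18.0, 65.0)
    p_male: float = 0.5
    education_probs: tuple[float, float, float, float] = (0.05, 0.15, 0.70, 0.10)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group n must be >= 1")
        if self.total_area_sd < 0 or self.hdrs_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.crown_frac + self.trunk_frac > 1 + 1e-9:
            raise ValueError("crown_frac + trunk_frac must not exceed 1")


def study_groups() -> dict[str, GroupSpec]:
    """The three study groups with the published marginal summaries.

    Group area shares come from the published component means relative to
    the total; the adolescent components add to slightly more than the
    printed total, so their shares are renormalised to sum to one (no roots).
    """
    return {
        "depressed-adolescent": GroupSpec(
            n=82,
            total_area_mean=54.61, total_area_sd=5.03,
            crown_frac=37.89 / 55.03, trunk_frac=17.14 / 55.03,
            hdrs_mean=26.73, hdrs_sd=9.03,
            hama_mean=22.36, hama_sd=1.17,
            age_mean=14.70, age_sd=1.89, age_range=(12.0, 17.0),
            p_male=38 / 82, education_probs=(0.0, 19 / 82, 63 / 82, 0.0),
        ),
        "depressed-adult": GroupSpec(
            n=43,
            total_area_mean=56.71, total_area_sd=4.20,
            crown_frac=45.18 / 56.71, trunk_frac=8.87 / 56.71,
            hdrs_mean=39.63, hdrs_sd=3.31,
            hama_mean=7.05, hama_sd=0.29,
            age_mean=45.02, age_sd=15.21, age_range=(18.0, 65.0),
            p_male=20 / 43, education_probs=(2 / 43, 6 / 43, 30 / 43, 5 / 43),
        ),
        "control": GroupSpec(
            n=59,
            total_area_mean=114.53, total_area_sd=9.53,
            crown_frac=90.84 / 114.53, trunk_frac=19.38 / 114.53,
            hdrs_mean=4.80, hdrs_sd=2.83,
            age_mean=43.95, age_sd=11.47, age_range=(18.0, 65.0),
            p_male=29 / 59, education_probs=(3 / 59, 5 / 59, 45 / 59, 6 / 59),
        ),
    }


@dataclass(frozen=True)
class CohortSpec:
    """A whole synthetic study: groups, their marginals, and the
    area–depression dependence.

    ``rho_area_hdrs`` is the *Spearman* rank correlation between total drawn
    area and HDRS within each group, induced through a Gaussian copula
    (Pearson latent correlation r = 2 sin(pi * rho / 6)).
    """

    groups: dict[str, GroupSpec] = field(default_factory=study_groups)
    rho_area_hdrs: float = -0.285
    dpi: float = 150.0
    style: str = "outline"
    noise_sigma: float = 6.0
    annotation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1 <= self.rho_area_hdrs <= 1:
            raise ValueError("rho_area_hdrs must lie in [-1, 1]")


def _clip_area(area: float) -> float:
    return float(np.clip(area, 8.0, 150.0))


def sample_cohort(cohort: CohortSpec) -> pd.DataFrame:
    """Draw the per-participant table (no images rendered).

    Returns one row per participant with demographics, scale scores, the
    tree geometry to be drawn, and the analytic ground-truth metrics.
    """
    master = np.random.default_rng(cohort.seed)
    r = 2 * math.sin(math.pi * cohort.rho_area_hdrs / 6)  # copula latent corr
    rows = []
    idx = 0
    for label in sorted(cohort.groups):
        g = cohort.groups[label]
        rng = np.random.default_rng(master.integers(2**31))
        for _ in range(g.n):
            z1 = rng.normal()
            z2 = r * z1 + math.sqrt(max(0.0, 1 - r * r)) * rng.normal()
            total_area = _clip_area(g.total_area_mean + g.total_area_sd * z1)
            hdrs = max(0, round(g.hdrs_mean + g.hdrs_sd * z2))
            hama = (
                max(0, round(rng.normal(g.hama_mean, g.hama_sd)))
                if g.hama_mean is not None
                else None
            )
            age = float(np.clip(rng.normal(g.age_mean, g.age_sd), *g.age_range))
            sex = "male" if rng.uniform() < g.p_male else "female"
            edu = EDUCATION_LEVELS[rng.choice(4, p=np.asarray(g.education_probs) /
                                              np.sum(g.education_probs))]
            crown_frac = float(np.clip(g.crown_frac + rng.normal(0, 0.02), 0.4, 0.92))
            trunk_frac = float(np.clip(g.trunk_frac + rng.normal(0, 0.01), 0.05,
                                       1 - crown_frac))
            spec = tree_spec_from_areas(
                total_area * crown_frac,
                total_area * trunk_frac,
                total_area * max(0.0, 1 - crown_frac - trunk_frac),
                rng=rng,
                seed=int(master.integers(2**31)),
                dpi=cohort.dpi,
                style=cohort.style,
                noise_sigma=cohort.noise_sigma,
                annotation=cohort.annotation,
            )
            truth = spec.ground_truth_metrics()
            row = {
                "id": f"P{idx:04d}",
                "group": label,
                "age": round(age, 1),
                "sex": sex,
                "education": edu,
                "hdrs": hdrs,
                "hama": hama,
                "target_total_area_cm2": total_area,
            }
            row.update({f"true_{k}": v for k, v in truth.as_dict(rounded=False).items()
                        if k != "confidence_flags"})
            row["spec"] = spec
            rows.append(row)
            idx += 1
    return pd.DataFrame(rows)


def tree_spec_from_areas(
    crown_area: float,
    trunk_area: float,
    root_area: float,
    *,
    rng: np.random.Generator,
    seed: int,
    dpi: float = 150.0,
    style: str = "outline",
    noise_sigma: float = 6.0,
    annotation: bool = True,
) -> SyntheticTreeSpec:
    """Solve tree dimensions from requested component areas (cm²).

    Crown aspect and trunk slenderness vary a little per participant; root
    length is capped at 3 cm (the ground truth is always recomputed from the
    final dimensions, so the cap never biases the truth tables).
    """
    aspect = float(np.clip(rng.normal(1.30, 0.10), 1.05, 1.60))  # a / b
    b = math.sqrt(crown_area / (math.pi * aspect))
    a = aspect * b
    slender = float(np.clip(rng.normal(4.0, 0.40), 2.5, 6.0))  # height / width
    w = math.sqrt(trunk_area / slender)
    h = slender * w
    root_count = 0
    root_len = 0.0
    spread = 50.0
    if root_area > 0.2:
        root_count = 3
        angles = np.linspace(-math.radians(spread) / 2, math.radians(spread) / 2, root_count)
        mean_cos = float(np.cos(angles).mean())
        root_len = min(3.0, 2 * root_area / (1.15 * w * mean_cos))
    depth = root_len  # upper bound on root depth
    tree_h = 2 * b + h + depth
    top = max(1.0, (A4_HEIGHT_CM - tree_h) / 2)
    return SyntheticTreeSpec(
        center_x_cm=A4_WIDTH_CM / 2,
        crown_top_cm=top,
        crown_a_cm=a,
        crown_b_cm=b,
        crown_jitter=0.04,
        trunk_top_width_cm=0.85 * w,
        trunk_bottom_width_cm=1.15 * w,
        trunk_height_cm=h,
        root_count=root_count,
        root_length_cm=root_len,
        root_spread_deg=spread,
        style=style,
        noise_sigma=noise_sigma,
        annotation=annotation,
        dpi=dpi,
        seed=seed,
    )


ROSTER_COLUMNS = ["id", "group", "age", "sex", "education", "hdrs", "hama"]


def generate_cohort(cohort: CohortSpec, output_dir: str | Path) -> pd.DataFrame:
    """Render a whole cohort to disk: images, roster CSV, ground-truth CSV.

    Writes ``<id>.png`` per participant (with DPI metadata), ``roster.csv``
    with demographics and scale scores, and ``ground_truth.csv`` with the
    analytic metrics.  Deterministic given ``cohort.seed``; returns the full
    participant table (including each participant's rendered image path).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = sample_cohort(cohort)
    paths = []
    for _, row in table.iterrows():
        image, _, _ = render(row["spec"])
        path = out / f"{row['id']}.png"
        save_image(image, path)
        paths.append(str(path))
    table = table.assign(image_path=paths)
    table[ROSTER_COLUMNS].to_csv(out / "roster.csv", index=False)
    truth_cols = ["id", "group"] + [c for c in table.columns if c.startswith("true_")]
    table[truth_cols].to_csv(out / "ground_truth.csv", index=False)
    return table
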