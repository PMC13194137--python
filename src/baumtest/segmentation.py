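"""Partitioning a tree silhouette into crown, trunk and roots.

The drawn tree is reduced to its filled silhouette (morphological closing
followed by hole filling) and then partitioned **by rows**: every pixel above
the crown/trunk boundary row belongs to the crown, every pixel at or below
the trunk/root boundary row belongs to the roots, the rest is trunk.  The
row partition makes the component masks pairwise disjoint with their union
exactly the silhouette, so the additive area and height identities hold by
construction for every input.

The boundaries are located on the silhouette's *width profile* — the per-row
horizontal extent.  A drawn tree is a wide crown over a narrow trunk, so the
crown/trunk boundary is where the smoothed extent collapses below a fraction
``alpha`` of its maximum and stops shrinking; a root flare, if present, is a
bottom-touching run of rows widening back above ``beta`` times the trunk's
median extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import closing as _closing

from .errors import NoDrawingError
from .ink_extraction import ComponentMask, _square

#: Flag set when the crown/trunk rule had to fall back to a single-row test.
LOW_CONFIDENCE_CROWN = "low-confidence-crown-boundary"


@dataclass
class WidthProfile:
    """Per-row occupancy of a silhouette over its vertical extent.

    ``counts[i]`` is the number of filled pixels in absolute row
    ``top_row + i``; ``extents[i]`` is the horizontal extent
    (rightmost - leftmost + 1) of that row.  ``extents_smoothed`` is a
    centered moving average with an odd window (no phase shift).
    """

    top_row: int
    counts: np.ndarray
    extents: np.ndarray
    extents_smoothed: np.ndarray
    smooth_window: int

    def __len__(self) -> int:
        return len(self.extents)

    @property
    def bottom_row(self) -> int:
        return self.top_row + len(self.extents) - 1


@dataclass(frozen=True)
class Boundaries:
    """Row boundaries of the crown/trunk/root partition (absolute rows).

    ``trunk_root_row`` equal to ``bottom_row + 1`` is the no-roots sentinel.
    """

    crown_trunk_row: int
    trunk_root_row: int
    flags: frozenset[str] = frozenset()


@dataclass
class TreeSegmentation:
    """Disjoint crown/trunk/root masks partitioning a filled silhouette."""

    silhouette_mask: np.ndarray
    crown_mask: np.ndarray
    trunk_mask: np.ndarray
    root_mask: np.ndarray
    crown_trunk_row: int
    trunk_root_row: int
    flags: frozenset[str] = frozenset()

    def validate(self) -> None:
        """Check the partition invariants (used by tests and audits)."""
        union = self.crown_mask | self.trunk_mask | self.root_mask
        if not np.array_equal(union, self.silhouette_mask):
            raise AssertionError("crown/trunk/root union differs from silhouette")
        overlap = (
            self.crown_mask.astype(int) + self.trunk_mask.astype(int) + self.root_mask.astype(int)
        )
        if overlap.max(initial=0) > 1:
            raise AssertionError("crown/trunk/root masks overlap")


def fill_silhouette(component: ComponentMask, closing_radius_px: int = 3) -> np.ndarray:
    """Close and hole-fill a drawn component into a solid silhouette.

    Outline-style drawings (closed pen contours) become solid regions; filled
    strokes pass through nearly unchanged.  The result is connected and
    hole-free.
    """
    mask = component.mask
    if closing_radius_px > 0:
        mask = _closing(mask, _square(closing_radius_px))
    return ndimage.binary_fill_holes(mask)


def width_profile(silhouette: np.ndarray, smooth_window_rows: int | None = None) -> WidthProfile:
    """Per-row pixel counts and horizontal extents of a silhouette.

    The smoothing window defaults to 2% of the silhouette's height, forced
    odd and at least 3 rows.
    """
    silhouette = np.asarray(silhouette, dtype=bool)
    row_any = silhouette.any(axis=1)
    rows = np.flatnonzero(row_any)
    if rows.size == 0:
        raise NoDrawingError("empty silhouette has no width profile")
    top, bottom = int(rows[0]), int(rows[-1])
    sub = silhouette[top : bottom + 1]
    counts = sub.sum(axis=1).astype(np.int64)
    n_rows, n_cols = sub.shape
    first = np.argmax(sub, axis=1)
    last = n_cols - 1 - np.argmax(sub[:, ::-1], axis=1)
    extents = np.where(counts > 0, last - first + 1, 0).astype(np.int64)

    if smooth_window_rows is None:
        smooth_window_rows = max(3, round(0.02 * n_rows))
    smooth_window_rows = max(1, int(smooth_window_rows))
    if smooth_window_rows % 2 == 0:
        smooth_window_rows += 1
    smoothed = ndimage.uniform_filter1d(
        extents.astype(np.float64), size=smooth_window_rows, mode="nearest"
    )
    return WidthProfile(
        top_row=top,
        counts=counts,
        extents=extents,
        extents_smoothed=smoothed,
        smooth_window=smooth_window_rows,
    )


def _runs_true(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive index pairs."""
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def find_boundaries(
    profile: WidthProfile,
    alpha: float = 0.45,
    beta: float = 1.6,
    run_rows: int | None = None,
) -> Boundaries:
    """Locate the crown/trunk and trunk/root boundary rows.

    Crown/trunk: starting below the row of maximum smoothed extent, find the
    first run of at least ``run_rows`` consecutive rows whose extent is at
    most ``alpha`` times the maximum, then walk further down while the extent
    keeps shrinking; the boundary is placed where the collapse flattens onto
    the trunk's plateau.  If no qualifying run exists the single-row test is
    used instead and the result is flagged low-confidence; a profile that
    never narrows puts the boundary at the top row (no crown).

    Trunk/root: with ``m`` the median smoothed extent of the trunk-and-below
    region, the deepest maximal run of rows at least ``beta * m`` wide marks
    a root flare, provided it reaches into the bottom quarter of that region
    and does not merely continue the crown's taper.  Without such a run the
    no-roots sentinel (bottom row + 1) is returned.

    All returned rows are absolute image rows.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if beta <= 1:
        raise ValueError(f"beta must exceed 1, got {beta}")
    ext = profile.extents_smoothed
    n = len(ext)
    if run_rows is None:
        run_rows = max(3, round(0.01 * n))
    run_rows = max(1, int(run_rows))

    flags: set[str] = set()
    i_max = int(np.argmax(ext))
    max_ext = float(ext[i_max])
    thr = alpha * max_ext

    below = ext <= thr
    below[: i_max + 1] = False
    ct_rel: int | None = None
    for start, end in _runs_true(below):
        if end - start + 1 >= run_rows:
            ct_rel = start
            break
    if ct_rel is None:
        idx = np.flatnonzero(below)
        if idx.size > 0:
            ct_rel = int(idx[0])
        else:
            ct_rel = 0  # profile never narrows: no crown region identified
        flags.add(LOW_CONFIDENCE_CROWN)

    # Refinement: the alpha crossing sits on the crown's collapsing flank;
    # descend while the extent still shrinks appreciably so the boundary
    # lands where the profile flattens onto the trunk plateau.
    eps = 0.002 * max_ext
    j = ct_rel
    while j + 1 < n and ext[j + 1] < ext[j] - eps:
        j += 1
    ct_rel = j

    bottom_rel = n - 1
    trunk_region = ext[ct_rel:]
    tr_rel = bottom_rel + 1  # no-roots sentinel
    if trunk_region.size > 0:
        m = float(np.median(trunk_region))
        wide = np.zeros(n, dtype=bool)
        wide[ct_rel:] = ext[ct_rel:] >= beta * m
        runs = _runs_true(wide)
        # ignore runs that are just the smoothing smear of the crown taper
        smear_limit = ct_rel + profile.smooth_window
        runs = [r for r in runs if r[0] > smear_limit]
        if runs:
            deepest = max(runs, key=lambda r: r[1])
            quarter_start = bottom_rel - 0.25 * (bottom_rel - ct_rel)
            if deepest[1] >= quarter_start:
                # The beta crossing sits partway down the flare's flank; walk
                # back up while the extent is still declining toward the
                # trunk plateau so the boundary lands at the flare onset.
                eps_up = max(0.25, 0.002 * m)
                j = deepest[0]
                while j - 1 > ct_rel and ext[j - 1] < ext[j] - eps_up:
                    j -= 1
                tr_rel = j
    tr_rel = max(tr_rel, ct_rel)

    return Boundaries(
        crown_trunk_row=profile.top_row + ct_rel,
        trunk_root_row=profile.top_row + tr_rel,
        flags=frozenset(flags),
    )


def segment_tree(silhouette: np.ndarray, boundaries: Boundaries) -> TreeSegmentation:
    """Partition a silhouette by the boundary rows.

    Crown = rows strictly above ``crown_trunk_row``; roots = rows at or
    below ``trunk_root_row``; trunk = the rows between.  Disjointness and
    exact union hold by construction.
    """
    silhouette = np.asarray(silhouette, dtype=bool)
    ct = boundaries.crown_trunk_row
    tr = boundaries.trunk_root_row
    if tr < ct:
        raise ValueError(f"inverted boundaries: trunk_root_row {tr} < crown_trunk_row {ct}")
    h = silhouette.shape[0]
    row_idx = np.arange(h)[:, None]
    crown = silhouette & (row_idx < ct)
    trunk = silhouette & (row_idx >= ct) & (row_idx < tr)
    roots = silhouette & (row_idx >= tr)
    return TreeSegmentation(
        silhouette_mask=silhouette,
        crown_mask=crown,
        trunk_mask=trunk,
        root_mask=roots,
        crown_trunk_row=ct,
        trunk_root_row=tr,
        flags=boundaries.flags,
    )


def segment_silhouette(
    silhouette: np.ndarray,
    alpha: float = 0.45,
    beta: float = 1.6,
    run_rows: int | None = None,
    smooth_window_rows: int | None = None,
) -> TreeSegmentation:
    """Convenience: width profile -> boundaries -> row partition."""
    profile = width_profile(silhouette, smooth_window_rows=smooth_window_rows)
    bounds = find_boundaries(profile, alpha=alpha, beta=beta, run_rows=run_rows)
    return segment_tree(silhouette, bounds)
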