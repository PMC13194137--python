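# Methods

## The measurement model

A tree drawing is treated as a filled silhouette on a calibrated page, not as
a set of pen strokes. The protocol produces closed pen contours (a crown
outline over a trunk outline), and the magnitudes reported for this test in
the clinical literature (crown areas of tens of cm² on A4) are only consistent
with enclosed-region areas, so every area here is the area of the filled,
hole-free region the ink encloses.

Pipeline, per page:

1. **Calibration.** `pixels_per_cm = dpi / 2.54` when the scan embeds its
   resolution; otherwise the page width is fitted to A4 (21.0 cm portrait;
   29.7 cm when the aspect ratio says landscape). The protocol fixes A4 paper,
   so page fitting is always available; a strict mode turns the fallback off.
   Calibration is linear: lengths scale as 1/ppcm, areas as 1/ppcm².
2. **Binarisation.** Otsu's criterion on the grayscale histogram; ink is the
   class at or below the threshold. Pen-on-paper pages are strongly bimodal,
   so the method is parameter-free and invariant to order-preserving intensity
   rescaling. A zero-contrast page is reported as "no ink".
3. **Cleaning.** Connected components smaller than `min_speck_px` are dust
   (default 25 px at 300 dpi ≈ 0.13 mm², scaled by (ppcm/118.11)²);
   components confined to the outer `margin_frac` band of the page (default
   8%) are the handwritten age/sex note the protocol requires and are removed.
   The remainder is morphologically closed (default half-width 3 px) to bridge
   pen skips. The closing footprint is a **square**: a radius-r disk fails to
   bridge collinear gaps in 1-px-thin strokes, while a radius-r square closes
   gaps up to 2r reliably. Largest-8-connected-component selection is a second,
   independent defence against stray marks.
4. **Silhouette.** Closing followed by hole filling turns an outline drawing
   into the solid region it encloses; filled strokes pass through unchanged.
5. **Partition.** The silhouette is split **by rows** at two boundary rows
   (crown above, trunk between, roots at and below). Row partitioning makes
   the component masks disjoint with union exactly the silhouette, so
   `total area = crown + trunk + roots` and
   `total height = crown + trunk + root heights` hold exactly for every
   input — an invariant the published component/total figures for this test do
   not themselves satisfy, which is why the additive identity is enforced
   rather than any reverse-engineered area rule. A branch crossing the
   boundary row is counted with the crown; this is a deliberate approximation
   that keeps the partition exact and auditable.

### Boundary finding

Boundaries are located on the silhouette's *width profile*: per-row horizontal
extent (rightmost − leftmost + 1), smoothed by a centred moving average
(window 2% of silhouette height, forced odd — no phase shift; minimum 3 rows).

- **Crown/trunk.** Below the row of maximum smoothed extent, the first run of
  at least `run_rows` consecutive rows (default max(3, 1% of height)) with
  extent ≤ `alpha` × maximum (default α = 0.45) marks the crown's collapse.
  Because the collapse of a convex crown is gradual, the α-crossing itself
  sits above the true junction (for a circular crown of radius r the
  α = 0.5 crossing is ≈ 0.13 r above the tangent row), so the boundary is
  then *refined*: walk down while the smoothed extent still falls by more
  than 0.2% of the maximum per row, and place the boundary where the profile
  flattens onto the trunk plateau. On tangent crown-over-trunk geometry this
  lands within a few rows of the true junction. If no qualifying run exists,
  a single-row test is used and the result is flagged low-confidence; a
  profile that never narrows yields an empty crown.
- **Trunk/root.** With m the median smoothed extent of the trunk-and-below
  region, a maximal run of rows with extent ≥ `beta` × m (default β = 1.6) is
  a candidate root flare. The deepest run is accepted only if it reaches into
  the bottom quarter of the region and is not the smoothing smear of the
  crown taper (runs starting within one smoothing window of the crown
  boundary are ignored). The β-crossing sits partway down the flare's flank,
  so the boundary is refined symmetrically: walk up while the extent still
  declines toward the trunk plateau (per-row threshold max(0.25 px,
  0.2% of m)), placing the boundary at the flare onset. With no accepted run
  the no-roots sentinel (bottom row + 1) is returned and the root mask is
  empty.

Both α and β act on *relative* widths, so the finder is invariant to
translation and horizontal mirroring and consistent across scan resolutions
(150 vs 300 dpi boundaries agree within 2 rows after rescaling).

### Metrics

area = pixels / ppcm²; height = partition row extent / ppcm (components sum to
the total by construction); width = maximum single-row extent of the component
(robust to stray pixels, unlike bounding-box width); total width = max of
component widths. Empty components score 0 throughout. Interface/CSV values
are rounded half-up to 2 decimals (the precision clinical tables print);
internal arithmetic is unrounded.

## Statistics

- Two-group comparisons: Shapiro–Wilk gate per group at α = 0.05; pooled
  Student *t* when both pass, Mann–Whitney U otherwise (also for constant or
  too-small groups). Pooled rather than Welch by default because the pooled
  form reproduces the internally consistent severity-scale statistics printed
  for this design; Welch is available by flag.
- The summary-statistics form `t_test_summary(m1, sd1, n1, m2, sd2, n2)` is
  algebraically identical to the raw-data test and is the tool for re-testing
  published tables; the suite enforces raw ≡ summary to 1e-12.
- Mann–Whitney: exact null distribution for tie-free samples with both
  n ≤ 20; tie-corrected normal approximation beyond.
- Spearman: midrank ties; for n ≤ 8 the two-sided *p* is the exact proportion
  of all n! pairings with |ρ| at least the observed (the *t* approximation is
  unreliable there); *t* approximation for larger n.
- Chi-square: Pearson, no continuity correction, df = (r−1)(k−1).
- Effect size: Cohen's d = (m₁ − m₂)/s_p with the pooled SD.
- Power/sample size: exact noncentral-*t* power for the two-sample design
  (df = 2n − 2, noncentrality d·√(n/2)); the smallest n attaining the target
  power is found by bisection. Cross-validated against vectorised Monte-Carlo
  power (10,000 replicates) to within ±0.02.
- No multiple-testing correction is applied anywhere, matching the analysis
  plan this battery reproduces; report headers state this.
- Stars: ** for p < 0.01, *** for p < 0.001 (table-footnote convention).

## The synthetic test bed

No corpus of patient drawings is publicly deposited, so validation runs on a
renderer whose ink and ground truth come from the same geometry:

- **Geometry.** Ellipse crown (semi-axes a, b), tangent trapezoid trunk,
  optional triangular root flares partitioning the trunk's bottom edge.
  Analytic truth: crown πab, trunk (w_top + w_bottom)h/2, roots as triangle
  areas — rasterisation error is measured, never baked into the truth. The
  crown boundary can be jittered by smooth low-order harmonics (default
  amplitude 4% of radius), tapered to zero at the trunk junction so the
  junction row stays defined; this stresses the boundary finder without
  biasing expected areas beyond O(amplitude²).
- **Realism knobs.** Outline style (strokes = region minus its erosion, so
  hole filling recovers the region exactly), Gaussian scanner noise
  (default σ = 6 grey levels), and a pseudo-handwriting block in the bottom
  margin emulating the protocol's age/sex note.
- **Cohorts.** Per-group marginals (total drawn area, component shares, HDRS,
  HAMA, age, sex, education) default to the published three-group study
  summaries: depressed adults 56.71 ± 4.20 cm² total area and HDRS
  39.63 ± 3.31, depressed adolescents 54.61 ± 5.03 and 26.73 ± 9.03, controls
  114.53 ± 9.53 and 4.80 ± 2.83, with the published group sizes (43/82/59)
  and sex/education counts. The published adolescent component means add to
  slightly more than their printed total, so that group's shares are
  renormalised to sum to one. The drawn-area–HDRS dependence is a Gaussian
  copula with Spearman ρ = −0.285 (the published total-area association):
  latent Pearson r = 2 sin(πρ/6), which is exact for the rank correlation the
  pipeline actually computes. All randomness descends from one integer seed;
  same seed, bit-identical images and rosters.
- **What it does not emulate.** Real drawings have branches, foliage texture,
  asymmetric and non-convex crowns, variable pen pressure and page skew.
  Passing the synthetic suite therefore shows that the pipeline measures
  *well-formed tree shapes* accurately and that the statistical machinery is
  correct; it does not certify accuracy on arbitrary clinical drawings.

## Problem sizes and numerical choices

Synthetic validation renders at 150 dpi (A4 = 1240 × 1754 px), where a 2-px
pen stroke is ≈ 0.3 mm — representative of the measurement problem while
keeping the randomized suites (50-tree recovery, 50-per-group end-to-end
cohort) fast; resolution-dependent defaults scale from a 300-dpi reference.
Ties in component selection break toward the topmost-then-leftmost bounding
box. Degenerate inputs (constant samples, zero marginals, empty masks) raise
typed errors rather than returning NaNs; the batch runner logs them per page
and continues.

## Known limitations

- The row partition assigns over-boundary branch pixels to the crown; widths
  of the trunk just below a misplaced boundary can inherit crown chords.
- Trunk area is the least accurate recovered metric (median error ~3–4% on
  the synthetic suite vs <1% for crown and total): both boundary refinements
  deposit their residual rows into the trunk slab.
- Page-fit calibration assumes the scan covers exactly the page; cropped or
  padded scans need a manual `pixels_per_cm`.
- De-skewing is out of scope; rotated pages degrade the width profile.
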