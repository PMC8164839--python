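# Methods

## Cell Shape Index

All morphometry is computed on exact polygon geometry. For a closed
polygon with vertices `(x_i, y_i)`:

* area by the shoelace formula (orientation-free absolute value);
* perimeter as the sum of edge lengths including the closing edge;
* the major axis `M` from the normalized second central moments of the
  filled polygon, evaluated in closed form via Green's theorem, as
  `M = 4·sqrt(λ_max)` with `λ_max` the larger eigenvalue of the 2×2
  moment tensor. For a true ellipse with semi-axes `(a, b)` the tensor's
  eigenvalues are `(a²/4, b²/4)`, so `M` recovers the full axis `2a`
  exactly; for a square of side `s` the moments are `s²/12`, giving
  `M = s·2/√3`.

From these, `Circularity = 4πA/P²`, `Roundness = 4A/(πM²)`, and
`CShin = Roundness/Circularity` (the quotient is formed bit-for-bit from
the two stored fields). Circularity obeys the isoperimetric bound
`C ≤ 1`; CShin is invariant under uniform scaling and rotation, both
asserted as properties in the test suite.

Contours are normalized at construction: closing duplicates and repeated
consecutive vertices are dropped, orientation is made counter-clockwise,
and self-intersecting or zero-area outlines are rejected (shapely's
simplicity test). Coordinates are pixel-centered, 0-based, x right /
y down.

### Raster inputs

Metrics on masks would be biased if computed on pixel boundaries: the
marching-squares trace at the 0.5-level is a staircase whose length
overestimates a smooth perimeter by several percent. `mask_to_contours`
therefore traces components with sub-pixel `find_contours` and applies a
circular moving average over 5 boundary vertices before measuring. With
this smoothing the rasterize→trace→measure round trip on a smooth blob
reproduces the exact-polygon CShin within 5% (asserted in tests); the
5-vertex window is a compromise between residual staircase bias (larger
error below 5) and corner erosion on small components (the 10×10-block
fixture loses ~4.5 px² of its 100 px²). Components under 50 px² are
discarded by default as segmentation specks. A `raster_metrics` route
(pixel-count area, Crofton perimeter, region-moments ellipse) is provided
for parity checks with raster particle analyzers, not as the default.

## Synthetic outlines

Radial shapes (circle, ellipse, blob) are sampled at `n_vertices`
(default 720) angles with radius `r(θ) = R(θ)·(1 + ε·w(kθ))`, where `w`
is a sine ("sinusoidal") or a triangle wave ("serrated"); since
`1 + ε·w > 0` for `ε < 1`, radial outlines are always star-shaped and
hence simple. Cornered shapes (square, rectangle, triangle) are sampled
at equal arc-length steps with corners included exactly, and the same
wave is applied along the outward normal, phased by arc length, with
amplitude `ε` times the mean centroid distance so that `ε` is comparable
across kinds; here strong high-frequency undulation can self-intersect
near corners, which is detected and reported with the offending
`(ε, k)`.

Population presets define the two morphology classes by the CShin
dichotomy itself, not by any further biological claim:

* **epithelial**: smooth ellipses, `ε = 0`, aspect ratio uniform in
  [1.2, 2.0], size uniform in [80, 120] px, rotation uniform — every
  individual CShin is below 1 (Roundness = minor/major < 1 while
  Circularity stays near 1);
* **mesenchymal**: the same ellipses with `ε` uniform in [0.08, 0.18]
  and `k` uniform in {10…20} — median CShin is well above 1.

These spreads are the study conditions for all population-level claims;
they were fixed once, before any downstream comparison, as values that
produce visually plausible cell-like outlines at 100 px scale. Every
generator is a pure function of (spec, seed) via a private
`numpy.random.Generator`; no global RNG state is read or written.

The wavy-circle CShin depends on the unknown amplitude/frequency of any
particular drawn figure, so only ordering properties (strict monotonicity
of CShin in `ε` at fixed `k`, smooth-vs-wavy separation) are asserted,
never a specific wavy-figure value.

## Group statistics

Shape-index distributions are skewed, so location comparisons are
rank-based and two-sided throughout:

* **Mann-Whitney** for two groups. The p-value is exact when
  `n_a·n_b ≤ 400` and the pooled sample has no ties (full null
  enumeration; verified in tests against an independent
  all-assignments oracle to 1e-12), otherwise a tie- and
  continuity-corrected normal approximation. U is reported as
  `min(U_a, U_b)`.
* **Kruskal-Wallis** (tie-corrected H, chi-square reference with k−1 df)
  for three or more groups, followed by the **Conover-Iman** post hoc on
  the pooled ranks: `t_ij = (R̄_i − R̄_j) / sqrt(S²·(N−1−H)/(N−k)·(1/n_i + 1/n_j))`
  with `S²` the tie-corrected pooled-rank variance, referred to
  Student's t with `N − k` df. Scipy provides the MW/KW machinery; the
  Conover step is implemented here (no established implementation is
  available in this stack) and tested against a hand-built rank-table
  computation.
* **Benjamini-Hochberg** step-up adjustment across the single family of
  all pairwise comparisons of one experiment.

The suite checks the empirical type-I error of the Mann-Whitney route at
α = 0.05 over 10,000 simulated null pairs (n = 20 each), and the
invariance of all rank tests under strictly monotone transformations.

## Colocalization

Masks are formed by strict thresholding (`intensity > T`; threshold
dialects differ between tools and the strict form makes the boundary rule
explicit), with Otsu available where a fixed visual threshold is not
supplied. A no-primary-antibody control image, when given, is thresholded
identically and must yield an essentially empty mask (≤ 0.1% foreground);
violations warn and are recorded in the run manifest rather than silently
accepted.

Manders coefficients are **count-based** (`M1 = |A∧B|/|A|`,
`M2 = |A∧B|/|B|`) — overlap fractions of mask-positive pixel counts.
This is deliberate: it makes M1 directly comparable to the belt
generator's ground-truth co-occurrence fraction, which is defined on
channel-A foreground pixels. The classical intensity-weighted split
coefficients are available as `manders_intensity` for comparison. An
empty mask makes the coefficients undefined and raises — it is never
reported as 0.

Pearson `Rr` is computed over all ROI pixels (not only mask-positive
ones). Li's analysis forms per-pixel `PDM = (A_i − Ā)(B_i − B̄)` over the
ROI; `ICQ = #{PDM > 0}/#{PDM ≠ 0} − 0.5`. Pixels with `PDM` exactly 0
are excluded from the denominator so the degenerate identities
(`ICQ = +0.5` for identical channels, `−0.5` for inverted ones) are
attained exactly. The ++PDM map marks pixels with both channels above
their ROI means. Polygon ROIs select pixels whose centers fall inside.

No automated threshold optimization (e.g. Costes) or randomization test
is included: the modelled workflow uses fixed thresholds validated on
empty controls.

## Belt-pair generator

A two-channel image pair on an annular belt (default 256×256 canvas,
centerline radius 90 px, width 14 px): channel A's foreground is the full
ring; channel B's is one seeded contiguous arc (pixels ordered by polar
angle) covering exactly `round(ρ·|A|)` pixels, so `ρ` is the expected M1
under correct thresholding; optional B-only foreground can be placed off
the belt. Foreground/background intensities default to 200/20 with
additive Gaussian noise (sd 8, clipped at 0), leaving the midpoint
threshold 110 more than 11 noise standard deviations from either mode —
mask recovery errors at defaults are vanishingly rare, and the recovery
degrades monotonically as noise grows (asserted over seeds). Ground-truth
masks are returned alongside the images.

On this generator the ++PDM route and the mask-product route identify
essentially the same region (Jaccard ≥ 0.5 asserted as a regression
property of the generator defaults — an empirical convergence of the two
analysis routes, not a theorem).

## Motif scanning and conservation

The scanner tests every window of the canonical hexamer `R-X-X-O-X-G`
and/or non-canonical heptamer `R-X-X-X-O-X-G` (`O ∈ {G,P,A,C}`);
overlapping and nested hits are all reported (no suppression rule is part
of the motif definition), coordinates are 1-based inclusive, and the
unknown-residue code X matches only the unconstrained positions — the
anchors are the definition. Equality with a brute-force window oracle is
asserted on 1,000 random sequences of length 10–2,000.

Conservation is read off a *precomputed* alignment (aligned FASTA or
Clustal via Biopython; alignment computation is out of scope). Each
reference motif locus maps to its alignment-column window; the other
species' ungapped residues under that window are classified **conserved**
(match the same pattern), **degenerate** (length-correct `R…G` frame with
the O-constraint violated), or **absent**. The third class exists to keep
near-misses inspectable instead of silently collapsing them into
present/absent; a row whose motif is ambiguous (e.g. a single invertebrate
motif alignable to either of two reference loci) simply shows its status
at every locus rather than being assigned to one.

Because no sequence database is bundled and none is fetched at run time,
positional end-to-end behaviour is exercised on a **synthetic surrogate**:
`make_surrogate_vcl` builds a 1066-residue random background carrying
human vinculin's three tankyrase-binding motifs (RARGQG, RRQGKG, RGLVAEG)
at their published coordinates (339, 449, 520) and repairs any spurious
background motif; `make_surrogate_homolog_alignment` is a hand-built toy
alignment reproducing the qualitative vertebrate/fly/worm conservation
pattern. Both are labelled synthetic and are not real sequence data —
results on them validate the scanner and the conservation logic, not any
biological claim about vinculin homologs.

## Problem sizes and reproducibility

Default problem sizes — 100-cell populations, 720-vertex outlines,
256×256 belt images, 20-seed recovery averages — were chosen as the
scale at which every closed-form and ground-truth check is already
stable to well inside its asserted tolerance. Every experiment driver
writes a `manifest.json` (config, seed, package version); reruns from the
same manifest reproduce all CSV outputs bit-identically.

## Known limitations

* The outline generator produces star-shaped-ish single cells; it does
  not emulate touching cells, segmentation errors, or image-derived
  contour noise, so passing tests say nothing about segmentation quality
  on real micrographs.
* The belt generator has no point-spread function, photobleaching or
  chromatic shift; its noise is i.i.d. Gaussian. Coefficient recovery
  under realistic optics is untested.
* Count-based Manders coefficients are threshold-sensitive by
  construction; on real images their values depend on the chosen
  thresholds in a way the generator's clean bimodal intensities do not
  probe.
* The conservation classifier trusts the supplied alignment; a
  misaligned column window will misclassify a locus.
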