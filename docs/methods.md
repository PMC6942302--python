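# Methods

## Problem and model

A maize stem cross-section imaged by μCT is modelled as three nested
regions bounded by closed contours: the slice outline (Contour1), the
inner edge of the epidermis rind (Contour3) and the pith outline
(Contour2).  Vascular bundles are bright compact blobs: dense, small and
often mutually fused in the periphery annulus (between Contour3 and
Contour2), sparse and isolated in the pith.  All detected structures
share one representation — an ordered closed polygon in (row, col)
pixel coordinates with its filled pixel region — from which every trait
is derived.

Coordinates are 0-based, row 0 at top.  Polygon vertices produced from
masks lie on the half-pixel marching-squares lattice, so the polygon of
an axis-aligned block has exactly its pixel-count area.

## Calibration

16-bit input codes are treated as Hounsfield units (the scanner
convention cannot be recovered from the file, so this is stated rather
than guessed).  The window [−1000, 9240] HU maps linearly onto
[0, 255]; out-of-window values are saturations and clamp.  Rounding is
nearest integer, ties away from zero, so the window endpoints map
exactly to 0 and 255 and water (0 HU) maps to grey 25.

## Zone detection

* Substance = grey strictly above the air level (default 0).
* The outer boundary is **valid** when its filled area exceeds 0.95 of
  the convex hull of the whole substance mask.  The hull is taken over
  the whole mask, not the largest component, so a rind cracked into
  fragments is correctly invalid.  Repair dilates with a 3×3 element
  until valid, then erodes the filled region by the same count (budget
  50 iterations).
* The pith is the largest 4-connected non-substance region strictly
  inside Contour1; its holes (isolated inner bundles) are filled.
  Substance objects use 8-connectivity, background 4-connectivity — the
  standard dual pairing.
* The rind+periphery annulus is segmented by a local-mean threshold
  (square 31×31 window).  The window mean is computed over **in-ROI
  pixels only**, so the dark pith across Contour2 cannot drag the local
  threshold down and create a false bright band along the zone
  boundary.  Foreground requires grey > mean + 1e−6: ties go to
  background and the epsilon absorbs the accumulation error of the
  separable window sums (uniform regions must stay empty).
* The reversed mask (cavities of the periphery) is cleaned by a small
  opening (disk 3): a zero-offset mean threshold marks ≈ half the
  pixels of any noisy homogeneous region, and that salt speckle would
  otherwise attach to the cavity network during closing.  Cavities are
  united with the pith, closed with a disk of diameter 15 (the size of
  the largest bundle), clipped to Contour1; the outer boundary of the
  largest resulting component is Contour3.
* Zone masks are set algebra on the region masks (epidermis =
  region1 − region3, periphery = region3 − region2, inner = region2),
  so the three zones partition the slice region exactly, by
  construction.  The stem center is the centroid of region1.

## Bundle detection

Inner track: threshold grey ≥ 1 inside the inner mask (redundant
candidates, ≥ 5 px), then a morphological Chan–Vese active contour (50
iterations, smoothing 1) run in a window of twice the candidate's
bounding box.  A vanished contour falls back to the candidate with a
warning; area change outside [0.2×, 5×] is an error and the candidate
is kept unrefined.

Periphery track: components of the adaptive mask inside the periphery
zone, after an opening with a disk of diameter 5 — below the smallest
bundle, large enough to remove percolating noise speckle.  The
exponential law *area = a − b·e^{c·DC}* is fitted to the candidates
(≥ 10 samples spanning ≥ 3 mm); a candidate more than 3 robust sigmas
(1.4826·MAD of residuals) above the prediction is flagged as merged.
Flagged candidates are decomposed into maximal inscribed circles via
the Euclidean distance transform (greedy extraction, stop radius 3 px,
argmax ties to the smallest (row, col)), circles within the sum of
their radii are merged into seed groups, and region pixels are assigned
to the geodesically nearest group by constant-image watershed
constrained to the region — label growth from the circle-covered
pixels, which conserves every pixel and handles crescent-shaped lobes
that a single seed point would misassign.

## Traits

MAL/MAW come from the minimum-area rotated rectangle of the contour
polygon (consistent with RA = A/(MAL·MAW)); CR from the minimum
enclosing circle; ICR from the distance-transform maximum minus half a
pixel (the transform measures center-to-center distance, the polygon
boundary runs through the half-pixel lattice).  Area is the filled
pixel count; the perimeter uses the Crofton estimator (4 directions),
which is close to unbiased on digitized curved outlines where raw
marching-squares arc length overestimates a circle's perimeter by
≈ 6% — with raw arc length a digitized disk would report CIR ≈ 0.89
instead of ≈ 0.99.  AI averages grey over the filled region; slice AI
and the substance ratio exclude grey 0, matching the histograms (255
bins over [1, 255]).

Layers scale Contour3 about the stem center by k/n (equal-distance) or
√(k/n) (equal-area — exact under similarity scaling).  Bundle-to-layer
and bundle-to-zone membership is by center point.  Voronoi growth
spaces are the bundles' Voronoi cells clipped to Contour3; duplicate
centers are perturbed by 10⁻⁶ px with a warning.  Epidermis thickness —
not operationally defined elsewhere — is the mean over 360 radial rays
of the distance between the Contour3 and Contour1 crossings.  Layer AI
uses all non-zero pixels of the layer, not only bundle pixels.  1-D
k-means on bundle areas uses deterministic quantile initialization, with
labels ordered by ascending cluster mean.

The exponential fit initializes a₀ = max(y),
b₀/c₀ from a log-linear fit of log(a₀ − y) over the strictly positive
residues, and refines by Levenberg–Marquardt least squares; the
residual scale is the normalized MAD.

## Phantom generator

The phantom emulates a dried stem at 27.1 µm/px (a 2×2-binned
acquisition; a ~20 mm stem then fits a 768-px frame): outer radius
370 px, rind width 12 px (≈ 0.33 mm — also below the 31-px block
radius, so a noise-free uniform rind still exceeds its local mean),
pith radius 215 px.  Default populations are 200 periphery and 30 inner
bundles; bundle areas follow the measured law
*A = 0.129 − 5.594·10⁻⁴·e^{0.475·DC}* (mm² vs mm) with lognormal jitter
(σ = 0.08); bundles are ellipses of axis ratio 0.6–1.0 at random
orientation, placed by rejection sampling with pairwise clearance.
Intensity means: epidermis 200, periphery matrix 90, bundles 160, pith
cell-wall speckle 20 on a zero background; per-tissue SDs are
multiples of the global noise SD (default 10), applied to substance
pixels only — calibrated air is exactly 0 — and clipped to [1, 255] so
substance stays substance.  Pith speckle is isolated pixels on a
jittered 4-px grid (4% coverage), so it never forms components above
the candidate size floor.

Stress modes: `fusion_fraction` places 2–4 bundles per clump at center
spacing 0.92× the sum of their semi-axes (touching, shallow overlap);
`epidermis_contact_fraction` (default 0, opt-in) pushes bundles into
contact with the rind; `boundary_break` cuts a radial wedge through the
rind to exercise boundary repair.  Rendering is a pure function of
(spec, seed).

What the phantom does **not** emulate: beam hardening, ring artifacts,
partial-volume blur at tissue interfaces, non-elliptical bundle shapes,
anisotropic texture, multiple stems per frame.  Passing tests therefore
demonstrate the pipeline's geometric and statistical correctness under
the modelled contrast, not robustness to every real-scanner artifact.

## Problem sizes

The counting-fidelity check uses a seeded batch of 20 phantoms with
100–500 bundles per slice, noise SD 5–15 and fusion fraction 0–0.1 —
the package's desk-scale stand-in for a multi-variety CT survey; a
slice takes a few seconds end to end.

## Known limitations

* Deeply fused clumps (overlap well beyond tangency) merge the lobes'
  maximal inscribed circles into one seed group and stay unsplit; pairs
  at shallow overlap split reliably, longer chains less so.  The
  counting statistic tolerates this (fusion is ≤ 10% of bundles).
* The merged-candidate flag needs a fitted size-distance model; slices
  with few periphery candidates (< 10, or < 3 mm of DC span) skip
  splitting with a warning.
* Zone detection assumes one stem per frame (the largest component
  wins) and a pith that is mostly air after drying.
* Crofton perimeters are biased low on long axis-aligned straight
  edges; for the near-convex roundish bundles this is negligible.
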