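# Methods

## Reconstruction model

A virtual large slide is a composite of scanned fragments under recorded
rigid poses. Every pose is a mirror (horizontal/vertical), a rotation
about the fragment's geometric center, and a translation:

```
M = T(tx, ty) · T(c) · R(θ) · F · T(−c),    c = (w/2, h/2)
```

Mirrors are applied before the rotation; any fixed order spans the same
pose group, but serialization must be unambiguous, so this order is part
of the layout JSON contract (schema version 1). The linear part always
has determinant ±1, so stitched distances and areas keep their physical
scale.

**Coordinates.** Continuous, origin at the top-left, x right, y down;
pixel `(i, j)` covers the unit square `[i, i+1) × [j, j+1)` and is
sampled at its center. `θ` is positive counter-clockwise as seen on
screen. With the geometric-center convention, rotations by multiples of
90° map the pixel grid onto itself exactly; those poses (plus mirrors
and integer translations) form the *lossless fast path* on which
reconstruction is bit-exact. Arbitrary angles are supported — physical
fragments sit at arbitrary orientations — via the same matrices with
nearest (default) or bilinear sampling; bit-exactness is then no longer
possible and is not claimed.

Stitching is arranged at thumbnail scale (fragments downsampled
64-fold, the interactive default) and the translation is multiplied by
the thumbnail factor for full-resolution rendering; rotation and
mirrors are scale-free, so the thumbnail→level-0 round trip is exact.

## Compositing

Rendering uses a binary-alpha painter's rule: for each canvas pixel,
fragments are consulted in ascending z-order and the top-most fragment
whose inverse-mapped source pixel is tissue supplies the RGB value
unchanged; everything else is opaque white (glass background). No
blending ever occurs, so every output pixel is a verbatim copy of
exactly one input pixel — the provenance property behind the "lossless"
claim. Overlaps resolve by z-order (last import on top), mirroring how
physically stacked slides occlude. Tiles render independently in
deterministic row-major order, so a full render behaves as a resumable
background job (synchronous function + progress callback; no
concurrency primitive is imposed) and repeated runs are byte-identical.

The output is a tiled (256 px, power of two) pyramidal TIFF, Deflate
(zip) compressed — lossless by construction; JPEG is deliberately not
offered. Level k is the level-0 plane area-downsampled by 2^k; pyramid
depth defaults to halving until the larger dimension is ≤ 1024 px.
Physical scale is stored as a single isotropic microns-per-pixel value
in the resolution tags (pixels per centimeter); anisotropic inputs are
rejected rather than silently averaged.

## Tissue matting

Matting exists to stop rectangular scans from occluding their
neighbours during stitching, not to segment tissue precisely. The
tissue signal is `max(255 − brightness, saturation)`: eosin-pink tissue
is saturated, hematoxylin-dark tissue is dark, glass is neither. The
signal is thresholded (Otsu by default, or a fixed threshold), cleaned
by 3×3 closing then opening, small components (< 64 px) are dropped and
enclosed holes filled. Masks are binary — {0, 255} — which keeps
round-trip tests exact and the compositing rule trivial.

Two numerical choices matter:

- **Otsu cap.** On sections holding both pale stroma and dark carcinoma
  the signal is trimodal, and unconstrained Otsu tends to split between
  the two tissue modes, discarding pale stroma wholesale. The adaptive
  threshold is therefore capped at the conservative glass level
  `255 − fixed_threshold` (default 20): Otsu may adapt downward for
  faint scans but never above the level that separates glass.
- **Mask scale.** Masks are computed on thumbnails and nearest-neighbour
  upsampled during level-0 rendering; each mask records its own
  downsample factor. Gigapixel scans mat at the 64× stitching-thumbnail
  scale; small or already-downsampled fragments fall back to finer
  factors (`choose_mask_factor`) so the morphological cleanup still has
  pixels to operate on. Render pipelines additionally dilate the mask
  by one mask pixel (`dilate_mask`): the extra rim is glass and
  composites as background, while boundary blocks that fell just under
  threshold are no longer dropped.

**Limitation.** A cut that passes near-tangentially through the tissue
boundary leaves slivers thinner than a mask block; binary matting at a
coarse scale can drop such slivers (observed at the 1e-4 level on
synthetic fixtures). The lossless guarantee of the renderer itself is
independent of matting — with opaque fragments and fast-path poses,
reconstruction is bit-exact.

## Measurement

All measurements live on the reconstructed canvas in level-0 pixels and
convert through mpp: `mm = px · mpp / 1000`. Annotations are GeoJSON
polygons labeled `tumor_bed`, `invasive` or `cis`.

- **Diameters.** The bed is the union of all `tumor_bed` polygons —
  disjoint pieces are one bed, since the reconstruction is of a single
  largest cross-section. Length is the maximum pairwise distance
  between convex-hull vertices; width is the hull's extent perpendicular
  to the length axis (standard bidimensional tumor measurement, not the
  second-longest independent chord).
- **Percentages.** `pct_ca = 100 · area(union(invasive ∪ cis) ∩ bed) /
  area(bed)`; `pct_cis` is the in-situ share of the carcinoma area
  (the usual RCB convention), switchable to a bed denominator because
  "proportion of carcinoma in situ" is ambiguous in clinical usage.
  Unions and bed-clipping (not sums) keep both in [0, 100] under
  overlapping or nested labels; carcinoma drawn outside the bed is
  excluded with a warning. These are *label-area* ratios: cellularity
  within a region is delegated to how finely the user outlines invasive
  foci, which is what an annotation-driven calculator can honestly
  compute.

## RCB scoring

`rcb_index` evaluates the published formula with two recorded
interpretations: the primary size is `sqrt(d1·d2)` (geometric mean of
the two measured diameters — the standard definition; `size_mode=
"longest"` is available), and the invasive fraction carries the CIS
correction `(pct_ca/100)·(1 − pct_cis/100)`. Each power term is defined
as 0 when its base is 0, making the score exactly 0 iff there is no
invasive primary disease and no positive node (pathologic complete
response). Band edges are upper-inclusive as published (1.36, 3.28);
ypT stages are T1 ≤ 20 < T2 ≤ 50 < T3, with 50 mm assigned to T2.
T4 depends on chest-wall/skin involvement, which is not a size — a
`skin_chest_wall` flag raises rather than guesses. Input validation
couples the nodal fields: a positive node count requires a positive
largest-metastasis diameter and vice versa.

## Synthetic fixtures

The generator emulates the study material: one largest cross-section of
a post-therapy tumor bed, scanned in fragments.

- **Section.** A 40 × 30 mm canvas at 32 µm/px (the scale of a 64-fold
  downsampled 0.5 µm/px scan; ~1250 × 938 px, desk-scale by design).
  The bed is an ellipse (default semi-axes 15 × 10 mm → 30 × 20 mm
  diameters); invasive and in-situ foci are ellipses strictly inside
  the bed and pairwise disjoint, so every area is `π·a·b` and every
  ground-truth quantity has a closed form. Defaults put 27 % invasive +
  3 % CIS by area in the bed (pct_ca = 30, pct_cis = 10) with 2
  positive nodes and a 5 mm metastasis — a mid-range grade-III case.
  Annotation polygons are inscribed 256-gons with vertex count
  divisible by 4, so polygon diameters equal the true diameters exactly
  and all area ratios are exact (the inscribed-polygon area deficit
  cancels in ratios). Tissue pixels carry seeded ±5 uniform noise
  (clipped below 255) so matting sees texture and "tissue" is
  identifiable as non-white; images are byte-identical per seed.
- **Cut plan.** 2–8 near-vertical cuts with positional jitter, matching
  serial grossing of a slab; `gap_px` columns lost per cut emulate
  blade kerf. Each fragment is independently mirrored (p = 0.5) and
  rotated by a 90° step, exactly as scanned slides arrive in arbitrary
  orientation; the emitted layout stores the inverse of each
  perturbation, so rendering it reconstructs the section (bit-exactly
  for the default 90° perturbations and zero gap). Free-angle
  perturbations cannot be realized exactly on the pixel grid when
  *generating* fragments, so free-angle plans perturb with mirrors only;
  the renderer's free-angle path is validated separately against a
  brute-force oracle. A degraded grayscale PNG stands in for the
  radiograph used as a stitching guide (synthetic; it is never
  computationally registered).
- **Rater panels.** Continuous ratings are truth + i.i.d. Gaussian
  noise per rater (clipped to the valid range); categorical ratings
  are redrawn uniformly over the category set with a confusion
  probability (so confusion 1 means category-blind raters and
  chance-level agreement). Defaults mirror a five-reader panel.

What passing these fixtures does *not* show: robustness to stain
variation, pen marks, coverslip artifacts, tissue deformation between
sections, or non-rigid distortion — real slides have all of these, and
the generator deliberately has none.

## Reliability statistics

ICC is fixed to the two-way random-effects, absolute-agreement,
single-measures model — ICC(2,1) — computed from the two-way ANOVA mean
squares; this is the standard choice when raters are interchangeable
readers and systematic rater offsets should count as disagreement. The
model name is echoed in all outputs since other ICC variants are not
comparable. Fleiss' kappa handles the categorical endpoints (grade,
stage). The paired t-test is two-sided with no multiple-testing
correction. Degenerate tables (zero variance; all ratings one category;
zero-variance differences) raise typed errors instead of returning
NaN. Implementations are closed-form and are cross-checked in the test
suite against independent references (pingouin, statsmodels, scipy).

## Problem sizes and tolerances

Test fixtures run at desk scale: ~1250 × 938 px sections, 2–8
fragments, 512² canvases for brute-force oracle comparisons, rater
panels up to 500 × 5. Key tolerances: measurement recovery within 1 %
(polygon discretization is ~4·10⁻⁴); renderer vs oracle exact on the
fast path and ≤ 1 intensity level for bilinear; reliability statistics
vs formula oracles at 1e-10; ICC parameter recovery within ±0.05
(median over 20 seeds at n = 500). Two-step thumbnailing agrees with
one-step within ±2 intensity levels (two 8-bit quantizations), with
≥ 99.9 % of pixels within ±1.
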