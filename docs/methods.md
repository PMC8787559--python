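# Methods

## Scope and model of the problem

The package operates on 2D instance label maps (non-negative integers, 0 =
background, each positive id one 8-connected nucleus) and on three-channel
softmax probability maps (inner nucleus / contour / background). It
implements the computational stages of a segmentation strategy in which a
semantic network and an instance network are trained with minimal manual
annotation and their outputs combined: label encoding for training,
semantic-to-instance post-processing, fusion, evaluation, and a parametric
simulator of nuclei masks. Network training and inference are explicitly
out of scope; the `synthgen` module supplies synthetic stand-ins for their
outputs so every stage is exercisable end to end.

8-connectivity is used everywhere (component labeling, adjacency,
morphology with a 3×3 square element); it matches the visual continuity of
rasterized ellipses and is stated once here rather than per function.

## Three-class encoding

A nucleus pixel is *inner* when every pixel within Chebyshev radius
`contour_width` (default 1) carries the same label; otherwise it is
*contour*. This inner-boundary convention keeps the contour band inside
the nucleus, so the background class is exactly the complement of the
foreground. Computed with grey-scale min/max filters, the band is exact
for any width.

Contours between touching nuclei are additionally dilated by
`touching_dilation_radius` (default 1, 3×3 square). The dilated touching
band overwrites inner pixels but is clipped to the foreground: background
is never reclassified, preserving the class partition. The original
processing chain does not state the dilation element or amount, so both
are parameters; the defaults are the smallest non-trivial choice.

Class weights for a weighted cross-entropy loss are the inverse pooled
class proportions, normalized so that equal-frequency classes give
(1, 1, 1): `w_c = T / (3 n_c)`. A class absent from the pooled pixels is
an error (its weight would be infinite), reported by name.

## Semantic-to-instance post-processing

Pipeline, in order: seeds → Voronoi assignment → object masking → gap
repair → area filter → id normalization.

- **Seeds** are 8-connected components of `p_inner − p_contour >
  seed_threshold` (default 0.35, strict). Subtracting the contour channel
  carves gaps between touching nuclei.
- **Voronoi assignment** gives every pixel the id of the seed component
  nearest in Euclidean distance to the component's pixel set, computed as
  one exact distance transform per component with strict-improvement
  updates in ascending id order, so exact ties deterministically go to the
  smaller component id. Squared distances are integers; the float
  comparisons are therefore exact.
- **Object mask**: `p_background < background_threshold` (default 0.95,
  strict, per the wording "inferior to").
- The mask can fragment a Voronoi cell; only the fragment containing the
  cell's seed is kept as the nucleus. Stray fragments are noise speckles
  far from any seed; keeping them would split nuclei and break the
  invariant that the output count never exceeds the seed count. With the
  default thresholds every seed pixel lies inside the object mask
  (`p_inner − p_contour > 0.35` forces `p_background < 0.65`), so each
  retained nucleus contains its seed.
- **Gap repair**: the tessellation-times-mask product leaves a thin
  unassigned strip between nuclei. Unlabeled object pixels 8-adjacent to a
  nucleus take the modal adjacent id (ties to the smaller id), iterated up
  to `gap_dilation_radius` times (default 1). This reproduces the
  dilate-and-multiply repair functionally rather than operation by
  operation.
- **Area filter**: nuclei under `min_area` (default 35 px) are removed
  *after* gap repair, matching the stated order; ids are then renormalized
  to 1..K in raster-scan order.

## Fusion

The combination starts from the instance-segmentation nuclei. Each rule's
overlap fraction is relative to the area of the nucleus being tested,
against the *other map's full foreground* (not per-nucleus pairing):

1. instance nuclei with semantic overlap < 0.20 are discarded
   (hallucination removal; kept at exactly 20 %);
2. semantic nuclei with instance overlap < 0.33 are added (exactly 33 % is
   not added), clipped to pixels not occupied by kept nuclei — kept nuclei
   take precedence, and a clipped addition falling under `min_area` is
   dropped;
3. nuclei under 35 px are removed and ids renormalized.

Whether the original tolerated overlapping labels is unstated; clipping is
this package's declared behavior, and it guarantees one id per pixel.

## Evaluation

The pairwise IoU matrix between ground-truth and estimated nuclei is
computed from integer intersection/area counts. A pair is matched iff its
IoU is positive and strictly the maximum of both its row and its column;
strictness is decided by integer cross-multiplication (`i1·u2 > i2·u1`),
never floating point, so exact ties — which produce no match, as the
strict inequalities require — are handled deterministically. FN and FP are
the complements of TP (`FN = n_gt − TP`, `FP = n_est − TP`), which the
one-to-one matching forces. Conventions: both maps empty → F1 = 1 at every
threshold (perfect agreement on nothing); one side empty → F1 = 0. The
default threshold grid is 0.05 to 0.90 in steps of 0.05 (the range is
standard; the step is this package's choice). Aggregation across images is
the per-threshold arithmetic mean and population standard deviation.

## Mask simulator

Counts per image are Gaussian (`mean`, sample-`sd` estimators), truncated
at 0 and rounded. Areas are Gumbel (`location` μ, `scale` β), fitted by
method of moments — β = sd·√6/π, μ = mean − γβ with γ the
Euler–Mascheroni constant — because the closed form is exactly testable;
maximum likelihood is available behind `method="mle"`. Size draws are
truncated below at 35 px² (the post-processing minimum), by redraw.

Each nucleus is an ellipse with uniform orientation on [0, π). The
eccentricity clause "axis ratio Gaussian with mean s/π and sd 0.2·s/π" is
dimensionally inconsistent for a ratio (s/π is an area), so it is realized
as: semi-major axis a ~ N(√(s/π), 0.2·√(s/π)) truncated positive, with
b = s/(πa), giving the stated 20 % coefficient of variation on the axis
while preserving the drawn area exactly. This is an interpretation, not a
claim about the original intent.

Placement is uniform; a candidate whose overlap with already-placed nuclei
exceeds `max_overlap` (default 0 — disjoint masks; the original is silent
on overlap) is redrawn up to 50 times, then skipped. Two placement
refinements exist for controlled experiments: `min_gap` requires the
candidate dilated by that many pixels to be free of other nuclei
(strictly non-touching masks), and `keep_inside` shrinks the center range
so no ellipse is clipped at the border. Border clipping truncates areas
and would bias any distribution refit; the fit/sample self-consistency
check therefore uses `keep_inside`. Rasterization counts pixel centers
inside the ellipse; for areas ≥ 35 the pixel count stays within 15 % of
the drawn area (checked statistically). With a fixed integer seed
(NumPy PCG64 via `default_rng`) all outputs are bit-reproducible;
dataset generation uses seed + image index.

Default generation parameters (count mean 30, sd 5 per 256×256 field;
Gumbel μ = 100 px², β = 20 px²) describe a dense epithelial field with
median nucleus diameter ~12 px and a heavy right tail, the regime the
35 px minimum-area rules were designed for.

## Synthetic network stand-ins

`render_image` draws foreground at `fg_mean` plus a low-frequency texture
field, background at `bg_mean`, then Gaussian blur and additive noise.
`probabilities_from_instances` one-hot encodes the three-class map,
smooths each channel (σ = `softness`), adds clipped Gaussian noise and
renormalizes per pixel; softness 0 / noise 0 gives the exact one-hot
encoding. `corrupt_instances` applies drop / merge (8-adjacent pairs
only — physically mergeable) / chord-split / boundary jitter, with
dilation claiming only background so jitter alone never merges nuclei.

These noise models are test instruments. They do not claim to match any
trained network's error statistics: real softmax maps have
spatially correlated errors, and real instance networks make
shape-dependent mistakes. What passing tests show is that the
*post-processing, fusion and evaluation stages* behave as specified on
inputs with known ground truth and controlled error modes — not that any
particular network reaches a given accuracy on real tissue. In the
end-to-end demonstrations the semantic stand-in uses softness 0.5 and
noise 0.02 (boundary uncertainty about one pixel, sharp softmax),
representing a competently trained network: under much heavier smoothing
the generous 0.95 background threshold balloons every nucleus — a
designed property of the post-processing on diffuse inputs, not an error
mode the fusion rules are meant to absorb.

## Problem sizes and numerical choices

The test suite and the acceptance script run on simulated 256×256 fields
(50 images for round-trip recovery, ~340 for the ~10⁴-area distribution
refit, 200 for count statistics, 10 for jitter and fusion experiments) —
sizes at which the statistical tolerances (3 standard errors for the
refit, ±1.0 on the mean count) are meaningful while the whole suite runs
in well under a minute of compute per module. Oracle-equivalence checks
(brute-force nearest-seed assignment; exhaustive rational-arithmetic
evaluation of the mutual-best rule) run on hundreds of random maps up to
20×20 with up to 6 nuclei per side, where exhaustive enumeration is exact
and cheap. Thresholding comparisons against the fixed grid values use
ordinary float comparison on IoU values stored as double-precision ratios
of integers; only the *tie* decisions inside the matching use exact
integer arithmetic, because ties are where floating point could change
the result.

## Known limitations

- The Voronoi assignment is quadratic in the number of seed components
  times image area (one distance transform per component); fine for
  realistic densities (hundreds of nuclei), slow for thousands.
- Fusion handles exactly two inputs and hard labels; no soft/probabilistic
  fusion.
- More than 65535 nuclei per image is unsupported (16-bit label files).
- The simulator draws nuclei independently (no spatial clustering or
  alignment of neighboring cells) and its ellipses have no boundary
  irregularity; real epithelial fields violate both.
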