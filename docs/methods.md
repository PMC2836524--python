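# Methods

## Imaging and segmentation

Input photographs are reduced to 8-bit grayscale with fixed BT.601 luma
weights (0.299 R + 0.587 G + 0.114 B), float input interpreted on [0, 1]
and 16-bit input on its dtype range, rounded half-up. No contrast
stretching is applied: the conversion is a fixed linear map, so thresholds
are comparable across images taken under the same conditions.

Both segmentation steps are global histogram thresholdings. The original
clinical protocol set thresholds by visual inspection; `cariescan`
defaults to automatic between-class-variance maximization (Otsu), with a
manual override, because a screening tool must be reproducible and
auditable. The Otsu split is computed by exhaustive evaluation of all 255
candidate split points of the 256-bin histogram (vectorized cumulative
sums), so it equals a brute-force search by construction; ties resolve to
the lowest split.

Polarity is fixed by the physics of intraoral photographs: enamel is
bright on a dark background, discoloration darker than enamel. The
surface mask is "strictly above threshold"; after thresholding, only the
largest 8-connected component is kept and interior holes are filled, so
dark fissures do not punch holes out of the surface area — the occlusal
surface is measured as a single region. The discoloration mask is
"strictly below threshold" restricted to surface pixels, with the
automatic threshold computed on the surface-restricted histogram. Because
Otsu classifies {≤ t} vs {> t}, the recorded discoloration threshold is
t + 1, so the strict inequality captures exactly the dark class.

`PA = discolored pixels / surface pixels` is exact integer arithmetic and
therefore invariant under translation, 90° rotation, and integer
upscaling of both masks.

Degenerate inputs: a single-intensity histogram has no valid split and
raises ("degenerate histogram"); an empty surface mask raises; an empty
discoloration mask is valid (PA = 0).

## Fractal dimension

Box counting is the primary estimator. The pattern is cropped to its
bounding box (grid anchored at the pattern's top-left corner, single
offset — no offset minimization, for determinism) and counted over a
dyadic ladder of box sizes, 2, 4, 8, … up to `max(maxdim // 4, 16)` where
`maxdim` is the larger bounding-box side. The floor of 16 guarantees at
least four scales for any pattern, including tiny isolated lesions; boxes
larger than the pattern simply count 1. Partial boxes at the right/bottom
edges are counted. FD is the negated slope of the ordinary least-squares
line of ln N(s) on ln s with equal weight per scale; r² below 0.95 sets a
quality flag. On the calibration shapes the dyadic ladder gives exactly
collinear log-log points (line: N = ⌈L/s⌉; square: N = (L/s)²; Sierpinski
at dyadic sizes: N = 3^(depth−k)), so those fits are exact. An empty mask
is an error (FD undefined); a single pixel gives N(s) = 1 at every scale
and hence FD = 0 through the fit — a point is zero-dimensional. FD is
computed on the filled discoloration region, not its outline.

The Minkowski cross-check dilates the pattern by Euclidean disks of
radius r (exact distance transform) and fits ln(A(r)/r) against ln(1/r);
since A(r) ~ r^(2−D) for a D-dimensional set, the dimension is 1 + slope.
Radii are an explicit argument (default 2, 4, 8, 16) because the valid
regime depends on the pattern: r must exceed the pixelation scale (a
1-px-wide line needs r ≳ 4 before its own width stops biasing the
sausage area) yet stay well below the feature size (a filled 128-px
square needs r ≲ 8 before the sausage is mostly perimeter). Within those
regimes the two estimators agree to better than 0.2 on the line, square,
and Sierpinski fixtures.

## Discriminant classification

The classifier is the two-class Fisher linear discriminant with pooled
within-class covariance and class-frequency priors: w = S_pooled⁻¹(μ_op −
μ_prev), intercept chosen so Y = 0 at the prior-weighted mean of the two
class score means (the grand mean score). Larger FD/PA/DD means deeper
caries, so the score is oriented with the operative class positive; all
four built-in reference formulas have positive feature coefficients
consistent with this. Ties (Y = 0) map to preventive — an arbitrary but
fixed convention, stated in the CLI help. For a one-variable model the
decision threshold is −intercept/coefficient; on the reference formulas
this yields FD 1.20, PA 0.012, DD 28.8 at their printed precisions.
Singular pooled covariance (e.g. collinear features) and single-class
inputs are errors. Evaluation of fitted models on their own training
table is resubstitution and is labeled as such; exact reproduction of the
reference coefficients is not attempted, since the underlying clinical
sample is not available — the decision geometry (threshold placement
between class means) is the reproducible object.

Model files store coefficients as IEEE-754 hex strings, making the JSON
round trip bit-exact.

## Synthetic data

The image generator renders a stylized occlusal view: an ellipse of
bright enamel (default level 200) on a dark background (30) carrying dark
discoloration (60), optionally with Gaussian intensity noise, at 256×256
px with ellipse semi-axes (100, 70). Severity controls morphology,
mirroring how lesion shape evolves from point to line to area:

- **C0** — 2–4 isolated point blobs;
- **C1** — a single jittered fissure polyline along the long axis;
- **C2** — a branching fissure tree with widened lesion patches.

The skeleton is drawn strictly inside an eroded interior of the ellipse,
then thickened to the target discolored-pixel count by thresholding the
Euclidean distance to the skeleton, topping up the final equidistant ring
with a random subset so the realized PA hits the target count exactly.
Default target PA per class is the clinical class mean (C0 0.005, C1
0.012, C2 0.051). Everything derives from one seeded generator, so a
spec + seed pair is bit-reproducible.

What this emulates — and does not: the generator produces clean two- or
three-level images with known ground truth, suitable for validating the
segmentation arithmetic, the FD severity ordering, and the end-to-end
plumbing. It does not model specular highlights, plaque, wetness, color
casts, camera blur, or neighboring teeth, so passing tests demonstrate
internal consistency of the pipeline, not clinical performance on real
photographs.

The feature-table generator draws (FD, PA, DD) per tooth from truncated
Gaussians (FD on [0, 2.5], PA on [0, 1], DD on [0, 99]) whose per-class
means/SDs and sizes default to the clinical reference sample (C0: n=64,
FD 1.09±0.16, PA 0.005±0.009, DD 16.9±15.0; C1: n=24, FD 1.34±0.09, PA
0.012±0.008, DD 45.2±25.1; C2: n=12, FD 1.52±0.09, PA 0.051±0.022, DD
57.9±27.7). Features are independent within a tooth by default — only
marginal moments are published for the clinical sample — with an optional
Gaussian-copula correlation knob for sensitivity studies. Left truncation
at 0 inflates the realized mean of the near-zero C0 PA cell above its
nominal 0.005; validation against the generator therefore uses the
truncated distribution's own analytic moments, not the naive Gaussian
ones.

## Numerical and design choices

- Coordinates are row-major, 0-based; masks are boolean in memory and
  export as 8-bit PNG with foreground 0 / background 255.
- Report formatting mirrors the clinical convention: FD 2 d.p., PA 3
  d.p., DD 1 d.p., metrics 2 d.p.
- Spearman's rho is the tie-aware midrank Pearson correlation (scipy);
  the C0/C1/C2 scale is coded ordinally 0/1/2. Constant sequences leave
  rho undefined (NaN with a warning).
- Sensitivity/specificity take operative as the positive class; a truth
  vector lacking a class leaves the corresponding metric NaN.
- Group-difference hypothesis tests (ANOVA-style) are out of scope; the
  report prints per-class means/SDs instead.

## Validation problem sizes

The self-tests use 50 synthetic teeth per severity class for the
end-to-end ordering check, 100 random 64×64 masks and 50 random images
for the brute-force oracle comparisons, 5000 samples per class for the
closed-form discriminant recovery, 10 000 draws per class for the
truncated-moment checks, and 20 replicate simulated tables at the
clinical class sizes (64/24/12) for the screening-performance bound.
These sizes put Monte-Carlo error well inside the asserted tolerances
while keeping the whole suite fast.

## Known limitations

- Global per-image thresholds; no per-region adaptation.
- Box counting assumes approximate self-similarity over the scanned
  scales; strongly anisotropic (self-affine) patterns are only
  approximated, which is why the Minkowski estimator ships alongside it.
- The reference discriminant formulas come from one clinical sample and
  are not universal; refitting on local data is expected.
- DD readings are consumed as numbers; the device and its confounders
  (staining, wetness, hypomineralization) are not modeled.
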