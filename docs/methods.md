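# Methods

## The estimator

The box dimension of a binary raster is the finite-scale estimate of the
Minkowski–Bouligand dimension: cover the foreground with a square grid of
cell side *r* pixels, count the occupied cells *N*(*r*), and fit

    log10 N(r) = log10 c − D_B · log10 r

by ordinary least squares over a schedule of sides. `D_B` is reported as the
slope magnitude and `R` as the magnitude of the Pearson correlation of the
fitted points; the slope's standard error and the intercept are carried in
the results object. All schedule points enter the fit — no endpoint
trimming — so the quality of the scaling regime is visible in `R²` rather
than hidden by point selection.

**Grid anchoring.** The grid is anchored at the top-left corner of the
foreground bounding box and tiles in steps of *r*; partial cells at the far
edges count like full cells if occupied. Anchoring to the foreground (not
the canvas) makes every estimate bit-exactly invariant to translation and to
empty margins. A single fixed grid is used — no minimum over grid offsets —
so the estimator is cheap and fully deterministic. The cost of the single
grid is a small corner dependence: a 90° rotation maps the top-left-anchored
partition onto a differently anchored one, so on asymmetric patterns the
counts at sizes not dividing the bounding box can shift *D_B* by up to a few
×10⁻² (measured 0.005–0.026 on the shipped tree fixtures). On patterns with
exact 4-fold symmetry the partition maps onto itself and quarter turns leave
*D_B* exactly unchanged. This residual orientation sensitivity is precisely
the motivation for the rotation-averaging protocol below.

**Schedules.** The *modified* schedule takes *r* = 2⁰, 2¹, …, 2^k, with *k*
the smallest exponent at which a single box covers the pattern. On
dyadically self-similar patterns every point of this schedule obeys the
power law exactly: a filled 2^m square gives *D_B* = 2 with *R*² = 1 to
machine precision, a 1-px line gives exactly 1, and the depth-*d* Sierpinski
sieve gives log 3 / log 2 = 1.585 exactly. The *standard* schedule is the
fixed mixed progression {2, 3, 4, 6, 8, 12, 16, 32, 64} used by common
box-counting tools, truncated to sizes not exceeding the longer bounding-box
side; it is declared in the configuration echo of every run and
configurable, since published "standard" analyses rarely print their size
lists. The non-dyadic sizes make even a filled power-of-two square fit
imperfectly (ceil effects at r = 3, 6, 12 give 2.0007 rather than 2), which
is the schedule-choice effect the modified protocol removes. Note that a
finite-scale fit over *all* scales reads hollow shapes as more than
1-dimensional: the outline frame of a filled 64-square fits at 1.29 because
its coarsest two schedule points behave plane-like; restricted to fine
scales (r ≤ 16 on a 256-frame) the same fit gives 1.0 within 0.05.

## Representations

- **binary**: the thresholded drawing. Binarization is a strict threshold
  (dark polarity: foreground iff value < threshold) and idempotent.
- **outline**: foreground pixels with at least one background pixel among
  their 8 neighbours; off-image counts as background. The 8-neighbourhood
  rule matches the usual binary-outline tool semantics; a 4-neighbourhood
  variant would thin diagonal contacts and is not offered.
- **skeleton**: Zhang–Suen two-sub-iteration parallel thinning iterated to
  a fixpoint, implemented exactly from the classical conditions (neighbour
  count B(p) ∈ [2, 6], transition count A(p) = 1, and the two directional
  pixel-product tests per pass). No spur pruning is applied — artifact
  removal is a curation step left to the user. One-pixel-wide structures
  are fixed points and the operation is idempotent. Degenerate limits are
  accepted: a filled square thins to a single pixel, on which no 3-point
  schedule exists; the batch pipeline records such combinations as NaN
  rows rather than failing the run.

Soma removal, axon/spine deletion and dendrite filling are documented as
manual preprocessing: the pipeline expects a pre-cleaned drawing.

## Rotation protocol

For cells without radial symmetry the apparent *D_B* depends on orientation.
The protocol: find the dendritic-field diameter (the maximal-distance pair
of foreground pixels; convex-hull reduction with exact integer
squared-distance tie-breaking, lexicographic on the point pair), rotate
about its midpoint, and average the apparent *D_B* at 45°, 135°, 225°, 315°.
The 0° value does not enter the average. A full profile at a configurable
step (default 15°) is available for inspection; on the shipped asymmetric
tree the profile maximum falls on one of the four oblique angles.

Rotation is inverse-mapped nearest-neighbour with half-up rounding
(`floor(x + 0.5)`), which keeps the operation purely binary — no
re-thresholding parameter — and makes every multiple of 90° an exact lattice
permutation regardless of whether the rotation centre sits on a half-integer
coordinate. The canvas is expanded so no foreground is ever clipped. Oblique
angles preserve foreground area only approximately (within ~2% on the tree
fixtures); this is inherent to binary nearest-neighbour resampling.

## Resolution sweep

Digitisation resolution is modelled as a pure size factor dpi / base_dpi
(default base 600 dpi, the usual scanning resolution for ink drawings;
default sweep 100–1100 dpi in steps of 100). Resampling is origin-aligned
nearest neighbour: output pixel *i* samples input pixel ⌊i·h/out⌋. The
origin-aligned convention was chosen over centre-aligned sampling because
dyadic downscales then land on the even sub-lattice, preserving dyadically
self-similar patterns exactly (halving the Sierpinski sieve yields the
next-lower sieve; a centre-aligned rule samples only odd indices and
annihilates it). The sweep result is the OLS slope of *D_B* against dpi; on
the tree fixtures it is below 10⁻³ per dpi, and exactly zero for a filled
square swept at dyadic factors.

## Statistics

Cohorts of 9–24 cells are too small to assume normality, so each group is
screened with the moment descriptors a₃ = m₃/m₂^{3/2} and e = m₄/m₂² − 3
(population central moments, divide by *n*; the group mean's standard error
uses the n−1 sample standard deviation). Their standard errors are

    σ₃(n) = sqrt(6(n−1) / ((n+1)(n+3)))
    σ₄(n) = sqrt(24 n (n−2)(n−3) / ((n+1)² (n+3)(n+5)))

σ₃ was adopted in this exact form because it reproduces the tabulated 0.452
at n = 24 (the alternative with n−2 gives 0.442). σ₄(24) = 0.737 under the
exact form; the published protocol value 0.768 for n = 24 matches no
standard formula, so it is kept in an explicit compatibility table
(`source="published"`, the default for normality screening) rather than
silently replacing the formula. The exact σ₄ is not monotone in *n*: it
rises from 0.60 at n = 6 to a mode near n = 15 before its asymptotic
sqrt(24/n) decay.

The normality screen has two modes. The *published* mode follows the
protocol literally: normal iff |σ₃/a₃| ≤ 2 and |σ₄/e| ≤ 2. This is the
reverse of the conventional ratio and behaves counterintuitively — an
exactly symmetric sample makes the quotient undefined (reported as an
explicit error, never silently passed), and very normal-looking samples
with small |e| are declared non-normal. The *conventional* mode
(|a₃/σ₃| ≤ 2 and |e/σ₄| ≤ 2) is available by flag and passes ≥ 90% of
simulated normal samples at n = 24. Both modes return the ratios so the
decision is auditable.

Mean comparisons use Student *t*: paired (t = mean(d)/(sd(d)/√n), df = n−1)
for the same cells under two schedules, pooled two-sample (df = n₁+n₂−2)
for independent cohorts. Results are reported against two-tailed critical
values at α = 0.05, 0.01, 0.001 (scipy `t.ppf`), matching the tabulated
presentation of this protocol rather than exact p-values; no
multiple-testing correction is applied across the three representations,
by design. The pooled test is calibrated: on same-distribution normal
groups of sizes 15 and 9 it rejects at α = 0.05 in 5% ± 2% of 1000 seeded
replicates.

Reference group means for type III aspiny neurons of the adult human
neostriatum (n = 24) under both schedules ship as
`stats.TYPE_III_REFERENCE_MEANS`; recomputing the schedule discrepancy from
them (denominator = modified-schedule mean) gives 2.7% (binary), 0.7%
(outline) and 0.4% (skeleton).

## Synthetic fixtures

The generators provide the study conditions for every test:

- *Analytic shapes* (filled rectangles, 1-px lines, the Sierpinski sieve
  with pixel (x, y) foreground iff x & y = 0, rasterised disks) have
  known exact dimensions and counts, usable as oracles.
- *Random branching trees* emulate sparsely branching neurons with a large
  dendritic field: `n_primary` trunks (default 5) leave a central soma
  point, segments of mean length 22 px (±30% jitter) continue or bifurcate
  with probability 0.35 per segment, direction wander of ±35°, up to 8
  segments deep, on a 512-px canvas with a ≥ 5% protected margin so
  rotation never clips. Segments are rasterised with 8-connected digital
  lines and optionally thickened by square dilation, so every tree is a
  single 8-connected component. Real morphometry for the emulated cell
  class is not published, so these parameters are plausibility choices,
  fixed once: they produce binary box dimensions around 1.3–1.45, in the
  range reported for sparsely branching neurons.
- *Cohorts* derive per-image seeds as seed + index, so a cohort can be
  extended without altering existing members.

What the fixtures do **not** emulate: grayscale staining texture, scanner
noise, somata and spine remnants, and the specific morphologies of real
cell classes. Passing tests therefore demonstrate correctness of the
estimator and protocol on controlled inputs, not that any particular
biological cohort has a particular dimension.

## Problem sizes and numerical choices

Test and validation runs use canvases of 64–512 px, trees of a few thousand
foreground pixels, cohorts of 9–24 images, 50 replicate pairs for the
power check and 1000 replicates for type-I calibration — sizes at which
every exactness claim is checkable by brute-force oracles while the whole
suite runs in seconds. Degenerate inputs are rejected loudly: empty
foreground, schedules shorter than 3 sizes, zero-variance samples, and
resamples below 8 px a side all raise with a message naming the cause.
Box counts use exact integer arithmetic; only the final log-log fit is in
floating point.

## Known limitations

- The single-grid estimator retains a small orientation dependence (see
  grid anchoring above); the rotation average mitigates but does not
  eliminate it.
- Box dimensions of hollow/outline shapes from full-range fits exceed the
  asymptotic curve dimension; compare outline values only against outline
  values fitted the same way.
- The published-mode normality screen is kept for protocol fidelity, not
  statistical merit; use conventional mode for new work.
- No 3D box counting, no mass-radius or caliper estimators, and no
  automated image curation.
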