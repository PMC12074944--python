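# Methods

## Calibration and area measurement

All physical measurements derive from a single pixel-to-millimetre factor
`mm_per_px = known_mm / ‖a − b‖`, where `a` and `b` are two annotated pixel
positions on the image's embedded millimetre scale. Pixels are assumed
isotropic (square), so one segment suffices and an area is simply
`foreground pixels × mm_per_px²`. Pixel counting is the primary area: it is
exact on binary masks and invariant to orientation. Contours (outer
boundaries of 8-connected components, traced at the half-intensity level)
and their shoelace polygon areas are retained only as a cross-check; on a
simply connected mask the two agree to within one perimeter's worth of
pixels, which the test suite asserts on random blobs.

The Pigmentation Coverage Ratio is
`PCR (%) = 100 × pigment area / lesion area`. It is undefined on an empty
lesion mask (an error, not a silent 0), bounded in [0, 100] by construction,
monotone in added pigment pixels, and invariant under rotations and under
rescaling of `mm_per_px` (areas scale by `s²`; their ratio does not).

Two pigment paths are exposed because annotation practice varies: the raw
pigment annotation as drawn, or the annotation intersected with inclusive
per-channel RGB windows (`threshold_pigment`). There are deliberately no
default colour bounds — they are image-set specific and belong in the
scenario configuration. A pigment annotation that overshoots the lesion
boundary is clipped to the intersection with a logged warning rather than
rejected, since hand annotations commonly overshoot by a pixel or two.

## Size and depth classification

Size bins: small ≤ 15 mm², medium (15, 50] mm², large > 50 mm². The
clinical wording defines the bins on integers (≤ 15, 16–50, > 50), leaving
(15, 16) formally unassigned; the half-open closure preserves every integer
membership while making the classifier total on real-valued areas.

Depth layers: the invasion depth in cm is rounded half-away-from-zero to one
decimal, then UL ≤ 0.2 < 0.3 ≤ ML ≤ 0.4 < 0.5 ≤ LL. Micrometer-read depths
are reported at one-decimal precision, so rounding makes the three layers
exhaustive; 0.5 cm is assigned to the lower layer. Both classifiers are
total, deterministic and monotone.

Summaries report the sample SD (n − 1 denominator). A layer with one lesion
reports its SD as undefined (`None`); correlations are undefined below three
pairs or under zero variance in either variable. The analysis unit is the
lesion, not the patient; no clustering correction is attempted.

## Exact test for sparse tables

`fh_exact_test` enumerates every nonnegative integer table with the observed
margins (recursive row-by-row generation with margin-feasibility pruning)
and sums the multivariate hypergeometric probabilities of those no more
probable than the observed table. Numerical choices:

- probabilities are computed in log-space from a precomputed log-factorial
  table up to the grand total, so no big-integer arithmetic is needed;
- "no more probable" uses a relative tie tolerance of 1e-12, because exact
  equality of floating-point log-probabilities is unreliable;
- enumeration is capped (default 5 × 10⁶ tables) and raises an explicit
  error directing to the Monte Carlo fallback, which draws tables exactly
  from the margin-conditional null by permuting column labels against fixed
  row labels and uses the add-one estimator `p̂ = (1 + hits)/(1 + B)`.

On 2×2 tables this reduces to the two-sided Fisher exact test; the suite
verifies agreement with the hypergeometric closed form exhaustively for all
tables with grand total ≤ 40.

One known discrepancy: for the hemorrhage-by-size table reconstructed from
the published percentages, full enumeration gives p = 0.0301 (confirmed
independently by R's `fisher.test` on the same counts, 0.03014915), whereas
the published table prints 0.034. No probability ordering, tie tolerance or
alternative statistic ordering we examined reproduces 0.034 by enumeration;
the printed value is consistent with a Monte Carlo exact estimate (SE ≈
0.0017 at the customary 10⁴ samples). The package reports the enumerated
value.

Pearson's r is the standard product-moment estimate with a two-sided p from
the t transform `r√((n−2)/(1−r²))` on n − 2 degrees of freedom. Spearman's ρ
is Pearson applied to mid-ranks (ties averaged); its p uses the same t
approximation at every n, matching common statistical-package behaviour —
it is approximate at small n and documented as such.

## Synthetic images

`generate_lesion_image` emulates an annotated dermoscopic photograph at the
level the measurement layer consumes: an RGB raster with a scale bar, a
lesion region and blue-gray pigment sub-regions, plus the two binary masks
and the calibration sidecar. Defaults: 1024×1024 px at 0.05 mm/px (a ~5 cm
field, typical of a 10× dermoscope frame), 30 mm² lesion (near the cohort
mean of 29.26 mm²), 25% pigment coverage, 6 pigment blobs, per-channel
Gaussian sensor noise with SD 2 intensity units.

- The lesion boundary is an ellipse (aspect drawn in [1, 1.3]) perturbed by
  radial cosine harmonics of orders 2–6 whose total amplitude is 15% of the
  radius — smooth, star-convex, guaranteed closable. The base radius is
  adjusted by fixed-point iteration (`r ← r√(target/measured)`) until the
  rasterised area is within 2% of target (hard failure beyond 5%).
- Pigment is a union of disks centred at random lesion pixels, clipped to
  the lesion. Coverage is monotone in a global radius scale, so a binary
  search lands the mask within ±0.005 of the target fraction (hard failure
  beyond ±0.02). A coverage target of 1 saturates to exactly the lesion
  mask; a target of 0 draws nothing; a positive target with zero blobs is an
  error.
- The scale bar lives in a reserved top strip the lesion may not enter, and
  its endpoint coordinates are written to the sidecar rather than detected
  from pixels: ruler detection is a separate problem, and the measurement
  layer's contract is "two annotated points plus a distance".
- Pigment is painted at RGB (100, 110, 130), inside the blue-gray band that
  colour thresholding targets; lesion and skin tones are far outside it.
- Identical parameters (including seed) give bit-identical images, masks and
  sidecars; all randomness flows through one `numpy` generator.

What the generator does *not* emulate: hair, immersion-fluid bubbles,
specular highlights, illumination gradients, multi-frame stitching, or
photorealistic lesion texture. Passing PCR-recovery tests therefore
demonstrates that calibration, masking, thresholding and the ratio are
implemented correctly — not that the pipeline is robust to real-world
dermoscopic artifacts, which the upstream manual annotation is assumed to
have handled.

## Synthetic cohorts

`generate_cohort` simulates lesion records with the published cohort's
structure as defaults: depth-layer probabilities 23/42, 12/42, 7/42;
per-layer PCR means 17.86 / 15.42 / 11.69 % with SDs 14.78 / 18.27 / 11.15;
lognormal areas with moments matched to mean 29.26 and SD 28.14 mm²
(log-mean 3.049, log-SD 0.809); site and subtype frequencies from the
published composition; and per-size-class Bernoulli feature flags at the
published prevalences.

Per-layer PCR is drawn from a scaled Beta distribution on [0, 100] whose
shape parameters are moment-matched to the layer's (mean, SD). A Beta is the
canonical law for a coverage fraction and reproduces the configured first
two moments exactly, which keeps the configured layer means recoverable
from simulated cohorts. Naive truncation of a normal cannot do this: with
SD > mean (the middle layer's published values) a normal truncated to
[0, ∞) cannot even realise the target moments, and rejection sampling
inflates the middle-layer mean from 15.42 to ≈ 21.8, destroying the
configured decreasing depth trend. Feasibility requires
SD² < mean × (100 − mean), validated at construction; SD = 0 degenerates to
the exact mean. Depth within a layer is uniform over the layer's one-decimal
cm values ({0.1, 0.2}, {0.3, 0.4}, {0.5, 0.6}).

Feature flags are independent Bernoulli draws given the size class. The
real joint distribution of dermoscopic features is unknown (only marginals
per size group are published), so simulated cohorts match marginal
prevalences but make no claim about feature co-occurrence.

## Printed-percentage inversion

Published tables print per-group percentages to two decimals under
half-away-from-zero rounding. For a group of size n ≤ 1000 the map
`count → round(100·count/n, 2)` is injective, so a printed percentage pins
down the count exactly — provided the group size is known. Group sizes are
recovered by exhaustive search over all compositions of the total into
positive parts, keeping those under which *every* printed percentage in
*every* row is realisable; the search demands a unique solution and raises
a dedicated error (listing candidates) on ambiguity or inconsistency.
Percentage matching is done in decimal arithmetic, never floating point.
For the published 14-row size table the composition (24, 13, 5) of 42 is
unique, and the pooled reconstructed counts independently reproduce all 14
printed overall prevalences.

## Problem sizes used in the test suite

Synthetic-image tests use 256×256 px images at 0.1 mm/px (PCR-recovery
checks use the full 1024×1024 default); the exhaustive 2×2 Fisher agreement
sweep covers all tables with total ≤ 40; Monte Carlo agreement uses 20
random 3×3 tables at 20 000 samples each; cohort moment recovery uses one
10 000-lesion cohort; depth-trend sign recovery uses 200 cohorts of 200
lesions. These sizes keep the full suite under a minute of compute while
leaving every statistical bound at ≥ 3 standard errors.

## Known limitations

- No automatic lesion segmentation, ruler detection, illumination
  correction or colour constancy: boundaries, pigment annotations and scale
  points are inputs.
- The Spearman p-value is a t approximation, not an exact permutation null.
- Within-layer depth–PCR correlations pair a variable with 1–2 distinct
  depth values per layer; the estimand is fragile at small n and reported
  with undefined-markers where it degenerates.
- Multiple-testing correction is intentionally absent (one exact p per
  feature table, as in the clinical reporting style this mirrors).
- The cohort simulator treats lesions as independent, ignoring that two
  lesions may share a patient.
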