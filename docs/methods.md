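# Methods

`octcornea` reimplements, end to end, an analysis that screens for
sub-clinical keratoconus (KC) from ultra-high-resolution OCT (UHR-OCT)
vertical B-scans of the cornea: layer segmentation, refraction
correction, reconstruction of entire vertical thickness profiles of the
epithelium, Bowman's layer and stroma, twelve diagnostic thickness
indices, and the discriminant/ROC statistics that evaluate them.  No
patient data are available, so a synthetic-cornea generator provides the
study conditions; this note records the model, its parameters, and what
the synthetic validation does and does not demonstrate.

## Scan model and geometry

A B-scan is a lateral sequence of A-scans; the axial axis measures
optical path length in air.  The default instrument geometry is
1,365 × 2,048 pixels over 2.02 mm (depth, in air) × 8.66 mm (width),
giving a lateral pitch of 4.23 µm/A-scan and an axial pitch of
1.48 µm (air).  A single group refractive index of 1.389 converts
optical to geometric depth inside the cornea; all layers share it and
refraction is applied at the anterior surface only.  An analysis window
is 1,000 A-scans (4.23-mm chord) split into 10 zones of 100 A-scans
(0.42 mm); these constants anchor all downstream arithmetic (`geometry`).

## Synthetic corneas (`synthetic`)

The generator emulates the three study groups — normal, sub-clinical KC
(the asymptomatic fellow eye of unilateral KC, the screening target) and
manifest KC:

* **Anterior surface**: a circular arc (radius 7.8 / 7.6 / 7.0 mm for
  normal / sub-clinical / KC).  Aspheric terms are out of scope.
* **Layer thickness**, perpendicular to the surface, is a monotone-cubic
  interpolant through 26 per-bin baseline means on the registered
  vertical axis (13 bins of 0.423 mm per side of the apex), derived from
  the published group-wise regional means (superior / central / inferior
  windows) by a quadratic through the three regional centres.
* **Subject variation**: one additive offset per layer (SD = the
  regional SD with the per-zone jitter subtracted in quadrature) plus
  independent per-bin jitter of fixed small SD (1.0 / 0.8 / 5.0 µm for
  epithelium / Bowman's / stroma).  Attributing the full regional SD to
  per-zone noise would make adjacent 0.42-mm zones swing by tens of µm —
  non-physiological, and steeper than a bounded-step boundary search can
  follow.  Draws are truncated at ±3 SD so thin layers stay positive.
* **Cone**: a Gaussian-in-chord thinning per layer,
  `t(x) −= depth · exp(−(x−c)²/2σ²)`, σ = 0.9 mm, centre drawn uniformly
  in [−2.5, 0] mm (central-to-inferior, matching where the thinnest
  zones are reported).  Default depths: 0 (normal), 5 / 1.5 / 15 µm
  (sub-clinical) and 12 / 3 / 40 µm (KC) for epithelium / Bowman's /
  stroma.  Bowman depths are small because the group baselines already
  carry most of the Bowman thinning.
* **Extent**: Bowman's layer terminates at ±13 bins (≈ ±5.50 mm, an
  11-mm edge-to-edge vertical meridian); epithelium and stroma continue
  0.5 mm further toward the limbus, so the Bowman edge is a contrast
  feature rather than a tissue cliff.

**Rendering.**  Each region (central / superior / inferior) is rendered
with the eye rotated about the centre of curvature so the region's
1,000-A-scan window sits at the scan pole — ≈ ±29° for the peripheral
regions, mirroring the protocol's 30° fixation targets.  Every A-scan is
traced through the refracting surface (vector Snell, Newton solve for
the interface intersections), and each echo is placed at its cumulative
*optical* depth, so the raw images carry exactly the distortion the
correction stage must undo.  Tissue classes get fixed 8-bit intensities
(background 20, epithelium 150, Bowman's 60, stroma 105 — chosen so each
interface has a distinct strongest gradient polarity in its search
domain, not as a speckle model) with hard transitions at the rounded
boundary rows, plus additive Gaussian noise (default SD 12) mixed
equally from a spatially correlated field (correlation 2 px axial ×
40 px lateral, speckle-like) and white noise.

## Segmentation (`segmentation`)

Boundary extraction is gradient cost + exact shortest path:

* cost = `max(g) − g + 1e−6`, where `g` is the signed backward
  difference along rows (+ for dark→bright, − for bright→dark).  The
  backward difference attributes a transition to the first row of the
  new medium, so the cost minimum sits on the interface row itself.
* The minimal-cost left-to-right path with |Δrow| ≤ `max_step`
  (default 2 px) between neighbouring columns is found by column-wise
  dynamic programming — exact for this graph class, linear time.  Ties
  prefer the smaller row change, then the upper row (deterministic).
* Search domains: the anterior surface is unconstrained (strongest
  dark→bright); the epithelium–Bowman interface is searched in a band
  25–95 µm (geometric) below the surface; Bowman–stroma within ±10 px of
  a cubic spline through operator seed points when given, else 6–40 µm
  below the epithelium–Bowman trace; the posterior surface 280–800 µm
  below Bowman–stroma (the wide upper bound absorbs the ~1/cos growth of
  the vertical gap near the steeply tilted Bowman edge).  The posterior
  search is this package's own choice; the source protocol never
  describes it.
* Sub-pixel refinement: parabolic fit of the cost across the 3 rows
  around the path, clamped to ±0.5 px.
* Validity: a column is valid where the vertical gradient at the trace
  (on a vertically-smoothed image — lateral smoothing would dilute
  tilted edges) exceeds 15 intensity units — above the column-wise
  *maximum* noise gradient (the path row is an extreme value, ~10 at the
  default noise), below the weakest true edge response (~30).  The Bowman–stroma trace
  uses a band-contrast criterion instead: the mean intensity between the
  two Bowman traces must be at least 15 units darker than the stroma
  just below.  Point gradients are fragile against spatially correlated
  noise, which can suppress them over tens of consecutive columns;
  band means average it out, and beyond the Bowman edge (where the two
  interfaces merge) the contrast vanishes, so the same criterion
  delimits where Bowman's layer exists.  Manual corrections
  `(interface, column range, row offset)` are applied afterwards; the
  ordering invariant (air–epi ≤ epi–Bowman ≤ Bowman–stroma ≤ posterior)
  is then enforced by clipping, with clipped columns flagged.

On noise-free renders all four interfaces are recovered to ≈ 0.3 px RMS
(the quantization floor of hard-edged 8-bit rendering); the acceptance
bound is 1 px RMS.

## Refraction correction and thickness (`optics`)

For each A-scan the local surface tangent (smoothed over ±25 A-scans)
gives the incidence angle; Snell's law (n₁ = 1, n₂ = 1.389) the
transmitted direction; the optical path below the surface is divided by
the index and laid along the refracted ray.  Setting the index to 1
makes the correction the identity.  Layer thickness is measured from the
layer's upper interface along the local anterior normal to the
(interpolated) lower interface, in µm.  On noise-free central windows
reconstructed thickness matches the generator to ≈ 0.3 µm RMS.

## Profiles and registration (`profiles`)

The central window is centred on the apex (the A-scan of maximal
corrected anterior elevation); peripheral windows run 1,000 A-scans from
the Bowman edge toward the centre.  The edge is the outermost validity
transition of the Bowman traces after bridging gaps ≤ 5 columns and
discarding merged runs shorter than 50 columns (noise islands are not
tissue); a transition within 10 columns of the image border is
field-of-view truncation, not an edge.  Zones with < 60% valid
A-scans are flagged partial and excluded.  The three regions are merged
onto a common apex-anchored axis of 0.423-mm bins — peripheral windows
anchored at their Bowman edge (semichord from configuration, default
5.50 mm), central at the apex — averaging overlapping bins with equal
region weights; ~26 bins (≈ 11 mm) result.

This edge-anchored tiling is the protocol's own approximation: zones are
blocks of A-scans in each (rotated) acquisition frame, and their true
chord span is compressed by the cosine of the regional rotation, so
peripheral and overlap bins are laterally misplaced by up to ~0.5 mm.
Consequently bins covered by the central window alone reproduce
ground-truth bin means to < 1 µm, while peripheral/overlap bins carry an
error proportional to the local thickness gradient (a few µm for the
thin layers; more for the stroma, and largest where a cone's flank falls
in the overlap).  Registration of regions *sampled* on the common axis
is lossless to < 0.5 µm — the residual is the acquisition-frame
distortion, not the merge.  Both a signed apex-anchored bin axis and
distance-from-apex labels are exposed; which of the two conventions the
original software used internally is not stated in the source and is
not guessed.

## Diagnostic indices (`indices`)

With halves taken on the entire registered profile, split at the apex
bin (excluded):

| index | definition | units |
|---|---|---|
| EI (EEI/BEI/SEI) | 100 · min(inferior half) / mean(superior half) | % |
| EI-MAX | 100 · min(inferior half) / max(superior half) | % |
| PV (EPV/BPV/SPV) | RMS of zonal thicknesses about the profile mean | µm |
| PSD (EPSD/BPSD/SPSD) | RMS about a normal-cohort pattern average | µm |

The pattern average is the per-bin mean over a reference cohort (normal
group I); PSD uses only bins present in both profile and pattern.
EI-MAX ≤ EI always; indices are computed in full precision and reported
to two decimals.

## Statistics (`stats`)

One-way fixed-effects ANOVA per index with Dunnett-style many-to-one
contrasts against normal (scipy); no multiple-testing correction by
default (none is applied in the source analysis; a Bonferroni option
exists).  Stepwise LDA is forward-only: at each step the candidate
minimising Wilks' λ = det(W)/det(T) of the selected set enters if its
partial F-to-enter `(N−g−p)/(g−1)·(λ_p/λ_{p+1}−1)` exceeds 3.84; ties
break lexicographically; no removal step.  The discriminant function
(Fisher's direction for two groups, leading canonical variate for
three) is scaled to unit pooled within-group variance and oriented so
diseased eyes score higher.  ROC curves are empirical over all
thresholds; AUC is trapezoidal (equal to the tie-corrected
concordance probability); the reported cutoff maximises Youden's J with
ties broken toward higher sensitivity — the cutoff criterion is this
package's choice, as the source reports single cutoffs without naming
one.

## What the synthetic validation shows — and does not

Passing tests demonstrate that the *machinery* is correct: exact path
optimality against enumeration, closed-form refraction, index
arithmetic against brute-force oracles, parameter recovery on noise-free
renders, and the qualitative diagnostic structure (epithelial indices
outrank stromal ones for sub-clinical detection; discriminant scores
order normal < sub-clinical < KC).  They do not certify clinical
performance: synthetic hard-edged interfaces are far cleaner than real
UHR-OCT tissue (repeated-render repeatability is ~0.1–0.3 µm, an order
better than the ~1.2–1.7 µm human-grader repeatability the clinical
protocol reports — the generator does not model grader interaction,
motion, or realistic speckle), group separations are sharper than
clinical ones because cones are layered on top of group-mean baselines,
and absolute AUCs from cohorts of tens of eyes carry wide sampling
error.  The stroma profile additionally depends on a posterior
segmentation the source never specified.

## Problem sizes

Default problem sizes are chosen so the whole validation runs on a
laptop-class single core: 15 rendered noise-free eyes for parameter
recovery, 20 eyes/group (ideal sampling) for the ranking statistics, and
12 eyes/arm rendered cohorts for the analysis drivers and the
reproduction script.
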