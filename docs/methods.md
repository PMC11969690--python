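# Methods

This note documents the measurement model, the synthetic-data generators,
the statistical conventions, and the numerical choices behind `retmorph`,
including the places where the design was genuinely open and a choice had
to be made.

## Measurement frame

All quantities are measured in a polar frame anchored at the optic disc
(center and diameter `dd_px` supplied as input; the package does not detect
the disc). Three annuli are defined by radial distance r from the disc
*center* in units of dd: zone A (0.5, 1.0], zone B (1.0, 1.5], zone C
(1.5, 2.5]; intervals are closed on the outer edge, so a point exactly on
r = 1.0 dd belongs to zone A, and the disc interior (r ≤ 0.5 dd) is never
measured. An alternative convention measures zone C as 0.5–2.0 dd from the
disc *margin*; the two coincide here except for the outer boundary, and the
adopted reading follows the captioned widths (0.5, 0.5, 1 dd) of the
standard three-zone scheme. Zone radii can be overridden through
`PipelineConfig.zone_bounds`.

Calibers (SD, CRAE/CRVE, AVR) are measured in zone B, where the major
arcades run roughly parallel and junction density is low; densities,
branching geometry, tortuosity and fractal dimension are measured in
zone C, which carries most first- and second-order bifurcations.

## From mask to vessel graph

Each class (artery, vein) is processed independently:

1. **Skeleton** — topology-preserving medial-axis thinning
   (scikit-image). The invariants asserted in tests are what matter:
   1-px-wide, 8-connected, idempotent, same number of connected components
   as the foreground.
2. **Widths** — local vessel width at a skeleton pixel is twice the
   Euclidean distance transform of the class foreground. This is the
   standard caliber proxy for tubular structures; it is biased high inside
   junction blobs, which is why all caliber statistics exclude points
   within one local width of a junction.
3. **Graph** — nodes are skeleton pixels of degree ≠ 2 (adjacent junction
   pixels are clustered into one node at their centroid); segments are the
   ordered degree-2 chains between nodes. Terminal spurs shorter than
   max(5 px, one local width) are pruned (skeletonization artifacts of wide
   vessels), tiny self-loops below the same threshold are dropped
   (artifacts of blunt vessel ends), and degree-2 junction remnants left by
   pruning are dissolved by concatenating their two segments. The surviving
   node types are endpoint (degree 1), bifurcation (3) and crossing (≥ 4).
4. **Smoothing** — every centerline carries a Gaussian-smoothed copy
   (fixed σ = 2 samples) used for directions, arc lengths and curvature.
   The chain is padded by linear extrapolation of its end directions before
   filtering; constant padding would contract the endpoints of short
   segments by a few pixels, which measurably biased arc-length-based
   quantities before this choice was made. Digital 8-connected chains
   overestimate true arc length by up to ~8% (staircase effect); smoothing
   removes this bias, which is essential for tortuosity.

## Parameter definitions and open choices

- **Knudtson equivalents.** The six largest zone-B calibers per class
  (mean in-zone width per segment, junction-adjacent points excluded;
  ties broken by in-zone length, then segment id) are combined pairwise —
  largest with smallest — as W = k·√(w₁² + w₂²), k = 0.88 (arterioles) /
  0.95 (venules); an odd set carries its median unpaired to the next
  round. With fewer than six candidates the set is flagged and the formula
  runs on what exists. Ranking by *mean* width rather than maximum width is
  a robustness choice against junction blobs.
- **Bifurcation measurement.** At a degree-3 node, each incident segment
  gets a measurement window starting one local width past the junction and
  extending 2·d0 of arc; the trunk is the widest segment over its window,
  d0/d1/d2 are window-mean widths and θ1/θ2 are angles between each
  daughter's least-squares direction and the trunk direction continued
  through the junction. Junctions whose windows touch the image border
  (margin 3 px) are skipped: a vessel clipped by the field of view carries
  corrupted widths and directions, and no real measurement protocol would
  score it. The window length is a tolerance-tested choice: long enough to
  average pixel-level direction noise, short enough not to bleed into the
  next junction.
- **JED.** The junctional exponent x solves d0ˣ = d1ˣ + d2ˣ, by bisection
  on x ∈ [0.2, 10] to |f| < 1e-10 (f is monotone in x after normalising by
  d0). The exponent is undefined when d0 ≤ max(d1, d2) and out-of-bracket
  for near-degenerate junctions (equal daughters barely thinner than the
  trunk); both yield a missing value for that junction. JED = x − 3 is the
  signed convention (negative below Murray's optimum); `PipelineConfig`
  can flip the sign for comparison with tools using 3 − x.
- **NFB.** A first-order vessel is a segment crossing the zone-B/zone-C
  boundary; it counts once if a bifurcation is reachable on its outer side
  without re-entering zone B. A vessel branching twice in zone C therefore
  counts once; a vessel that already branched in zone B contributes one
  countable entry per daughter that crosses into zone C — the definition
  counts *entering vessels*, not arcades.
- **Tortuosity.** ST = arc/chord of the zone-restricted smoothed
  centerline; CT = L·∫κ² ds with curvature from finite differences, which
  is dimensionless, zero for straight vessels, and equals π² on a
  semicircle. CT conventions differ across tools by normalisation, so
  absolute CT values are comparable only within a convention; eye-level
  STa/STv/CTa/CTv are length-weighted means over zone-C segment runs of
  ≥ 5 points (mean vs median aggregation is configurable, length-weighted
  mean is the default).
- **FrD.** Box counting on the pooled two-class skeleton clipped to
  zone C: dyadic box sizes 2, 4, 8, … ≤ min(H, W)/4 anchored at the image
  origin, FrD = −slope of log N(s) vs log s, requiring ≥ 3 sizes.
  Grid-offset averaging is deliberately off: it changes FrD by less than
  the seed-to-seed spread of the synthetic eyes and complicates
  reproducibility.
- **Densities.** VAD and VLD pool both classes over the zone-C annulus
  clipped to the image; skeleton length counts orthogonal steps as 1 and
  diagonal steps as √2, skipping diagonals that shortcut an orthogonal
  path.

Eye-level aggregation of per-bifurcation parameters (BA/AA/BC/AR/OD/JED)
is the arithmetic mean over zone-C bifurcations (median behind the config
switch). Calibers are reported in px, or µm when `scale_um_per_px` is
given; ratios and densities are scale-free.

## Synthetic eyes

`TreeSpec`/`generate_eye` grow binary trees from the disc margin: daughter
calibers obey d1ˣ + d2ˣ = d0ˣ with the configured exponent (Murray's
x = 3 by default, making OD = JED = 0 true by construction), the asymmetry
ratio AR = (d2/d1)² and both branching angles are drawn uniformly from
configurable ranges, the larger daughter takes the smaller deflection, and
segment length is a fixed multiple of local caliber. Centerlines are
straight paths plus a sinusoidal normal displacement under a sin² envelope
that pins endpoint position *and* tangent, so junction geometry is exact
and the chord direction defines the ground-truth angle. Branches thinner
than 1.5 px truncate. Rendering stamps disks of radius r − ½ px at dense
centerline samples (pixel-center geometry: the rendered tube then measures
2r wide under the distance transform), veins first so artery overwrites
vein at any residual overlap, and clears the disc interior.

Default conditions (one 512×512 eye, dd = 120 px): six arcades per class,
interleaved azimuthally so the classes never cross; arterial roots
12 px / length factor 12, venular roots 15 px / factor 10 — chosen so every
first bifurcation falls inside zone C and inside the measurable field of
view; angle range 20–45°, AR range 0.5–0.9, tortuosity amplitude 2 px at
wavelength 70 px (ST ≈ 1.01, mild clinical-range tortuosity); depth 3;
root calibers jittered ±10% so the "six largest" ranking is non-trivial.

What the generator does *not* emulate: segmentation noise (masks are
perfect tubes), artery/vein misclassification, central light reflex and
caliber measurement artifacts, inter-class crossings (off by default; a
crossing mode exists), vessel taper within segments, and the curved
temporal arcade geometry of real eyes. Passing the full-loop tests
therefore demonstrates that the measurement layer is correct on clean
geometry at realistic scale — not that it is robust to segmentation error.

Recovery is validated two ways: 50 isolated Y-junctions with known
(d0, d1, d2, θ1, θ2) must come back with mean absolute errors ≤ 5°
(BA/AA) and ≤ 0.15 (BC/AR); and full rendered eyes must reproduce NFB
exactly, eye-level ST within 2%, and matched-junction aggregate BA/AA
within 5° and BC/AR within 0.15. Matching is by junction position
(< 8 px); junctions the pipeline correctly refuses to measure (border
clipping) are excluded from the angle comparison and covered by the NFB
check instead.

## Synthetic cohorts

`CohortSpec`/`generate_cohort` simulate a disease table and a control
table. Rank structure is imposed through a Gaussian copula: a target
Spearman ρs becomes a latent Pearson correlation 2·sin(πρs/6), the latent
normal sample is transformed to normal marginals (continuous variables,
means/SDs defaulting to the packaged group-summary table, with median/IQR
rows converted as SD ≈ IQR/1.349) or quantile-binned onto ordinal ranges
(imaging scores: ARWMC 0–30, Fazekas 0–3, EPVS 0–4, MARS 0–10, lacunes
0–5, SVDS 0–4, GCA 0–15). Missingness is Bernoulli per variable at rates
matching the packaged cohort. Everything is deterministic given the seed.

The default correlation targets are the fifteen reported
vascular-clinical rank correlations. These alone are not jointly
realisable — one asymmetry parameter carries five strong imaging-score
correlations whose squared sum exceeds 1 — so any consistent latent model
*requires* the clinical scores to be mutually correlated. The defaults
therefore add structural entries (imaging scores mutually 0.65,
biomarker-linked vascular parameters mutually 0.5, and cross-links whose
signs follow from the reported pairs), verified once to give a positive
definite latent matrix (smallest eigenvalue ≈ 0.13). A user-supplied
target set that is not positive semi-definite raises an error naming the
most offending pairs (largest contributions to the negative eigenvector).
Quantile binning ties attenuate recovered correlations slightly; at the
default ranges the attenuation is well inside the ±0.07 recovery tolerance
at n = 500.

## Statistics

The statistical layer reproduces a conventional SPSS-style workflow:
Shapiro–Wilk at α = 0.05 gates each two-group comparison between unpaired
Student's t (equal-variance, mean ± SD summaries) and two-sided
Mann–Whitney U (median with 25th/75th percentile summaries); degenerate
inputs (n < 3 or constant) force the nonparametric path and are flagged.
The U test is exact for min(n) ≤ 8 without ties, otherwise the
tie-corrected normal approximation with continuity correction. Percentiles
use the weighted-average-at-(n+1)p definition, which reproduces the
packaged cohort's printed quartiles exactly; nearest-rank is available per
call. Categorical rates use Pearson chi-square without continuity
correction. Correlations are pairwise-complete Spearman with t-approximate
two-sided p values and *no* multiplicity adjustment (a Benjamini–Hochberg
step would be easy to add but is off to match the conventional reporting
style this layer mirrors). ROC analysis is the empirical curve with
trapezoidal AUC, a 2000-replicate stratified bootstrap percentile CI, and
the Youden-J operating point; disease severity is dichotomised at
MSSI = 20 when driven through the pipeline. The packaged 27-patient table
is validated on load (labels, ordinal ranges, 19 M / 8 F) and analysed
with pairwise deletion throughout, one row per patient (right-eye-only is
an upstream data rule).

Null calibration of the gated comparison was measured at 20 000 replicates
(n = 27 per group, normal data): rejection rate 4.8%, i.e. the
Shapiro-gate does not distort the level materially.

## Problem sizes and determinism

The test suite and the acceptance script run on: 512×512 eyes (three
seeds for full-loop checks), 50 single-junction renders, 1000 null
replicates for the type-I rate, n = 500 for copula recovery, n = 1000 for
the null AUC, and 100–200 replicates at n = 100 for copula calibration —
sizes at which every tolerance above is comfortably resolved while the
whole suite completes in well under a minute. All stochastic steps take
explicit seeds; `scripts/acceptance.py` derives every sub-seed from its
`--seed` argument, and identical inputs, configuration and seed produce
byte-identical outputs (CSV outputs carry a version/config-hash/seed
header).

## Known limitations

- Calibers are in pixels unless a µm/px scale is supplied; absolute
  caliber and CT values are not comparable across instruments or tools
  with different conventions.
- Crossings (degree-4 nodes) are detected but not measured; artery-over-
  vein occlusion in real masks fragments the occluded vein, which the
  default generator does not emulate.
- The junction measurement declines bifurcations within ~3 px of the
  image border and daughters shorter than one measurement window; heavily
  cropped fields of view will under-sample junctions (visible in the
  per-eye log counts).
- The box-counting dimension is grid-anchored; values are reproducible but
  differ slightly from offset-averaged implementations.
- The cohort simulator's ordinal marginals are quantile-uniform over their
  ranges, which is adequate for rank-based statistics but flatter than
  real imaging-score distributions.
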