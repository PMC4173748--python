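# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `cdlskit`, and what the tests do and do not establish
about behaviour on real patient data.

## Cohort model and reporting conventions

A patient record carries growth z-scores (birth weight, weight, height and
head circumference in SD units against an age/sex growth reference), a
composite clinical severity score, a genotype group, a mosaicism flag and up
to three per-rater gestalt scores. z-scores are consumed as given —
converting raw measurements against a growth standard is out of scope — and
missing values are represented explicitly and never imputed; each downstream
stage declares its own handling.

Severity categories use the published boundaries: scores below 15 are mild,
15–22 inclusive moderate, above 22 severe. Both boundary values are
moderate.

All cohort-level percentages are **truncated toward zero**, not rounded,
computed in exact rational arithmetic (`floor(100·num·10^d / den) / 10^d`).
This is the only convention consistent with the reported values this package
reproduces (44/56 → 78%, 32/34 → 94%, 19/103 → 18%, 31/206 → 15%,
6/163 → 3.6%). One reported value (5/163 printed as 3.1%) is inconsistent
with it — truncation gives 3.0% — and the package keeps the consistent
convention rather than special-casing that entry.

## Gestalt scores

Facial typicality is scored 1 (highly atypical) to 10 (highly typical) by
several raters blinded to genotype. The per-patient mean over available
raters is the working score. Its use is gated on inter-rater concordance:
every pairwise Pearson correlation (pairwise-complete observations, ≥ 3
shared patients per pair) must reach 0.60. The correlation p-value is
reported but does not enter the gate, because p depends on the number of
jointly rated patients, which varies across synthetic runs; r does not. A
rater with constant scores has an undefined correlation, which is reported
as such and fails the gate.

## Classification trees and the NIPBL-like filter

Tree induction is deliberately minimal CART: greedy binary splits maximising
Gini impurity decrease, candidate thresholds at midpoints between
consecutive distinct observed values of each feature, a node split only
while it holds at least `min_split` observations (default 3) and sits above
the depth cap (default 3 edges from the root, at most 8 leaves). No pruning,
no cost-complexity parameter, no surrogate splits: the published analysis
reports a single shallow tree, and surrogate behaviour is unspecified, so
records missing the split feature are excluded from the subtree by default
(majority-branch routing is available as a config option). Determinism is
pinned: equal-gain ties resolve to the lowest feature index, then the
smallest threshold; a value equal to a threshold routes to the "≥" (right)
branch, matching the "birth weight ≥ −4.4 SD" phrasing of the published
rule. When a feature has missing values, its split gain is computed over the
rows where it is observed and down-weighted by the observed fraction, so
sparsely observed features are not favoured.

The exact published tree cannot be re-fitted without patient-level data, so
fitting is validated two ways: depth-1 fits are compared against an
exhaustive search over every (feature, midpoint) split on random small
datasets, and a planted two-feature AND structure at the published
thresholds (−2.4 / −4.4 SD, 0.5 SD empty margins, 60 cases per arm) must be
recovered with both split features and thresholds inside the planted
margins. The published rule itself — flag a mutation-negative case iff
weight < −2.4 SD (strict) and birth weight ≥ −4.4 SD (inclusive) — is
hard-coded as the `NipblLikeFilter` defaults; records missing either feature
are never flagged but stay in the denominator.

## Average faces

Each face is an anteroposterior photograph annotated with an ordered
36-point landmark constellation. The published annotation scheme is not
available, so this package fixes its own documented template (13 jaw/outline
points, 3 per brow, 4 per eye, 4 nose, 5 mouth/philtrum); it is an explicit
stand-in, not a reconstruction.

Registration is full Procrustes — translation, isotropic scale and proper
rotation, reflections never selected (a mirrored face is not a valid
superimposition) — solved in closed form by SVD with a determinant
correction. Generalized Procrustes analysis initialises the mean as the
first constellation (centred, unit centroid size), alternates aligning all
constellations to the mean and recomputing the normalised mean, and stops
when the mean moves < 1e-7 RMS or after 100 iterations (cap → warning, best
iterate returned; in practice convergence takes ~3 iterations).

A Procrustes mean is defined only up to rotation, and the reference frame
must not inherit the inputs' arbitrary orientation, so the converged mean is
rotated to a canonical orientation: principal axis to +y, the 180° ambiguity
resolved by the sign of the third moment of y (then x). This makes the whole
pipeline invariant to one global similarity transform applied to every
input. The canonical mean is placed on the output raster by a fixed
similarity fitting its bounding box into a central 80% box.

The reference mesh is the Delaunay triangulation of the placed mean
constellation (this package takes "reference mesh" to be the mean
constellation itself). Warping is piecewise affine: for each output pixel
centre inside the mesh hull, the containing triangle's affine map — its
barycentric coordinates applied to the corresponding source landmarks —
gives a source location, sampled bilinearly with out-of-bounds samples
taking the nearest edge value. Bilinear sampling is convex, so warped
intensities never leave the input range. Pixels outside the landmark hull
(hair, background) have no landmark correspondence and are excluded from
averaging; the per-pixel coverage count is part of the output. Colour images
get identical geometric treatment per channel.

Tolerances: identity warps are exact to ~1e-15 and tested at 1e-6; the
global-similarity invariance of the averaged appearance is tested at 0.1
max-abs / 0.03 RMS on [0, 1] intensities — the residual is bilinear
resampling error of the sharpest rendered features plus occasional Delaunay
diagonal flips between floating-point-perturbed meshes, not a geometric
error.

## Mosaic quantification

VAF is alt/total with a Wilson score 95% interval (chosen over Wald for
small-count stability; the interval method is a single swappable function).
Pyrosequencing-style instrument percentages enter as count-equivalents at a
stated n. The mosaic call formalises the reasoning "15% of reads in a male
autosomal site ⇒ mosaic": a quantification is consistent-with-mosaic if its
interval lies entirely below 0.5 − margin, consistent-with-heterozygous if
the interval covers the whole band [0.5 − margin, 0.5 + margin], else
indeterminate; margin defaults to 0.05. Empirical coverage of the Wilson
interval is verified by simulation (10,000 binomial replicates at true
fractions 0.05/0.15/0.5, depths 50 and 200; coverage within [0.93, 0.97]).
Fold changes between samples are ratios of point estimates with a CI-overlap
flag; no model of clonal selection over time is attempted.

## Synthetic data: what it emulates, what it does not

The cohort generator draws group-specific Gaussians for growth z-scores,
severity and a latent gestalt typicality, adds independent Gaussian rater
noise (clipped to [1, 10]) and applies independent per-field missingness.
Defaults are study-scale: 163 referrals with 46/5/5/6/1 gene-positive cases
and 100 mutation-negative; the NIPBL group is simulated with progressive
growth failure (birth weight −2.3 ± 0.9 SD, weight −3.5 ± 1.0 SD), the
highest severity (21 ± 5) and gestalt typicality (8 ± 1), HDAC8 less severe
growth than NIPBL, negatives mildest; rater noise SD 1.0 and missingness
0.1 throughout. These produce inter-rater correlations near 0.8 and a
clinically plausible mild/moderate/severe split; they are point choices, not
fits to data.

The face generator renders schematic faces as sums of anisotropic Gaussian
shaded regions (head, brows, eyes, nose ridge, nostrils, philtrum, mouth)
whose positions, orientations and widths are functions of the landmark
constellation alone. This makes rendering exactly covariant with similarity
transforms — the property the averaging tests exploit — at the cost of
realism: no hair, ears, lighting direction, perspective, occlusion, or
annotation error on real photographs. Per-individual variation is landmark
noise (default SD 2 px), per-feature amplitude jitter (5%) and global
illumination jitter (5%); a random similarity transform (±8°, scale
0.9–1.1, ±8 px) is applied consistently to landmarks and rendering.
Passing tests therefore establish the geometry and averaging machinery, not
performance on photographs; with real images the landmark annotation itself
is the dominant error source and is out of scope.

## Pipeline and problem sizes

The orchestrated pipeline expands one global seed into fixed per-stage
substreams, so toggling a stage never perturbs another stage's randomness,
and two runs under one config are byte-identical (timestamps only in the
log). The demo configuration runs the face stage at 128×128 with 4 faces
per group and the analysis scripts default to 256×256 with 10 per group;
averaging is linear in faces × pixels, and the default sizes keep a full
demo run in seconds while leaving the geometry checks at full 256×256
resolution in the test suite.

## Known limitations

- The 36-point template and the rendered appearance model are stand-ins;
  none of the shape offsets between synthetic groups are calibrated to real
  CdLS facial morphology.
- The tree module accepts any label encoding but was exercised mainly on
  NIPBL vs non-NIPBL vs negative collapses; with many classes the
  lowest-index tie rule can matter.
- The severity score itself (a published composite) is consumed as an input
  field; its formula is not implemented.
- Percent-vs-control normalisation of pyrosequencing peak heights is not
  modelled; instrument output enters as a bare percentage with an assumed
  n-equivalent.
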