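# Methods

## Volumetric mass properties

Each body segment is a closed, consistently oriented triangle mesh with a
homogeneous density (default 1.0; heterogeneous sets such as lungs or air
sacs are supplied via the sidecar configuration).  Volume and first moment
come from signed-tetrahedron summation over faces (divergence theorem):
face (p0, p1, p2) contributes det(p0, p1, p2)/6 with centroid
(p0 + p1 + p2)/4.  The result is origin-independent for closed surfaces.
Closedness and orientation are verified by directed-edge counting: every
undirected edge must be traversed exactly once in each direction.  If the
net signed volume is negative the whole mesh is treated as inward-wound and
flipped once; *mixed* winding inside one mesh is an error, never silently
repaired, because it usually indicates a broken segmentation export.
Degenerate meshes (net volume below 1e-12 times the cubed coordinate
scale) are rejected.

Relative CoM is defined as the ratio of two projections onto a stored
anteroposterior unit axis — displacement of the mass-weighted CoM from the
acetabulum over the glenoacetabular distance.  Projection (not 3D
landmark distance) is used because the reference pose aligns the axial
skeleton anteroposteriorly and the quantity of interest is fore–aft mass
distribution; dorsoventral landmark offsets therefore cancel exactly.
Values outside [0, 1] are legitimate (extremely front- or rear-heavy
bodies) and are flagged downstream rather than clamped.

## Indices

The four stylopodial indices are plain humeral/femoral ratios and are
dimensionless and scale-invariant.  Mass-relative dimensions divide each
linear measurement by body_mass^(1/3); limb-intrinsic robusticity divides
each shaft dimension by its own bone's length.  Missing measurements
propagate as missing outputs — no imputation, so each regression subset
simply drops incomplete taxa for its particular index.  Measurement units
are taken as given (only ratios and, for mass-relative dimensions, a
consistent length/mass pairing matter); the table loader validates
positivity, the closed clade vocabulary and taxon uniqueness, and reports
all row/column problems in one pass.

## Phylogenetics

Trees are rooted Newick with branch lengths required on every non-root
edge.  The Brownian variance–covariance matrix holds shared root-to-MRCA
path lengths, computed in one postorder sweep (each internal node at depth
d contributes d to every tip pair split between its child subtrees).

Ancestral states under Brownian motion are maximum-likelihood estimates
computed by the two-pass weighted-mean algorithm: a pruning downpass gives
each node the inverse-branch-length-weighted estimate from its subtree; an
uppass propagates the complementary estimate from the rest of the tree, so
each internal node's state equals the GLS root estimate of the tree
re-rooted at that node — the dense-matrix GLS construction is kept as an
independent oracle in the test suite.  The rate σ² is estimated by ML
(contrast sum of squares divided by n, not n−1), consistent with the
joint-ML state estimates.  Polytomies are handled by sequential pairwise
combination; zero-length *internal* branches are collapsed with a warning,
while zero-length terminal pairs with conflicting tip values are rejected
as singular.

Pruning a tree to a taxon subset preserves root-to-tip depths by
accumulating the branches below the subset's MRCA into a root edge.  The
pruned tree's covariance is therefore exactly the corresponding submatrix
of the full tree's covariance, which keeps PGLS on a subset consistent
with the full-tree model.

## Allometric fits

Both OLS and PGLS fit log10–log10 simple regressions; inputs must be
strictly positive before transformation.  PGLS profiles the Brownian rate
out by ML: β = (X'C⁻¹X)⁻¹X'C⁻¹y via Cholesky whitening, σ²_ML = r'C⁻¹r/n.
Two deliberate conventions:

* **Slope inference** uses the n−2 denominator for the residual variance,
  so PGLS t-tests and confidence intervals reduce exactly to the OLS ones
  on a star tree.
* **Log-likelihoods** (hence AICc) use the ML variance in both methods, so
  AICc differences between an OLS fit and its PGLS counterpart are
  meaningful.  k = 3 (slope, intercept, variance/rate) in both.  AICc is
  reported as NaN for n ≤ 4, where the small-sample correction is
  undefined.

The mean absolute prediction error of a fit is computed on the
back-transformed relative-CoM scale (mean |10^ŷ − 10^y|), the scale on
which predictions are used.

### Outlier protocol

Residual boxplot fences (1.5 × IQR) are computed under two quartile
conventions: inclusive-median (Tukey hinges — with n odd the median joins
both halves) and exclusive-median (the median joins neither).  A taxon is
excluded only if outside the fences under **both**.  A consequence worth
recording: excluding the median pushes both hinges outward, so the
exclusive fences always contain the inclusive ones and the both-convention
rule resolves to the exclusive-convention flag set; the conservative
intersection is still computed explicitly so either convention can be
swapped out.  With n < 5 the screen is skipped with a warning.  Outliers
are detected in the log10 residual space the regression is fitted in.

`fit_suite` runs one primary fit per (subset × predictor × method),
automatically refits with flagged outliers removed, and adds
ratite-excluded variants wherever a subset contains ratite-flagged taxa
(large flightless birds with small forelimbs inflate bird-index variance).
Subsets below n = 3 are skipped with a warning.

## Prediction

Predictive equations are (slope, intercept, mean_error) triples, either
exported from significant OLS fits (slope p < 0.05, the export rule) or
the built-in published set of seven extant equations.  Predictions are
10^(slope·log10(index) + intercept); uncertainty bands are the symmetric
additive ±mean_error on the relative-CoM scale, a descriptive device with
no distributional claim.  Concordance with reference (volumetric)
estimates is summarized per clade as the mean absolute difference and per
equation as Spearman's rho over taxa holding both values (average ranks
for ties; constant inputs make rho undefined and are reported as omitted).

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
log10(index) evolves by Brownian motion (rate 0.02 per unit depth, giving
realistic ~0.15 log10-unit spreads) on ultrametric pure-birth trees;
log10(relative CoM) follows the clade's log-linear relation plus either
i.i.d. Gaussian residuals (the OLS regime) or Brownian residuals (the
PGLS regime).  Default clade parameters are the published extant
equations — slopes 0.866 / 1.375 / 0.652 and intercepts −0.294 / −0.374 /
−0.245 for the mammal-W1, non-avian-sauropsid-C and bird-C relations —
with residual SDs 0.02 / 0.06 / 0.075 in log10 space, matching the
equations' reported mean prediction errors in order of magnitude, and
sample sizes 10 / 16 / 31 (the study-design clade sizes; 4 of the birds
are ratite analogues, chosen as the lowest-index tips).  These are
illustrative calibrations, not re-derivations.

Raw measurement rows are expanded from simulated indices by fixing
clade-typical femoral dimensions (times a lognormal body-size factor) and
multiplying by the index for the humeral counterpart, so the designated
ratio round-trips exactly; the remaining indices track the designated one
with 3% lognormal jitter, making them correlated proxies as in real limb
data.  Fossil tables use the same law with the non-avian-sauropsid C
equation as generator and reference values equal to the noiseless truth,
giving known answers (zero error, rho = 1) for round-trip checks.

Toy body models are boxes, cylinders, spheres and ellipsoids from trimesh
primitives with analytic mass/CoM attached (cylinders use the exact volume
of the meshed polygonal prism; sphere-family centroids are exact by
symmetry).  One seed drives everything through spawned `SeedSequence`
substreams, and all file outputs are byte-identical under a repeated seed.

What passing the synthetic suite does **not** show: the generator contains
no measurement error in the linear dimensions, no missing data, no model
misspecification (the true relation really is log-linear), and toy bodies
are nothing like real anatomies; results on real tables depend on those
factors.

## Problem sizes

The test suite and the acceptance script use the study-scale sizes
(57 extant taxa, 24 fossils) for single-study checks, 500 replicates for
parameter-recovery means and CI coverage, and 1000 replicates for the
type-I-error calibration at n = 20 — sizes at which all Monte Carlo
standard errors are comfortably below the tolerances being asserted and
the whole suite runs in well under a minute.

## Known limitations

* PGLS supports only the Brownian correlation structure (no Pagel's λ or
  OU transforms), matching the analysis it implements.
* Ancestral-state output is point estimates; no variances or CIs.
* The CLI measure command handles one body per invocation.
* AICc comparisons across indices are not meaningful when their taxon
  samples differ (only OLS-vs-PGLS comparisons for the same data are).
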