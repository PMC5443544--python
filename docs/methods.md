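# Methods

This note documents the statistical models, numerical choices and design
decisions behind `morphosignal`, and what the synthetic-data tests do and
do not establish about real data.

## Superimposition

Shapes are k-landmark configurations in 2-D (k = 8 by default, matching the
anchor landmark scheme the package was built around; any k ≥ 3 works).
Generalized Procrustes Analysis proceeds by centering each configuration,
scaling it to unit centroid size (partial Procrustes — no cosine
re-scaling, so centroid size stays interpretable as a size variable),
rotating it onto the running consensus by the SVD solution of the
two-configuration problem, and re-estimating the consensus as the mean of
the rotated configurations rescaled to unit centroid size.  The consensus
is initialized from the first configuration and iteration stops when the
root-mean-square consensus change falls below `tol = 1e-10` (at most
`max_iter = 100` iterations; non-convergence raises an error carrying the
last delta).

Centroid size is the square root of the summed squared landmark distances
to the centroid.  Some verbal definitions in the morphometrics literature
omit the square root; the square-root form is the standard one (homogeneous
of degree 1: doubling the coordinates doubles CS) and is what this package
computes.

Two deliberate choices:

* **Rotations are proper (det +1) only.**  Left and right anchors are
  mirror objects; silently fitting a reflection would destroy that
  distinction.  `allow_reflection=True` opts into the full orthogonal
  group per call.
* **Canonical consensus orientation.**  The GPA consensus is only defined
  up to rotation, so after convergence it is rotated onto its principal
  axes with a deterministic sign rule (largest-magnitude coordinate made
  positive).  This makes tangent coordinates exactly invariant to a common
  similarity transform of all inputs, which both the tests and downstream
  reproducibility rely on.

The fit finishes with an orthogonal projection of the aligned coordinates
onto the tangent space at the consensus (removing the component along the
consensus direction).  After centering and rotation optimality this leaves
row vectors orthogonal to all four similarity directions, so ordinary
covariance-based statistics apply; the tangent data have rank at most
2k − 4.

## Outlier screening

Squared Mahalanobis distances of shape variables are compared with
chi-squared quantiles.  Superimposed data are rank-deficient, so distances
are computed on PCA scores in a full-rank subspace: all covariance
eigenvalues above 1e-12 × the largest, or a user-fixed dimension m (a
singular request raises an error reporting the usable rank).  The default
cutoff probability is 0.975 — a conventional choice, recorded in the run
report.  Screening defaults to per-species-and-side (each specimen judged
against its own species' covariance, the usual definition of a
morphometric outlier) with a pooled option.  The screen only *flags*;
exclusion is an explicit, logged pipeline step.

## PCA

Covariance-matrix PCA (divisor n − 1) of the centered tangent data, via
SVD.  Both specimen-level and species-mean-level decompositions are
first-class because summary tables in this field are usually reported at
the species-mean level while ordinations are drawn at either.  Loading
signs follow a deterministic rule (largest-magnitude element positive) so
scores are platform-stable.

## Allometry

Static allometry regresses tangent coordinates on log centroid size.
"Regression through the origin" is implemented as a no-intercept regression
of *mean-centered* shape on *mean-centered* logCS — the standard
morphometrics reading, since a strict through-origin fit on raw coordinates
would conflate the mean shape with allometry (the strict variant is
available behind `center=False`).  The effect size is the percent of total
shape variation carried by the predicted values; significance permutes
logCS across specimens (default 10,000 permutations, +1-corrected p).
Size-corrected shapes are the residuals re-centered on the grand mean, so
they drop into any downstream analysis; the correction is idempotent.

Evolutionary allometry is assessed on Felsenstein's standardized
independent contrasts of species means (post-order pruning with
branch-length extension; polytomies resolved to zero-length bifurcations
with a warning; zero lengths floored at 1e-8).  Contrasts have zero
expectation, so the contrast regression really is through the origin with
no centering; the permutation null both re-pairs and sign-flips the size
contrasts, reflecting the sign-arbitrariness of contrasts.

## Phylogenetic signal

**Tree length.**  Squared-change parsimony places each internal node so as
to minimize L = Σ_branches ‖x_child − x_parent‖²/ℓ (equivalently the
Brownian-motion maximum-likelihood reconstruction).  The stationarity
conditions make each internal node the branch-length-weighted average of
its neighbours; the resulting linear system is solved exactly, one trait
dimension at a time (the objective separates by coordinate).  For
permutation testing the internal nodes are eliminated analytically: L is a
quadratic form tr(XᵀQX) in the tip data, with Q the Schur complement of the
weighted graph Laplacian on the tips, so each of the (default 10,000)
tip permutations costs one matrix product.  Signal is evidenced by a
*short* observed tree, hence p = (#draws ≤ observed + 1)/(n + 1).  When the
input tree is a bare topology, branch lengths default to 1 — mapping a
topology — and the weighted and unweighted objectives coincide; with
lengths present the weighted objective is used and the mode is visible in
the stored tree.

The same machinery applied to logCS (p = 1) gives the size signal; its
tree length is in squared-logCS units.  An absolute-change ("distance")
variant of the unit would be computable from the same reconstruction, but
the squared convention is the default so that one objective serves shape
and size alike.

**Multivariate K.**  With Y the tip matrix, C the Brownian tip covariance
(C_ij = shared root-to-MRCA path length), a the GLS phylogenetic mean and
E = Y − 1a:

    K = [tr(EᵀE) / tr(EᵀC⁻¹E)] ÷ [(tr C − N/(1ᵀC⁻¹1)) / (N − 1)]

K = 1 in expectation under Brownian motion (exactly 1 on a unit-branch
star tree, where C = I), K < 1 means more among-relative divergence than
Brownian, K > 1 less.  Significance: tip randomizations (default 999),
favourable draws ≥ observed.  At p = 1 this reduces to Blomberg's K; the
test suite cross-checks that reduction against the independent R
implementation (`picante::Kcalc`) and against an eigen-free
Cholesky-whitened GLS route.

Signal tests default to the full tangent-space data, with an option to
restrict to the first m PC scores — ordinations are usually drawn in 2
PCs, and the two conventions differ, so both are one flag apart and the
choice is recorded in every report.

All permutation p-values use the +1 Monte-Carlo correction and are never
exactly zero.  Seeds are explicit arguments everywhere; null draws are
returned for audit.

## Synthetic data

The generator emulates exactly the structure the analysis assumes: species
mean shapes = an asymmetric 8-landmark anchor-like template plus
multivariate Brownian deviations confined to the template's tangent space;
specimen shapes = species mean + β·(logCS − species mean logCS) + isotropic
landmark noise; logCS = grand mean + Brownian species component +
within-species Gaussian noise.  Each emitted configuration receives a
random rotation, translation and digitizer scale (the scale stored as the
TPS-style `scale_factor`), so the pipeline must genuinely superimpose and
can still recover the intended physical size with `scale_policy="apply"`.
One global seed feeds independent per-stage streams (tree, shape BM, size,
noise, rigid motions), so stages can be varied or regenerated
independently.

Default conditions mirror the study scale the package was designed around:
14 species, 20 specimens per species, 8 landmarks.  The default shape
Brownian rate (1e-3 per dimension) against within-species landmark noise
(5e-3) puts between-species shape variance at roughly the level where both
signal tests operate comfortably at n = 14; size defaults (BM rate 0.01,
specimen sd 0.05 on logCS) give a few-percent coefficient of variation in
size, typical of congeneric series.

Null scenarios are label-only operations: `shuffle_species` permutes
species names across cohesive species groups (destroying the
species↔tree association while preserving group structure), and
`iid_species` permutes the specimen-to-species assignment across all
specimens, making each species' sample an i.i.d. draw from the pooled
population — species means then carry no tree structure by construction.

**What passing synthetic tests does not show.**  Real anchors violate the
generator in known ways: landmark noise is anisotropic and
landmark-specific, within-species variation includes allometric growth not
reducible to one β, digitizing error is not rotation-free, and real
evolution need not be Brownian (the K statistic's calibration to 1 is
model-specific).  The simulations therefore validate the *computations* —
estimators recover their own generating parameters, tests hold their
nominal level and have power against their intended alternatives — not the
biological adequacy of the Brownian model for any particular dataset.

## Numerical conventions and degenerate inputs

* Branch lengths: absent → 1.0; anything below 1e-8 floored (warning).
* GPA: all-coincident landmarks raise a degenerate-shape error rather than
  producing NaNs; a collapsed consensus aborts the fit.
* Datasets with zero shape variance pass through the pipeline (the outlier
  screen reports "nothing to screen", tree lengths are 0, all p-values 1).
* Permutation tie-breaking: tree-length comparisons use a 1e-12 relative
  tolerance so bit-level reordering noise cannot flip a tie.
* All report tables round to 3 significant digits (eigenvalues) and one
  decimal (percentages); full precision lives in the JSON report.

## Problem sizes used in the test suite

Calibration checks run 500 null replicates at 199
permutations each; power checks 100 replicates; the Monte-Carlo mean of K
uses 500 Brownian replicates on a 14-tip tree in 12 trait dimensions; the
contrast-variance check uses a 64-tip tree.  These sizes give binomial /
Monte-Carlo error comfortably inside the asserted bands while keeping the
whole suite around a quarter of a minute.
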