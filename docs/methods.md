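# Methods

`caniform` implements a landmark-based morphometric workflow for deciding
whether a canid skull is a dog, a wolf, or neither. This note documents
the models and procedures, the numerical choices, what the synthetic data
emulate, and the limitations of both.

## Superimposition

Raw data are 3D coordinates of named landmarks, digitized per specimen in
a dorsal and a ventral view that share four landmarks, with two replicate
digitizations. The ventral view is fitted onto the dorsal one by a
least-squares rigid motion (Kabsch solution with the determinant forced
to +1 — a reflection would silently swap anatomical sides), and shared
landmarks are replaced by the midpoint of the fitted pair so the combined
configuration has a fixed landmark count (36 in the default design).

Superimposition is *partial* generalized Procrustes analysis: every
configuration is centred and rescaled once to unit centroid size
(CS = square root of summed squared landmark distances to the centroid),
then only translated and rotated during the iterations. Object symmetry
is handled by the reflect-and-relabel construction: each configuration
enters the fit together with its mirrored, label-swapped copy, the
consensus is re-symmetrized every iteration (which makes it an exact
fixed point of reflect-and-relabel), and a specimen's **symmetric
component** — the mean of its two aligned copies — is what all downstream
analyses use. Replicates are averaged after alignment; centroid size is
averaged on the original millimetre scale.

Numerical choices:

- Convergence: root-mean-square change of the consensus < 1e-10, at most
  100 iterations (both configurable). Structured skull-like samples
  converge in < 10 iterations; fully random configurations may need more.
- A GPA solution is defined only up to a global rotation. The consensus
  is therefore put in a canonical orientation (principal axes with
  deterministic third-moment sign conventions; with a symmetry map, only
  rotations keeping the symmetry axis are used and the left side is
  placed on positive x). This makes superimposed *coordinates* — not
  just shapes — invariant to arbitrary rigid motion and scaling of the
  inputs, which is the contract the tests assert.
- Degenerate inputs (all landmarks coincident) raise immediately.

Measurement error is quantified by a two-effect Procrustes ANOVA
(among-individual vs replicate error), with degrees of freedom scaled by
the shape-space dimension 3K − 7 and Goodall's F referred to an F
distribution. A side/directional-asymmetry effect is deliberately not
modelled: replicate error is the only quantity of interest here.

## Form space

The form matrix is the flattened symmetric shape coordinates augmented
with one column of ln CS. PCA is on the covariance matrix (no variable
weighting), computed by SVD of the centred matrix. Unknown specimens
never enter the decomposition: they are rescaled, fitted to the frozen
reference consensus by a single rigid step, symmetric-component-extracted,
centred by the reference mean and projected on the reference
eigenvectors.

Procrustes data are rank-deficient: centering, rotation and the one-off
scaling suppress 4 dimensions of the symmetric space (2 in-plane
translations, 1 in-plane rotation, scale) to *near* zero without zeroing
them exactly. The exact symmetric form-space rank, 3·(landmark pairs) +
2·(midline landmarks) − 4 + 1, is therefore threaded to every consumer of
the eigenvalue spectrum, so leakage eigenvalues (~1e-4 of the leading
one) never enter sphericity tests.

**PC retention.** The number of PCs worth interpreting is chosen by the
classical test of equality of trailing eigenvalues: for the q smallest,
n′·[q·ln(mean λ) − Σ ln λ] with Lawley's small-sample multiplier
n′ = n − k − (2q² + q + 2)/(6q), referred to chi-square with
q(q+1)/2 − 1 df. Blocks grow from the smallest trailing pair upward and
each is tested at the Bonferroni-corrected level α/(p−1): the union bound
then guarantees that on truly spherical data the chance of retaining any
PC stays below α (measured keep-rate 98–99% at α = 0.05), while blocks
containing genuine structure are rejected decisively.

**Size tests.** Two-group permutation tests (n_perm configurable,
two-sided, add-one p-value convention so p ≥ 1/(n_perm+1)) are run on
lnCS: group means for dog-vs-wolf size, and variances of within-group
lnCS deviations for the Arctic-vs-Eurasian size-variability contrast.
lnCS rather than CS is used throughout, for symmetry with the form-space
variable.

**PC extremes.** A morph at position ±m on PC j is the consensus plus
±m times the shape block of eigenvector j, with all coordinates then
multiplied by exp(±m·v_lnCS) so the size content of the PC appears as
actual scale. The default magnitude is two standard deviations of the
reference scores on that PC.

## Classification

The reference sample is unbalanced (91 dogs vs 315 wolves), so
classification uses balanced resampling. Per iteration i (pseudo-random
stream derived from (seed, i), so runs are reproducible and individual
iterations re-derivable):

1. draw a without-replacement wolf subsample of the dog sample size;
2. refit the form-space PCA on the balanced sample;
3. choose the retained PC count k by the sphericity test (clipped to
   [1, n_dogs − 2] so group covariances stay invertible);
4. fit a two-group QDA with equal priors (0.5/0.5) on the retained
   scores — group means and unbiased covariances, posteriors as
   normalized prior-weighted Gaussian densities;
5. score each projected unknown: assign the maximum-posterior group only
   when that posterior strictly exceeds 0.90, else undetermined;
6. compute each unknown's typicality against both groups: the chi-square
   upper tail (df = k) of its squared Mahalanobis distance under the
   pooled covariance (an F-based small-sample variant is available as an
   option). Typ.P ≤ 0.05 flags a specimen that fits neither group.

Aggregation over iterations yields, per unknown: mean posteriors, the
percentage of iterations classified dog / wolf / undetermined, the final
call (a group must win ≥ 90% of iterations, else "Ind" — the fraction is
configurable), the percentage of iterations whose typicality call was
atypical, and the majority typicality group. Reference-sample
discrimination is summarized per iteration by leave-one-out
cross-validation (undetermined calls count as errors), Klecka's tau
(n_correct − Σ prior·n_g)/(N − Σ prior·n_g), Wilks' lambda
det(W)/det(T), and Box's M with the standard scaling correction,
averaged over iterations. Leave-one-out refits use exact rank-one
mean/SSCP downdates rather than refitting from scratch.

Boundary conventions: a posterior of exactly 0.90 is undetermined
(strict inequality), as is an exact 0.5/0.5 tie.

## Cranial indices (negative control)

Five caliper distances (total skull length = prosthion–basion,
viscerocranial length, alveolar P4–M1 row, greatest and minimum palate
width) are measured on the original millimetre coordinates, averaged
over replicates, and combined into four indices as ratios of log10
distances (a log-of-ratio alternative is available; the ratio-of-logs
default is deliberately not scale-free, and the tests document that).
Distances ≤ 1 mm are rejected because the log10 denominator would be
non-positive. The index PCA projects unknowns onto reference
eigenvectors exactly like the form-space PCA, and bivariate exports
include per-group convex-hull vertices. The point of the module is
negative: index-space group hulls overlap heavily where the form-space
classifier separates cleanly. The exact anatomical definitions of the
viscerocranial and palate measurements are configurable landmark pairs;
the defaults are stand-ins on the synthetic template.

## Synthetic data

No landmark data are deposited for the original skull sample, so the
generator produces datasets with the statistical structure the analysis
assumes, with recorded ground truth:

- a 36-landmark bilaterally symmetric skull-like template (14 left/right
  pairs + 8 midline points), exactly fixed under reflect-and-relabel;
- a dog–wolf mean-shape contrast confined to nasal/frontal landmarks
  (nasals shifted caudally, frontals rostrally — the "stop"), symmetric
  by construction;
- a common allometric field (relative widening of the zygomatic arch,
  muzzle elongation, relative braincase flattening with size);
- structured within-group shape variation: orthonormal symmetric modes
  with decaying variances, the first aligned with the stop axis. Real
  skull samples concentrate most shape variance in a handful of
  biological directions; with purely isotropic variation, any
  group-contrast PC strong enough for the sphericity test to retain
  would force near-perfect classification, so the modes are what let the
  generator hit the published regime (7 retained PCs, ~96% correct)
  honestly;
- isotropic per-landmark noise (σ = 0.012 in unit-CS shape units) and
  replicate digitization error (σe = 0.003, scaling with skull size in
  mm);
- log-normal sizes: dogs lnCS ~ N(5.99, 0.085), Arctic wolves
  N(6.14, 0.055), Eurasian wolves N(6.16, 0.100) — wolves larger but
  overlapping, Eurasians more size-variable; group counts 91/258/57
  reproduce the study design's imbalance;
- unknowns: draws from the group distributions with a 0.5 dispersion
  multiplier (they represent typical, museum-quality specimens — the
  published fossil classifications were near-unanimous), plus a
  "constructed ambiguity" unknown *placed* exactly at the midpoint of
  the dog and wolf means with digitization error only;
- every specimen is emitted as dorsal + ventral views sharing four
  matching landmarks, two replicates each, under independent random
  rigid motions.

Everything is reproducible bit-for-bit from (params, seed).

With these defaults the full pipeline lands in the published regime:
retention chooses 7 PCs in essentially every balanced iteration, LOOCV
accuracy at the 0.90 threshold is ~95–96%, tau ~0.91, Wilks' lambda
~0.16, PC1 is a size-allometry axis with |r(PC1, lnCS)| > 0.99 while
PC2/PC3 are size-free, and >70% of dogs fall inside the wolf hull in
index space.

What passing tests do *not* show about real data: the generator's
covariance structure is far simpler than real cranial integration (a few
global modes rather than regionalized covariation), landmark noise is
homogeneous across landmarks, there are no missing landmarks or broken
specimens, and the fossil taphonomy that motivates typicality checks is
absent. Results on synthetic data validate the machinery, not the
biology.

## Problem sizes

The test suite runs the full default design (406 reference specimens,
two replicates, both views) with 100 resampling iterations, and
simulation-based checks at 100–600 replicates; the acceptance script
runs the full 1000-iteration resampling. These sizes were chosen so the
whole analysis reruns in well under a minute while keeping Monte-Carlo
error far below every asserted tolerance.

## Known limitations

- Partial (not full) Procrustes: no per-iteration optimal scaling. For
  the small shape distances here the difference is far below the noise.
- The sphericity-based retention rule tests trailing *blocks*; a weak
  signal eigenvalue adjacent to the noise band can be absorbed into it.
  The balanced designs used here keep the retained set stable at 7.
- Two reference groups only; no missing-landmark estimation; no sliding
  semilandmarks; mesh warping for visualization is out of scope (PC
  extremes are exported as landmark configurations).
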