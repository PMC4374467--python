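# Methods

`morphoqtl` maps quantitative trait loci for the shape and size of a
bilaterally symmetric 3D structure — the motivating application is the mouse
skull in an N2 backcross — from raw landmark coordinates and marker
genotypes. This note documents the statistical models, the numerical
choices, and what the synthetic-data generator does and does not emulate.

## Shape phenotype: Procrustes superimposition with object symmetry

Each specimen is a configuration of k 3D landmarks comprising p bilateral
(left/right) pairs and l midline landmarks, k = 2p + l. Size is measured by
centroid size (the root summed squared distances of landmarks to their
centroid) and removed, together with position and orientation, by a full
generalized Procrustes analysis: configurations are centered, scaled to unit
centroid size, and iteratively rotated to a running consensus until the
consensus stabilizes (Frobenius change < 1e-10, at most 200 iterations).

Object symmetry is handled by doubling the sample with reflected,
relabeled copies (the x axis is negated and each left/right pair of labels
swapped — the axis is a convention; any choice is equivalent after
alignment) and superimposing all 2n configurations jointly. The consensus
of the doubled sample is symmetrized exactly (averaged with its own
reflection) before a final alignment pass. Per specimen, the symmetric
component is the average of the aligned original and its aligned reflected
copy, and the asymmetric component the half-difference. The split is an
exact even/odd decomposition under the reflection operator, so the two
components are pointwise orthogonal; their *sample* cross-covariance is
zero only in expectation, at the usual O(1/sqrt(n)) finite-sample rate.

Aligned symmetric shapes are projected orthogonally onto the tangent space
at the consensus, v = (I - mu mu^T) x with mu the unit-norm flattened
consensus, and reduced by PCA. Only components with eigenvalues above a
relative tolerance of 1e-9 times the largest are retained. For generic data
this retains exactly 3p + 2l - 4 dimensions (3p + 2l free coordinates of a
mirror-symmetric configuration minus two in-plane translations, one
in-plane rotation, and scale); with 22 pairs and 9 midline landmarks that
is 80. The numerical spectrum shows a gap of roughly thirteen orders of
magnitude at the cut, so the tolerance is not delicate. Because the PC
basis is orthonormal, all downstream statistics (Pillai trace, effect
norms, variance fractions) are invariant to working in scores rather than
tangent coordinates.

A landmark-repeatability screen compares two replicate placements and flags
landmarks whose median (configurable quantile) replicate distance exceeds a
cutoff in mm; 0.125 mm is a conventional choice at typical microCT
resolution.

## Genotype probabilities

An N2 backcross has two genotype classes per autosomal locus, HOM and HET.
Posterior genotype probabilities on a cM grid are computed by a two-state
hidden Markov model: uniform (1/2, 1/2) initial distribution, symmetric
transitions whose off-diagonal is the recombination fraction of the
inter-position distance, and emissions that flip the observed code with the
genotyping error rate (default 1e-4); missing codes emit uniformly, so an
individual with a whole chromosome untyped simply gets flat posteriors.
Pseudomarkers subdivide each inter-marker interval uniformly into the
fewest segments with spacing at most the grid step (default 1 cM) and enter
the chain as untyped observations. The forward-backward recursion is
scaled (no log-space needed for two states) and vectorized over
individuals; an exhaustive hidden-path enumeration oracle verifies it to
1e-10 on short chromosomes.

Map distance and recombination fraction are linked by the Carter-Falconer
map function, which models the strong crossover interference of the mouse:
d(r) = 12.5 ln((1+2r)/(1-2r)) + 25 arctan(2r) cM. The forward direction
r(d) has no closed form and is computed by Brent root finding on [0, 0.5)
to 1e-12. Interval bounds in cM are converted to bp by piecewise-linear
interpolation through a user-supplied anchor table; queries outside the
anchors are extrapolated from the terminal segment and flagged, since
genome-build-specific conversion is outside the package's scope.

## Genome scans

At each grid position the q-dimensional score matrix Y is regressed on
covariates (intercept, sex, direction of cross, log centroid size) plus the
single additive backcross regressor P(HET) (Haley-Knott regression). The
position's evidence is Pillai's trace V = tr[H (H + E)^-1] of the nested
fits, converted through the standard approximate F (exact for single-df
hypotheses, where it coincides with Hotelling's T^2) to
logP = -log10(p), comparable to a LOD score. Log centroid size is scanned
with the classical LOD = (n/2) log10(RSS_reduced/RSS_full).

Two structural facts make scans cheap: for nested least squares H + E
equals the reduced-model residual SSCP, which does not depend on the tested
position; and the QTL term is a single column, so
V_j = b_j^T T^-1 b_j with b_j the residualized genotype column projected
against the residualized responses. A genome scan is therefore one QR
decomposition, one Cholesky factorization, and one matrix product;
permutation thresholds at 300-10,000 iterations are routine on one CPU.
Monomorphic (zero-residual-variance) positions score 0 with a warning.
Scans require error df >= q + 2 and refuse to run otherwise, directing the
user to truncate the PC scores.

Genome-wide significance uses the permutation scheme in which phenotype
rows and covariate rows are reshuffled *jointly* by one permutation per
iteration while genotype probabilities stay fixed, destroying only the
genotype-phenotype association. The threshold is the empirical (1 - alpha)
quantile (linear interpolation of order statistics) of the stored
genome-wide maxima; the maxima are kept so any alpha can be re-read.

## Multiple-QTL model search

Model comparison uses a penalized joint logP: the Pillai logP of all model
QTL tested jointly against the covariate-only design, minus the genome-wide
threshold T times the number of QTL. The null model scores 0. The forward
search adds, at each step, the grid position with the largest joint-logP
gain conditional on the current model, then refines positions; the search
runs to `max_qtl` (default 50, capped so error df stays >= q + 2).
Backward elimination then walks from the forward endpoint to the null
model, dropping at each step the QTL whose removal leaves the largest joint
logP, refining after each drop. The best model is the penalized-score
argmax over everything visited. A significance-driven stepwise variant adds
QTL while the best candidate's conditional logP reaches T and drops any QTL
whose conditional logP falls below T.

Position refinement re-scans the genome for each QTL conditional on all
others (a QTL may migrate between chromosomes; a chromosome-restricted mode
exists). The criterion maximized during refinement is the *joint* model
logP — computed from the same conditional scan via the covariate-only
residual metric — rather than the conditional logP itself. The two profiles
have nearly identical argmaxes on real signals, but only the joint
criterion guarantees that refinement never decreases the model score, which
the implementation asserts on its trace. Ties break toward the lowest
chromosome index, then the lowest cM. Refinement stops when a full cycle
moves nothing or after 20 cycles.

Per-QTL location uncertainty is a Bayes credible interval from the 1/p
profile: the QTL's conditional logP profile over its chromosome (all other
QTL fixed at their refined positions) is exponentiated, w ∝ 10^logP,
normalized to unit mass over the chromosome grid, and grid positions are
accumulated in decreasing-weight order until the coverage level (default
0.95) is reached; the interval is the min-max position of the accumulated
set. An all-zero profile yields the whole chromosome with a warning.
Endpoints are reported at grid positions. Simulations show near-nominal
coverage for moderate effects; very strong signals concentrate the profile
onto few grid points and coverage becomes anti-conservative, consistent
with the known liberality of such intervals in multiple-QTL settings.

## Effects and their anatomical decomposition

A fitted model is an ordinary multivariate least-squares fit of Y on
[intercept | covariates | P(HET) per locus]; per-dimension coefficients
stack into q-dimensional effect vectors, reported both in score space and
back-transformed to landmark displacements. Effect magnitude is the
Euclidean norm (a Procrustes distance, basis-invariant). Each term's
contribution is its drop-one sum of squares over all dimensions as a
percentage of the total Procrustes sum of squares. Projection scores
s = Y beta^T / ||beta|| give the shape variable along an effect's
direction; the variance share of the QTL in its own direction is the
conditional R^2 of the term in a regression of s on the full model design.

Region decomposition assigns each landmark's displacement norm to its
anatomical region(s); a boundary landmark splits its magnitude equally
among its regions. Raw proportions divide region sums by the grand sum;
count-normalized proportions divide by fractional landmark counts and
renormalize. The null reference is the decomposition of isotropic
standard-normal vectors drawn in the q-dimensional symmetric tangent
subspace and back-transformed to displacements — QTL effects are confined
to that subspace, so the null lives there too. Empirical (alpha/2,
1-alpha/2) intervals per region flag observed proportions outside them.

Angles between effect vectors and the phenotypic PC structure are computed
in two modes, because "the leading PCs" is genuinely ambiguous: angle to
PC1, or angle to the orthogonal projection onto the span of the first k PCs
(k defaults to the count spanning 90% of phenotypic variance). The null is
the same angle for isotropic random vectors (for which E[cos^2] = 1/q); a
Monte-Carlo p tests whether the observed mean angle is smaller than random,
and the angle-magnitude association is a Pearson correlation with a
permutation p (10,000 shuffles), appropriate for the small number of QTL.

## Enrichment

Genes overlap a credible interval if they share at least one bp
(1-based inclusive; BED input is converted from 0-based half-open), with a
strict-containment mode available; genes hit by several intervals count
once. Enrichment of a training gene set among the candidates is the exact
hypergeometric upper tail P(X >= k), summed in log space. The genome-wide
gene count N is an input, not a constant, since it is annotation-build
dependent. On the bundled published counts (N=22,644, K=102, n=2,476,
k=23) the exact tail is 5.5e-4 — reproducibly computable but notably larger
than the sub-1e-4 level sometimes quoted for these counts.

## Synthetic data generator

The generator emulates the motivating study design: 433 N2 individuals in
four sex-by-direction strata (84/79/128/142), 19 autosomes of 73 cM with 46
evenly spaced markers (~880 total), and 53-landmark configurations with 22
bilateral pairs and 9 midline landmarks. Hidden genotypes follow the
marker-interval Markov chain with Carter-Falconer recombination fractions
(no interference modeling within intervals beyond the map function);
observed genotypes flip with the genotyping error rate (1e-4) and drop to
missing at 2%. Planted QTL positions join the chain as latent loci, so
loci between markers get exact genotypes, and all ground truth (positions,
effect vectors, hidden genotypes) is stored with every dataset.

Shape phenotypes follow the additive model used in mapping, built inside
the symmetric tangent subspace of a generic base configuration: planted QTL
effects (isotropic or region-targeted directions, magnitudes in Procrustes
units), covariate effects (allometry 4%, direction-of-cross 2%, sex 1% of
the total shape variance — the observed 1-4% range), and a correlated
residual with a 10-factor low-rank plus diagonal covariance (decay 0.9,
factors carrying 60% of the residual) chosen so that variance is diffuse
and no single PC exceeds ~12%. Total symmetric shape variance defaults to
5e-4 squared Procrustes units, a typical within-cross magnitude for a
mammalian skull. Raw configurations add isotropic coordinate noise
(default 0.002 shape units) that generically breaks symmetry, then a random
rotation, translation, and scale per specimen; centroid sizes are
log-normal around 60 mm with small sex, direction, and size-QTL effects. A
backcross effect of magnitude b contributes b^2/4 to the shape variance, so
`effect_magnitude_for_share` converts variance shares to magnitudes.

What the generator does *not* emulate: imaging artifacts and
observer-specific landmarking error beyond the offset fixtures of the
repeatability screen, linkage maps with irregular marker spacing or
genotype clustering, selection or family structure within the cross,
dominance or epistasis (the mapping model is additive-only by design), and
X-linked loci. Passing tests therefore demonstrate the statistical
machinery under the stated additive, autosomal, two-class model — not
robustness to violations of it.

## Numerical conventions and limitations

- Rank and collinearity are decided by pivoted QR with an
  eps-times-dimension tolerance; errors name the offending columns.
- Pillai V is clipped to [0, min(q, h)]; a singular H + E (noiseless
  responses) falls back to the pseudoinverse.
- logP uses the logarithmic survival function of the F distribution, so
  scores beyond p ~ 1e-308 do not overflow.
- Empirical quantiles use linear interpolation of order statistics
  throughout (thresholds, null intervals).
- bp coordinates are 1-based inclusive in reports and 0-based half-open in
  BED exports; the conversion is centralized in the writers.
- Credible intervals inherit the known liberality of 1/p-profile intervals
  under multiple-QTL uncertainty; they condition on the other QTL's point
  positions.
- The expected direction correlation between a fitted and a planted effect
  vector is bounded by the attenuation sqrt(lambda/(lambda + tr(S)/(n/4)))
  at effect share lambda; at 1% of trace and n=400 this is ~0.90 for any
  response dimension, which is why small-q regimes are used when that
  recovery property is asserted.
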