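# Methods

`morphoquant` implements a landmark-morphometrics and quantitative-
genetics analysis for a juvenile Atlantic salmon common-garden study of
two biallelic life-history loci, *vgll3* and *six6* (alleles E =
early-maturation-associated, L = late). This note documents the models,
the numerical choices, and what the synthetic-data generator does and
does not emulate.

## Genotype coding and the breeding design

Genotypes are coded additively as the count of L alleles (EE = 0,
EL = LE = 1, LL = 2), so a unit change is one allele substitution from
E to L. The emulated breeding design crosses 44 parents in 11
two-by-two factorial units; within each unit one male and one female
are *vgll3* EE homozygotes and one of each sex LL, so the four full-sib
families per unit are each fixed for one offspring *vgll3* genotype
(EE, EL, LE, LL). *six6* is not controlled by the design and segregates
within families; the generator draws parental *six6* genotypes from a
configurable distribution (default Hardy–Weinberg at allele frequency
0.5) and transmits alleles by Mendelian sampling.

A consequence worth stating explicitly: because *vgll3* is constant
within families, its genotype vector lies in the span of the family
factor. In the multivariate shape model (where family is a fixed
factor) the family dummies are listed last and rank-deficient levels
are merged into the reference level, so the genotype terms remain
estimable — mirroring how a fixed-effects `lm` drops later aliased
columns. In the pedigree mixed model the same confounding means the
genotype-*free* model's animal variance absorbs the family-patterned
locus variance at roughly twice its nominal value (a family-constant
effect has full-sib covariance equal to its variance, not half of it).
This is a property of the design, not of the estimator; the
parameter-recovery experiments therefore validate unbiasedness on the
correctly specified genotype-including model, and validate the locus
contribution formula under a locus segregating in Hardy–Weinberg
proportions (see "Validation experiments").

## Pedigree and the relationship matrix

The additive (numerator) relationship matrix A is built by the tabular
recursion over a topologically ordered pedigree: A_ii = 1 + A_{s,d}/2
and A_ij = (A_{j,s} + A_{j,d})/2, with unknown parents treated as
unrelated, non-inbred founders. An independent gene-dropping Monte
Carlo (two distinct neutral alleles per founder, Mendelian transmission
vectorised over drops) serves as a simulation oracle; the test suite
requires agreement within three Monte-Carlo standard errors at 10^5
drops. The matrix is returned dense — at the study scale (~900–1000
individuals) sparse structures buy nothing.

## Landmarks, Procrustes superimposition, filters

Landmark configurations (2-D, fixed count per body plane: 21 for the
lateral body, 9 and 16 for the small and large cross-sections) are read
from TPS files (LM=/ID=/SCALE= records, with PLANE=/REPLICATE=
extension records) or a wide CSV. Missing landmarks stay NaN until
imputed by a thin-plate-spline warp (scipy's RBF interpolator with the
TPS kernel and linear polynomial tail) mapping the consensus onto the
specimen's observed landmarks; TPS reproduces affine maps exactly,
which the tests exploit as an oracle.

Generalized Procrustes analysis centres each configuration, scales it
to unit centroid size (full Procrustes, matching shape variables
normalised for centroid size), rotates it onto the running consensus by
the SVD-optimal proper rotation (reflections corrected by a sign flip
of the smallest singular vector — landmarks have fixed chirality), and
iterates until the summed squared deviation from the consensus changes
by less than 1e-8 (maximum 100 iterations). The converged solution is
rotated to a canonical frame (consensus principal axes on x/y, sign
fixed by the landmark farthest along the first axis) so the result is
invariant, to 1e-8, to arbitrary similarity transforms of the inputs.

Outlier filtering follows the study's rule: per landmark, the scatter
SD is the root-mean-square deviation of that landmark from its
consensus position across configurations; a landmark farther than 4 SD
is an outlier, and a configuration is excluded iff **more than one** of
its landmarks is an outlier. Individual-level filters remove fish with
fork length strictly below 9 cm (the lower mode of the bimodal juvenile
length distribution), missing *vgll3*, *six6* or sex, and precociously
mature males, in that order; the audit log counts each removal under
the first rule it fails.

Trait extraction evaluates the 21 trait definitions (inter-landmark
distances, means of distances for bilateral or multi-segment traits,
and centroid sizes over landmark subsets) on the raw coordinates in cm.
The default definition set ships as a YAML config; the eye-diameter
entry is read as the mean of the horizontal (2–3) and vertical (4–5)
bony-orbit distances, and users can override any entry. Replicate
measurements are kept as separate rows for the mixed models and
averaged only for the shape MANOVA. Fulton's condition factor is
K = 100·W/L³ (W in g, L in cm); length and condition covariates are
centred and scaled to unit sample SD (n−1 denominator).

## Multivariate shape model and RRPP

Aligned shape variables (n × 2k) are regressed on scaled length,
scaled condition factor, feed treatment, tank, sex, both additive
genotype codes, and family — all fixed, dummy-coded terms (the
multivariate model takes no random effects). Each term is tested
marginally: the effect SSCP is the difference of projections onto the
full and the term-deleted design space (with no interactions this
marginal SS is the type-III SS), the residual SSCP comes from the full
model, and Pillai's trace tr(H(H+E)^-1) summarises the pair (singular
H+E falls back to a pseudo-inverse with a warning; aligned shape data
are rank-deficient by construction, losing 4 dimensions to the
similarity group).

Significance uses residual randomization (RRPP): each of B = 999
permutations shuffles the reduced-model residual rows, adds back the
reduced-model fitted values and recomputes the statistic;
p = (1 + #{perm ≥ observed})/(B + 1) with inclusive ties, and the
permutation z-score standardises the observed statistic against the
null sample. z is computed on the untransformed statistic by default; a
log-scale option exists since permutation software differs on this
convention. Projections are cached as orthonormal bases, so a
permutation costs two small matrix products — 1,000 null datasets of
n = 60 with 199 permutations run in seconds.

Genotype shape-displacement vectors are the difference in predicted
landmark positions between code 2 and code 0 with all other covariates
at their reference/mean, optionally magnified (default 10×) for
display.

## The animal model

Each trait is modelled as

    y = μ + L + CF + Feed + Sex + Vgll3 + Six6 + e_ID + e_tank + e_animal + e_error

with fixed covariates as above and three random terms: an i.i.d.
individual effect (between-individual residual), an i.i.d. tank
effect, and the additive-genetic animal effect with covariance
V_animal·A. With repeated measurements the individual term and the
per-measurement error are separately identified; the error term then
quantifies deviations between repeated measurements (digitising error).

Coefficients reported per trait come from the ML fit; variance
components for the decomposition come from REML fits. Estimation
maximises the (restricted) likelihood over log-variance components with
L-BFGS-B using an analytic score, three deterministic starts
(equal-split, residual-heavy, genetic-heavy) to avoid boundary traps,
and a convergence tolerance of ~1e-13 on the relative objective.
Components driven to the lower box bound are reported as exact zeros.

Two likelihood engines share one interface. The generic engine treats
the ID and animal terms as a single low-rank block (they share the
individual incidence matrix; with A = QΛQ' the joint covariance
Z(V_a·A + V_id·I)Z' becomes W·diag(V_a·λ + V_id)·W' for W = ZQ) and
evaluates the likelihood through the Woodbury identity. The collapsed
engine applies when every individual's rows share covariates and tank
(true of all study-shaped data): the likelihood factorises exactly into
a within-individual part (SS_w against V_error) and a between part on
individual means whose covariance, rotated by Q, is diagonal plus a
rank-(r + t) correction (r = replicated individuals, t = tanks), giving
O(m(r+t)²) per evaluation. The two engines agree to ~1e-11 on shared
inputs (asserted in the tests), and closed-form oracles (balanced
one-way ANOVA estimator, OLS) are matched to 1e-6/1e-8.

The observed information of the variance components is a central-
difference Jacobian of the analytic score on the raw variance scale;
its inverse (times 2, as the objective is −2·logL) is the component
covariance used by the Satterthwaite approximation and the CI
simulator. Satterthwaite denominator df for a contrast c is
2(c'Φc)²/Var(c'Φc) with Φ = (X'V⁻¹X)⁻¹ and the delta method over the
component covariance; with no variance parameters this collapses to the
exact n − p, and multi-column terms report the mean of per-column dfs.

AIC uses the ML log-likelihood with fixed coefficients plus variance
components as the parameter count. The additive-vs-dominance comparison
fits, by ML, the additive (numeric) coding, the free 3-level factor,
and the two constrained dominance codings (EL ≡ LL and EL ≡ EE),
reporting all AICs, delta = AIC_additive − AIC_factor, and a
"meaningful" flag at delta ≥ 2. Length-by-genotype interaction fits add
L×locus product columns and report interaction t-values plus the shift
in the main genetic effects. Composite traits are means of z-scored
component traits (the construction is underdetermined in the source
analysis; equal weights are the default and weights are exposed).

## Variance decomposition

From the genotype-free REML fit ("full additive-variance model"):
V_A = V_animal; h² = V_animal/(V_animal + V_tank + V_ID) — measurement
error is deliberately excluded from the denominator; evolvability
I_A = V_A/ȳ² (unitless, scale-invariant); percent repeatability
R = 100·V_ID/(V_ID + V_error). From the genotype-including fit, each
locus' percent contribution to the additive variance is

    %V_A.locus = 100 · 2·p_L·p_E·(β² − se(β)²) / V_animal

truncated at zero; subtracting se² corrects the upward bias of β̂² as an
estimator of β². Allele frequencies are computed from the analysed
individuals.

Interval estimates come from a large-sample parametric simulator:
10,000 draws of the variance components from a Gaussian at the REML
estimates with the inverse-information covariance, truncated at zero
(draws where a whole denominator is zero take the boundary value 0),
plus Gaussian draws of the fixed effects; the 95% CI is the 250th and
9,750th order statistics and the reported point summary is the median.
This is the package's analogue of an approximate-posterior simulator,
documented as such rather than claimed identical to any other
implementation; both the medians and the plug-in point estimates are
retained since either may be quoted.

## Synthetic-data generator

The generator reproduces the study's statistical structure with known
truth: the factorial breeding design above; 8 rearing tanks with feed
restriction on half; a bimodal fork-length distribution (lower mode
mean 8 cm, SD 0.35; upper mode mean 12.5 cm, SD 1.2; lower-mode
fraction 7.5%) whose sub-9-cm fish exercise the length filter; planted
missing-genotype/sex counts (2, 12, 4) and 19 precociously mature
males, drawn disjointly from the above-threshold fish so the audit can
be checked exactly; and trait values generated from the same mixed
model the pipeline fits, with animal effects drawn through a Cholesky
factor of A. Default offspring count (21 per family, 924 total) leaves
roughly 810–820 individuals after filtering. Default trait parameters
are on a convenient unit scale (μ = 10; V_animal = 0.3, V_ID = 0.3,
V_tank = 0.1, V_error = 0.2, so h² ≈ 0.43 and repeatability = 60%;
β_vgll3 = −0.42, β_six6 = +0.30, i.e. the *vgll3* locus at about 30% of
the total additive variance — squarely in the range this kind of study
reports for its largest locus contributions).

A fraction of individuals (default 0.25) is measured twice. The real
study's replicate fractions ranged from ~2% (cross-sections) to ~92%
(body plane); a single default had to be chosen for the generic trait
generator, and 0.25 keeps V_ID and V_error well identified without
doubling the dataset.

Landmark configurations are built from synthetic per-plane templates
(tapered ellipse for the body, ellipses for the cross-sections — no
digitised specimen stands behind them), scaled allometrically with fork
length, displaced by a planted per-*vgll3*-code head-elongation field,
rigidly rotated and translated at random, and jittered with Gaussian
digitising noise per replicate. The displacement field is
orthogonalised against the similarity modes (translation, scale,
rotation) at the template, so the planted pattern lies in shape space
and survives Procrustes superimposition intact; the tests recover it
from the fitted genotype effect with cosine similarity > 0.95.

What the generator does **not** emulate: growth dynamics, real landmark
covariance structure (digitising noise is isotropic and homogeneous),
measurement-protocol artefacts, linkage between the loci, dominance and
epistasis (unless planted explicitly), or genotyping error. Passing
tests therefore demonstrate correctness of the estimators under the
stated generative model, not robustness to every feature of real
morphometric data.

## Validation experiments and problem sizes

The acceptance-style tests run, on one CPU: the gene-dropping oracle at
10^5 drops on pedigrees of ≤ 30 members plus PSD checks on 100 random
pedigrees; GPA geometry checks; 50 univariate Pillai/eta² oracle
datasets; 1,000 pure-noise RRPP datasets (n = 60, 199 permutations)
with the empirical type-I error required in [0.03, 0.07] at α = 0.05;
closed-form REML/OLS/Satterthwaite oracles; and the core recovery
surface at 50 replicate datasets of the default design (≈ 810
individuals each) — variance components and substitution effects
within 3 Monte-Carlo SEs of truth, h² interval coverage in [90%, 98%]
at 10,000 draws, and the locus-contribution estimator within 10% of
the planted 30% under the HWE-locus condition (β_vgll3 = 0,
2pq·β²_six6 = 0.3·V_A). Fifty replicates (rather than hundreds) keeps
the whole suite in a few minutes; the Monte-Carlo error bars in the
assertions account for the replicate count.

## Known limitations

- The %V_A denominator (genotype-free V_animal) overstates total
  additive variance for a locus fully confounded with family (see
  above); under the factorial design this applies to *vgll3*. The
  estimator is faithful to its definition; interpretation should keep
  the design in mind.
- Satterthwaite df for multi-df terms averages per-column dfs — exact
  for the balanced classical cases the tests cover, approximate
  otherwise.
- Component CIs are large-sample (information-based) and mildly
  anticonservative for variance components near the boundary; coverage
  for V_A in pilot runs sat at the low edge of the nominal band, while
  h² coverage was well calibrated.
- The collapsed likelihood engine requires replicate rows to share
  covariates; rows violating this fall back to the generic engine
  automatically.
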