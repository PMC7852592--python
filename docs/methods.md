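# Methods

`penblup` implements genetic evaluation for traits recorded on groups of
animals (pen sums) rather than on individuals, together with the forward
simulator used to validate it.  This note documents the models, the
numerical choices, and what the simulation study the package ships does and
does not establish.

## The group-record mixed model

The individual-record animal model for a trait is

    y = 1 mu + Z_l l + Z_c c + Z_a a + e,

with random litter effects `l ~ N(0, I sigma_l^2)` (common environment of a
full-sib group before weaning), pen effects `c ~ N(0, I sigma_c^2)` (shared
environment during test), breeding values `a ~ N(0, Omega sigma_a^2)` and
residuals `e ~ N(0, I sigma_e^2)`.  `Omega` is the pedigree numerator
relationship matrix `A` (PBLUP), the blended genomic matrix `G_w` (GBLUP) or
the single-step matrix `H` (ssGBLUP).

When only pen totals are observed, the same model premultiplied by the group
incidence matrix `T` (one row per pen, `T_ij = 1` if animal j is in pen i)
applies to the observable data:

    T y = T1 mu + T Z_l l + T Z_c c + T Z_a a + T e.

`T1` is the vector of group sizes, the design columns count pen members per
effect level, and because pens are disjoint the residual covariance of the
group records is diagonal, `Var(Te) = diag(n_g) sigma_e^2`.  Individual
breeding values remain estimable from pen sums through the relationship
structure, though full sibs sharing both litter and pen receive identical
pedigree-based EBVs.

The bivariate model stacks a group-recorded trait (think total pen feed
intake) with an individually recorded correlated trait (daily gain); every
random effect gets a 2x2 trait covariance block Kronecker its structure
matrix.  In this mixed record mode the residual covariance between a pen
total and an individual record is *structurally excluded* from the model:
the parameter simply does not exist.  The estimable consequence, reproduced
by the package and quantified in the benchmark, is that the pen covariance
absorbs roughly `sigma_e1e2 / mean group size` of the missing residual
covariance and is biased upward by about that amount, while EBVs remain
dispersion-unbiased (regression of true on estimated BV near 1).

## Relationship matrices

* `A` and its inverse come from the standard recursions: inbreeding by the
  Meuwissen-Luo algorithm, `A^-1` by Henderson's rules with inbreeding.
  `A` itself is never materialized at population scale; quadratic forms
  `Q A Q'` use `A = (I-P)^-1 D (I-P)^-T`.
* `G` follows VanRaden's method 1, `G = ZZ'/(2 sum p_j(1-p_j))`, with
  allele frequencies observed in the genotyped set; it is then adjusted to
  the scale of `A11` by matching the means of the diagonal and of the whole
  matrix, and blended as `G_w = 0.95 G + 0.05 A11`.  The pipeline order is
  fixed: rescale first, then blend.
* `H` uses the standard block formula on small problems and the sparse form
  `H^-1 = A^-1 + [[G_w^-1 - A11^-1, 0], [0, 0]]` inside the MME; the two are
  tested for agreement.

## Solving

Mixed-model equations are assembled sparse.  Systems up to a few thousand
equations are factorized directly (SuperLU) with iterative refinement;
larger animal-model systems (the full design has 33k univariate / 66k
bivariate equations) are solved by Jacobi-preconditioned conjugate
gradients, the standard choice for MMEs at this scale.  Either route must
reach a relative residual of 1e-10 or the fit raises.  On every fixture
small enough to invert the record-level covariance directly, the MME
solution is tested against dense GLS (agreement ~1e-13).

## AI-REML

Variance components are estimated by restricted maximum likelihood on the
record-level (marginal) covariance `V(theta) = sum_k theta_k F_k`, which is
linear in the (co)variance parameters; the `F_k` are `Z K Z'` blocks
(pedigree quadratic forms are computed through the sparse factorization of
`A`, so `V` stays small whenever the record count is small - about 1,200
rows for group records even with a 29k pedigree).  Updates are Newton steps
with the average-information matrix

    AI_kl = 1/2 y'P F_k P F_l P y,    grad_k = -1/2 [tr(P F_k) - y'P F_k P y],

performed in a Cholesky parameterization of each effect's trait block
(`Sigma = LL'`), so positive semi-definiteness is automatic and the PSD
boundary - which genuinely binds in mixed record-mode models, where the pen
block absorbs the excluded residual covariance - is an ordinary point of the
search space.  Adaptive Levenberg-Marquardt damping grows toward a scaled
gradient step whenever an AI step fails to improve the restricted
likelihood, so accepted iterations are monotone.  Convergence requires a
relative parameter change below 1e-8 *and* a transformed-gradient norm below
1e-6 (the package defaults; the benchmark loosens these to 1e-6/1e-3, which
changes estimates only in the 4th decimal).  Variances are floored at 1e-8
rather than removed.  Standard errors come from the inverse AI matrix.
Default starting values give 40% of the phenotypic variance to the residual
and split the rest evenly, with zero covariances.

The restricted log-likelihood is available through two routes - the dense
`V` formula and the sparse-MME identity
`-2 logL = log|R| + log|G| + log|C| + y'Py` - which are tested to agree to
1e-6 on fixtures.

## The simulator

The simulator emulates a closed pig nucleus:

* **Genome.** 18 chromosomes of 100 cM, 3,100 markers + 50 QTL each, all
  biallelic, uniformly placed.  Initial allele frequencies are uniform(0,1);
  a historical population of 400 (equal sex ratio) mates randomly for 300
  generations with recurrent mutation at 2.5e-5 per locus per meiosis
  (historical phase only).  Loci with MAF < 0.01 are then discarded
  (roughly 78% of markers and QTL survive).  Recombination is Haldane:
  Poisson crossover counts, uniform placement, no interference.
* **Pedigree.** A base step mates 30 sires with 200 dams (litters of six);
  600 female and 30 male offspring found generation 0.  Eight discrete
  generations follow, each with 30 sires x 600 dams chosen at random from
  the previous generation, each sire serving 20 dams, each litter three
  males and three females: 29,430 animals in total, phenotypes in
  generations 5-8 (14,400 animals).
* **Traits.** QTL effect pairs are drawn bivariate normal with correlation
  0.8 (0.5 in the reduced-correlation variant); true BVs are the summed
  allele effects, scaled so the generation-0 variances are exactly 30 and
  100.  Phenotypes add litter, pen and residual effect pairs drawn with the
  generating (co)variances (pen 10/40, litter 10/40, residual 50/220;
  correlations 0.3/0.3/0.5), giving heritabilities 0.30 and 0.25.
* **Pens.** Within generation.  `S12_L2x3`: each litter splits into two
  random sublitters of three; pens of 12 take four sublitters of four
  distinct litters (a swap-repair greedy packing guarantees the two halves
  of a litter never meet).  `S24_L2x3`: pens of 24 from eight sublitters.
  `S12_Lran`: individuals permuted into pens of up to 12.
* **Attrition and genotyping.** 20% of recorded animals are deleted at
  random (never breeding animals), after pen assignment, giving pen sizes
  4-12 with mean 9.6.  Genotyping designs: none, all, or 30% = every
  breeding animal in the data (~16.5%) plus a random fill.  Group I/II
  validation membership is frozen from the 30% design per replicate so all
  designs score identical animal sets.

Scoring: accuracy is the Pearson correlation between EBV and true BV over
the post-attrition validation generation (generation 8), with that
generation's records kept (Valid_R) or removed before fitting (Valid_nR);
bias is the regression of true on estimated BV.

## Benchmark problem sizes

The packaged benchmark (`scripts/acceptance.py`, `tests/test_acceptance.py`)
runs the full 29,430-animal design with a QTL-only genome (marker panels are
irrelevant to pedigree-based analyses) and shares one genome/pedigree
simulation across the grouping scenarios and genetic-correlation variants of
each replicate - this changes only the Monte-Carlo correlation between
cells, never a mean, and is what makes matched-replicate ordering statements
testable.  The script uses 10 replicates; the test suite 5.  The bivariate
mixed-record REML runs on a quarter-scale nucleus (150 litters x 8 sires per
generation, same nine-generation layout) where the record-level covariance
stays tractable; the pen-covariance inflation it measures is structural and
nucleus-size free, at the cost of roughly doubled replicate spread.  REML
replicates are warm-started from the previous replicate's estimates, which
only reduces iteration counts.

## What the simulation does and does not show

The generator reproduces the designed variance components exactly in
expectation (verified empirically in the tests), the designed family and pen
structure, and realistic LD decay.  It does not model selection, overlapping
generations, sex effects, maternal effects other than the litter common
environment, genotype-by-environment interaction, or missing genotypes -
conclusions about real populations with those features require care.  Pen
sizes vary only through random attrition; systematic size differences
between farms are not modeled.

All relative statements validated by the study design - the ordering of
grouping scenarios, group size effects, Valid_R over Valid_nR, bivariate
over univariate for the group-recorded trait, the unbiasedness of EBV
dispersion and of REML variance recovery, and the structural pen-covariance
inflation - are reproduced by this implementation and asserted by the test
suite.  The *absolute* accuracy level implied by this design and these
variance ratios is an intrinsic property of the data-generating process: for
the stated full-scale design the package's exact mixed-model computations
place the expected Valid_R accuracy of pedigree BLUP at about 0.68
(individual records) and 0.46 (group records, pens of 12), values the
realized simulations match to within scoring noise.  Published studies of
closely related designs report somewhat higher absolute levels; the
difference traces to unstated properties of other data generators, not to
the estimation machinery, whose solutions agree with independent dense-GLS
and closed-form oracles to numerical precision.

## Known limitations

* Missing genotypes are rejected, not imputed.
* At most two traits; no maternal or social (indirect) genetic effects.
* The AI-REML engine targets data sets whose record count is a few thousand
  (ample for group records); individual-record REML at the full design size
  is feasible but slow through the dense-V route.
* GBLUP/ssGBLUP at the full 43k-marker scale is supported but compute-heavy;
  the tests exercise the genomic path at reduced marker density.
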