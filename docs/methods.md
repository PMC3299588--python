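# Methods

`gsrelate` studies a single question: how much of the accuracy of genomic
breeding-value prediction (gBLUP) comes from close relatives in the
reference population, and how much from population-wide linkage
disequilibrium that pedigree-based BLUP cannot see.  Everything in the
package serves a replicated simulation experiment that compares gBLUP with
shallow- and deep-pedigree BLUP for test animals at three levels of
relatedness to a fixed-size reference set.

## Genetic simulation

**Base haplotypes.** Each of 30 autosomes (1e8 bp, 100 cM at a uniform
1 cM/Mb map) is simulated independently under a neutral coalescent with
recombination (msprime) at constant diploid effective size Ne = 100, with
an infinite-sites binary mutation model at 2.5e-8 per bp per generation and
recombination at 1e-8 per bp.  Every site is biallelic and segregating in
the sample.  The sample size is 2 × (number of founders): the breeding
structure below needs 80 male + 2,000 female founders, hence 4,160
haplotypes.  Segregating-site counts are validated against the Watterson
expectation `4 Ne mu L sum_{i<n} 1/i` in the test suite; LD is checked to
decay with genetic distance.

**Trait architecture.** 60,000 marker and 10,000 QTL sites are drawn
uniformly, disjointly, without replacement from all segregating sites — no
MAF ascertainment, so the marker frequency spectrum is the neutral SFS.
QTL effect magnitudes are Gamma(shape 0.4, scale 1.66), sign ±1 with equal
probability.  True breeding values are `TBV_k = sum_j beta_j Q_kj` with
dosages Q in {0,1,2}.

**Breeding population.** Founders receive two panel haplotypes each,
without replacement.  Ten discrete generations follow: 80 sires × 25 dams
× 2 offspring = 4,000 animals per generation, half male and half female,
mating entirely at random (no selection).  Each dam is used once, so
maternal half sibs do not exist and paternal half-sib families have 50
members.  Gametes recombine as a Poisson process with one expected
crossover per Morgan, positions uniform on the genetic map, start strand
random per chromosome, no interference.

**Phenotypes.** `y = TBV + e`, `e ~ N(0, sigma_e^2)` with
`sigma_e^2 = var(TBV_base) (1 - h2)/h2` at h2 = 0.3.  The environmental
variance is frozen from the base generation so drift in later generations
cannot silently rescale the trait.  Phenotypes are generated for all
animals but only reference-set phenotypes ever enter a model fit; test-set
phenotypes are never used.

## Reference/test designs

All designs use 1,750 reference and 250 disjoint test animals.

* **close** — reference and test both from generation 10; family
  accounting guarantees every test animal exactly 20 paternal half sibs
  (and zero full sibs) in the reference.  With 80 half-sib families of 50,
  75 families host the test animals (20 reference members each), and the
  remaining families fill the reference to 1,750.
* **distant** — test animals come from whole sire families disjoint from
  the reference families, so no test animal shares a parent with any
  reference animal; cousin-level and deeper background links remain
  (they arise through the previous generations' shared breeders).
* **unrelated** — the reference is generation-1 females, the test set
  generation 10: nine generations of separation leave a mean pedigree
  relationship of ~0.003.  Because all 2,000 generation-1 females breed,
  complete exclusion of test lineages is impossible; the residual
  relatedness is part of the scenario.

## Estimation

The single-trait animal model is `y = 1 mu + Z g + e`, `var(g) = K
sigma_g^2`, with K one of:

* gBLUP — VanRaden (method 1) GRM from the markers,
  `G = WW'/(2 sum p_i(1-p_i))`, with **base-generation** allele
  frequencies in simulations so that `E[G]` matches the pedigree
  expectation (observed frequencies are the default for user data);
* BLUP-D — numerator relationship matrix from the full ten-generation
  pedigree;
* BLUP-S — NRM from the pedigree truncated to a single generation.

The NRM is computed by the tabular method.  For the ~42,000-animal deep
pedigree the required sub-blocks are obtained by an exact layered
recurrence over generations (relationships of a new cohort follow from the
parent cohort's matrix), which keeps memory at the size of the largest
active layer; it is cross-validated against the tabular method and an
independent recursive-coancestry oracle.

**REML.** Variance components are re-estimated per design and method from
the reference animals only.  The restricted likelihood of the
one-random-effect model is profiled to the ratio sigma_g^2/sigma_e^2 using
the spectral decomposition of the projected relationship matrix, and
maximized by a bounded scalar search on the log ratio (grid bracketing +
Brent, tolerance 1e-6).  This evaluates the exact restricted likelihood —
the same estimand iterative EM/AI-REML schemes converge to — at one
eigendecomposition per fit.  A flat likelihood (e.g. K = I for the
shallow-pedigree unrelated design, where only the total variance is
identified) is flagged; the fit still yields exactly zero EBVs for
unrelated test animals, which is the scientifically relevant output.

**MME.** Henderson's equations are solved by dense Cholesky factorization
with a 1e-6 ridge on K before inversion.  The full inverse coefficient
matrix is formed, giving exact per-animal `C_ii` and
`PEV_i = sigma_e^2 C_ii`.

## Accuracy measures

* `r_cor`: Pearson correlation of EBV with TBV in the test set.  If the
  EBVs are constant (shallow pedigree, unrelated test animals) the
  correlation is reported as 0 — the convention used in the reported
  table.
* `r_pev = sqrt(1 - sigma_e^2 C_ii / (sigma_a^2 K_ii))` per animal.  For
  an animal carrying no information the radicand is exactly 0; the ridge
  can push it to ~-1e-6, so radicands within 1e-4 of zero are clipped
  (with a warning) and anything lower raises.
* Deterministic predictions: the Goddard formula
  `r = sqrt(1 - lambda/(2N sqrt(a)) ln(rho+/rho-))` with `k = 1/ln(2Ne)`,
  `lambda = Me k / h2`, `a = 1 + 2 lambda/N`,
  `rho± = 1 + a ± 2 sqrt(a)`, and the Daetwyler formula
  `r = sqrt(N h2/(N h2 + Me))`.  `lambda = Me k/h2` treats the total
  phenotypic variance as standardized; this evaluation reproduces all
  reported intermediates (k = 0.189, a = 5.31, r = 0.36 for N = 1750,
  Ne = 100, h2 = 0.3, L = 30 Morgans) to printed precision.  Me variants
  2NeL (default), 4NeL and 2NeL/ln(4NeL) are provided; 2NeL is the one
  consistent with the simulated baseline accuracy.

## Scale presets and runtimes

The `paper` preset is the full study: 60k markers, 10k QTL, 10 replicates.
A `desk` preset (15k markers, 2.5k QTL, 3 replicates) exists for quick
exploration; expect close-design gBLUP accuracy to drift downward at
reduced marker density, because within-family Mendelian-sampling terms are
marker-hungry.  The acceptance script runs
the study's ten replicates and the test suite five, both at full marker
density — one replicate (simulation plus all nine design × method fits)
takes ~2 minutes on a single CPU, so the replicated experiment stays
within a desktop budget without reducing density.

## What the generator does and does not emulate

The simulation reproduces the stated population structure exactly (family
sizes, discrete generations, random mating, no selection) and the neutral
LD structure implied by Ne = 100.  It does not emulate: marker
ascertainment bias of real SNP chips (sites are drawn from the neutral
SFS, so many markers are rare), genotyping error or missingness, selection
or assortative mating, overlapping generations, or heterogeneous
sub-populations.  Passing tests therefore demonstrate correctness of the
method chain under the idealized breeding scheme, not performance on field
data.  The SNP QC filter set (call rate, GC score, MAF, heterozygosity,
HWE, location, LD pruning) targets real-chip artefacts and is exercised on
synthetic perturbations in the tests.

## Numerical choices and edge cases

* Replicate and stage seeds are derived from the master seed by labelled
  hashing; adding a pipeline stage never shifts another stage's stream.
* Eigenvalues of the projected K are clipped at 0; the REML search runs on
  log(gamma) in [-14, 14].
* Monomorphic markers are excluded from the GRM numerator and denominator
  with a warning.
* Top-k relationship summaries use all reference animals when the
  reference is smaller than k.
* Pedigrees may arrive in any row order; they are topologically sorted,
  and cycles raise a data error.
* Correlations of groups smaller than two are reported as NaN rather than
  0, to distinguish "undefined" from the zero-variance convention.

## Known limitations

* The layered NRM recurrence requires parents to live in earlier
  topological layers than offspring (true for discrete generations); for
  arbitrary overlapping-generation pedigrees use the tabular method.
* EM-style REML standard errors are not reported; only point estimates and
  the log-likelihood.
* The PEV-based reliability inherits whatever bias the REML variance
  components carry; with family-structured references the estimated
  genetic variance (and hence r_pev) can run slightly high.
* LD pruning in the QC filter is O(m^2) per chromosome; for very dense
  user panels pre-thin or raise the r^2 cutoff.
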