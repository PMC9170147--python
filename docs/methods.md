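# Methods

This note records the models implemented in `landracegp`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and
the numerical choices that affect results.

## Allele coding and genome representation

All genotypes are coded as counts of the capture-line allele (0/1/2;
gametes 0/1), and `p` always denotes that allele's frequency in the
ancestral landrace. This single orientation convention makes the
closed-form expectations direct (the capture line is the all-ones genome)
and gives signed LD a consistent orientation across populations, which the
linkage-phase-similarity statistic requires. Re-orienting a locus maps
`(p, a) → (1−p, −a)` and leaves every variance formula invariant, so the
convention costs no generality.

Maps carry bp and cM per marker; cM is proportional to bp at 1 cM/Mb by
default (configurable per chromosome via the map constructor arguments).
Defaults of 10 chromosomes × 150 cM produce a maize-like genome.

## The ancestral landrace and its LD

The landrace is a finite pool of phased gametes. Founder haplotypes are
drawn locus-independently with frequencies from a Beta(0.5, 0.5) spectrum
truncated to [0.02, 0.98] — the U-shape typical of allele-frequency spectra
in old open-pollinated populations — then the pool undergoes random mating
with recombination for a burn-in (default 20 generations at pool size 400
gametes). Drift in the finite pool builds within-chromosome LD of order
`1/(1+4Nc)` while leaving cross-chromosome LD at the sampling floor, and
random mating keeps genotype frequencies at Hardy–Weinberg proportions.
This is deliberately not a coalescent or demographic model: it is the
simplest generator that yields HWE plus decaying LD with a controllable
strength, which is what the downstream statistics (decay fits, LPS,
GBLUP) need to be exercised against. No mutation, selection or
demographic history is modelled, and markers are strictly biallelic.

The capture line is constructed from the pool: a chosen fraction of
markers (default 3%, matching the order observed for real capture lines)
is made private — the pool fixed for allele 0, the capture line carrying
allele 1 — and at all other markers the capture allele is drawn
Bernoulli(p) by default, i.e. the capture line looks like a random DH line
from the landrace ("major"/"minor" rules are available). Marker codes are
then flipped so the capture line is all-ones and `p` re-expressed.

## Meiosis

Crossover counts per chromosome are Poisson with mean equal to the map
length in Morgans; breakpoints are uniform on the cM scale; chromosomes
assort independently; there is no interference. Consequently
recombination fractions follow the Haldane map function exactly, which the
tests verify by simulation. A zero-length chromosome degenerates to
transmitting a random whole strand.

## Population derivation

- DH lines: one random gamete (directly from the pool, or via meiosis from
  sampled plants) duplicated into both slots.
- GC: each S0 plant is (capture gamete, random landrace gamete) — all S0
  are half-sibs sharing the capture gamete. Each S0 is selfed and exactly
  one S1 plant per family is kept, mirroring the one-plant-per-ear design;
  multiple S1 per family are available for variance-decomposition
  experiments via `self_progeny`.
- GC-S1:2 entries: the genotyped unit is the S1 plant; the field entry
  value is the S2-family mean. `true_entry_values` computes that mean
  analytically (expectation over selfing the S1 genotype) by default, or
  from a simulated S2 family of configurable size. The analytic route
  removes Monte-Carlo noise without changing the expectation.
- Testcrosses: the tester is a haploid genome of a fully homozygous line.
  Expected testcross values are computed analytically (the testcross value
  is linear in the entry's allele dosage); a sampling mode
  (`make_testcross`) exists for realism checks.

## Genotypic values and the expectation table

Per QTL the per se (PP) values are `−a`, `Δ/2 + d_het`, `a + Δ` for doses
0/1/2, summed over QTL around an intercept. `Δ` (the capture-allele effect
deviation) is free only at private loci; at loci where the capture allele
segregates in the landrace it is structurally 0 and the heterozygote
dominance is the landrace `d12`. The genotype class pairing a landrace A1
with a *novel* capture allele (dominance `d1x`) would require a third
allele at one SNP; with biallelic markers it cannot occur, so `d1x` is
carried in the closed forms but is always 0 in simulated architectures and
`[d*]` reduces to `(1−p)·d2x`.

Testcross (TP) values are computed mechanistically: the hybrid carries the
tester allele plus one entry gamete, hybrid heterozygotes take a
tester-specific dominance deviation, and the entry's TP value is the
expectation over its gametes. The classical TP columns of the expectation
table (no dominance parameters; the allele-substitution effect on the
tester background playing the role of `2a`) then *follow* rather than
being hard-coded; the enumeration tests confirm every cell.

`expected_population_stats` evaluates the coefficient table by summing
per-locus closed forms over QTL. This is exact under linkage equilibrium
between QTL; with linked QTL the sums ignore covariance terms and the
report sets `linked_qtl=True` (QTL pairs closer than 50 cM). Note the
table's variance cells are the *additive* components: with dominance
present, segregating generations (LS per se, GC-S1:2 per se) additionally
carry dominance variance. The tests therefore check means for arbitrary
dominance and variance cells under additivity (inbred rows stay exact for
any dominance).

The two threshold frequencies — where GC and LS/DH molecular variances
cross (1/3) and where GC and DH genetic variances cross for a
shared-allele capture locus (1/6) — are solved by root bracketing to 1e−9
rather than hard-coded.

## Diversity statistics

- Genetic distance is 1 − simple matching with allele-sharing scores
  (1 / 0.5 / 0 per locus), i.e. `mean(|d₁−d₂|)/2` on dosages. This
  convention reproduces the expected F2-to-parent distance of 0.5 used as
  the GC-to-capture-line benchmark.
- The polymorphism census resamples gametes without replacement (defaults
  80 gametes, 500 replicates) and reports mean ± SD counts for every Venn
  region plus the GC-private polymorphisms attributable to the capture
  line.
- AMOVA partitions squared Euclidean distances on gamete allele indicators
  into between- and within-individual components by the method of moments;
  negative between-components are truncated at zero and flagged.
- LD is the signed correlation of allele indicators across gametes
  (default pairs within 1 Mb); the decay fit minimizes unweighted squared
  error of the drift-recombination expected-r² curve with the
  finite-sample term in the number of gametes, with the single per-bp
  coefficient optimized on a log scale; the decay distance δ (curve = 0.2)
  is solved by bracketing and reported in kb, flagged undefined if the
  curve never crosses the threshold within 10× the data range.
- LPS defaults to the proportion of marker pairs with the same sign of r
  in both populations per 10-kb bin up to 1 Mb (half-open bins); a
  correlation-of-signed-r mode is provided since different conventions
  circulate. Empty bins carry NaN.

## Field trials and REML

Phenotypes are `value = g + env + g×env + ε` in a balanced E-environment,
R-replicate design (defaults E=4, R=2, matching a typical per se
evaluation; the lattice/incomplete-block bookkeeping of real trials is
experimental logistics and is deliberately not simulated — one complete
block per replicate). When a target entry-mean heritability is given, the
nuisance variances are back-solved with the convention
`σ²_ε = 2σ²_g×e`. Environment main effects are fixed; genotype and g×e
variances are estimated per population (populations are independent).

Balanced data are fitted by the closed-form expected-mean-squares solution
(identical to REML at interior estimates; negative components truncated at
zero and flagged), with SEs from `Var(MS) = 2MS²/df`. Unbalanced data go
through iterative REML (Nelder–Mead on log-variances, restricted
likelihood via Cholesky, convergence flagged; SEs from the numerical
Hessian). BLUEs come from the fixed-genotype least-squares refit with
environment effects averaged out. Entry-mean heritability uses
`h² = σ²_g / (σ²_g + σ²_g×e/E + σ²_ε/(ER))` with a delta-method SE, and
the significance convention is estimate > 2·SE. The PP–TP genetic
correlation is the correlation of BLUEs, optionally attenuation-corrected
by `1/√(h²_PP·h²_TP)` and clipped to [−1, 1] — a deliberate simplification
of a bivariate REML covariance model, which is out of scope.

An optional automated outlier rule (|studentized residual| > 4 against the
additive entry+environment fit → plot dropped) stands in for manual
residual-plot curation; it is off by default.

## GBLUP and cross-validation

The relationship matrix is VanRaden method 1,
`U = WW′ / (2Σp_j(1−p_j))` with `W` the column-centred dose matrix;
frequencies default to the combined entry set (all genotypes treated as
one population), monomorphic columns are dropped. REML for
`y = 1μ + u + e`, `u ~ N(0, Uσ²_g)` is profiled over the variance ratio on
the spectrum of U (one eigendecomposition per training set, then 1-D
bounded optimization of the restricted likelihood on log₁₀γ ∈ [−8, 8] to
1e−10), with an explicit boundary check at σ²_g = 0. The significance of
σ²_g uses the likelihood-ratio test against the variance-free null with a
plain χ²₁ reference (the boundary-corrected ½χ²₀:½χ²₁ mixture is available
as `lrt_pvalue_boundary`). Unphenotyped entries are predicted as
`û = U[pred,train](U[train,train] + λI)⁻¹(y − μ̂)`; equivalence with ridge
regression on centred markers and with the joint mixed-model equations is
tested to 1e−6.

Prediction accuracy is `ρ = cor(observed, predicted)/√h²` with the
population-level entry-mean h² applied to all prediction sets of that
population (per-fold re-estimation would be an alternative; the
population-level value is the stable default). ρ can exceed 1 by sampling
noise and is not clipped. Replicates whose fit does not converge, or whose
predictions are constant (σ²_g at the zero boundary), are recorded as
missing, never dropped; non-significant genomic variance (LRT P > 0.05) is
flagged per replicate. The CV engine implements within-population
10×5-fold CV under entry (N) or marker (M) subsampling, across-population
and across-landrace prediction with disjoint train/prediction samples
(defaults 200/50 per se, 75/25 testcross, 100 sampling replicates), and
pooled-training prediction with within-population baselines. Under a pure
null, k-fold CV correlations carry a small negative bias (predictions
shrink toward the training mean); this is a property of the estimator, not
an implementation artifact.

## What the synthetic data do not show

The generator produces idealized data: truth-phased gametes (no phasing or
imputation error), no genotyping error or missingness (the QC filter is
exercised on constructed tables), no population admixture or structure in
the landrace beyond drift, no genetic load or segregation distortion, no
epistasis, and Gaussian trial effects. Passing tests therefore demonstrate
the correctness of the estimators and the internal consistency of theory
and simulation — not robustness to the artifacts of real array data.
Real genotype/phenotype tables can be ingested through the same readers
(phased VCF, dosage CSV, long-format trial CSV), but no result in this
package depends on external data.

## Problem sizes and reproducibility

Default study and validation sizes are desk-scale (hundreds of entries,
10³–10⁴ markers, tens of replicates), chosen so each theoretical check has
Monte-Carlo error well inside its stated tolerance — e.g. the DH/landrace
variance-doubling ratio uses 200 QTL × 2,000 DH × 20 replicates for a
standard error around 0.015 against a ±0.05 band. Every stochastic
function takes an explicit seed or numpy Generator; study runs spawn all
stage seeds from one master `SeedSequence`, so identical configs are
byte-identical.
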