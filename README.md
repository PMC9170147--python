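# landracegp

Quantitative-genetic simulation and genomic evaluation of breeding
populations derived from crop landraces.

Landraces of outcrossing crops such as maize harbor genetic variation that
elite breeding pools lack, but tapping it requires choosing how to sample
gametes from the landrace. `landracegp` models and compares the two
standard strategies:

- the **pure approach** — doubled-haploid (DH) lines produced directly from
  landrace gametes, fully homozygous, carrying twice the additive genetic
  variance of the ancestral landrace;
- the **admixed approach** — *gamete capture* (GC): landrace pollen is
  crossed onto an inbred capture line, so each GC-S0 plant carries one
  capture gamete and one landrace gamete; selfing gives GC-S1 plants and
  their GC-S1:2 field families.

The package simulates the whole pipeline with known truth (genetic maps,
an ancestral gamete pool in Hardy–Weinberg equilibrium with realistic LD, a
capture line with private alleles, meiosis, selfing, testcrosses,
multi-environment field trials) and provides the analysis stack used to
evaluate such populations: closed-form expectations of means and genetic
variances, molecular diversity statistics, REML variance components and
heritability, and GBLUP genomic prediction with cross-validation.

## The model in brief

Markers are coded as counts of the capture-line allele, with `p` the
frequency of that allele in the ancestral landrace. Per locus, with
additive effect `a` (capture-line deviation `Δ`) and dominance `d`:

- additive variance of the landrace: `σ²_A = 2p(1−p)a²`
- additive variance from capture alleles: `σ²_A* = 2((1−p)a + Δ/2)²`
- cumulative dominance contributions: `[d] = 2p(1−p)d₁₂`,
  `[d*] = p·d₁ₓ + (1−p)·d₂ₓ`

Population means and variances follow from a coefficient table (e.g. DH
total variance `2σ²_A`; GC-S1:2 between-family variance
`¾σ²_A + ¼σ²_A*`), all verified in the test suite against exact
single-locus enumeration. Two consequences worth knowing:

- molecular variance: `ς²_GC-S1 = 0.5(1+p)(1−p)` exceeds
  `ς²_LS = ς²_DH = 2p(1−p)` iff `p ≤ 1/3`;
- genetic variance: when the capture line carries a landrace allele, the GC
  variance exceeds the DH variance only for `p ≤ 1/6`.

Genomic prediction uses GBLUP, `y = 1μ + Zu + e` with
`u ~ N(0, U σ²_g)` and the VanRaden method-1 relationship matrix `U`, fitted
by spectral REML; prediction accuracy is reported as
`ρ = cor(y, û) / √h²` with the entry-mean heritability
`h² = σ²_g / (σ²_g + σ²_g×e/E + σ²_ε/(E·R))`.

## Worked example

```python
import numpy as np
import landracegp as lg

# frequency thresholds for when gamete capture beats the pure approach
p_mol, p_gen = lg.variance_thresholds()
print(f"GC molecular variance exceeds LS/DH below p = {p_mol:.4f}")
print(f"GC genetic variance exceeds DH below p = {p_gen:.4f}")

# a maize-like landrace with LD, a capture line with 3% private alleles
gmap = lg.make_genetic_map(10, 100, chrom_length_cm=150, chrom_length_bp=150e6, seed=1)
pool = lg.simulate_ancestral_pool(gmap, pool_size=400, burnin_generations=20, seed=2)
capture, pool = lg.make_capture_line(pool, private_fraction=0.03, seed=3)

# the pure and admixed populations
dh = lg.derive_dh(pool, 471, rng=4)
s0, gc = lg.derive_gc(pool, capture, 274, rng=5)
prop = lg.capture_genome_proportion(gc, capture)
print(f"mean capture-genome proportion in GC-S1: {prop.mean():.3f}")

# an additive trait: simulated variances vs closed-form expectations
trait = lg.assign_trait(gmap, pool.p, 200, seed=6, private_loci=capture.private_loci)
rep = lg.expected_population_stats(trait, pool.p)
v_dh = np.var(lg.genotypic_value_pp(dh, trait), ddof=1)
v_gc = np.var(lg.true_entry_values(gc, trait), ddof=1)
print(f"DH variance: simulated {v_dh:.1f}, expected {rep.row('DH', 'PP')['total']:.1f}")
print(f"GC between-family variance: simulated {v_gc:.1f}, "
      f"expected {rep.row('GC_S1_2', 'PP')['primary']:.1f}")
```

prints

```
GC molecular variance exceeds LS/DH below p = 0.3333
GC genetic variance exceeds DH below p = 0.1667
mean capture-genome proportion in GC-S1: 0.507
DH variance: simulated 101.3, expected 106.5
GC between-family variance: simulated 46.7, expected 55.0
```

The thresholds are the two crossing frequencies solved numerically; the
GC-S1 plants carry on average half capture-line genome, as the half-sib
design dictates. Simulated variances track the closed forms; the residual
gap reflects finite samples (471 DH, 274 GC families) and linkage between
QTL, under which the locus-wise sums are approximate —
`rep.linked_qtl` flags this.

An end-to-end synthetic study (populations → diversity statistics → trials
→ REML → GBLUP cross-validation, with all tables written as CSV) runs via

```python
from landracegp.study import StudyConfig, run_study
run_study(StudyConfig(seed=1), "study_out")
```

or from the shell: `landracegp run-study --outdir study_out`. The CLI also
exposes `landracegp thresholds`, `landracegp simulate` (VCF + map output)
and `landracegp qc` (missingness/heterozygosity filtering).

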