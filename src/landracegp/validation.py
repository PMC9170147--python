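"""Standard validation experiments: simulation vs closed-form theory.

Each function runs a self-contained synthetic experiment that checks one of
the package's central theoretical predictions and returns the simulated
quantity (whose theoretical value is stated in the docstring).  They are
used by the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import diversity, genome, populations, traits
from .genome import CaptureLine, GametePool

__all__ = [
    "dh_variance_doubling_ratio",
    "gc_capture_distance_on_diagnostic_loci",
    "gc_private_locus_molecular_variance",
    "random_dh_capture_variance_ratio",
]


def _hwe_pool(p: np.ndarray, pool_size: int, gmap, rng) -> GametePool:
    gam = (rng.random((pool_size, len(p))) < p).astype(np.uint8)
    return GametePool(gametes=gam, gmap=gmap)


def dh_variance_doubling_ratio(
    seed: int, n_qtl: int = 200, n_dh: int = 2000, n_reps: int = 20, pool_size: int = 4000
) -> float:
    """Additive variance among DH lines over the landrace additive variance.

    An HWE landrace with unlinked QTL (frequencies uniform on [0.05, 0.95])
    and a purely additive trait; DH lines are doubled random gametes.  The
    expected ratio is 2: doubling a gamete doubles the allele-substitution
    variance.  Returns the ratio averaged over ``n_reps`` seeded replicates.
    """
    ss = np.random.SeedSequence(seed).spawn(n_reps)
    gmap = genome.make_genetic_map(1, n_qtl, 100.0, 100e6, seed=seed)
    ratios = []
    for child in ss:
        rng = np.random.default_rng(child)
        p = rng.uniform(0.05, 0.95, n_qtl)
        pool = _hwe_pool(p, pool_size, gmap, rng)
        trait = traits.assign_trait(gmap, pool.p, n_qtl, seed=rng.integers(2**31))
        dh = populations.derive_dh(pool, n_dh, rng)
        var_dh = float(np.var(traits.genotypic_value_pp(dh, trait), ddof=1))
        sigma2_a = traits.expected_population_stats(trait, pool.p).components["PP"]["sigma2_A"]
        ratios.append(var_dh / sigma2_a)
    return float(np.mean(ratios))


def gc_capture_distance_on_diagnostic_loci(
    seed: int, n_lines: int = 500, n_loci: int = 1000, n_chrom: int = 10
) -> float:
    """Mean genetic distance of GC-S1 lines to the capture line at loci where
    the landrace is fixed for the non-capture allele.  Expected 0.5: the S0 is
    fully heterozygous there, so its selfed progeny behave like an F2 whose
    allele-sharing distance to a parent averages (2*(1/4) + 1*(1/2)) / 2 = 0.5.
    Loci are spread over a 10-chromosome maize-like map so that line-level
    distances average over many independently segregating blocks.
    """
    rng = np.random.default_rng(seed)
    gmap = genome.make_genetic_map(n_chrom, n_loci // n_chrom, 150.0, 150e6, seed=seed)
    n_loci = gmap.n_markers
    pool = GametePool(gametes=np.zeros((200, n_loci), dtype=np.uint8), gmap=gmap)
    capture = CaptureLine(genome=np.ones(n_loci, dtype=np.uint8), private_loci=np.arange(n_loci))
    _, s1 = populations.derive_gc(pool, capture, n_lines, rng)
    cap_dose = 2.0 * np.ones(n_loci)
    dose = s1.dosage()
    gds = [diversity.genetic_distance(dose[i], cap_dose) for i in range(n_lines)]
    return float(np.mean(gds))


def gc_private_locus_molecular_variance(
    seed: int, n_lines: int = 1000, n_loci: int = 500, n_reps: int = 10
) -> float:
    """Mean per-locus molecular variance 2f(1-f) in GC-S1 at loci with
    ancestral capture-allele frequency p=0.  Expected 0.5(1+p)(1-p) = 0.5.
    """
    ss = np.random.SeedSequence(seed).spawn(n_reps)
    gmap = genome.make_genetic_map(1, n_loci, 150.0, 150e6, seed=seed)
    vals = []
    for child in ss:
        rng = np.random.default_rng(child)
        pool = GametePool(gametes=np.zeros((200, n_loci), dtype=np.uint8), gmap=gmap)
        capture = CaptureLine(
            genome=np.ones(n_loci, dtype=np.uint8), private_loci=np.arange(n_loci)
        )
        _, s1 = populations.derive_gc(pool, capture, n_lines, rng)
        mv = diversity.molecular_variance(s1)
        vals.append(float(mv.per_locus.mean()))
    return float(np.mean(vals))


def random_dh_capture_variance_ratio(
    seed: int,
    n_qtl: int = 200,
    n_lines: int = 1000,
    n_reps: int = 20,
    pool_size: int = 2000,
    n_chrom: int = 10,
) -> float:
    """Between-family GC-S1:2 variance over DH variance when the capture line
    is a random DH from the ancestral landrace.

    With sigma2_A* = sigma2_A in expectation (the capture allele is drawn
    with the landrace frequencies), the GC primary variance is
    (3/4 + 1/4) sigma2_A against 2 sigma2_A among DH: expected ratio 0.5.
    QTL are spread over ``n_chrom`` chromosomes to keep linkage weak.
    """
    ss = np.random.SeedSequence(seed).spawn(n_reps)
    gmap = genome.make_genetic_map(n_chrom, n_qtl // n_chrom, 150.0, 150e6, seed=seed)
    m = gmap.n_markers
    ratios = []
    for child in ss:
        rng = np.random.default_rng(child)
        p = rng.uniform(0.05, 0.95, m)
        pool = _hwe_pool(p, pool_size, gmap, rng)
        capture, pool = genome.make_capture_line(
            pool, private_fraction=0.0, private_locus_rule="random_gamete",
            seed=rng.integers(2**31),
        )
        trait = traits.assign_trait(gmap, pool.p, m, seed=rng.integers(2**31))
        dh = populations.derive_dh(pool, n_lines, rng)
        _, s1 = populations.derive_gc(pool, capture, n_lines, rng)
        var_dh = float(np.var(traits.genotypic_value_pp(dh, trait), ddof=1))
        entry_vals = traits.true_entry_values(s1, trait, level="PP")
        var_gc = float(np.var(entry_vals, ddof=1))
        ratios.append(var_gc / var_dh)
    return float(np.mean(ratios))
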