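"""Deriving populations from the landrace: DH lines, gamete capture, testcrosses.

Two sampling strategies are modelled.  The *pure* approach doubles random
landrace gametes into fully homozygous DH lines.  The *admixed* approach
("gamete capture") crosses landrace pollen onto an inbred capture line:
every GC-S0 plant carries one capture gamete and one landrace gamete (the
S0 plants are half-sibs), is selfed to give one genotyped GC-S1 plant per
family, whose selfed progeny (the S2 family, grown ear-to-row) represents
the GC-S1:2 entry in field trials.

Meiosis uses a no-interference (Poisson) crossover model on the cM scale,
so recombination fractions follow the Haldane map function.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import CaptureLine, GametePool, GeneticMap

__all__ = [
    "PopType",
    "Population",
    "meiosis",
    "derive_dh",
    "derive_gc",
    "self_progeny",
    "make_testcross",
    "capture_genome_proportion",
]


class PopType(str, enum.Enum):
    LS = "LS"
    DH = "DH"
    GC_S0 = "GC_S0"
    GC_S1 = "GC_S1"
    GC_S1_2 = "GC_S1_2"
    TESTCROSS = "TESTCROSS"


@dataclass
class Population:
    """A set of diploid individuals, each two phased gametes over a map."""

    gamete_a: np.ndarray  # (n, m) uint8
    gamete_b: np.ndarray  # (n, m) uint8
    ptype: PopType
    gmap: GeneticMap
    family: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gamete_a.shape != self.gamete_b.shape:
            raise ValueError("gamete matrices must have equal shape")
        if self.gamete_a.shape[1] != self.gmap.n_markers:
            raise ValueError("gamete matrix does not match the map")
        if self.family is None:
            self.family = np.arange(self.n)
        if self.ptype == PopType.DH and not np.array_equal(self.gamete_a, self.gamete_b):
            raise ValueError("DH individuals must have identical gametes")

    @property
    def n(self) -> int:
        return self.gamete_a.shape[0]

    @property
    def n_markers(self) -> int:
        return self.gamete_a.shape[1]

    def dosage(self) -> np.ndarray:
        """0/1/2 counts of the capture-line allele, (n, m) int8."""
        return (self.gamete_a.astype(np.int8) + self.gamete_b.astype(np.int8))

    def gametes(self) -> np.ndarray:
        """All 2n phased gametes stacked (a-gametes then b-gametes)."""
        return np.vstack([self.gamete_a, self.gamete_b])

    def allele_frequencies(self) -> np.ndarray:
        return self.dosage().mean(axis=0) / 2.0

    def subset(self, idx) -> "Population":
        idx = np.asarray(idx)
        return Population(
            gamete_a=self.gamete_a[idx],
            gamete_b=self.gamete_b[idx],
            ptype=self.ptype,
            gmap=self.gmap,
            family=self.family[idx],
        )

    def pedigree_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": np.arange(self.n),
                "type": self.ptype.value,
                "family": self.family,
            }
        )


def _meiose_batch(
    ga: np.ndarray, gb: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete per row of (ga, gb).

    Crossover counts per chromosome are Poisson(length in Morgans),
    breakpoint positions uniform on the cM scale, no interference;
    chromosomes assort independently (fresh random start strand each).
    """
    k, m = ga.shape
    out = np.empty((k, m), dtype=np.uint8)
    for c in gmap.chromosomes:
        sl = gmap.chrom_slice(int(c))
        cm = gmap.pos_cm[sl]
        length_m = gmap.chrom_length_morgan(int(c))
        start = rng.integers(0, 2, size=k)
        n_co = rng.poisson(length_m, size=k)
        strands = np.empty((k, sl.stop - sl.start), dtype=np.uint8)
        for i in range(k):
            if n_co[i] == 0:
                strands[i] = start[i]
            else:
                bp = rng.uniform(cm[0], cm[-1], size=n_co[i])
                crossings = np.searchsorted(np.sort(bp), cm, side="left")
                strands[i] = (start[i] + crossings) % 2
        seg_a = ga[:, sl]
        seg_b = gb[:, sl]
        out[:, sl] = np.where(strands == 0, seg_a, seg_b)
    return out


def meiosis(individual, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """A single recombinant gamete from ``individual = (gamete_a, gamete_b)``."""
    ga, gb = individual
    return _meiose_batch(ga[None, :], gb[None, :], gmap, rng)[0]


def derive_dh(source, n_lines: int, rng, from_plants: bool = False) -> Population:
    """Derive fully homozygous DH lines by doubling random gametes.

    ``source`` is a :class:`GametePool` (default: one random pool gamete per
    line, sampled with replacement) or, with ``from_plants=True``, a
    :class:`Population` of landrace plants each contributing one gamete by
    meiosis.  Either way a DH line is one gamete duplicated into both slots.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = np.random.default_rng(rng)
    if from_plants:
        plants: Population = source
        if plants.n == 0:
            raise ValueError("empty source population")
        idx = rng.integers(0, plants.n, size=n_lines)
        gam = _meiose_batch(plants.gamete_a[idx], plants.gamete_b[idx], plants.gmap, rng)
        gmap = plants.gmap
    else:
        pool: GametePool = source
        if pool.n_gametes == 0:
            raise ValueError("empty gamete pool")
        idx = rng.integers(0, pool.n_gametes, size=n_lines)
        gam = pool.gametes[idx].copy()
        gmap = pool.gmap
    return Population(gamete_a=gam, gamete_b=gam.copy(), ptype=PopType.DH, gmap=gmap)


def derive_gc(
    pool: GametePool,
    capture_line: CaptureLine,
    n_families: int,
    rng,
) -> tuple[Population, Population]:
    """Gamete capture: half-sib GC-S0 plants and one selfed GC-S1 per family.

    Each S0 plant = (capture gamete, random landrace gamete); the S0 plants
    are selfed and exactly one S1 plant per family is kept, mirroring the
    one-genotyped-plant-per-ear design.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, pool.n_gametes, size=n_families)
    cap = np.broadcast_to(capture_line.genome, (n_families, pool.n_markers)).copy()
    s0 = Population(
        gamete_a=cap,
        gamete_b=pool.gametes[idx].copy(),
        ptype=PopType.GC_S0,
        gmap=pool.gmap,
        family=np.arange(n_families),
    )
    s1_a = _meiose_batch(s0.gamete_a, s0.gamete_b, pool.gmap, rng)
    s1_b = _meiose_batch(s0.gamete_a, s0.gamete_b, pool.gmap, rng)
    s1 = Population(
        gamete_a=s1_a,
        gamete_b=s1_b,
        ptype=PopType.GC_S1,
        gmap=pool.gmap,
        family=np.arange(n_families),
    )
    return s0, s1


def self_progeny(
    individual, n_offspring: int, gmap: GeneticMap, rng, ptype: PopType = PopType.GC_S1_2
) -> Population:
    """Selfed offspring of one individual (independent meiosis pairs).

    Used to expand a GC-S1 plant into the S2 family that represents its
    S1:2 entry in the field.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    rng = np.random.default_rng(rng)
    ga, gb = individual
    A = np.broadcast_to(ga, (n_offspring, len(ga)))
    B = np.broadcast_to(gb, (n_offspring, len(ga)))
    off_a = _meiose_batch(A, B, gmap, rng)
    off_b = _meiose_batch(A, B, gmap, rng)
    return Population(gamete_a=off_a, gamete_b=off_b, ptype=ptype, gmap=gmap)


def make_testcross(line: Population, tester: np.ndarray, rng=None) -> Population:
    """Testcross genotypes: one gamete from each entry x the tester gamete.

    ``tester`` is the haploid genome of a fully homozygous tester (0/1
    vector).  For fully inbred entries the sampled gamete is the entry's
    unique gamete, so all testcross plants of an entry are identical.  For
    segregating entries a random gamete is sampled per entry (sampling
    mode); downstream expectations are usually computed analytically via
    :func:`landracegp.traits.genotypic_value_tp` instead.
    """
    tester = np.asarray(tester, dtype=np.uint8)
    if tester.ndim != 1 or tester.shape[0] != line.n_markers:
        raise ValueError("tester must be a haploid genome over the same markers")
    rng = np.random.default_rng(rng)
    gam = _meiose_batch(line.gamete_a, line.gamete_b, line.gmap, rng)
    t = np.broadcast_to(tester, gam.shape).copy()
    return Population(
        gamete_a=gam, gamete_b=t, ptype=PopType.TESTCROSS, gmap=line.gmap, family=line.family
    )


def capture_genome_proportion(
    population: Population, capture_line: CaptureLine, diagnostic_loci=None
) -> np.ndarray:
    """Per-individual proportion of capture-line genome on diagnostic markers.

    Diagnostic markers are those where the ancestral landrace is fixed for
    the non-capture allele (p = 0), so any capture allele there traces to
    the capture line.  Proportion = capture-allele count / (2 x #loci).
    """
    loci = capture_line.private_loci if diagnostic_loci is None else np.asarray(diagnostic_loci)
    if loci.size == 0:
        raise ValueError("empty diagnostic locus set")
    dose = population.dosage()[:, loci]
    return dose.sum(axis=1) / (2.0 * loci.size)
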