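"""Genetic maps and synthetic ancestral-landrace gamete pools.

The simulator emulates an open-pollinated landrace in Hardy-Weinberg
equilibrium: a large pool of phased gametes over a marker map, with a
realistic (by default U-shaped) allele-frequency spectrum and
within-chromosome linkage disequilibrium generated by random mating in a
finite pool.  An inbred *capture line* shares most of its alleles with the
landrace but carries private alleles (frequency 0 in the landrace) at a
controllable fraction of loci.

Allele coding is fixed package-wide as counts of the capture-line allele:
every gamete is a 0/1 vector where 1 is the allele carried by the capture
line, and diploid dosages are 0/1/2.  ``p`` always denotes the frequency of
the capture-line allele in the ancestral landrace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "GametePool",
    "CaptureLine",
    "make_genetic_map",
    "simulate_ancestral_pool",
    "make_capture_line",
    "sample_plants",
]


@dataclass(frozen=True)
class GeneticMap:
    """Marker coordinates in bp and cM, one row per marker.

    Markers are strictly increasing in bp within each chromosome and cM is
    non-decreasing with bp.  Chromosome ids are positive integers.
    """

    chrom: np.ndarray  # int, per marker
    pos_bp: np.ndarray  # int, 1-based
    pos_cm: np.ndarray  # float, >= 0
    marker: np.ndarray  # str ids

    def __post_init__(self) -> None:
        n = len(self.chrom)
        if not (len(self.pos_bp) == len(self.pos_cm) == len(self.marker) == n):
            raise ValueError("map fields must have equal length")
        for c in np.unique(self.chrom):
            sel = self.chrom == c
            bp = self.pos_bp[sel]
            cm = self.pos_cm[sel]
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"bp positions not strictly increasing on chromosome {c}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM positions decrease on chromosome {c}")
            if np.any(cm < 0):
                raise ValueError("negative cM position")

    @property
    def n_markers(self) -> int:
        return len(self.chrom)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chrom)

    def chrom_slice(self, c: int) -> slice:
        """Contiguous marker slice of chromosome ``c`` (markers are stored sorted)."""
        idx = np.flatnonzero(self.chrom == c)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def chrom_length_morgan(self, c: int) -> float:
        cm = self.pos_cm[self.chrom == c]
        return float(cm[-1] - cm[0]) / 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.marker, "chrom": self.chrom, "pos_bp": self.pos_bp, "pos_cm": self.pos_cm}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        df = df.sort_values(["chrom", "pos_bp"], kind="stable")
        return cls(
            chrom=df["chrom"].to_numpy(dtype=np.int64),
            pos_bp=df["pos_bp"].to_numpy(dtype=np.int64),
            pos_cm=df["pos_cm"].to_numpy(dtype=float),
            marker=df["marker"].to_numpy(dtype=object),
        )

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class GametePool:
    """A pool of phased landrace gametes (rows) over the markers of ``gmap``.

    ``p`` is the realized frequency of allele 1 (the capture-line allele once
    a capture line has been attached) in the pool; it is recomputed from the
    gametes, never assumed.
    """

    gametes: np.ndarray  # (n_gametes, n_markers) uint8 in {0,1}
    gmap: GeneticMap
    p: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gametes.ndim != 2 or self.gametes.shape[1] != self.gmap.n_markers:
            raise ValueError("gamete matrix shape does not match the map")
        if self.gametes.shape[0] % 2 != 0:
            raise ValueError("pool size must be even")
        self.gametes = np.asarray(self.gametes, dtype=np.uint8)
        if self.gametes.shape[0] == 0:
            self.p = np.zeros(self.gmap.n_markers)
        else:
            self.p = self.gametes.mean(axis=0)

    @property
    def n_gametes(self) -> int:
        return self.gametes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.gametes.shape[1]

    def refresh_p(self) -> np.ndarray:
        self.p = self.gametes.mean(axis=0)
        return self.p


@dataclass(frozen=True)
class CaptureLine:
    """Fully homozygous inbred capture line, stored as a single gamete.

    Under the package-wide coding the capture line carries allele 1 at every
    marker, so ``genome`` is all-ones after construction; ``private_loci``
    indexes markers where the ancestral landrace is fixed for allele 0.
    """

    genome: np.ndarray  # (n_markers,) uint8
    private_loci: np.ndarray  # int indices

    def __post_init__(self) -> None:
        if not np.all(self.genome == 1):
            raise ValueError("capture line must carry allele 1 at every marker (coding convention)")

    @property
    def n_markers(self) -> int:
        return len(self.genome)


def make_genetic_map(
    n_chrom: int,
    markers_per_chrom: int,
    chrom_length_cm: float = 150.0,
    chrom_length_bp: float = 150e6,
    seed=None,
    placement: str = "uniform",
) -> GeneticMap:
    """Build a genetic map with ``n_chrom`` chromosomes.

    placement="uniform": markers evenly spaced at bp positions
    ``round(i * L / (m+1))`` for i=1..m.  placement="random": bp positions are
    ``m`` distinct uniform draws on [1, L].  cM is proportional to bp
    (``chrom_length_cm`` at ``chrom_length_bp``, i.e. 1 cM/Mb by default).
    """
    if n_chrom <= 0 or markers_per_chrom <= 0:
        raise ValueError("chromosome and marker counts must be positive")
    if chrom_length_cm <= 0 or chrom_length_bp <= 0:
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    chroms, bps, cms, names = [], [], [], []
    L = int(chrom_length_bp)
    for c in range(1, n_chrom + 1):
        if placement == "uniform":
            bp = np.round(np.arange(1, markers_per_chrom + 1) * L / (markers_per_chrom + 1)).astype(np.int64)
            bp = np.maximum(bp, 1)
            # guard against ties on very short chromosomes
            bp = np.maximum.accumulate(bp + np.arange(markers_per_chrom) * 0).astype(np.int64)
            if len(np.unique(bp)) != markers_per_chrom:
                bp = np.arange(1, markers_per_chrom + 1, dtype=np.int64)
        elif placement == "random":
            bp = np.sort(rng.choice(np.arange(1, L + 1), size=markers_per_chrom, replace=False))
        else:
            raise ValueError(f"unknown placement rule {placement!r}")
        cm = bp / chrom_length_bp * chrom_length_cm
        chroms.append(np.full(markers_per_chrom, c, dtype=np.int64))
        bps.append(bp)
        cms.append(cm)
        names.extend(f"chr{c}_m{i+1}" for i in range(markers_per_chrom))
    return GeneticMap(
        chrom=np.concatenate(chroms),
        pos_bp=np.concatenate(bps),
        pos_cm=np.concatenate(cms),
        marker=np.asarray(names, dtype=object),
    )


def draw_allele_frequencies(n_markers: int, rng: np.random.Generator, spec="beta_u") -> np.ndarray:
    """Sampling distribution for ancestral allele frequencies.

    "beta_u" (default): Beta(0.5, 0.5) truncated to [0.02, 0.98] -- the
    U-shaped spectrum typical of landraces.  "uniform": U[0.02, 0.98].
    A (low, high) tuple gives U[low, high].
    """
    if isinstance(spec, tuple):
        lo, hi = spec
        return rng.uniform(lo, hi, size=n_markers)
    if spec == "uniform":
        return rng.uniform(0.02, 0.98, size=n_markers)
    if spec == "beta_u":
        p = rng.beta(0.5, 0.5, size=n_markers)
        return np.clip(p, 0.02, 0.98)
    raise ValueError(f"unknown frequency spectrum {spec!r}")


def simulate_ancestral_pool(
    gmap: GeneticMap,
    pool_size: int,
    freq_spectrum="beta_u",
    burnin_generations: int = 20,
    seed=None,
) -> GametePool:
    """Simulate the ancestral landrace as a finite pool of phased gametes.

    Founder gametes are drawn independently per locus at target frequencies
    (linkage equilibrium), then ``burnin_generations`` of random mating with
    recombination in the finite pool let drift build up within-chromosome LD
    (r2 of order 1/(1+4Nc) at recombination distance c) while LD across
    chromosomes stays negligible.  Loci stay in Hardy-Weinberg proportions
    because mating is random.
    """
    from .populations import _meiose_batch  # local import to avoid a cycle

    if pool_size < 4 or pool_size % 2 != 0:
        raise ValueError("pool_size must be an even number >= 4")
    if burnin_generations < 0:
        raise ValueError("burnin_generations must be >= 0")
    rng = np.random.default_rng(seed)
    p0 = draw_allele_frequencies(gmap.n_markers, rng, freq_spectrum)
    gametes = (rng.random((pool_size, gmap.n_markers)) < p0).astype(np.uint8)
    for _ in range(burnin_generations):
        # random union of gametes into transient diploids, one meiosis each offspring gamete
        perm = rng.permutation(pool_size)
        ga = gametes[perm[0::2]]
        gb = gametes[perm[1::2]]
        parent_idx = rng.integers(0, pool_size // 2, size=pool_size)
        gametes = _meiose_batch(ga[parent_idx], gb[parent_idx], gmap, rng)
    return GametePool(gametes=gametes, gmap=gmap)


def make_capture_line(
    pool: GametePool,
    private_fraction: float = 0.03,
    private_locus_rule: str = "random_gamete",
    seed=None,
) -> tuple[CaptureLine, GametePool]:
    """Create an inbred capture line and re-express the pool in its coding.

    A ``private_fraction`` of markers (chosen at random) is made *private*:
    the pool is fixed for allele 0 there while the capture line carries
    allele 1 (the paper's FV2-like situation: the capture line contributes a
    SNP allele absent from the landrace).  At all other markers the capture
    allele is drawn per ``private_locus_rule``:

    - "random_gamete": Bernoulli(p) per locus, i.e. the capture line looks
      like a random DH line from the ancestral landrace;
    - "major": the more frequent landrace allele;
    - "minor": the less frequent landrace allele.

    Finally the package coding (allele 1 = capture allele) is re-established
    by flipping marker codes where the capture line drew allele 0, and ``p``
    is re-expressed as the frequency of the capture-line allele.
    """
    if not 0.0 <= private_fraction <= 0.2:
        raise ValueError("private_fraction must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    m = pool.n_markers
    n_private = int(round(private_fraction * m))
    private = rng.choice(m, size=n_private, replace=False)
    gametes = pool.gametes.copy()
    gametes[:, private] = 0

    p = gametes.mean(axis=0)
    capture = np.ones(m, dtype=np.uint8)
    nonpriv = np.setdiff1d(np.arange(m), private)
    if private_locus_rule == "random_gamete":
        draw = (rng.random(nonpriv.size) < p[nonpriv]).astype(np.uint8)
    elif private_locus_rule == "major":
        draw = (p[nonpriv] >= 0.5).astype(np.uint8)
    elif private_locus_rule == "minor":
        draw = (p[nonpriv] < 0.5).astype(np.uint8)
    else:
        raise ValueError(f"unknown private_locus_rule {private_locus_rule!r}")
    flip = nonpriv[draw == 0]
    gametes[:, flip] = 1 - gametes[:, flip]
    new_pool = GametePool(gametes=gametes, gmap=pool.gmap)
    line = CaptureLine(genome=capture, private_loci=np.sort(private))
    return line, new_pool


def sample_plants(pool: GametePool, n: int, seed=None):
    """Draw ``n`` diploid landrace plants (LS) as 2n gametes without replacement."""
    from .populations import Population, PopType

    if 2 * n > pool.n_gametes:
        raise ValueError(f"cannot draw {2*n} gametes from a pool of {pool.n_gametes}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pool.n_gametes, size=2 * n, replace=False)
    return Population(
        gamete_a=pool.gametes[idx[:n]].copy(),
        gamete_b=pool.gametes[idx[n:]].copy(),
        ptype=PopType.LS,
        gmap=pool.gmap,
    )
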