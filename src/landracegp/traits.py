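"""Trait architecture and closed-form quantitative-genetic expectations.

Model
-----
Per QTL, with the package-wide coding (allele 1 = capture-line allele) and
``p`` the ancestral frequency of allele 1, genotypic values for line per se
performance (PP) are parameterized as

    value(dose 0) = -a,   value(dose 2) = a + Delta,
    value(dose 1) = Delta/2 + d_het,

summed over QTL around an intercept x_bar.  ``a`` is the additive effect of
the landrace allele contrast; ``Delta`` is the deviation of the capture-line
allele effect (nonzero only where the capture allele is absent from the
landrace, i.e. at private loci); ``d_het`` is the dominance deviation of the
heterozygote, which is the landrace dominance d12 at loci where the capture
allele segregates in the landrace and the capture-specific dominance d2x at
private loci.  The genotype class A1Ax (dominance d1x) would require a
third allele at one locus and cannot occur with biallelic markers; d1x is
kept in the closed forms for completeness and is structurally zero in
simulated architectures.

Testcross performance (TP) is computed mechanistically as the expected
genotypic value of an entry's testcross progeny with a homozygous tester:
per locus the hybrid carries the tester allele plus one entry gamete
allele, with a tester-specific dominance deviation for hybrid
heterozygotes.  TP is therefore linear in the entry's expected gamete and
the classical coefficient table for TP variances follows as a consequence
(verified by the enumeration tests), with the allele-substitution effect on
the tester background playing the role of 2a and no dominance parameters
required.

Closed forms (summed over QTL, assuming linkage equilibrium between QTL):

    sigma2_A  = sum 2 p (1-p) a^2
    sigma2_A* = sum 2 ((1-p) a + Delta/2)^2
    [d]       = sum 2 p (1-p) d12
    [d*]      = sum p d1x + (1-p) d2x
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genome import GeneticMap
from .populations import Population, PopType

__all__ = [
    "TraitArchitecture",
    "ExpectationReport",
    "assign_trait",
    "genotypic_value_pp",
    "genotypic_value_tp",
    "genotypic_value_testcross_genotype",
    "true_entry_values",
    "expected_population_stats",
    "molecular_variance_expected",
    "variance_thresholds",
    "estimate_inbreeding_contributions",
    "expected_gc_frequency",
]


# Coefficient table for means and additive variances: rows are population
# levels, columns are (a+Delta, (p-(1-p))a, [d], [d*]) for the mean and
# (sigma2_A, sigma2_A*) for primary / within-family / total variance.
_COEFFS = {
    "LS": {"mean": (0, 1, 1, 0), "primary": (1, 0), "within": (0, 0), "total": (1, 0)},
    "DH": {"mean": (0, 1, 0, 0), "primary": (2, 0), "within": (0, 0), "total": (2, 0)},
    "GC_S1_2": {
        "mean": (0.5, 0.5, 0, 0.25),
        "primary": (0.75, 0.25),
        "within": (0.125, 0.125),
        "total": (0.875, 0.375),
    },
    "GC_S1_INF": {
        "mean": (0.5, 0.5, 0, 0),
        "primary": (0.75, 0.25),
        "within": (0.25, 0.25),
        "total": (1.0, 0.5),
    },
    "CAPTURE": {"mean": (1, 0, 0, 0), "primary": (0, 0), "within": (0, 0), "total": (0, 0)},
}


@dataclass
class TraitArchitecture:
    """Per-QTL effects of a simulated trait.

    All effect arrays are aligned with ``qtl`` (marker indices into the
    map / genotype matrices).  ``private`` marks QTL where the capture
    allele is absent from the ancestral landrace; construction enforces the
    coding constraints Delta = 0, d2x = d12, d1x = 0 at non-private QTL and
    d12 = d1x = 0 at private QTL.
    """

    qtl: np.ndarray  # marker indices
    a: np.ndarray
    delta: np.ndarray
    d12: np.ndarray
    d1x: np.ndarray
    d2x: np.ndarray
    private: np.ndarray  # bool
    tester: np.ndarray = None  # type: ignore[assignment]  # tester allele (0/1) per QTL
    tester_d: np.ndarray = None  # type: ignore[assignment]  # hybrid dominance per QTL
    intercept: float = 0.0
    qtl_chrom: np.ndarray = None  # type: ignore[assignment]
    qtl_cm: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.qtl)
        for name in ("a", "delta", "d12", "d1x", "d2x"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per QTL")
            setattr(self, name, arr)
        self.private = np.asarray(self.private, dtype=bool)
        if self.tester is None:
            self.tester = np.ones(n, dtype=np.uint8)
        if self.tester_d is None:
            self.tester_d = np.zeros(n)
        nonpriv = ~self.private
        if np.any(self.delta[nonpriv] != 0):
            raise ValueError("Delta must be 0 where the capture allele segregates in the landrace")
        if np.any(self.d2x[nonpriv] != self.d12[nonpriv]) or np.any(self.d1x[nonpriv] != 0):
            raise ValueError("at non-private QTL the capture heterozygote is A1A2: d2x=d12, d1x=0")
        if np.any(self.d12[self.private] != 0) or np.any(self.d1x[self.private] != 0):
            raise ValueError("at private QTL the landrace is monomorphic: d12=d1x=0")
        if not np.all(np.isfinite(self.a)) or not np.all(np.isfinite(self.delta)):
            raise ValueError("effects must be finite")

    @property
    def n_qtl(self) -> int:
        return len(self.qtl)

    @property
    def d_het(self) -> np.ndarray:
        """Dominance of the coded heterozygote per QTL (d12 or d2x)."""
        return np.where(self.private, self.d2x, self.d12)

    # --- testcross machinery -------------------------------------------------
    def _v_hybrid(self, dose: np.ndarray) -> np.ndarray:
        """Per-locus genotypic value of hybrid dose 0/1/2 with tester dominance."""
        return (dose - 1) * self.a + (dose / 2.0) * self.delta + (dose == 1) * self.tester_d

    def tp_substitution_effect(self) -> np.ndarray:
        """Allele-substitution effect s of the coded allele on the tester background."""
        t = self.tester.astype(float)
        return self._v_hybrid(t + 1) - self._v_hybrid(t)

    def tp_base(self) -> float:
        """Sum of per-locus midpoints of testcross values (dose-0 vs dose-2 entries)."""
        t = self.tester.astype(float)
        s = self.tp_substitution_effect()
        return float(np.sum(self._v_hybrid(t) + s / 2.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "qtl_marker": self.qtl,
                "a": self.a,
                "delta": self.delta,
                "d12": self.d12,
                "d1x": self.d1x,
                "d2x": self.d2x,
                "private": self.private.astype(int),
                "tester_allele": self.tester,
                "tester_d": self.tester_d,
            }
        )

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.attrs["intercept"] = self.intercept
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, intercept: float = 0.0) -> "TraitArchitecture":
        df = pd.read_csv(path, sep="\t")
        return cls(
            qtl=df["qtl_marker"].to_numpy(),
            a=df["a"].to_numpy(float),
            delta=df["delta"].to_numpy(float),
            d12=df["d12"].to_numpy(float),
            d1x=df["d1x"].to_numpy(float),
            d2x=df["d2x"].to_numpy(float),
            private=df["private"].to_numpy(bool),
            tester=df["tester_allele"].to_numpy(np.uint8),
            tester_d=df["tester_d"].to_numpy(float),
            intercept=intercept,
        )


def _draw_effects(spec, n: int, rng: np.random.Generator, scale_ref: np.ndarray | None = None):
    """Draw an effect vector from a small spec language.

    float -> constant; ("normal", mu, sd) -> N(mu, sd); ("prop", k) ->
    k * |reference effect| (used for dominance degrees).
    """
    if spec is None:
        return np.zeros(n)
    if np.isscalar(spec):
        return np.full(n, float(spec))
    kind = spec[0]
    if kind == "normal":
        return rng.normal(spec[1], spec[2], size=n)
    if kind == "prop":
        if scale_ref is None:
            raise ValueError("'prop' dominance spec needs additive effects as reference")
        return spec[1] * np.abs(scale_ref)
    raise ValueError(f"unknown effect spec {spec!r}")


def assign_trait(
    gmap: GeneticMap,
    p: np.ndarray,
    n_qtl: int,
    effect_distribution=("normal", 0.0, 1.0),
    dominance_spec: dict | None = None,
    seed=None,
    private_loci=None,
    delta_spec=("normal", 0.0, 1.0),
    tester_allele_freq: float = 0.5,
    intercept: float = 0.0,
) -> TraitArchitecture:
    """Draw a trait architecture on ``n_qtl`` markers of the map.

    ``p`` is the ancestral frequency vector (capture-allele coding);
    ``private_loci`` (marker indices with p=0) restricts where Delta and d2x
    can differ from the landrace parameters.  ``dominance_spec`` is a dict
    with optional keys "d12", "d2x_private", "tester" (each a spec accepted
    by the internal effect-draw helper); omitted keys give a purely
    additive trait (all dominance terms zero).
    """
    if n_qtl <= 0:
        raise ValueError("n_qtl must be positive")
    if n_qtl > gmap.n_markers:
        raise ValueError("more QTL requested than markers available")
    rng = np.random.default_rng(seed)
    qtl = np.sort(rng.choice(gmap.n_markers, size=n_qtl, replace=False))
    p = np.asarray(p, dtype=float)
    if private_loci is None:
        private = p[qtl] == 0.0
    else:
        private = np.isin(qtl, np.asarray(private_loci))
    a = _draw_effects(effect_distribution, n_qtl, rng)
    delta = np.where(private, _draw_effects(delta_spec, n_qtl, rng), 0.0)
    dom = dominance_spec or {}
    d12 = np.where(~private, _draw_effects(dom.get("d12"), n_qtl, rng, a), 0.0)
    d2x = np.where(private, _draw_effects(dom.get("d2x_private"), n_qtl, rng, a), d12)
    d1x = np.zeros(n_qtl)
    tester = (rng.random(n_qtl) < tester_allele_freq).astype(np.uint8)
    tester_d = _draw_effects(dom.get("tester"), n_qtl, rng, a)
    return TraitArchitecture(
        qtl=qtl,
        a=a,
        delta=delta,
        d12=d12,
        d1x=d1x,
        d2x=d2x,
        private=private,
        tester=tester,
        tester_d=tester_d,
        intercept=intercept,
        qtl_chrom=gmap.chrom[qtl],
        qtl_cm=gmap.pos_cm[qtl],
    )


def _qtl_dosage(genotypes, trait: TraitArchitecture) -> np.ndarray:
    if isinstance(genotypes, Population):
        dose = genotypes.dosage()[:, trait.qtl]
    else:
        dose = np.asarray(genotypes, dtype=float)
        if dose.ndim == 1:
            dose = dose[None, :]
        if dose.shape[1] == trait.n_qtl:
            pass
        else:
            dose = dose[:, trait.qtl]
    if not np.isin(dose, (0, 1, 2)).all():
        raise ValueError("dosages must be 0/1/2 in the capture-allele coding")
    return dose.astype(float)


def genotypic_value_pp(genotypes, trait: TraitArchitecture) -> np.ndarray:
    """Per se genotypic values for diploid genotypes (Population or dosage)."""
    G = _qtl_dosage(genotypes, trait)
    val = (
        (G - 1) @ trait.a
        + (G / 2.0) @ trait.delta
        + (G == 1).astype(float) @ trait.d_het
    )
    return trait.intercept + val


def genotypic_value_tp(entries, trait: TraitArchitecture) -> np.ndarray:
    """Expected testcross value of each entry (expectation over entry gametes).

    Because each testcross plant carries the tester gamete plus one entry
    gamete, the expected value is linear in the entry's allele dosage.
    """
    G = _qtl_dosage(entries, trait)
    s = trait.tp_substitution_effect()
    return trait.intercept + trait.tp_base() + (G - 1) @ (s / 2.0)


def genotypic_value_testcross_genotype(testcross, trait: TraitArchitecture) -> np.ndarray:
    """Genotypic value of explicitly constructed testcross plants (sampling mode)."""
    H = _qtl_dosage(testcross, trait)
    return trait.intercept + trait._v_hybrid(H).sum(axis=1)


def true_entry_values(
    population: Population, trait: TraitArchitecture, level: str = "PP",
    s2_family_size: int | None = None, rng=None,
) -> np.ndarray:
    """True genetic entry values used for phenotype generation.

    For PP of a GC-S1 population the field entry is the S1:2 family; with
    ``s2_family_size`` set, the entry value is the mean PP over a simulated
    S2 family of that size, otherwise the analytic expectation over the S2
    family (selfing the S1 genotype) is used.  For inbred entries all
    definitions coincide.  level="TP" returns expected testcross values.
    """
    if level == "TP":
        return genotypic_value_tp(population, trait)
    if population.ptype != PopType.GC_S1:
        return genotypic_value_pp(population, trait)
    if s2_family_size is not None:
        from .populations import self_progeny

        rng = np.random.default_rng(rng)
        vals = np.empty(population.n)
        for i in range(population.n):
            fam = self_progeny(
                (population.gamete_a[i], population.gamete_b[i]),
                s2_family_size,
                population.gmap,
                rng,
            )
            vals[i] = genotypic_value_pp(fam, trait).mean()
        return vals
    # analytic expectation over the selfed family, per locus
    G = _qtl_dosage(population, trait)
    het = G == 1
    v0 = -trait.a
    v1 = trait.delta / 2.0 + trait.d_het
    v2 = trait.a + trait.delta
    e_self = 0.25 * v0 + 0.5 * v1 + 0.25 * v2  # expected value of a selfed heterozygote's offspring
    per_locus = np.where(het, e_self, (G - 1) * trait.a + (G / 2.0) * trait.delta)
    return trait.intercept + per_locus.sum(axis=1)


@dataclass
class ExpectationReport:
    """Closed-form means and additive variances per population and level.

    ``table`` has one row per (population, level) with columns mean,
    primary, within_family and total variance; the aggregate components
    sigma2_A, sigma2_A_star, d_sum ([d]) and d_star_sum ([d*]) are carried
    for PP and TP separately.  ``linked_qtl`` flags architectures with QTL
    closer than 50 cM, for which the between-QTL independence behind the
    closed forms is violated and the sums are approximate.
    """

    table: pd.DataFrame
    components: dict
    linked_qtl: bool

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def row(self, population: str, level: str = "PP") -> pd.Series:
        sel = (self.table["population"] == population) & (self.table["level"] == level)
        return self.table[sel].iloc[0]


def expected_population_stats(trait: TraitArchitecture, p_vector: np.ndarray) -> ExpectationReport:
    """Evaluate the coefficient table over the trait's QTL.

    ``p_vector`` is the ancestral capture-allele frequency per marker (the
    QTL subset is taken internally).  Exact under linkage equilibrium
    between QTL; flagged approximate otherwise.
    """
    p_all = np.asarray(p_vector, dtype=float)
    p = p_all[trait.qtl] if p_all.shape[0] != trait.n_qtl else p_all
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")

    a, delta = trait.a, trait.delta
    per_s2a = 2 * p * (1 - p) * a**2
    per_s2astar = 2 * ((1 - p) * a + delta / 2.0) ** 2
    per_d = 2 * p * (1 - p) * trait.d12
    per_dstar = p * trait.d1x + (1 - p) * trait.d2x
    comp_pp = {
        "sigma2_A": float(per_s2a.sum()),
        "sigma2_A_star": float(per_s2astar.sum()),
        "d_sum": float(per_d.sum()),
        "d_star_sum": float(per_dstar.sum()),
    }
    sum_a_delta = float(np.sum(a + delta))
    sum_contrast = float(np.sum((2 * p - 1) * a))

    s = trait.tp_substitution_effect()
    aT = s / 2.0
    comp_tp = {
        "sigma2_A": float(np.sum(2 * p * (1 - p) * aT**2)),
        "sigma2_A_star": float(np.sum(2 * ((1 - p) * aT) ** 2)),
        "d_sum": 0.0,
        "d_star_sum": 0.0,
    }
    tp_base = trait.tp_base()
    sum_aT = float(np.sum(aT))
    sum_contrast_T = float(np.sum((2 * p - 1) * aT))

    rows = []
    for popname, co in _COEFFS.items():
        c1, c2, c3, c4 = co["mean"]
        mean_pp = (
            trait.intercept
            + c1 * sum_a_delta
            + c2 * sum_contrast
            + c3 * comp_pp["d_sum"]
            + c4 * comp_pp["d_star_sum"]
        )
        mean_tp = trait.intercept + tp_base + c1 * sum_aT + c2 * sum_contrast_T
        for level, comp, mean in (("PP", comp_pp, mean_pp), ("TP", comp_tp, mean_tp)):
            rec = {"population": popname, "level": level, "mean": mean}
            for part in ("primary", "within", "total"):
                kA, kAs = co[part]
                rec[part if part != "within" else "within_family"] = (
                    kA * comp["sigma2_A"] + kAs * comp["sigma2_A_star"]
                )
            rows.append(rec)
    table = pd.DataFrame(rows)[["population", "level", "mean", "primary", "within_family", "total"]]

    linked = False
    if trait.qtl_chrom is not None and trait.qtl_cm is not None:
        for c in np.unique(trait.qtl_chrom):
            cm = np.sort(trait.qtl_cm[trait.qtl_chrom == c])
            if len(cm) > 1 and np.min(np.diff(cm)) < 50.0:
                linked = True
    return ExpectationReport(
        table=table, components={"PP": comp_pp, "TP": comp_tp}, linked_qtl=linked
    )


def molecular_variance_expected(pop_type, p) -> np.ndarray:
    """Expected per-locus molecular variance 2f(1-f) from ancestral frequency p.

    LS and DH: 2p(1-p) (identical by construction).  GC-S1: the capture
    allele moves to frequency f=(p+1)/2, giving 0.5(1+p)(1-p).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    key = pop_type.value if isinstance(pop_type, PopType) else str(pop_type)
    if key in ("LS", "DH"):
        return 2 * p * (1 - p)
    if key in ("GC_S1", "GC_S0", "GC_S1_2"):
        return 0.5 * (1 + p) * (1 - p)
    raise ValueError(f"unknown population type {pop_type!r}")


def variance_thresholds(tol: float = 1e-9) -> tuple[float, float]:
    """Boundary ancestral frequencies of the capture allele, solved numerically.

    First value: p where the GC-S1 molecular variance 0.5(1+p)(1-p) equals
    the LS/DH molecular variance 2p(1-p) (GC exceeds LS/DH below it).
    Second value: p where the GC-S1:2 primary genetic variance
    (3/4) sigma2_A + (1/4) sigma2_A* equals the DH variance 2 sigma2_A when
    the capture line carries a landrace allele (Delta=0, so
    sigma2_A* = 2(1-p)^2 a^2); the additive effect cancels.  Both are found
    by bisection-type root finding on [0, 1).
    """

    def mol_diff(p):
        return 0.5 * (1 + p) * (1 - p) - 2 * p * (1 - p)

    def gen_diff(p):
        s2a = 2 * p * (1 - p)
        s2astar = 2 * (1 - p) ** 2
        return (0.75 * s2a + 0.25 * s2astar) - 2 * s2a

    p1 = brentq(mol_diff, 1e-12, 1 - 1e-6, xtol=tol)
    p2 = brentq(gen_diff, 1e-12, 1 - 1e-6, xtol=tol)
    return float(p1), float(p2)


def estimate_inbreeding_contributions(
    mean_ls: float, mean_dh: float, mean_gc: float, mean_capture: float
) -> tuple[float, float]:
    """Estimate the cumulative dominance contributions [d] and [d*] from means.

    [d] = mean(LS) - mean(DH); [d*] = 4 (mean(GC-S1:2) - (mean(DH)+mean(capture))/2),
    since the GC-S1:2 mean carries 1/4 [d*] and otherwise lies exactly
    between the DH mean and the capture line under additivity.
    """
    d_hat = mean_ls - mean_dh
    dstar_hat = 4.0 * (mean_gc - (mean_dh + mean_capture) / 2.0)
    return float(d_hat), float(dstar_hat)


def expected_gc_frequency(p) -> np.ndarray:
    """Expected capture-allele frequency in GC generations: (p+1)/2."""
    p = np.asarray(p, dtype=float)
    return (p + 1.0) / 2.0
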