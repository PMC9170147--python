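"""Molecular diversity statistics: polymorphism census, molecular variance and
AMOVA, genetic distances, LD, LD-decay fitting and linkage-phase similarity.

All statistics operate on the package coding (gametes 0/1, dosages 0/1/2 of
the capture-line allele), which also fixes a consistent allele orientation
for signed LD across populations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.spatial.distance import cdist

from .genome import GeneticMap
from .populations import Population

__all__ = [
    "allele_frequencies",
    "polymorphism_census",
    "molecular_variance",
    "MolecularVarianceResult",
    "genetic_distance",
    "genetic_distance_matrix",
    "ld_pairs",
    "DecayFit",
    "fit_ld_decay",
    "cross_chromosome_ld",
    "linkage_phase_similarity",
]


def _dosage(population) -> np.ndarray:
    if isinstance(population, Population):
        return population.dosage().astype(float)
    return np.asarray(population, dtype=float)


def _gametes(population) -> np.ndarray:
    if isinstance(population, Population):
        return population.gametes().astype(float)
    return np.asarray(population, dtype=float)


def allele_frequencies(population) -> np.ndarray:
    """Frequency of the capture-line allele per marker (mean dosage / 2)."""
    dose = _dosage(population)
    if dose.shape[0] == 0:
        raise ValueError("empty population")
    return dose.mean(axis=0) / 2.0


def polymorphism_census(
    populations: dict,
    n_gametes: int = 80,
    n_reps: int = 500,
    seed=None,
) -> pd.DataFrame:
    """Gamete-resampling census of shared and private marker polymorphisms.

    For each replicate, ``n_gametes`` gametes are drawn without replacement
    from every population and each marker is classified by the subset of
    populations in which it segregates.  Returns mean +- SD counts for every
    region of the Venn partition over the population names, plus (when the
    populations are named LS, DH and GC) the GC-private polymorphisms
    attributable to the capture line, i.e. markers segregating only in GC
    while the LS and DH samples are fixed for the non-capture allele 0.
    """
    names = list(populations)
    gams = {k: _gametes(v) for k, v in populations.items()}
    for k, g in gams.items():
        if g.shape[0] < n_gametes:
            raise ValueError(f"population {k!r} supplies {g.shape[0]} < {n_gametes} gametes")
    rng = np.random.default_rng(seed)
    regions = [frozenset(c) for r in range(1, len(names) + 1) for c in itertools.combinations(names, r)]
    counts = {r: [] for r in regions}
    capture_priv = []
    for _ in range(n_reps):
        seg = {}
        fixed0 = {}
        for k, g in gams.items():
            idx = rng.choice(g.shape[0], size=n_gametes, replace=False)
            f = g[idx].mean(axis=0)
            seg[k] = (f > 0) & (f < 1)
            fixed0[k] = f == 0
        membership = np.stack([seg[k] for k in names])
        any_seg = membership.any(axis=0)
        for r in regions:
            mask = np.ones(membership.shape[1], dtype=bool)
            for i, k in enumerate(names):
                mask &= membership[i] if k in r else ~membership[i]
            counts[r].append(int((mask & any_seg).sum()))
        if {"LS", "DH", "GC"} <= set(names):
            only_gc = seg["GC"] & ~seg["LS"] & ~seg["DH"]
            capture_priv.append(int((only_gc & fixed0["LS"] & fixed0["DH"]).sum()))
    rows = [
        {
            "region": "&".join(sorted(r)),
            "n_populations": len(r),
            "mean_count": float(np.mean(counts[r])),
            "sd_count": float(np.std(counts[r], ddof=1)) if n_reps > 1 else 0.0,
        }
        for r in regions
    ]
    if capture_priv:
        rows.append(
            {
                "region": "GC_private_capture_line",
                "n_populations": 1,
                "mean_count": float(np.mean(capture_priv)),
                "sd_count": float(np.std(capture_priv, ddof=1)) if n_reps > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MolecularVarianceResult:
    """Per-locus molecular variances and the AMOVA decomposition.

    ``per_locus`` is 2f(1-f) from the realized allele frequency; the AMOVA
    partitions squared Euclidean distances on gamete allele indicators into
    a between-individual and a within-individual (between the two gametes
    of a plant) component by the method of moments.  Negative component
    estimates are truncated at zero and flagged.
    """

    per_locus: np.ndarray
    total: float
    ss_between: float
    ss_within: float
    var_between: float
    var_within: float
    truncated: bool


def molecular_variance(population) -> MolecularVarianceResult:
    if isinstance(population, Population):
        ga = population.gamete_a.astype(float)
        gb = population.gamete_b.astype(float)
    else:
        dose = np.asarray(population, dtype=float)
        # unphased dosage: split heterozygotes arbitrarily (AMOVA within-SS exact anyway)
        ga = np.clip(dose - 1, 0, 1)
        gb = dose - ga
    n = ga.shape[0]
    f = (ga + gb).mean(axis=0) / 2.0
    per_locus = 2 * f * (1 - f)
    X = np.vstack([ga, gb])
    grand = X.mean(axis=0)
    ss_total = float(((X - grand) ** 2).sum())
    ss_within = float((((ga - gb) / 2.0) ** 2).sum() * 2)  # two gametes, each (x - mean)^2
    ss_between = ss_total - ss_within
    ms_within = ss_within / n
    ms_between = ss_between / max(n - 1, 1)
    var_within = ms_within
    var_between = (ms_between - ms_within) / 2.0
    truncated = False
    if var_between < 0:
        var_between, truncated = 0.0, True
    return MolecularVarianceResult(
        per_locus=per_locus,
        total=float(per_locus.sum()),
        ss_between=ss_between,
        ss_within=ss_within,
        var_between=var_between,
        var_within=var_within,
        truncated=truncated,
    )


def genetic_distance(genotype_a, genotype_b) -> float:
    """GD = 1 - SM with allele-sharing matching (1 / 0.5 / 0 per locus).

    On 0/1/2 dosages the per-locus match score is 1 - |d1 - d2| / 2, so
    GD = mean |d1 - d2| / 2 across loci.
    """
    d1 = np.asarray(genotype_a, dtype=float)
    d2 = np.asarray(genotype_b, dtype=float)
    if d1.size == 0:
        raise ValueError("empty marker set")
    return float(np.mean(np.abs(d1 - d2)) / 2.0)


def genetic_distance_matrix(population_a, population_b=None, marker_subset=None) -> np.ndarray:
    """Pairwise GD matrix within one population or between two."""
    A = _dosage(population_a)
    B = A if population_b is None else _dosage(population_b)
    if marker_subset is not None:
        idx = np.asarray(marker_subset)
        if idx.size == 0:
            raise ValueError("empty marker subset")
        A = A[:, idx]
        B = B[:, idx]
    m = A.shape[1]
    return cdist(A, B, metric="cityblock") / (2.0 * m)


def _signed_r_matrix(gametes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise signed correlation of allele indicators; returns (r, polymorphic mask)."""
    X = np.asarray(gametes, dtype=float)
    f = X.mean(axis=0)
    poly = (f > 0) & (f < 1)
    Xc = X - f
    sd = X.std(axis=0)
    sd[~poly] = 1.0
    Z = Xc / sd
    r = (Z.T @ Z) / X.shape[0]
    return r, poly


def ld_pairs(
    gametes, gmap: GeneticMap, max_dist_bp: int = 1_000_000, n_gametes: int | None = None, seed=None
) -> pd.DataFrame:
    """Signed r and r2 for same-chromosome marker pairs within ``max_dist_bp``.

    Monomorphic markers are skipped.  ``n_gametes`` subsamples gametes
    without replacement first (the convention of working with a fixed
    number of gametes per population, e.g. 94).
    """
    X = _gametes(gametes)
    if n_gametes is not None:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], size=n_gametes, replace=False)]
    recs = []
    for c in gmap.chromosomes:
        sl = gmap.chrom_slice(int(c))
        bp = gmap.pos_bp[sl]
        names = gmap.marker[sl]
        r, poly = _signed_r_matrix(X[:, sl])
        ii, jj = np.triu_indices(len(bp), k=1)
        dist = bp[jj] - bp[ii]
        keep = (dist <= max_dist_bp) & poly[ii] & poly[jj]
        if not keep.any():
            continue
        recs.append(
            pd.DataFrame(
                {
                    "marker_i": names[ii[keep]],
                    "marker_j": names[jj[keep]],
                    "chrom": int(c),
                    "dist_bp": dist[keep],
                    "r": r[ii[keep], jj[keep]],
                }
            )
        )
    if not recs:
        return pd.DataFrame(columns=["marker_i", "marker_j", "chrom", "dist_bp", "r", "r2"])
    out = pd.concat(recs, ignore_index=True)
    out["r2"] = out["r"] ** 2
    return out


def hill_weir_expected_r2(dist_bp: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Expected r2 as a function of physical distance under drift-recombination
    equilibrium with a finite-sample term for n sampled gametes; C = rho * d."""
    C = np.asarray(dist_bp, dtype=float) * rho
    term1 = (10 + C) / ((2 + C) * (11 + C))
    term2 = 1 + ((3 + C) * (12 + 12 * C + C**2)) / (n * (2 + C) * (11 + C))
    return term1 * term2


@dataclass
class DecayFit:
    """Fitted LD-decay curve: per-bp coefficient, sample size, decay distance."""

    rho: float  # per-bp recombination-scale coefficient C = rho * distance
    n_gametes: int
    delta_kb: float  # distance where the fitted curve reaches r2 = 0.2 (nan if never)
    sse: float
    converged: bool

    def predict(self, dist_bp) -> np.ndarray:
        return hill_weir_expected_r2(np.asarray(dist_bp, float), self.rho, self.n_gametes)


def fit_ld_decay(ld_records: pd.DataFrame, n_gametes: int, r2_threshold: float = 0.2) -> DecayFit:
    """Least-squares fit of the expected-r2 decay curve to observed pairs.

    The single parameter rho (C = rho * distance) is optimized on a log
    scale; the decay distance delta solves expected r2 = ``r2_threshold``
    and is reported in kb (nan, flagged, if the curve never crosses the
    threshold within 10x the data range).
    """
    if len(ld_records) < 10:
        raise ValueError("need at least 10 LD records to fit a decay curve")
    d = ld_records["dist_bp"].to_numpy(float)
    y = ld_records["r2"].to_numpy(float)
    if d.max() <= d.min():
        raise ValueError("LD records must span a range of distances")

    def sse(log_rho):
        return float(np.sum((y - hill_weir_expected_r2(d, np.exp(log_rho), n_gametes)) ** 2))

    res = minimize_scalar(sse, bounds=(np.log(1e-12), np.log(1.0)), method="bounded")
    rho = float(np.exp(res.x))

    def g(x):
        return hill_weir_expected_r2(np.array([x]), rho, n_gametes)[0] - r2_threshold

    hi = 10 * d.max()
    if g(1e-6) <= 0 or g(hi) >= 0:
        delta_kb = float("nan")
    else:
        delta_kb = brentq(g, 1e-6, hi) / 1e3
    return DecayFit(
        rho=rho, n_gametes=n_gametes, delta_kb=delta_kb, sse=float(res.fun),
        converged=bool(res.success),
    )


def cross_chromosome_ld(
    gametes,
    gmap: GeneticMap,
    n_markers_per_chrom: int = 5000,
    n_pairs_per_chrom_pair: int = 5000,
    seed=None,
) -> tuple[float, pd.DataFrame]:
    """Mean r2 over random marker pairs on different chromosomes.

    Markers are sampled with replacement per chromosome; all pairwise
    chromosome combinations are enumerated (45 for a 10-chromosome genome).
    Returns the overall mean r2 and a per-chromosome-pair table.
    """
    chroms = gmap.chromosomes
    if len(chroms) < 2:
        raise ValueError("need at least two chromosomes for cross-chromosome LD")
    X = _gametes(gametes)
    rng = np.random.default_rng(seed)
    f = X.mean(axis=0)
    poly = (f > 0) & (f < 1)
    Z = (X - f) / np.where(poly, X.std(axis=0), 1.0)
    rows = []
    vals = []
    for ca, cb in itertools.combinations(chroms, 2):
        ia = np.flatnonzero((gmap.chrom == ca) & poly)
        ib = np.flatnonzero((gmap.chrom == cb) & poly)
        if ia.size == 0 or ib.size == 0:
            continue
        k = min(n_pairs_per_chrom_pair, n_markers_per_chrom)
        sa = rng.choice(ia, size=min(k, n_markers_per_chrom), replace=True)
        sb = rng.choice(ib, size=sa.size, replace=True)
        r = (Z[:, sa] * Z[:, sb]).mean(axis=0)
        r2 = float(np.mean(r**2))
        rows.append({"chrom_a": int(ca), "chrom_b": int(cb), "mean_r2": r2, "n_pairs": sa.size})
        vals.append(r2)
    table = pd.DataFrame(rows)
    return float(np.mean(vals)), table


def linkage_phase_similarity(
    gametes_a,
    gametes_b,
    gmap: GeneticMap,
    bin_kb: float = 10.0,
    max_dist_kb: float = 1000.0,
    mode: str = "sign",
) -> pd.DataFrame:
    """LPS between two populations per physical-distance bin.

    Over marker pairs polymorphic in both populations, mode="sign" reports
    the proportion of pairs whose signed r has the same sign in A and B;
    mode="corr" reports the Pearson correlation of the signed r values.
    Allele orientation is consistent by the package-wide capture-allele
    coding.  Bins are half-open [lo, hi) in kb; empty bins carry NaN.
    """
    if mode not in ("sign", "corr"):
        raise ValueError("mode must be 'sign' or 'corr'")
    XA = _gametes(gametes_a)
    XB = _gametes(gametes_b)
    edges = np.arange(0.0, max_dist_kb + bin_kb, bin_kb)
    ra_all, rb_all, dist_all = [], [], []
    for c in gmap.chromosomes:
        sl = gmap.chrom_slice(int(c))
        bp = gmap.pos_bp[sl]
        rA, polyA = _signed_r_matrix(XA[:, sl])
        rB, polyB = _signed_r_matrix(XB[:, sl])
        ii, jj = np.triu_indices(len(bp), k=1)
        dist_kb = (bp[jj] - bp[ii]) / 1e3
        keep = (dist_kb < max_dist_kb) & polyA[ii] & polyA[jj] & polyB[ii] & polyB[jj]
        ra_all.append(rA[ii[keep], jj[keep]])
        rb_all.append(rB[ii[keep], jj[keep]])
        dist_all.append(dist_kb[keep])
    ra = np.concatenate(ra_all) if ra_all else np.array([])
    rb = np.concatenate(rb_all) if rb_all else np.array([])
    dist = np.concatenate(dist_all) if dist_all else np.array([])
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (dist >= lo) & (dist < hi)
        n = int(m.sum())
        if n == 0:
            lps = float("nan")
        elif mode == "sign":
            lps = float(np.mean(np.sign(ra[m]) == np.sign(rb[m])))
        else:
            lps = float(np.corrcoef(ra[m], rb[m])[0, 1]) if n > 1 else float("nan")
        rows.append({"bin_lo_kb": lo, "bin_hi_kb": hi, "n_pairs": n, "lps": lps, "mode": mode})
    return pd.DataFrame(rows)
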