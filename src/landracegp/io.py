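"""File I/O and quality-control filtering.

Genotypes round-trip through phased VCF (GT field, contig headers from the
genetic map) and plain CSV dosage matrices; maps are 4-column TSV.  The QC
filter mirrors the standard array-data rules: markers then individuals
with >10% missing calls are removed, and for DH material markers and
individuals with >5% heterozygous calls are removed with residual
heterozygous calls set to missing (a DH line is homozygous by
construction, so remaining heterozygosity is technical error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GeneticMap
from .populations import Population, PopType

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_csv",
    "read_dosage_csv",
    "qc_filter",
    "QCReport",
]

MISSING = -1  # standardized missing dosage code; VCF ./. maps to it


def write_vcf(population: Population, path, sample_prefix: str | None = None) -> None:
    """Write a population as a phased VCF (REF = non-capture, ALT = capture allele)."""
    gmap = population.gmap
    prefix = sample_prefix or population.ptype.value
    samples = [f"{prefix}_{i:04d}" for i in range(population.n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=landracegp\n")
        for c in gmap.chromosomes:
            sl = gmap.chrom_slice(int(c))
            length = int(gmap.pos_bp[sl][-1]) + 1
            fh.write(f"##contig=<ID={int(c)},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        ga = population.gamete_a
        gb = population.gamete_b
        for j in range(gmap.n_markers):
            gts = "\t".join(f"{ga[i, j]}|{gb[i, j]}" for i in range(population.n))
            fh.write(
                f"{int(gmap.chrom[j])}\t{int(gmap.pos_bp[j])}\t{gmap.marker[j]}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path, gmap: GeneticMap | None = None, ptype: PopType = PopType.LS) -> Population:
    """Read a phased VCF back into a Population.

    If a map is given, the VCF markers must match it (same ids in order);
    otherwise a map is rebuilt from the VCF coordinates with cM proportional
    to bp at 1 cM/Mb.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    chroms, bps, names, rows = [], [], [], []
    for var in vcf:
        chroms.append(int(var.CHROM))
        bps.append(var.POS)
        names.append(var.ID)
        gts = np.array([g[:2] for g in var.genotypes], dtype=int)
        rows.append(gts)
    vcf.close()
    geno = np.stack(rows, axis=1)  # (n_samples, n_markers, 2)
    if gmap is None:
        gmap = GeneticMap(
            chrom=np.asarray(chroms, dtype=np.int64),
            pos_bp=np.asarray(bps, dtype=np.int64),
            pos_cm=np.asarray(bps, dtype=float) / 1e6,
            marker=np.asarray(names, dtype=object),
        )
    else:
        if list(gmap.marker) != names:
            unknown = set(names) - set(gmap.marker)
            raise ValueError(f"VCF markers do not match the map (unknown: {sorted(unknown)[:5]} ...)")
    if np.any(geno < 0):
        raise ValueError("missing genotypes not supported in phased population VCFs")
    return Population(
        gamete_a=geno[:, :, 0].astype(np.uint8),
        gamete_b=geno[:, :, 1].astype(np.uint8),
        ptype=ptype,
        gmap=gmap,
    )


def write_dosage_csv(dosage, path, markers=None, individuals=None, header_comment: str | None = None) -> None:
    """Dosage matrix (individuals x markers, 0/1/2, -1 missing) as CSV."""
    dose = np.asarray(dosage)
    idx = individuals if individuals is not None else [f"ind_{i}" for i in range(dose.shape[0])]
    cols = markers if markers is not None else [f"m_{j}" for j in range(dose.shape[1])]
    df = pd.DataFrame(dose, index=pd.Index(idx, name="individual"), columns=cols)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh)


def read_dosage_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, comment="#")
    vals = df.to_numpy()
    bad = ~np.isin(vals, (0, 1, 2, MISSING)) & ~np.isnan(vals.astype(float))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid dosage {vals[i, j]!r} at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return df


@dataclass
class QCReport:
    markers_missing_removed: int
    individuals_missing_removed: int
    markers_het_removed: int
    individuals_het_removed: int
    het_calls_set_missing: int

    def total_removed(self) -> int:
        return (
            self.markers_missing_removed
            + self.individuals_missing_removed
            + self.markers_het_removed
            + self.individuals_het_removed
        )


def qc_filter(
    genotype_table: pd.DataFrame,
    max_missing_rate: float = 0.10,
    max_het_rate_dh: float = 0.05,
    is_dh: bool = False,
) -> tuple[pd.DataFrame, QCReport]:
    """Quality-control filter on a dosage table (individuals x markers).

    Missing values are NaN or -1.  Markers, then individuals, with a
    missing rate above ``max_missing_rate`` are dropped.  With
    ``is_dh=True``, markers then individuals with a heterozygous-call rate
    above ``max_het_rate_dh`` are additionally dropped and the remaining
    heterozygous calls are set to missing.
    """
    df = genotype_table.astype(float).replace(MISSING, np.nan)
    rep = dict.fromkeys(
        ("markers_missing_removed", "individuals_missing_removed",
         "markers_het_removed", "individuals_het_removed", "het_calls_set_missing"), 0)

    miss_m = df.isna().mean(axis=0)
    keep_m = miss_m <= max_missing_rate
    rep["markers_missing_removed"] = int((~keep_m).sum())
    df = df.loc[:, keep_m]
    miss_i = df.isna().mean(axis=1)
    keep_i = miss_i <= max_missing_rate
    rep["individuals_missing_removed"] = int((~keep_i).sum())
    df = df.loc[keep_i]

    if is_dh:
        het_m = (df == 1).mean(axis=0)
        keep_m = het_m <= max_het_rate_dh
        rep["markers_het_removed"] = int((~keep_m).sum())
        df = df.loc[:, keep_m]
        het_i = (df == 1).mean(axis=1)
        keep_i = het_i <= max_het_rate_dh
        rep["individuals_het_removed"] = int((~keep_i).sum())
        df = df.loc[keep_i]
        het_mask = df == 1
        rep["het_calls_set_missing"] = int(het_mask.to_numpy().sum())
        df = df.mask(het_mask)

    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"QC filtering removed everything: {rep}")
    return df, QCReport(**rep)
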