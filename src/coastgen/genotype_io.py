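"""Genotype I/O, LD pruning, diversity indices and PCA.

Genotypes live in a :class:`HaplotypeMatrix`: a (2N x L) matrix of 0/1
alleles (``-1`` = missing) with one pair of rows per diploid sample, plus
a :class:`VariantTable` of coordinates.  Positions are 1-based inclusive
at the file boundary (VCF/GFF convention) and kept that way in the
tables; window arithmetic converts internally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "VariantTable",
    "HaplotypeMatrix",
    "PopulationMap",
    "DiversityReport",
    "read_vcf",
    "write_vcf",
    "read_population_map",
    "ld_prune",
    "diversity_indices",
    "pca_coords",
]


class VariantTable(pd.DataFrame):
    """Per-variant coordinates: chrom, pos (1-based), ref, alt, id.

    A thin DataFrame subclass; positions must be strictly increasing
    within each chromosome and all records biallelic SNPs.
    """

    _metadata: list[str] = []

    @property
    def _constructor(self):
        return VariantTable

    @classmethod
    def from_arrays(cls, chrom, pos, ref=None, alt=None, vid=None) -> "VariantTable":
        n = len(pos)
        df = cls({
            "chrom": pd.Series(chrom, dtype=str),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": ref if ref is not None else ["A"] * n,
            "alt": alt if alt is not None else ["T"] * n,
            "id": vid if vid is not None else ["."] * n,
        })
        df.validate()
        return df

    def validate(self) -> None:
        for _, sub in self.groupby("chrom", sort=False):
            p = sub["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise ValueError("positions not strictly increasing within chrom")


@dataclass
class HaplotypeMatrix:
    """Phased (or flagged-unphased) alleles, 2 rows per sample.

    ``alleles`` is int8 with values {0, 1, -1(missing)}; row ``2*i`` and
    ``2*i + 1`` are the two haplotypes of ``sample_ids[i]``.
    """

    alleles: np.ndarray
    sample_ids: list[str]
    phased: bool = True

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] % 2 != 0:
            raise ValueError("alleles must be 2-D with an even row count")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("row count must equal 2 x number of samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def dosages(self) -> np.ndarray:
        """Per-sample alt-allele dosage (0/1/2, NaN where missing)."""
        a = self.alleles.astype(float)
        a[a == MISSING] = np.nan
        return a[0::2] + a[1::2]

    def subset_samples(self, sample_ids: list[str]) -> "HaplotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        rows = np.ravel([[2 * i, 2 * i + 1] for i in idx])
        return HaplotypeMatrix(self.alleles[rows], list(sample_ids), self.phased)

    def subset_sites(self, cols: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(self.alleles[:, cols], list(self.sample_ids), self.phased)


@dataclass
class PopulationMap:
    """sample_id -> (site, population) assignment."""

    site_of: dict[str, str]
    population_of: dict[str, str]

    @classmethod
    def from_tsv(cls, path: str) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        need = {"sample", "site", "population"}
        if not need.issubset(df.columns):
            raise ValueError(f"population map needs columns {sorted(need)}")
        return cls(
            site_of=dict(zip(df["sample"], df["site"])),
            population_of=dict(zip(df["sample"], df["population"])),
        )

    def to_tsv(self, path: str) -> None:
        pd.DataFrame({
            "sample": list(self.site_of),
            "site": [self.site_of[s] for s in self.site_of],
            "population": [self.population_of[s] for s in self.site_of],
        }).to_csv(path, sep="\t", index=False)

    def populations(self) -> list[str]:
        return sorted(set(self.population_of.values()))

    def sites(self) -> list[str]:
        return sorted(set(self.site_of.values()))

    def samples_in_population(self, pop: str) -> list[str]:
        return [s for s, p in self.population_of.items() if p == pop]

    def samples_at_site(self, site: str) -> list[str]:
        return [s for s, t in self.site_of.items() if t == site]


read_population_map = PopulationMap.from_tsv


@dataclass
class DiversityReport:
    """Per-population diversity summary.

    ho / hs are fractions in [0, 1]; fis = 1 - mean(Ho)/mean(Hs) over
    polymorphic SNPs; tajima_d is the across-window mean when supplied.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def read_vcf(path: str, pop_map: PopulationMap | None = None):
    """Read a VCF into (VariantTable, HaplotypeMatrix).

    Multiallelic and non-SNP records are skipped with a warning counter.
    Unphased genotypes are accepted; the matrix is then flagged
    ``phased=False`` (Rsb refuses such input).
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if pop_map is not None:
        missing = [s for s in samples if s not in pop_map.population_of]
        if missing:
            raise ValueError(f"samples absent from population map: {missing}")
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    all_phased = True
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        gt = np.asarray(rec.genotype.array())  # (N, 3): a0, a1, phased flag
        if not np.all(gt[:, 2] == 1):
            all_phased = False
        hap = gt[:, :2].astype(np.int8)  # -1 already marks missing
        rows.append(hap.reshape(-1))
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        ids.append(rec.ID or ".")
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    if n_skipped:
        log.warning("skipped %d multiallelic/non-SNP records", n_skipped)
    alleles = np.stack(rows, axis=1)
    variants = VariantTable.from_arrays(chroms, poss, refs, alts, ids)
    hap = HaplotypeMatrix(alleles, samples, phased=all_phased)
    col_missing = (hap.alleles == MISSING).all(axis=0)
    if col_missing.any():
        raise ValueError("VCF contains sites with no non-missing calls")
    frac_missing = float((hap.alleles == MISSING).mean())
    if frac_missing > 0:
        log.info("missing genotype fraction: %.4f", frac_missing)
    return variants, hap


def write_vcf(path: str, variants: VariantTable, hap: HaplotypeMatrix) -> None:
    """Write a minimal VCF v4.2 preserving GT fields."""
    sep = "|" if hap.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(hap.sample_ids) + "\n")
        a = hap.alleles
        for j in range(len(variants)):
            v = variants.iloc[j]
            gts = []
            for i in range(hap.n_samples):
                h0, h1 = a[2 * i, j], a[2 * i + 1, j]
                s0 = "." if h0 == MISSING else str(int(h0))
                s1 = "." if h1 == MISSING else str(int(h1))
                gts.append(f"{s0}{sep}{s1}")
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def _dosage_r2(dos: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of two dosage columns, pairwise-complete."""
    x, y = dos[:, i], dos[:, j]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2:
        return 0.0
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0  # monomorphic: r2 undefined, treat as unlinked
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(
    hap: HaplotypeMatrix,
    window_snps: int = 5,
    step_snps: int = 1,
    r2_max: float = 0.9,
) -> np.ndarray:
    """Greedy window LD pruning on genotype dosages.

    Within each sliding window of ``window_snps`` SNPs (advancing by
    ``step_snps``), any pair with r^2 > ``r2_max`` loses its
    later-position member.  Returns the sorted retained column indices.
    """
    dos = hap.dosages()
    L = hap.n_sites
    keep = np.ones(L, dtype=bool)
    for start in range(0, max(L - window_snps + 1, 1), step_snps):
        idx = [k for k in range(start, min(start + window_snps, L)) if keep[k]]
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if not keep[idx[b]]:
                    continue
                if _dosage_r2(dos, idx[a], idx[b]) > r2_max:
                    keep[idx[b]] = False  # drop the later-position SNP
    return np.flatnonzero(keep)


def diversity_indices(
    hap: HaplotypeMatrix,
    pop_map: PopulationMap,
    tajima_d: dict[str, float] | None = None,
) -> DiversityReport:
    """Per-population Ho, Hs (unbiased) and Fis averaged across SNPs.

    Ho = fraction of heterozygous samples per SNP; Hs = 2p(1-p) n/(n-1)
    with n the non-missing diploid count; Fis = 1 - mean(Ho)/mean(Hs)
    over SNPs polymorphic in the population.  Monomorphic SNPs contribute
    Ho = Hs = 0 to the plain averages but are excluded from Fis.
    """
    rows = []
    for pop in pop_map.populations():
        sub = hap.subset_samples(pop_map.samples_in_population(pop))
        if sub.n_samples < 2:
            raise ValueError(f"population {pop} has < 2 samples; Hs undefined")
        dos = sub.dosages()
        n = np.sum(~np.isnan(dos), axis=0).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nansum(dos, axis=0) / (2.0 * n)
            ho = np.nanmean(dos == 1, axis=0)
        hs = 2.0 * p * (1.0 - p) * n / np.maximum(n - 1.0, 1.0)
        poly = (p > 0) & (p < 1) & (n > 1)
        fis = 1.0 - ho[poly].mean() / hs[poly].mean() if poly.any() else np.nan
        rows.append({
            "population": pop,
            "n_samples": sub.n_samples,
            "Ho": float(ho.mean()),
            "Hs": float(hs.mean()),
            "Fis": float(fis),
            "mean_tajima_d": (tajima_d or {}).get(pop, np.nan),
        })
    return DiversityReport(pd.DataFrame(rows))


def pca_coords(hap: HaplotypeMatrix, n_components: int = 2):
    """PCA of scaled dosages.

    Dosages are centred and scaled by sqrt(p(1-p)) per SNP; scores come
    from the eigendecomposition of the sample covariance.  Returns
    (scores [N x k], explained-variance fractions [k]).
    """
    dos = hap.dosages()
    N, L = dos.shape
    if n_components > min(N, L):
        raise ValueError("more components than min(n_samples, n_sites)")
    col_mean = np.nanmean(dos, axis=0)
    p = col_mean / 2.0
    scale = np.sqrt(np.maximum(p * (1.0 - p), 0.0))
    keep = scale > 0
    if not keep.any():
        raise ValueError("all sites monomorphic; PCA undefined")
    X = (dos[:, keep] - col_mean[keep]) / scale[keep]
    X = np.where(np.isnan(X), 0.0, X)  # mean-impute missing after centering
    cov = X @ X.T / X.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = evals.sum()
    if total <= 1e-12:
        raise ValueError("zero total variance; samples identical")
    scores = evecs[:, :n_components] * np.sqrt(np.maximum(evals[:n_components], 0.0))
    return scores, evals[:n_components] / total
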