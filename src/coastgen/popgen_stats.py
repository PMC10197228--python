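"""Per-SNP and windowed population-genetic statistics.

Selection-signature scanning works on a sliding-window grid (default
50 kb windows advancing by 10 kb) over each chromosome and contrasts a
"north" population A against a "south" population B with four statistics:

* Weir & Cockerham (1984) FST, windowed as a ratio of sums of variance
  components;
* nucleotide diversity pi per population, and its log2 ratio
  omega = log2(pi_A / pi_B) — a hard sweep depresses pi in the swept
  population, pushing omega away from 0;
* Tajima's D per population — an excess of rare variants after a sweep
  drives D negative;
* Rsb, the standardized log-ratio of the site-integrated extended
  haplotype homozygosity (iES) between the two populations — extended
  haplotypes in the swept population push Rsb toward that population's
  side.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, HaplotypeMatrix, PopulationMap, VariantTable

log = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "window_grid",
    "wc_fst",
    "windowed_fst",
    "windowed_pi",
    "omega",
    "tajimas_d",
    "ehh_profile",
    "ies",
    "rsb",
    "window_stat_table",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in bp (start-anchored at position 1)."""

    size: int = 50_000
    step: int = 10_000

    def __post_init__(self) -> None:
        if self.size <= 0 or self.step <= 0 or self.step > self.size:
            raise ValueError("require 0 < step <= size")


def window_grid(chrom_lengths: dict[str, int], spec: WindowSpec) -> pd.DataFrame:
    """Tile each chromosome with windows [start, start+size-1] (1-based).

    The final partial window is kept only if it spans at least ``step`` bp.
    """
    rows = []
    for chrom, L in chrom_lengths.items():
        start = 1
        while start <= L:
            end = min(start + spec.size - 1, int(L))
            if end - start + 1 >= spec.step:
                rows.append((chrom, start, end))
            start += spec.step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _pop_freq_stats(hap: HaplotypeMatrix, pop_map: PopulationMap, pop: str):
    """Per-SNP (n_diploid, p_alt, het_fraction) for one population."""
    sub = hap.subset_samples(pop_map.samples_in_population(pop))
    dos = sub.dosages()
    n = np.sum(~np.isnan(dos), axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nansum(dos, axis=0) / np.maximum(2.0 * n, 1e-300)
        h = np.nansum(dos == 1, axis=0) / np.maximum(n, 1e-300)
    return n, p, h


def wc_fst(
    hap: HaplotypeMatrix,
    pop_map: PopulationMap,
    pop_a: str,
    pop_b: str,
) -> pd.DataFrame:
    """Weir & Cockerham (1984) two-population variance components per SNP.

    Returns a DataFrame with columns ``a, b, c, fst`` where
    fst = a / (a + b + c).  SNPs monomorphic across both populations get
    zero components and NaN fst (excluded from windowed ratio-of-sums).
    """
    n1, p1, h1 = _pop_freq_stats(hap, pop_map, pop_a)
    n2, p2, h2 = _pop_freq_stats(hap, pop_map, pop_b)
    if (n1 < 2).any() or (n2 < 2).any():
        raise ValueError("need >= 2 genotyped samples per population at every SNP")
    r = 2.0
    nbar = (n1 + n2) / r
    nc = r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)
    nc /= (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (
        s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = nbar / (nbar - 1.0) * (
        pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    mono = (pbar <= 0.0) | (pbar >= 1.0)
    a[mono] = b[mono] = c[mono] = 0.0
    denom = a + b + c
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fst = np.where(denom != 0.0, a / np.where(denom == 0, 1, denom), np.nan)
    fst[mono] = np.nan
    return pd.DataFrame({"a": a, "b": b, "c": c, "fst": fst})


def _window_snp_slices(variants: VariantTable, windows: pd.DataFrame):
    """Yield (window_row_index, snp_index_array) using searchsorted per chrom."""
    by_chrom = {}
    for chrom, sub in variants.groupby("chrom", sort=False):
        by_chrom[chrom] = (sub["pos"].to_numpy(), sub.index.to_numpy())
    for wi, w in windows.iterrows():
        if w.chrom not in by_chrom:
            yield wi, np.array([], dtype=int)
            continue
        pos, idx = by_chrom[w.chrom]
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end, side="right")
        yield wi, idx[lo:hi]


def windowed_fst(
    components: pd.DataFrame,
    variants: VariantTable,
    windows: pd.DataFrame,
) -> np.ndarray:
    """Ratio-of-sums windowed FST: sum(a) / sum(a+b+c) over window SNPs."""
    a = components["a"].to_numpy()
    abc = (components["a"] + components["b"] + components["c"]).to_numpy()
    out = np.full(len(windows), np.nan)
    for wi, idx in _window_snp_slices(variants, windows):
        denom = abc[idx].sum()
        if len(idx) and denom != 0.0:
            out[wi] = a[idx].sum() / denom
    return out


def _per_snp_pi(hap: HaplotypeMatrix, pop_map: PopulationMap, pop: str) -> np.ndarray:
    """Unbiased per-SNP heterozygosity 2p(1-p) n/(n-1), n = haplotype count."""
    sub = hap.subset_samples(pop_map.samples_in_population(pop))
    alle = sub.alleles
    ok = alle != MISSING
    n = ok.sum(axis=0).astype(float)
    cnt = np.where(ok, alle, 0).sum(axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = cnt / np.maximum(n, 1)
    return 2.0 * p * (1.0 - p) * n / np.maximum(n - 1.0, 1.0)


def windowed_pi(
    hap: HaplotypeMatrix,
    pop_map: PopulationMap,
    pop: str,
    variants: VariantTable,
    windows: pd.DataFrame,
) -> np.ndarray:
    """Per-window nucleotide diversity per bp.

    Window pi = sum of per-SNP unbiased heterozygosity divided by the full
    window span.  Windows without SNPs get 0 (monomorphic, low-information).
    """
    per_snp = _per_snp_pi(hap, pop_map, pop)
    out = np.zeros(len(windows))
    spans = (windows["end"] - windows["start"] + 1).to_numpy().astype(float)
    for wi, idx in _window_snp_slices(variants, windows):
        out[wi] = per_snp[idx].sum() / spans[wi]
    return out


def omega(pi_a: np.ndarray, pi_b: np.ndarray) -> np.ndarray:
    """omega = log2(pi_A / pi_B); NaN where either pi is 0."""
    pi_a, pi_b = np.asarray(pi_a, float), np.asarray(pi_b, float)
    if pi_a.shape != pi_b.shape:
        raise ValueError("mismatched window grids")
    out = np.full(pi_a.shape, np.nan)
    ok = (pi_a > 0) & (pi_b > 0)
    out[ok] = np.log2(pi_a[ok] / pi_b[ok])
    return out


def _tajima_constants(n: int):
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, e1, e2


def tajimas_d(
    hap: HaplotypeMatrix,
    pop_map: PopulationMap,
    pop: str,
    variants: VariantTable,
    windows: pd.DataFrame,
) -> np.ndarray:
    """Tajima (1989) D per window from S and mean pairwise differences.

    Uses the population's full haplotype count n for the normalizing
    constants; windows with no segregating sites are NaN.
    """
    sub = hap.subset_samples(pop_map.samples_in_population(pop))
    n = 2 * sub.n_samples
    if n < 4:
        raise ValueError("Tajima's D needs >= 4 haplotypes")
    a1, e1, e2 = _tajima_constants(n)
    alle = sub.alleles
    ok = alle != MISSING
    nh = ok.sum(axis=0).astype(float)
    cnt = np.where(ok, alle, 0).sum(axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = cnt / np.maximum(nh, 1)
    seg = (p > 0) & (p < 1)
    # mean pairwise differences per SNP: 2 p (1-p) nh/(nh-1)
    k_snp = 2.0 * p * (1.0 - p) * nh / np.maximum(nh - 1.0, 1.0)
    out = np.full(len(windows), np.nan)
    for wi, idx in _window_snp_slices(variants, windows):
        S = int(seg[idx].sum())
        if S == 0:
            continue
        k = k_snp[idx].sum()
        theta_w = S / a1
        var = e1 * S + e2 * S * (S - 1.0)
        if var <= 0:
            continue
        out[wi] = (k - theta_w) / np.sqrt(var)
    return out


# ---------------------------------------------------------------------------
# Extended haplotype homozygosity


def _group_homozygosity(groups: np.ndarray) -> float:
    """sum_h C(n_h, 2) / C(n, 2) over distinct haplotype groups."""
    n = len(groups)
    if n < 2:
        return 0.0
    _, counts = np.unique(groups, return_counts=True)
    return float(np.sum(counts * (counts - 1)) / (n * (n - 1)))


def ehh_profile(
    hap: HaplotypeMatrix,
    focal_snp: int,
    allele: int,
) -> tuple[np.ndarray, np.ndarray]:
    """EHH of one focal allele at every site of the matrix.

    EHH(x) = sum over distinct extended haplotypes (focal..x) of
    C(n_h, 2) / C(n_c, 2) among the n_c carriers.  Returns (site index
    array, EHH array) covering all sites; EHH at the focal site is 1 and
    is non-increasing moving away from it.
    """
    if not hap.phased:
        raise ValueError("EHH requires phased haplotypes")
    carriers = hap.alleles[:, focal_snp] == allele
    n_c = int(carriers.sum())
    if n_c < 2:
        raise ValueError("focal allele carried by < 2 haplotypes")
    alle = hap.alleles[carriers]
    L = hap.n_sites
    ehh = np.zeros(L)
    ehh[focal_snp] = 1.0
    for direction in (1, -1):
        groups = np.zeros(n_c, dtype=np.int64)
        j = focal_snp + direction
        while 0 <= j < L:
            groups = _extend_groups(groups, alle[:, j])
            ehh[j] = _group_homozygosity(groups)
            j += direction
    idx = np.arange(L)
    return idx, ehh


def _extend_groups(groups: np.ndarray, column: np.ndarray) -> np.ndarray:
    """Refine haplotype group ids by one more site (missing = own symbol)."""
    key = groups * 3 + (column.astype(np.int64) + 1)  # alleles in {-1,0,1} -> {0,1,2}
    _, new = np.unique(key, return_inverse=True)
    return new


def _ehhs_one_side(
    alle: np.ndarray,
    pos: np.ndarray,
    focal: int,
    direction: int,
    cutoff: float,
    max_extend: int,
) -> float:
    """Trapezoid integral of EHHS from the focal SNP outward (one side), in bp.

    EHHS is the allele-frequency-weighted average of per-allele EHH
    (Tang-style), which at each step equals the group homozygosity
    within each focal-allele class, weighted by class frequency.
    Integration stops when EHHS drops below ``cutoff``, at the end of the
    chromosome's SNPs, or after ``max_extend`` SNPs.
    """
    n = alle.shape[0]
    focal_col = alle[:, focal]
    classes = {}
    for val in np.unique(focal_col):
        classes[val] = np.flatnonzero(focal_col == val)
    weights = {val: len(idx) / n for val, idx in classes.items()}
    groups = {val: np.zeros(len(idx), dtype=np.int64) for val, idx in classes.items()}
    ehhs_prev = 1.0
    pos_prev = pos[focal]
    total = 0.0
    j = focal + direction
    steps = 0
    L = alle.shape[1]
    while 0 <= j < L and steps < max_extend:
        ehhs = 0.0
        for val, idx in classes.items():
            if len(idx) < 2:
                continue
            groups[val] = _extend_groups(groups[val], alle[idx, j])
            ehhs += weights[val] * _group_homozygosity(groups[val])
        dist = abs(float(pos[j]) - float(pos_prev))
        total += 0.5 * (ehhs_prev + ehhs) * dist
        if ehhs < cutoff:
            break
        ehhs_prev, pos_prev = ehhs, pos[j]
        j += direction
        steps += 1
    return total


def ies(
    hap: HaplotypeMatrix,
    variants: VariantTable,
    ehh_cutoff: float = 0.05,
    max_extend: int = 1000,
) -> np.ndarray:
    """Site-integrated EHHS (iES) per SNP for one population's haplotypes.

    The integral runs in physical bp on both sides of each focal SNP
    until EHHS < ``ehh_cutoff`` and never crosses a chromosome boundary.
    """
    if not hap.phased:
        raise ValueError("iES requires phased haplotypes")
    out = np.zeros(hap.n_sites)
    for chrom, sub in variants.groupby("chrom", sort=False):
        cols = sub.index.to_numpy()
        alle = hap.alleles[:, cols]
        pos = sub["pos"].to_numpy()
        for k in range(len(cols)):
            left = _ehhs_one_side(alle, pos, k, -1, ehh_cutoff, max_extend)
            right = _ehhs_one_side(alle, pos, k, +1, ehh_cutoff, max_extend)
            out[cols[k]] = left + right
    return out


def rsb(
    hap: HaplotypeMatrix,
    pop_map: PopulationMap,
    pop_a: str,
    pop_b: str,
    variants: VariantTable,
    windows: pd.DataFrame | None = None,
    ehh_cutoff: float = 0.05,
    center: str = "median",
    max_extend: int = 1000,
):
    """Standardized Rsb per SNP (and optional per-window means).

    lnRatio = ln(iES_A / iES_B); standardized genome-wide as
    (lnRatio - center) / SD with median (default) or mean centering.
    SNPs where either iES is 0 are NaN.  Returns (per-SNP Rsb, per-window
    mean or None).
    """
    hap_a = hap.subset_samples(pop_map.samples_in_population(pop_a))
    hap_b = hap.subset_samples(pop_map.samples_in_population(pop_b))
    ies_a = ies(hap_a, variants, ehh_cutoff, max_extend)
    ies_b = ies(hap_b, variants, ehh_cutoff, max_extend)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lnr = np.where((ies_a > 0) & (ies_b > 0),
                       np.log(np.maximum(ies_a, 1e-300) / np.maximum(ies_b, 1e-300)),
                       np.nan)
    ok = ~np.isnan(lnr)
    if ok.sum() < 2:
        raise ValueError("too few SNPs with defined iES ratio")
    loc = np.nanmedian(lnr) if center == "median" else np.nanmean(lnr)
    sd = np.nanstd(lnr)
    # identical populations give identically-zero log-ratios; leave them at 0
    z = (lnr - loc) / sd if sd > 0 else lnr - loc
    win_mean = None
    if windows is not None:
        win_mean = np.full(len(windows), np.nan)
        for wi, idx in _window_snp_slices(variants, windows):
            vals = z[idx]
            vals = vals[~np.isnan(vals)]
            if len(vals):
                win_mean[wi] = vals.mean()
    return z, win_mean


def window_stat_table(
    hap: HaplotypeMatrix,
    variants: VariantTable,
    pop_map: PopulationMap,
    pop_a: str,
    pop_b: str,
    chrom_lengths: dict[str, int],
    spec: WindowSpec = WindowSpec(),
    ehh_cutoff: float = 0.05,
    max_extend: int = 1000,
) -> pd.DataFrame:
    """Assemble the full per-window statistic table for a two-population scan.

    Columns: chrom, start, end, n_snps, fst, pi_a, pi_b, omega, rsb_mean,
    tajd_a, tajd_b.
    """
    windows = window_grid(chrom_lengths, spec)
    comp = wc_fst(hap, pop_map, pop_a, pop_b)
    fst_w = windowed_fst(comp, variants, windows)
    pi_a = windowed_pi(hap, pop_map, pop_a, variants, windows)
    pi_b = windowed_pi(hap, pop_map, pop_b, variants, windows)
    om = omega(pi_a, pi_b)
    _, rsb_w = rsb(hap, pop_map, pop_a, pop_b, variants, windows,
                   ehh_cutoff=ehh_cutoff, max_extend=max_extend)
    td_a = tajimas_d(hap, pop_map, pop_a, variants, windows)
    td_b = tajimas_d(hap, pop_map, pop_b, variants, windows)
    n_snps = np.zeros(len(windows), dtype=int)
    for wi, idx in _window_snp_slices(variants, windows):
        n_snps[wi] = len(idx)
    out = windows.copy()
    out["n_snps"] = n_snps
    out["fst"] = fst_w
    out["pi_a"] = pi_a
    out["pi_b"] = pi_b
    out["omega"] = om
    out["rsb_mean"] = rsb_w
    out["tajd_a"] = td_a
    out["tajd_b"] = td_b
    return out
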