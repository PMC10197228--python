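"""Independent brute-force implementations used as test oracles.

Everything here is coded separately from the package (explicit loops,
textbook formulas, no shared helpers) so that agreement with the
vectorised implementations is meaningful.
"""

from __future__ import annotations

import math
from itertools import combinations


def wc_fst_oracle(geno_a: list[tuple[int, int]], geno_b: list[tuple[int, int]]):
    """Weir & Cockerham (1984) variance components for one SNP, two samples.

    ``geno_a`` / ``geno_b`` are lists of diploid genotypes (allele pairs,
    0/1).  Returns (a, b, c).
    """
    r = 2
    pops = [geno_a, geno_b]
    n = [len(g) for g in pops]
    p = []
    h = []
    for g in pops:
        alleles = [x for pair in g for x in pair]
        p.append(sum(alleles) / len(alleles))
        h.append(sum(1 for x, y in g if x != y) / len(g))
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (s2 - (1 / (nbar - 1))
                       * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                               - ((2 * nbar - 1) / (4 * nbar)) * hbar)
    c = hbar / 2
    return a, b, c


def pi_allpairs_oracle(haplotypes: list[list[int]]) -> float:
    """Mean pairwise difference count over all haplotype pairs (one window).

    Includes the n/(n-1) unbiased correction implicitly: the all-pairs
    mean IS the unbiased estimator.
    """
    n = len(haplotypes)
    total = 0
    count = 0
    for i, j in combinations(range(n), 2):
        total += sum(1 for x, y in zip(haplotypes[i], haplotypes[j]) if x != y)
        count += 1
    return total / count if count else 0.0


def tajimas_d_oracle(haplotypes: list[list[int]]) -> float:
    """Tajima (1989) D from scratch for one window of phased haplotypes."""
    n = len(haplotypes)
    L = len(haplotypes[0])
    S = 0
    for j in range(L):
        col = {h[j] for h in haplotypes}
        if len(col) > 1:
            S += 1
    if S == 0:
        return float("nan")
    k = pi_allpairs_oracle(haplotypes)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (k - S / a1) / math.sqrt(var)


def ehh_oracle(haplotypes: list[list[int]], focal: int, allele: int,
               target: int) -> float:
    """EHH at site ``target`` for carriers of ``allele`` at ``focal``.

    Counts distinct extended haplotypes between focal and target by
    string comparison.
    """
    carriers = [h for h in haplotypes if h[focal] == allele]
    nc = len(carriers)
    lo, hi = min(focal, target), max(focal, target)
    groups: dict[tuple, int] = {}
    for h in carriers:
        key = tuple(h[lo:hi + 1])
        groups[key] = groups.get(key, 0) + 1
    num = sum(g * (g - 1) // 2 for g in groups.values())
    den = nc * (nc - 1) // 2
    return num / den


def law_of_cosines_km(lat1, lon1, lat2, lon2, radius=6371.393) -> float:
    """Spherical law-of-cosines great-circle distance (independent of the
    haversine route)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    cosc = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return radius * math.acos(max(-1.0, min(1.0, cosc)))


def gaussian_aic_bic(y, yhat, k):
    """Closed-form AIC/BIC from the Gaussian MLE log-likelihood."""
    n = len(y)
    sse = sum((a - b) ** 2 for a, b in zip(y, yhat))
    ll = -0.5 * n * (math.log(2 * math.pi * sse / n) + 1.0)
    return 2 * k - 2 * ll, k * math.log(n) - 2 * ll


def interval_overlap_oracle(genes, regions):
    """All-pairs inclusive-coordinate overlap scan."""
    hits = []
    for gid, gchrom, gstart, gend in genes:
        for rchrom, rstart, rend in regions:
            if gchrom == rchrom and gstart <= rend and gend >= rstart:
                hits.append(gid)
                break
    return hits


def nearest_region_distance_oracle(chrom, pos, regions):
    """Linear scan for the distance from a SNP to the nearest region."""
    best = None
    for rchrom, rstart, rend in regions:
        if rchrom != chrom:
            continue
        if rstart <= pos <= rend:
            return 0
        d = min(abs(pos - rstart), abs(pos - rend))
        best = d if best is None else min(best, d)
    return best
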