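"""Genotype-environment association.

Two complementary detectors of temperature-associated loci:

* a covariance-corrected Bayes factor per SNP — per-SNP standardized
  population allele frequencies and the covariate are whitened by the
  inverse square root of the across-population covariance matrix (so
  shared drift does not masquerade as an environmental effect), and the
  evidence for the covariate term is summarised by the BIC approximation
  BF = exp((BIC0 - BIC1)/2), reported in decibans (10*log10 BF) with the
  decisive-evidence rule BF > 20 dB;
* redundancy-analysis (RDA) outliers — individual dosages are regressed
  on the environmental covariates, the fitted matrix is decomposed by
  SVD, and each SNP's loadings on the constrained axes are converted to
  a chi-square statistic.

Candidate SNPs are the intersection of the two detectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import HaplotypeMatrix, PopulationMap
from .selection_scan import GeneModel

log = logging.getLogger(__name__)

__all__ = [
    "PopFreqMatrix",
    "pop_freqs",
    "pop_covariance",
    "bayes_factor",
    "rda_outliers",
    "intersect_candidates",
    "genes_near_snps",
]

BF_DECISIVE_DB = 20.0


@dataclass
class PopFreqMatrix:
    """Allele frequencies per population (or site) x SNP, with sample sizes."""

    freqs: np.ndarray  # (P, L) in [0, 1]
    sizes: np.ndarray  # (P, L) haplotype counts
    labels: list[str]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.sizes = np.asarray(self.sizes, float)
        if self.freqs.min() < 0 or self.freqs.max() > 1:
            raise ValueError("frequencies outside [0, 1]")


def pop_freqs(hap: HaplotypeMatrix, pop_map: PopulationMap,
              by: str = "site") -> PopFreqMatrix:
    """Allele-frequency matrix per site (default) or per population."""
    groups = pop_map.sites() if by == "site" else pop_map.populations()
    getter = pop_map.samples_at_site if by == "site" else pop_map.samples_in_population
    F, S = [], []
    for g in groups:
        sub = hap.subset_samples(getter(g))
        alle = sub.alleles
        ok = alle != -1
        n = ok.sum(axis=0).astype(float)
        cnt = np.where(ok, alle, 0).sum(axis=0).astype(float)
        F.append(cnt / np.maximum(n, 1))
        S.append(n)
    return PopFreqMatrix(np.array(F), np.array(S), list(groups))


def _standardize_freqs(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center by across-population mean and scale by sqrt(pbar(1-pbar)).

    Returns (standardized (P, L) matrix, boolean mask of polymorphic SNPs).
    """
    pbar = freqs.mean(axis=0)
    poly = (pbar > 0) & (pbar < 1)
    scale = np.sqrt(np.maximum(pbar * (1 - pbar), 1e-300))
    return (freqs - pbar) / scale, poly


def pop_covariance(fm: PopFreqMatrix) -> np.ndarray:
    """Across-population covariance of standardized allele frequencies.

    SNPs monomorphic across all populations are dropped first.  The
    result is symmetric positive semi-definite (P x P).
    """
    P, L = fm.freqs.shape
    if L < 10 * P:
        raise ValueError(f"need >= {10 * P} SNPs to estimate a {P}x{P} covariance")
    X, poly = _standardize_freqs(fm.freqs)
    X = X[:, poly]
    omega = X @ X.T / X.shape[1]
    return (omega + omega.T) / 2.0


def _inv_sqrt(omega: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    evals, evecs = np.linalg.eigh(omega)
    if evals.min() < ridge:
        evals = evals + ridge
    if evals.min() <= 0:
        raise ValueError("population covariance singular after regularization")
    return evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T


def bayes_factor(
    fm: PopFreqMatrix,
    covariate: np.ndarray,
    omega: np.ndarray | None = None,
) -> np.ndarray:
    """Per-SNP Bayes factor (deciban) for one environmental covariate.

    Standardized frequencies and the (z-scored) covariate are whitened by
    Omega^(-1/2); each SNP is then fit by linear regression with and
    without the covariate, and BF = exp((BIC0 - BIC1)/2) is returned as
    10*log10(BF) dB.  Monomorphic SNPs get -inf.
    """
    cov = np.asarray(covariate, float)
    P = fm.freqs.shape[0]
    if len(cov) != P:
        raise ValueError("covariate length != number of populations")
    if cov.std() == 0:
        raise ValueError("constant covariate")
    cov = (cov - cov.mean()) / cov.std()
    if omega is None:
        omega = pop_covariance(fm)
    W = _inv_sqrt(omega)
    X, poly = _standardize_freqs(fm.freqs)
    Y = W @ X  # whitened frequencies, (P, L)
    ones_w = W @ np.ones(P)
    cov_w = W @ cov
    n = P

    def _bic(design: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
        resid = Y - design @ beta
        rss = np.maximum((resid ** 2).sum(axis=0), 1e-300)
        k = design.shape[1]
        return n * np.log(rss / n) + k * np.log(n)

    bic0 = _bic(ones_w[:, None])
    bic1 = _bic(np.column_stack([ones_w, cov_w]))
    ln_bf = (bic0 - bic1) / 2.0
    db = 10.0 * ln_bf / np.log(10.0)
    db[~poly] = -np.inf
    return db


def rda_outliers(
    hap_or_dosage: HaplotypeMatrix | np.ndarray,
    env: np.ndarray,
    n_axes: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """RDA outlier p-values per SNP.

    ``env`` is (N x q) per-sample covariates (site values broadcast to
    samples by the caller).  Dosages are centred, regressed on the
    covariates, and the fitted matrix SVD gives the constrained axes.
    Per SNP, loadings on the retained axes are z-scored per axis and
    summed as z^2; p comes from chi-square with df = retained axes.
    Returns (statistic, p).
    """
    G = (hap_or_dosage.dosages() if isinstance(hap_or_dosage, HaplotypeMatrix)
         else np.asarray(hap_or_dosage, float))
    G = np.where(np.isnan(G), np.nanmean(G, axis=0), G)
    G = G - G.mean(axis=0)
    E = np.asarray(env, float)
    if E.ndim == 1:
        E = E[:, None]
    if E.shape[0] != G.shape[0]:
        raise ValueError("env rows must match samples")
    Es = (E - E.mean(axis=0)) / E.std(axis=0)
    corr = np.corrcoef(Es.T) if Es.shape[1] > 1 else np.array([[1.0]])
    off = corr[~np.eye(len(corr), dtype=bool)]
    if len(off) and np.max(np.abs(off)) > 1 - 1e-12:
        i, j = np.unravel_index(np.argmax(np.abs(corr - np.eye(len(corr)))), corr.shape)
        raise ValueError(f"covariates {i} and {j} are collinear")
    design = np.column_stack([np.ones(G.shape[0]), Es])
    beta, *_ = np.linalg.lstsq(design, G, rcond=None)
    fitted = design @ beta
    q = Es.shape[1] if n_axes is None else n_axes
    U, s, Vt = np.linalg.svd(fitted - fitted.mean(axis=0), full_matrices=False)
    load = (Vt[:q].T * s[:q])  # (L, q) SNP loadings on constrained axes
    mu = load.mean(axis=0)
    sd = load.std(axis=0)
    sd[sd == 0] = 1.0
    z = (load - mu) / sd
    stat = (z ** 2).sum(axis=1)
    p = stats.chi2.sf(stat, df=q)
    return stat, p


def intersect_candidates(
    snps: pd.DataFrame,
    bf_db: dict[str, np.ndarray],
    rda_p: np.ndarray,
    rda_alpha: float = 0.001,
    bf_threshold: float = BF_DECISIVE_DB,
) -> pd.DataFrame:
    """Candidate SNPs: decisive BF for a covariate AND RDA p < alpha.

    ``bf_db`` maps covariate name -> per-SNP BF (dB).  The threshold is a
    strict inequality (BF = 20 dB exactly is not a hit).  Returns the SNP
    table with per-covariate hit flags, ``rda_hit``, ``candidate`` and a
    ``tag`` naming the covariate(s) driving each candidate.
    """
    out = snps.reset_index(drop=True).copy()
    names = list(bf_db)
    any_bf = np.zeros(len(out), dtype=bool)
    for name in names:
        v = np.asarray(bf_db[name], float)
        if len(v) != len(out):
            raise ValueError("BF vector length != SNP count")
        hit = v > bf_threshold
        out[f"bf_db_{name}"] = v
        out[f"bf_hit_{name}"] = hit
        any_bf |= hit
    out["rda_p"] = np.asarray(rda_p, float)
    out["rda_hit"] = out["rda_p"] < rda_alpha
    out["candidate"] = any_bf & out["rda_hit"]
    tags = []
    for i in range(len(out)):
        if not out.loc[i, "candidate"]:
            tags.append("")
            continue
        hit_names = [n for n in names if out.loc[i, f"bf_hit_{n}"]]
        tags.append("both" if len(hit_names) > 1 else hit_names[0])
    out["tag"] = tags
    return out


def genes_near_snps(
    candidates: pd.DataFrame,
    genes: list[GeneModel],
    radius: int = 5000,
) -> list[str]:
    """Genes whose body lies within ``radius`` bp of any candidate SNP.

    Distance is 0 when the SNP falls inside the gene body; the boundary
    is inclusive (distance == radius is a hit).
    """
    hits = []
    for g in genes:
        sub = candidates[candidates["chrom"].astype(str) == g.chrom]
        if len(sub) == 0:
            continue
        pos = sub["pos"].to_numpy()
        dist = np.where(
            (pos >= g.start) & (pos <= g.end), 0,
            np.minimum(np.abs(pos - g.start), np.abs(pos - g.end)),
        )
        if (dist <= radius).any():
            hits.append(g.gene_id)
    return hits
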