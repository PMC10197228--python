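"""Composite selection score and positively-selected region/gene calling.

The composite selection score (CSS) rank-transforms each window
statistic to a normal z, averages the z across statistics, rescales by
sqrt(k) so the null is standard normal, and reports -log10 of the
upper-tail p.  Positively selected regions (PSRs) are runs of windows
jointly in the 95th-percentile tails of FST, |omega| and |Rsb|, assigned
to a population side by the sign concordance of omega and Rsb (a sweep
reduces diversity and extends haplotypes in the same population).
Genes whose bodies overlap a PSR by at least 1 bp are positively
selected genes (PSGs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "SelectionRegion",
    "read_gff_genes",
    "css",
    "call_psrs",
    "call_psgs",
    "snp_to_psr_distance",
    "compare_psr_strength",
    "regions_to_frame",
]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"


@dataclass
class SelectionRegion:
    """A merged run of qualifying windows, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    side: str  # "A" or "B"
    window_ids: list[int] = field(default_factory=list)
    mean_fst: float = float("nan")
    mean_omega: float = float("nan")
    mean_rsb: float = float("nan")

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("region end < start")


def read_gff_genes(path: str) -> list[GeneModel]:
    """Extract gene features from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(path, ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("ID", [g.id])[0]
        genes.append(GeneModel(gid, g.seqid, g.start, g.end, g.strand or "+"))
    return genes


def css(stats_table: pd.DataFrame,
        statistics: list[str] = ("fst", "omega_abs", "rsb_abs")) -> pd.DataFrame:
    """Composite selection score per window.

    For each statistic column (oriented so larger = more selected):
    fractional rank r = rank/(n+1) with average ranks for ties,
    z = Phi^-1(r).  The mean z across the k statistics is rescaled by
    sqrt(k); p = 1 - Phi(zbar * sqrt(k)); CSS = -log10(p).  Windows with
    a missing value in any column are excluded (NaN throughout).
    """
    statistics = list(statistics)
    cols = {}
    valid = np.ones(len(stats_table), dtype=bool)
    for s in statistics:
        v = stats_table[s].to_numpy(dtype=float)
        valid &= ~np.isnan(v)
    n = int(valid.sum())
    if n < 10:
        raise ValueError("need >= 10 windows with complete statistics for CSS")
    zsum = np.zeros(n)
    out = pd.DataFrame(index=stats_table.index)
    for s in statistics:
        v = stats_table[s].to_numpy(dtype=float)[valid]
        if np.all(v == v[0]):
            log.warning("CSS statistic %r is constant; all ranks tied", s)
        r = stats.rankdata(v, method="average") / (n + 1.0)
        z = stats.norm.ppf(r)
        zsum += z
        full_r = np.full(len(stats_table), np.nan)
        full_z = np.full(len(stats_table), np.nan)
        full_r[valid], full_z[valid] = r, z
        out[f"rank_{s}"] = full_r
        out[f"z_{s}"] = full_z
    k = len(statistics)
    zbar = zsum / k
    p = stats.norm.sf(zbar * np.sqrt(k))
    p = np.maximum(p, 1e-300)
    full_zbar = np.full(len(stats_table), np.nan)
    full_p = np.full(len(stats_table), np.nan)
    full_css = np.full(len(stats_table), np.nan)
    full_zbar[valid] = zbar
    full_p[valid] = p
    full_css[valid] = -np.log10(p)
    out["z_mean"] = full_zbar
    out["p"] = full_p
    out["css"] = full_css
    return out


def call_psrs(
    stats_table: pd.DataFrame,
    percentile: float = 0.95,
    max_gap: int = 0,
) -> tuple[list[SelectionRegion], list[SelectionRegion]]:
    """Call positively selected regions from the window statistic table.

    A window qualifies when FST, |omega| and |Rsb| are all at or above
    their genome-wide ``percentile`` cutoffs.  Qualifying windows with
    omega < 0 and Rsb > 0 belong to side A (diversity reduced, haplotypes
    extended in population A); omega > 0 and Rsb < 0 to side B; windows
    with discordant signs are discarded (count logged).  Overlapping or
    abutting same-side windows (gap <= ``max_gap`` bp) merge into maximal
    regions.  Returns (A-side regions, B-side regions).
    """
    df = stats_table.reset_index(drop=True)
    if len(df) < 20:
        raise ValueError("need >= 20 windows for a stable percentile cutoff")
    fst = df["fst"].to_numpy(float)
    om = df["omega"].to_numpy(float)
    rs = df["rsb_mean"].to_numpy(float)
    q = percentile * 100.0
    fst_cut = np.nanpercentile(fst, q)
    om_cut = np.nanpercentile(np.abs(om), q)
    rs_cut = np.nanpercentile(np.abs(rs), q)
    with np.errstate(invalid="ignore"):
        qual = (fst >= fst_cut) & (np.abs(om) >= om_cut) & (np.abs(rs) >= rs_cut)
    qual &= ~(np.isnan(fst) | np.isnan(om) | np.isnan(rs))
    side = np.full(len(df), "", dtype=object)
    with np.errstate(invalid="ignore"):
        side[qual & (om < 0) & (rs > 0)] = "A"
        side[qual & (om > 0) & (rs < 0)] = "B"
    n_discord = int(qual.sum() - (side != "").sum())
    if n_discord:
        log.warning("discarded %d qualifying windows with discordant omega/Rsb signs",
                    n_discord)

    def _merge(tag: str) -> list[SelectionRegion]:
        sel = df[side == tag].sort_values(["chrom", "start"])
        regions: list[SelectionRegion] = []
        for _, w in sel.iterrows():
            if (regions and regions[-1].chrom == w.chrom
                    and w.start <= regions[-1].end + 1 + max_gap):
                regions[-1].end = max(regions[-1].end, int(w.end))
                regions[-1].window_ids.append(int(w.name))
            else:
                regions.append(SelectionRegion(str(w.chrom), int(w.start), int(w.end),
                                               tag, [int(w.name)]))
        for reg in regions:
            sub = df.loc[reg.window_ids]
            reg.mean_fst = float(sub["fst"].mean())
            reg.mean_omega = float(sub["omega"].mean())
            reg.mean_rsb = float(sub["rsb_mean"].mean())
        return regions

    return _merge("A"), _merge("B")


def regions_to_frame(regions: list[SelectionRegion]) -> pd.DataFrame:
    return pd.DataFrame([
        {"chrom": r.chrom, "start": r.start, "end": r.end, "side": r.side,
         "n_windows": len(r.window_ids), "mean_fst": r.mean_fst,
         "mean_omega": r.mean_omega, "mean_rsb": r.mean_rsb}
        for r in regions
    ], columns=["chrom", "start", "end", "side", "n_windows",
                "mean_fst", "mean_omega", "mean_rsb"])


def call_psgs(regions: list[SelectionRegion], genes: list[GeneModel]) -> list[str]:
    """Genes whose bodies overlap any region by >= 1 bp (inclusive coords)."""
    hits = []
    for g in genes:
        for r in regions:
            if g.chrom == r.chrom and g.start <= r.end and g.end >= r.start:
                hits.append(g.gene_id)
                break
    return hits


def snp_to_psr_distance(
    snps: pd.DataFrame,
    regions: list[SelectionRegion],
) -> np.ndarray:
    """Distance (bp) from each SNP to the nearest region; 0 inside, NaN if
    the SNP's chromosome carries no region."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for c in by_chrom:
        by_chrom[c].sort()
    out = np.full(len(snps), np.nan)
    for i, (chrom, pos) in enumerate(zip(snps["chrom"], snps["pos"])):
        regs = by_chrom.get(str(chrom))
        if not regs:
            continue
        best = np.inf
        for s, e in regs:
            if s <= pos <= e:
                best = 0
                break
            best = min(best, abs(pos - s), abs(pos - e))
        out[i] = best
    return out


def compare_psr_strength(
    stats_table: pd.DataFrame,
    regions_a: list[SelectionRegion],
    regions_b: list[SelectionRegion],
    columns: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One-way ANOVA of selection statistics, A-side vs B-side PSR windows.

    ``columns`` maps report names to stats_table columns; defaults cover
    CSS, FST, |omega|, |Rsb| and both populations' Tajima's D.  Returns a
    DataFrame with F and p per statistic (NaN + warning if constant).
    """
    if not regions_a or not regions_b:
        raise ValueError("need at least one region per side")
    ids_a = sorted({w for r in regions_a for w in r.window_ids})
    ids_b = sorted({w for r in regions_b for w in r.window_ids})
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("need >= 2 windows per side for ANOVA")
    df = stats_table.reset_index(drop=True)
    if columns is None:
        columns = {"fst": "fst", "omega_abs": "omega", "rsb_abs": "rsb_mean",
                   "tajd_a": "tajd_a", "tajd_b": "tajd_b"}
        if "css" in df.columns:
            columns["css"] = "css"
    rows = []
    for name, col in columns.items():
        va = df.loc[ids_a, col].to_numpy(float)
        vb = df.loc[ids_b, col].to_numpy(float)
        if name.endswith("_abs"):
            va, vb = np.abs(va), np.abs(vb)
        va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
        if len(va) < 2 or len(vb) < 2 or (np.ptp(np.r_[va, vb]) == 0):
            log.warning("ANOVA undefined for statistic %r", name)
            rows.append({"statistic": name, "F": np.nan, "p": np.nan,
                         "mean_A": np.nan if not len(va) else va.mean(),
                         "mean_B": np.nan if not len(vb) else vb.mean()})
            continue
        F, p = stats.f_oneway(va, vb)
        rows.append({"statistic": name, "F": float(F), "p": float(p),
                     "mean_A": float(va.mean()), "mean_B": float(vb.mean())})
    return pd.DataFrame(rows)
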