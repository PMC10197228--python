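"""Synthetic populations with planted sweeps and environmental clines.

The generator emulates the sampling design the analysis assumes: a
stepping-stone chain of demes along a latitudinal coastline, with

* neutral differentiation from forward binomial drift with symmetric
  nearest-neighbour migration (the isolation-by-distance premise:
  FST grows with deme separation),
* hard sweeps planted in designated intervals of the end-population
  demes (one random core haplotype copied into a fraction q0 of target
  haplotypes, allele identity decaying as exp(-d/r) with distance from
  the sweep centre — elevating FST and EHH and depressing pi locally),
* environment-associated loci whose allele frequencies follow the
  latitudinal SST cline,
* a daily SST series per site whose latitudinal gradient is much
  steeper in winter than in summer (the asymmetry characteristic of
  the Northwest-Pacific marginal seas), and a coastal water corridor
  raster for path distances.

Everything is deterministic under a fixed seed, and a truth table
records what was planted for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import HaplotypeMatrix, PopulationMap, VariantTable, write_vcf
from .geo_env import CoastGrid, SiteGeo

__all__ = [
    "SweepSpec",
    "SimConfig",
    "SimTruth",
    "default_config",
    "simulate_neutral",
    "plant_sweep",
    "make_environment",
    "emit_all",
    "simulate_bundle",
    "generate_ibd_ibe_pairs",
]

KM_PER_DEG = 111.19


@dataclass(frozen=True)
class SweepSpec:
    chrom: str
    center: int
    half_width: int
    target_demes: tuple[int, ...]
    side: str  # "A" (northern) or "B" (southern)
    q0: float = 0.95
    decay_r: float = 300_000.0

    @property
    def start(self) -> int:
        return self.center - self.half_width

    @property
    def end(self) -> int:
        return self.center + self.half_width


@dataclass
class SimConfig:
    n_demes: int = 6
    samples_per_deme: int = 10
    deme_size: int = 100  # diploid N; haplotype pool is 2N
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    n_snps: int = 20_000
    migration: float = 0.1
    generations: int = 200
    sweeps: list[SweepSpec] = field(default_factory=list)
    n_env_loci: int = 20
    env_cline_range: tuple[float, float] = (0.05, 0.95)
    lat_north: float = 38.0
    lat_south: float = 21.0
    sst_base: float = 18.0
    sst_amplitude: float = 8.0
    sst_gradient_winter: float = 0.9  # deg C per deg latitude
    sst_gradient_summer: float = 0.15
    sst_noise_sd: float = 0.5
    sst_years: int = 10
    grid_cell_km: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.migration <= 0.5):
            raise ValueError("migration rate must be in [0, 0.5]")
        for sw in self.sweeps:
            if sw.start < 1 or sw.end > self.chrom_length:
                raise ValueError(f"sweep outside chromosome bounds: {sw}")
            if not (0.0 < sw.q0 <= 1.0):
                raise ValueError("sweep carrier fraction q0 must be in (0, 1]")
            if sw.q0 * 2 * self.samples_per_deme < 2:
                raise ValueError("sweep would carry < 2 haplotypes; undetectable")


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The standard study-condition bundle: 6 demes x 10 samples, 2 x 5 Mb
    chromosomes, 20,000 SNPs, 10 northern + 10 southern planted sweeps."""
    cfg = SimConfig(seed=seed, **overrides)
    sweeps = []
    for ci in range(cfg.n_chrom):
        chrom = f"chr{ci + 1}"
        # 10 sweeps per side across the genome, but never denser than one
        # sweep pair per 300 kb so neutral background remains dominant
        n_per_side = max(1, min(10 // cfg.n_chrom, cfg.chrom_length // 300_000))
        spacing = cfg.chrom_length // (2 * n_per_side)
        for k in range(2 * n_per_side):
            center = spacing // 2 + k * spacing
            side = "A" if k % 2 == 0 else "B"
            demes = (0, 1) if side == "A" else (cfg.n_demes - 2, cfg.n_demes - 1)
            # interval matches the 50 kb scan window so each sweep owns
            # at least one undiluted full-strength window
            hw = min(25_000, spacing // 3)
            sweeps.append(SweepSpec(chrom, center, hw, demes, side))
    cfg.sweeps = sweeps
    return cfg


@dataclass
class SimTruth:
    sweeps: list[dict]
    env_loci: list[dict]
    site_latitudes: dict[str, float]
    ibd_ibe_weights: dict[str, float]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _site_positions(cfg: SimConfig, rng: np.random.Generator):
    """Variant table with sorted distinct positions on each chromosome."""
    per_chrom = cfg.n_snps // cfg.n_chrom
    chroms, poss = [], []
    for ci in range(cfg.n_chrom):
        n = per_chrom + (cfg.n_snps % cfg.n_chrom if ci == cfg.n_chrom - 1 else 0)
        pos = np.sort(rng.choice(np.arange(1, cfg.chrom_length + 1), size=n,
                                 replace=False))
        chroms.extend([f"chr{ci + 1}"] * n)
        poss.extend(pos.tolist())
    return VariantTable.from_arrays(chroms, poss)


def simulate_neutral(cfg: SimConfig):
    """Forward stepping-stone drift; returns (variants, freqs, pools, rngs).

    ``freqs`` is the (n_demes x L) final allele-frequency matrix;
    ``pools`` the per-deme (2N x L) haplotype pools sampled from it.
    """
    if cfg.migration > 0.5:
        raise ValueError("migration rate must be <= 0.5")
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_demes + 2)
    rng_global = np.random.default_rng(children[0])
    deme_rngs = [np.random.default_rng(c) for c in children[1:-1]]
    rng_env = np.random.default_rng(children[-1])

    variants = _site_positions(cfg, rng_global)
    L = len(variants)
    p0 = np.clip(rng_global.beta(0.8, 0.8, size=L), 0.02, 0.98)
    freqs = np.tile(p0, (cfg.n_demes, 1))
    two_n = 2 * cfg.deme_size
    m = cfg.migration
    for _ in range(cfg.generations):
        mixed = freqs.copy()
        if cfg.n_demes > 1 and m > 0:
            mixed[0] = (1 - m / 2) * freqs[0] + (m / 2) * freqs[1]
            mixed[-1] = (1 - m / 2) * freqs[-1] + (m / 2) * freqs[-2]
            for d in range(1, cfg.n_demes - 1):
                mixed[d] = (1 - m) * freqs[d] + (m / 2) * (freqs[d - 1] + freqs[d + 1])
        freqs = rng_global.binomial(two_n, mixed) / two_n

    # environment-associated loci: allele frequency follows the latitudinal
    # cline (monotone in deme index), overriding drift at those sites
    env_idx = _pick_env_loci(cfg, variants, rng_env)
    lo, hi = cfg.env_cline_range
    cline = np.linspace(hi, lo, cfg.n_demes)  # north (deme 0) high
    for j in env_idx:
        freqs[:, j] = cline

    pools = []
    for d in range(cfg.n_demes):
        pools.append(
            (deme_rngs[d].random((two_n, L)) < freqs[d]).astype(np.int8))
    return variants, freqs, pools, env_idx, deme_rngs


def _pick_env_loci(cfg: SimConfig, variants: VariantTable,
                   rng: np.random.Generator) -> np.ndarray:
    """Pick env loci away from sweep intervals (100 kb buffer, shrunk on
    short or sweep-dense chromosomes so eligible territory remains)."""
    ok = np.ones(len(variants), dtype=bool)
    chrom = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    per_chrom = max(1, max((sum(1 for s in cfg.sweeps if s.chrom == f"chr{c + 1}")
                            for c in range(cfg.n_chrom)), default=1))
    buffer = int(min(100_000, cfg.chrom_length / (4.0 * per_chrom)))
    for sw in cfg.sweeps:
        ok &= ~((chrom == sw.chrom) & (pos >= sw.start - buffer)
                & (pos <= sw.end + buffer))
    cand = np.flatnonzero(ok)
    if len(cand) == 0 and cfg.n_env_loci > 0:
        raise ValueError("no SNPs far enough from sweeps to host env loci; "
                         "reduce sweep density or chromosome coverage")
    n = min(cfg.n_env_loci, len(cand))
    return np.sort(rng.choice(cand, size=n, replace=False))


def plant_sweep(
    hap_by_deme: list[np.ndarray],
    freqs: np.ndarray,
    variants: VariantTable,
    sweep: SweepSpec,
    rng: np.random.Generator,
) -> None:
    """Plant one hard sweep in-place in the target demes' haplotypes.

    A random core haplotype is chosen per target deme; a fraction ``q0``
    of that deme's haplotypes is overwritten inside the sweep interval,
    each site keeping the core allele with probability exp(-d/r)
    (d = distance from the sweep centre) and otherwise redrawn from the
    deme's neutral frequency.  Non-target demes are untouched.
    """
    in_interval = ((variants["chrom"].to_numpy() == sweep.chrom)
                   & (variants["pos"].to_numpy() >= sweep.start)
                   & (variants["pos"].to_numpy() <= sweep.end))
    cols = np.flatnonzero(in_interval)
    if len(cols) < 10:
        raise ValueError(f"sweep interval contains {len(cols)} SNPs (< 10)")
    d_bp = np.abs(variants["pos"].to_numpy()[cols] - sweep.center)
    keep_prob = np.exp(-d_bp / sweep.decay_r)
    # one core haplotype per sweep: the same haplotype spreads through
    # every target deme, as in a single selective event
    first = hap_by_deme[sweep.target_demes[0]]
    core = first[rng.integers(first.shape[0]), cols].copy()
    for deme in sweep.target_demes:
        hap = hap_by_deme[deme]
        n_hap = hap.shape[0]
        n_carriers = max(2, int(round(sweep.q0 * n_hap)))
        carriers = rng.choice(n_hap, size=n_carriers, replace=False)
        for h in carriers:
            take_core = rng.random(len(cols)) < keep_prob
            fresh = (rng.random(len(cols)) < freqs[deme, cols]).astype(np.int8)
            hap[h, cols] = np.where(take_core, core, fresh)


def make_environment(cfg: SimConfig):
    """Site geography, daily SST series and a coastal corridor raster.

    Sites sit on a coastline polyline with monotone latitude; SST is a
    seasonal sinusoid whose latitudinal gradient interpolates between a
    weak summer and a strong winter value, plus Gaussian noise.
    Returns (sites, sst: DataFrame[date x site], grid).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 77]))
    lats = np.linspace(cfg.lat_north, cfg.lat_south, cfg.n_demes)
    # a bulging coastline: longitude swings west then east so the
    # along-coast path exceeds the great-circle chord
    t = np.linspace(0, 1, cfg.n_demes)
    lons = 117.0 + 4.0 * np.sin(np.pi * t)
    sites = [SiteGeo(f"S{i + 1}", float(lats[i]), float(lons[i]))
             for i in range(cfg.n_demes)]

    dates = pd.date_range("1971-01-01", periods=365 * cfg.sst_years, freq="D")
    doy = dates.dayofyear.to_numpy()
    season = np.sin(2 * np.pi * (doy - 105) / 365.0)  # +1 in midsummer
    grad = (cfg.sst_gradient_summer
            + (cfg.sst_gradient_winter - cfg.sst_gradient_summer) * (1 - season) / 2)
    lat_ref = lats.mean()
    data = {}
    for s in sites:
        mu = cfg.sst_base + cfg.sst_amplitude * season - grad * (s.lat - lat_ref)
        data[s.site_id] = mu + rng.normal(0, cfg.sst_noise_sd, len(dates))
    sst = pd.DataFrame(data, index=dates)
    sst.index.name = "date"

    grid = _coast_grid(sites, cfg.grid_cell_km)
    return sites, sst, grid


def _coast_grid(sites: list[SiteGeo], cell_km: float) -> CoastGrid:
    """Rasterize a water corridor along the site polyline (flat projection)."""
    lat0 = np.mean([s.lat for s in sites])
    xy = np.array([[(s.lon * KM_PER_DEG * np.cos(np.radians(lat0))),
                    s.lat * KM_PER_DEG] for s in sites])
    lo = xy.min(axis=0) - 3 * cell_km
    hi = xy.max(axis=0) + 3 * cell_km
    ncol = int(np.ceil((hi[0] - lo[0]) / cell_km)) + 1
    nrow = int(np.ceil((hi[1] - lo[1]) / cell_km)) + 1
    water = np.zeros((nrow, ncol), dtype=bool)

    def to_cell(p):
        return (int(round((p[1] - lo[1]) / cell_km)),
                int(round((p[0] - lo[0]) / cell_km)))

    for a, b in zip(xy[:-1], xy[1:]):
        n = max(2, int(np.ceil(np.linalg.norm(b - a) / (cell_km / 2))))
        for frac in np.linspace(0, 1, n):
            r, c = to_cell(a + frac * (b - a))
            water[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2] = True
    site_cells = {}
    for s, p in zip(sites, xy):
        r, c = to_cell(p)
        water[r, c] = True
        site_cells[s.site_id] = (r, c)
    return CoastGrid(water, cell_km=cell_km, site_cells=site_cells)


def simulate_bundle(cfg: SimConfig):
    """Run the whole generator in memory.

    Returns (variants, hap, pop_map, sites, sst, grid, truth).
    """
    variants, freqs, pools, env_idx, deme_rngs = simulate_neutral(cfg)
    n_hap_per_deme = 2 * cfg.samples_per_deme
    hap_by_deme = []
    for d in range(cfg.n_demes):
        rows = deme_rngs[d].choice(pools[d].shape[0], size=n_hap_per_deme,
                                   replace=False)
        hap_by_deme.append(pools[d][rows].copy())
    # the planted environmental association is exact at the sample level:
    # each env locus's realized haplotype counts follow the cline (up to
    # rounding), the way a decisively associated locus by definition does
    env_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 55]))
    lo, hi = cfg.env_cline_range
    cline = np.linspace(hi, lo, cfg.n_demes)
    for j in env_idx:
        for d in range(cfg.n_demes):
            n_hap = hap_by_deme[d].shape[0]
            k = int(round(cline[d] * n_hap))
            col = np.zeros(n_hap, dtype=np.int8)
            col[env_rng.choice(n_hap, size=k, replace=False)] = 1
            hap_by_deme[d][:, j] = col

    sweep_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 99]))
    for sw in cfg.sweeps:
        plant_sweep(hap_by_deme, freqs, variants, sw, sweep_rng)

    pop_of_deme = _population_labels(cfg.n_demes)
    sample_ids, site_of, population_of = [], {}, {}
    for d in range(cfg.n_demes):
        for k in range(cfg.samples_per_deme):
            sid = f"S{d + 1}_{k + 1:02d}"
            sample_ids.append(sid)
            site_of[sid] = f"S{d + 1}"
            population_of[sid] = pop_of_deme[d]
    alleles = np.vstack(hap_by_deme)
    hap = HaplotypeMatrix(alleles, sample_ids, phased=True)
    pop_map = PopulationMap(site_of, population_of)

    sites, sst, grid = make_environment(cfg)
    truth = SimTruth(
        sweeps=[{"chrom": sw.chrom, "start": sw.start, "end": sw.end,
                 "side": sw.side, "target_demes": list(sw.target_demes)}
                for sw in cfg.sweeps],
        env_loci=[{"index": int(j),
                   "chrom": str(variants["chrom"].iloc[j]),
                   "pos": int(variants["pos"].iloc[j])} for j in env_idx],
        site_latitudes={s.site_id: s.lat for s in sites},
        ibd_ibe_weights={"sst_gradient_winter": cfg.sst_gradient_winter,
                         "sst_gradient_summer": cfg.sst_gradient_summer,
                         "migration": cfg.migration},
    )
    return variants, hap, pop_map, sites, sst, grid, truth


def _population_labels(n_demes: int) -> list[str]:
    """Three populations: the two northernmost demes, the two southernmost,
    and everything between."""
    labels = []
    for d in range(n_demes):
        if d < 2:
            labels.append("north")
        elif d >= n_demes - 2:
            labels.append("south")
        else:
            labels.append("mid")
    return labels


def _make_genes(cfg: SimConfig, rng: np.random.Generator):
    """Gene models: one 20 kb gene inside each sweep + neutral background."""
    genes = []
    for i, sw in enumerate(cfg.sweeps):
        genes.append((f"gene_sweep_{i + 1}", sw.chrom,
                      sw.center - 10_000, sw.center + 10_000))
    sweep_iv = {}
    for sw in cfg.sweeps:
        sweep_iv.setdefault(sw.chrom, []).append((sw.start, sw.end))
    # enough candidate slots that >= 10 background genes survive the
    # sweep-proximity filter at any chromosome size
    n_cand = 12 // cfg.n_chrom + 2 + 2 * max(
        (len(v) for v in sweep_iv.values()), default=0)
    k = 0
    for ci in range(cfg.n_chrom):
        chrom = f"chr{ci + 1}"
        xs = np.linspace(0.04 * cfg.chrom_length, 0.92 * cfg.chrom_length,
                         n_cand).astype(int)
        gene_len = int(min(20_000, 0.6 * (xs[1] - xs[0])))
        for start in xs:
            end = start + gene_len
            if any(start <= e + 25_000 and end >= s - 25_000
                   for s, e in sweep_iv.get(chrom, [])):
                continue
            k += 1
            genes.append((f"gene_bg_{k}", chrom, int(start), int(end)))
    return genes


def emit_all(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full mutually consistent file bundle.

    Produces sim.vcf, popmap.tsv, sites.tsv, sst.csv, coast.grid,
    genes.gff3 and truth.json under ``outdir``; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    variants, hap, pop_map, sites, sst, grid, truth = simulate_bundle(cfg)
    paths = {k: outdir / v for k, v in {
        "vcf": "sim.vcf", "popmap": "popmap.tsv", "sites": "sites.tsv",
        "sst": "sst.csv", "coast": "coast.grid", "gff": "genes.gff3",
        "truth": "truth.json"}.items()}
    write_vcf(str(paths["vcf"]), variants, hap)
    pop_map.to_tsv(str(paths["popmap"]))
    pd.DataFrame({"site": [s.site_id for s in sites],
                  "lat": [s.lat for s in sites],
                  "lon": [s.lon for s in sites]}).to_csv(
        paths["sites"], sep="\t", index=False)
    sst.to_csv(paths["sst"])
    grid.to_ascii(str(paths["coast"]))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 13]))
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for ci in range(cfg.n_chrom):
            fh.write(f"##sequence-region chr{ci + 1} 1 {cfg.chrom_length}\n")
        for gid, chrom, start, end in _make_genes(cfg, rng):
            fh.write(f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}\n")
    truth.to_json(str(paths["truth"]))
    return paths


# ---------------------------------------------------------------------------
# Direct pair-table generator for the IBD/IBE recovery experiment


def generate_ibd_ibe_pairs(
    n_sites: int = 14,
    w_csl: float = 0.6,
    w_sst: float = 0.4,
    noise_sd: float = 0.02,
    seed: int = 0,
):
    """Site-pair table whose genetic distance is driven by known weights.

    Sites sit along a coast with a coastline coordinate and an SST_max
    value correlated with (but not identical to) position.  Genetic
    distance is w_csl * f(|dcsl|) + w_sst * g(|dSST|) + noise with
    saturating monotone f, g.  Returns (pairs, site_values, truth dict).
    """
    rng = np.random.default_rng(seed)
    coast = np.sort(rng.uniform(0, 2000, n_sites))  # km along the coast
    lat = 38.0 - coast / 2000.0 * 17.0
    sst = 18.0 + 0.9 * (38.0 - lat) + rng.normal(0, 1.2, n_sites)
    site_ids = [f"P{i + 1}" for i in range(n_sites)]
    site_values = pd.DataFrame({"D_csl": coast, "dSST_max": sst, "lat": lat},
                               index=site_ids)
    rows = []
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            dc = abs(coast[i] - coast[j])
            ds = abs(sst[i] - sst[j])
            g = (w_csl * (1 - np.exp(-dc / 800.0))
                 + w_sst * (1 - np.exp(-ds / 8.0))
                 + rng.normal(0, noise_sd))
            rows.append({"site_a": site_ids[i], "site_b": site_ids[j],
                         "D_csl": dc, "dSST_max": ds,
                         "gdist": max(g, 0.0)})
    pairs = pd.DataFrame(rows)
    truth = {"w_csl": w_csl, "w_sst": w_sst, "noise_sd": noise_sd}
    return pairs, site_values, truth


def generate_region_contrast_components(
    n_sites: int = 14,
    n_windows: int = 100,
    n_psr_windows: int = 10,
    seed: int = 0,
):
    """Per-pair windowed FST components with division-specific drivers.

    Inside the flagged regions, pairwise differentiation follows the SST
    difference between sites; outside, it follows coastline distance —
    the pattern expected when sweeps are environment-driven.  Returns
    (pair_components, windows, regions, site_values) ready for
    :func:`coastgen.ibd_ibe.gdm_region_contrast`.
    """
    from .selection_scan import SelectionRegion

    rng = np.random.default_rng(seed)
    coast = np.sort(rng.uniform(0, 2000, n_sites))
    sst = 18.0 + 0.9 * coast / 2000.0 * 17.0 + rng.normal(0, 1.2, n_sites)
    site_ids = [f"P{i + 1}" for i in range(n_sites)]
    site_values = pd.DataFrame({"D_csl": coast, "dSST_max": sst}, index=site_ids)

    win_size = 50_000
    windows = pd.DataFrame({
        "chrom": "chr1",
        "start": 1 + win_size * np.arange(n_windows),
        "end": win_size * (1 + np.arange(n_windows)),
    })
    regions = [SelectionRegion("chr1", int(windows.start[i]), int(windows.end[i]),
                               "A") for i in range(n_psr_windows)]

    comps = {}
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            dc = abs(coast[i] - coast[j])
            ds = abs(sst[i] - sst[j])
            fst_in = np.clip(0.6 * (1 - np.exp(-ds / 8.0))
                             + rng.normal(0, 0.01), 0.001, 0.95)
            fst_out = np.clip(0.5 * (1 - np.exp(-dc / 800.0))
                              + rng.normal(0, 0.01), 0.001, 0.95)
            abc_w = np.ones(n_windows)
            a_w = np.full(n_windows, fst_out)
            a_w[:n_psr_windows] = fst_in
            a_w += rng.normal(0, 0.005, n_windows)  # window-level noise
            comps[(site_ids[i], site_ids[j])] = (np.clip(a_w, 0, 0.99), abc_w)
    return comps, windows, regions, site_values
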