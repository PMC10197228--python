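"""End-to-end orchestration of the analysis stages.

Stages (each reads only the documented file formats of the previous):

1. ``simulate`` — write the synthetic bundle (VCF, population map, site
   table, SST series, coast raster, gene models, truth table).
2. ``scan`` — windowed selection statistics, CSS, PSR/PSG calling and
   the north-vs-south ANOVA contrast.
3. ``gea`` — SST climatology covariates, covariance-corrected Bayes
   factors, RDA outliers, candidate intersection and nearby genes.
4. ``ibdibe`` — pairwise genetic distance, geographic/climatic
   predictors, single-factor OLS, regularized regression, GDM (whole
   genome and PSR/non-PSR contrast) and commonality analysis.
5. ``report`` — aggregate results and, when truth is available, recovery
   metrics (sweep recall, side accuracy, candidate-locus recall).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import gea as gea_mod
from . import genotype_io, geo_env, ibd_ibe, popgen_stats, selection_scan
from . import synthetic_data

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "run_all"]


@dataclass
class RunConfig:
    outdir: str = "coastgen_out"
    seed: int = 0
    window_size: int = 50_000
    window_step: int = 10_000
    percentile: float = 0.95
    bf_threshold_db: float = 20.0
    rda_alpha: float = 0.001
    gene_radius: int = 5_000
    ehh_cutoff: float = 0.05
    rsb_max_extend: int = 300
    gdm_permutations: int = 200
    commonality_bootstraps: int = 200
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self) -> None:
        if not (0.0 < self.percentile < 1.0):
            raise ValueError(f"percentile must be in (0, 1), got {self.percentile}")
        if not (0.0 < self.rda_alpha < 1.0):
            raise ValueError("rda_alpha must be in (0, 1)")
        if self.window_step > self.window_size:
            raise ValueError("window step must not exceed window size")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _provenance(cfg: RunConfig, stage: str) -> dict:
    from . import __version__

    return {"stage": stage, "config_hash": cfg.config_hash(), "seed": cfg.seed,
            "version": __version__}


def _stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    sim_cfg = synthetic_data.default_config(seed=cfg.seed, **cfg.sim)
    paths = synthetic_data.emit_all(sim_cfg, outdir / "sim")
    return {"paths": {k: str(v) for k, v in paths.items()},
            "n_sweeps": len(sim_cfg.sweeps)}


def _load_bundle(outdir: Path):
    sim = outdir / "sim"
    pop_map = genotype_io.read_population_map(str(sim / "popmap.tsv"))
    variants, hap = genotype_io.read_vcf(str(sim / "sim.vcf"), pop_map)
    sites = geo_env.read_sites_tsv(str(sim / "sites.tsv"))
    sst = geo_env.read_sst_csv(str(sim / "sst.csv"))
    grid = geo_env.CoastGrid.from_ascii(str(sim / "coast.grid"))
    genes = selection_scan.read_gff_genes(str(sim / "genes.gff3"))
    truth = None
    if (sim / "truth.json").exists():
        truth = synthetic_data.SimTruth.from_json(str(sim / "truth.json"))
    return variants, hap, pop_map, sites, sst, grid, genes, truth


def _chrom_lengths(variants) -> dict[str, int]:
    return {c: int(sub["pos"].max()) for c, sub in variants.groupby("chrom")}


def _stage_scan(cfg: RunConfig, outdir: Path) -> dict:
    variants, hap, pop_map, _, _, _, genes, truth = _load_bundle(outdir)
    pops = pop_map.populations()
    pop_a = "north" if "north" in pops else pops[0]
    pop_b = "south" if "south" in pops else pops[-1]
    spec = popgen_stats.WindowSpec(cfg.window_size, cfg.window_step)
    stats_table = popgen_stats.window_stat_table(
        hap, variants, pop_map, pop_a, pop_b, _chrom_lengths(variants), spec,
        ehh_cutoff=cfg.ehh_cutoff, max_extend=cfg.rsb_max_extend)
    stats_table["omega_abs"] = np.abs(stats_table["omega"])
    stats_table["rsb_abs"] = np.abs(stats_table["rsb_mean"])
    css_table = selection_scan.css(stats_table)
    stats_table = pd.concat([stats_table, css_table[["z_mean", "p", "css"]]], axis=1)
    regions_a, regions_b = selection_scan.call_psrs(stats_table, cfg.percentile)
    psg_a = selection_scan.call_psgs(regions_a, genes)
    psg_b = selection_scan.call_psgs(regions_b, genes)
    anova = None
    if regions_a and regions_b:
        try:
            anova = selection_scan.compare_psr_strength(stats_table, regions_a,
                                                        regions_b)
        except ValueError as exc:
            log.warning("PSR strength ANOVA skipped: %s", exc)
    scan_dir = outdir / "scan"
    scan_dir.mkdir(exist_ok=True)
    stats_table.to_csv(scan_dir / "window_stats.tsv", sep="\t", index=False)
    selection_scan.regions_to_frame(regions_a + regions_b).to_csv(
        scan_dir / "psrs.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": psg_a + psg_b,
                  "side": ["A"] * len(psg_a) + ["B"] * len(psg_b)}).to_csv(
        scan_dir / "psgs.tsv", sep="\t", index=False)
    if anova is not None:
        anova.to_csv(scan_dir / "psr_anova.tsv", sep="\t", index=False)
    result = {"n_windows": len(stats_table),
              "n_psr_a": len(regions_a), "n_psr_b": len(regions_b),
              "psg_a": psg_a, "psg_b": psg_b}
    if truth is not None:
        result["recovery"] = _sweep_recovery(truth, regions_a, regions_b)
    return result


def _sweep_recovery(truth, regions_a, regions_b) -> dict:
    """Per-side planted-sweep recall and side-assignment accuracy."""
    def overlaps(sw, regions):
        return [r for r in regions
                if r.chrom == sw["chrom"] and sw["start"] <= r.end
                and sw["end"] >= r.start]

    recall = {}
    for side, regions in (("A", regions_a), ("B", regions_b)):
        sweeps = [s for s in truth.sweeps if s["side"] == side]
        hit = sum(1 for s in sweeps if overlaps(s, regions))
        recall[side] = hit / len(sweeps) if sweeps else float("nan")
    correct = total = 0
    for side, regions in (("A", regions_a), ("B", regions_b)):
        for r in regions:
            match = [s for s in truth.sweeps
                     if s["chrom"] == r.chrom and s["start"] <= r.end
                     and s["end"] >= r.start]
            if match:
                total += 1
                if all(s["side"] == side for s in match):
                    correct += 1
    side_acc = correct / total if total else float("nan")
    return {"recall_A": recall["A"], "recall_B": recall["B"],
            "side_accuracy": side_acc}


def _site_env_table(sites, sst) -> list[geo_env.SiteEnv]:
    envs = []
    for s in sites:
        ser = sst[s.site_id]
        envs.append(geo_env.sst_climatology(s.site_id, ser.index, ser.to_numpy()))
    return envs


def _stage_gea(cfg: RunConfig, outdir: Path) -> dict:
    variants, hap, pop_map, sites, sst, _, genes, truth = _load_bundle(outdir)
    envs = _site_env_table(sites, sst)
    env_by_site = {e.site_id: e for e in envs}
    fm = gea_mod.pop_freqs(hap, pop_map, by="site")
    omega = gea_mod.pop_covariance(fm)
    cov_max = np.array([env_by_site[s].sst_max for s in fm.labels])
    cov_min = np.array([env_by_site[s].sst_min for s in fm.labels])
    bf = {"SST_max": gea_mod.bayes_factor(fm, cov_max, omega),
          "SST_min": gea_mod.bayes_factor(fm, cov_min, omega)}
    env_rows = np.array([[env_by_site[pop_map.site_of[s]].sst_max,
                          env_by_site[pop_map.site_of[s]].sst_min]
                         for s in hap.sample_ids])
    _, rda_p = gea_mod.rda_outliers(hap, env_rows)
    cand = gea_mod.intersect_candidates(variants, bf, rda_p,
                                        rda_alpha=cfg.rda_alpha,
                                        bf_threshold=cfg.bf_threshold_db)
    hits = cand[cand["candidate"]]
    near = gea_mod.genes_near_snps(hits, genes, radius=cfg.gene_radius)
    gea_dir = outdir / "gea"
    gea_dir.mkdir(exist_ok=True)
    cand.to_csv(gea_dir / "gea_snps.tsv", sep="\t", index=False)
    result = {"n_candidates": int(cand["candidate"].sum()),
              "genes_near_candidates": near}
    if truth is not None:
        env_idx = [e["index"] for e in truth.env_loci]
        flagged = cand["candidate"].to_numpy()
        result["env_locus_recall"] = (float(flagged[env_idx].mean())
                                      if env_idx else float("nan"))
        order = np.argsort(cand["rda_p"].to_numpy())
        rank = np.empty(len(cand))
        rank[order] = np.arange(len(cand)) / len(cand)
        result["env_locus_median_rda_rank"] = float(np.median(rank[env_idx]))
    return result


def _site_level_values(sites, envs, grid) -> pd.DataFrame:
    """Site-level predictor values for GDM splines.

    Between-site distances are represented by 1-D site coordinates along
    the coast (cumulative coastline / great-circle distance from the
    first site; meridional km for latitude), so that pair differences of
    the coordinates reproduce the chain distances.
    """
    coast = [0.0]
    gcc = [0.0]
    for a, b in zip(sites[:-1], sites[1:]):
        coast.append(coast[-1] + geo_env.coastline_distance(a, b, grid))
        gcc.append(gcc[-1] + geo_env.great_circle(a, b))
    return pd.DataFrame({
        "D_csl": coast,
        "D_gcc": gcc,
        "D_lat": [s.lat * 2 * np.pi * geo_env.EARTH_RADIUS_KM / 360.0 for s in sites],
        "dSST_max": [e.sst_max for e in envs],
        "dSST_min": [e.sst_min for e in envs],
        "dSST_med": [e.sst_med for e in envs],
    }, index=[s.site_id for s in sites])


def _stage_ibdibe(cfg: RunConfig, outdir: Path) -> dict:
    variants, hap, pop_map, sites, sst, grid, _, truth = _load_bundle(outdir)
    envs = _site_env_table(sites, sst)
    fst = ibd_ibe.pairwise_fst(hap, variants, pop_map, by="site")
    fst["gdist"] = ibd_ibe.linearized_gdist(np.clip(fst["fst"].to_numpy(), 0, None))
    preds = geo_env.pair_predictors(sites, envs, grid)
    pairs = preds.merge(fst[["site_a", "site_b", "gdist"]], on=["site_a", "site_b"])
    predictors = [c for c in ibd_ibe.DEFAULT_PREDICTORS if c in pairs.columns]

    ols = {p: ibd_ibe.single_factor_ols(pairs, p) for p in predictors}
    lasso_rep, enet_rep = ibd_ibe.rls_fit(pairs, predictors, seed=cfg.seed)
    site_values = _site_level_values(sites, envs, grid)
    gdm = ibd_ibe.gdm_fit(pairs, site_values, predictors,
                          n_perm=cfg.gdm_permutations, seed=cfg.seed)
    common = ibd_ibe.commonality_analysis(pairs, predictors,
                                          n_boot=cfg.commonality_bootstraps,
                                          seed=cfg.seed)

    # PSR vs non-PSR contrast needs per-pair per-window FST components
    contrast = None
    psr_path = outdir / "scan" / "psrs.tsv"
    if psr_path.exists():
        psrs = pd.read_csv(psr_path, sep="\t")
        regions = [selection_scan.SelectionRegion(str(r.chrom), int(r.start),
                                                  int(r.end), str(r.side))
                   for r in psrs.itertuples()]
        if regions:
            windows = popgen_stats.window_grid(
                _chrom_lengths(variants),
                popgen_stats.WindowSpec(cfg.window_size, cfg.window_step))
            comps = _pair_window_components(hap, variants, pop_map, windows)
            try:
                fit_in, fit_out = ibd_ibe.gdm_region_contrast(
                    comps, windows, regions, site_values, predictors)
                contrast = {"psr_max_height": fit_in.max_height,
                            "non_psr_max_height": fit_out.max_height}
            except ValueError as exc:
                log.warning("GDM region contrast skipped: %s", exc)

    ibe_dir = outdir / "ibdibe"
    ibe_dir.mkdir(exist_ok=True)
    pairs.to_csv(ibe_dir / "site_pairs.tsv", sep="\t", index=False)
    pd.DataFrame([{ "predictor": p, "r2": r.r2, "r2_adj": r.r2_adj,
                    "p": r.model_p, "loglik": r.loglik, "aic": r.aic,
                    "bic": r.bic} for p, r in ols.items()]).to_csv(
        ibe_dir / "single_factor_ols.tsv", sep="\t", index=False)
    lasso_rep.params.to_csv(ibe_dir / "rls_lasso.tsv", sep="\t", index=False)
    enet_rep.params.to_csv(ibe_dir / "rls_enet.tsv", sep="\t", index=False)
    common.table.to_csv(ibe_dir / "commonality.tsv", sep="\t", index=False)
    curves = []
    for p in gdm.predictors:
        x, y = gdm.spline_curve(p)
        curves.append(pd.DataFrame({"predictor": p, "x": x, "spline": y}))
    pd.concat(curves).to_csv(ibe_dir / "gdm_splines.tsv", sep="\t", index=False)

    return {
        "ols": {p: {"r2_adj": r.r2_adj, "aic": r.aic, "p": r.model_p}
                for p, r in ols.items()},
        "rls": {"lasso_r2": lasso_rep.r2, "enet_r2": enet_rep.r2,
                "retained": [row["term"] for _, row in enet_rep.params.iterrows()
                             if row["term"] != "intercept" and row["coef"] != 0.0]},
        "gdm": {"deviance_explained": gdm.deviance_explained,
                "max_height": gdm.max_height, "perm_p": gdm.perm_p},
        "commonality_r2": common.r2,
        "region_contrast": contrast,
    }


def _pair_window_components(hap, variants, pop_map, windows):
    """Per site pair: windowed WC FST numerator/denominator sums."""
    from itertools import combinations

    comps = {}
    for sa, sb in combinations(pop_map.sites(), 2):
        samples = pop_map.samples_at_site(sa) + pop_map.samples_at_site(sb)
        sub = hap.subset_samples(samples)
        pm = genotype_io.PopulationMap(
            {s: ("A" if pop_map.site_of[s] == sa else "B") for s in samples},
            {s: ("A" if pop_map.site_of[s] == sa else "B") for s in samples})
        c = popgen_stats.wc_fst(sub, pm, "A", "B")
        a = c["a"].to_numpy()
        abc = (c["a"] + c["b"] + c["c"]).to_numpy()
        a_w = np.zeros(len(windows))
        abc_w = np.zeros(len(windows))
        for wi, idx in popgen_stats._window_snp_slices(variants, windows):
            a_w[wi] = a[idx].sum()
            abc_w[wi] = abc[idx].sum()
        comps[(sa, sb)] = (a_w, abc_w)
    return comps


STAGES = {
    "simulate": _stage_simulate,
    "scan": _stage_scan,
    "gea": _stage_gea,
    "ibdibe": _stage_ibdibe,
}


def run(stage: str, cfg: RunConfig) -> dict:
    """Run one stage (or ``all`` / ``report``) and write its artifacts."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stage == "all":
        report = {}
        for name in ("simulate", "scan", "gea", "ibdibe"):
            report[name] = run(name, cfg)
        report.update(_aggregate_report(cfg, outdir, report))
        return report
    if stage == "report":
        return _aggregate_report(cfg, outdir, None)
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    t0 = time.time()
    if stage != "simulate":
        needed = outdir / "sim" / "sim.vcf"
        if not needed.exists():
            raise FileNotFoundError(f"missing input: {needed}")
    result = STAGES[stage](cfg, outdir)
    result["provenance"] = _provenance(cfg, stage)
    result["elapsed_s"] = round(time.time() - t0, 2)
    with open(outdir / f"{stage}.json", "w") as fh:
        json.dump(result, fh, indent=1, default=_json_default)
    log.info("stage %s finished in %.1f s", stage, result["elapsed_s"])
    return result


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _aggregate_report(cfg: RunConfig, outdir: Path, stage_results) -> dict:
    report = {"provenance": _provenance(cfg, "report")}
    if stage_results is None:
        stage_results = {}
        for name in ("simulate", "scan", "gea", "ibdibe"):
            p = outdir / f"{name}.json"
            if p.exists():
                with open(p) as fh:
                    stage_results[name] = json.load(fh)
        report.update(stage_results)

    def _stable(obj):
        if isinstance(obj, dict):
            return {k: _stable(v) for k, v in obj.items()
                    if k not in ("elapsed_s", "paths", "provenance")}
        return obj

    payload = json.dumps(_stable(stage_results), sort_keys=True,
                         default=_json_default)
    report["report_hash"] = hashlib.sha256(payload.encode()).hexdigest()[:16]
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default)
    return report


def run_all(cfg: RunConfig) -> dict:
    return run("all", cfg)
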