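"""Isolation-by-distance vs isolation-by-environment dissection.

Pairwise genetic distance between sampling sites, linearized as
FST/(1-FST), is modelled against geographic and climatic predictors
four ways:

* single-factor OLS (one predictor at a time, the classic IBD/IBE test);
* regularized least squares — a LASSO stage discards unimportant
  predictors, then an elastic net (mixing 0.5) is fit on the survivors;
* generalized dissimilarity modelling (GDM) — monotone I-spline
  transforms of site-level predictor values with an exponential link
  d = 1 - exp(-eta), fitted by iterated non-negative least squares;
  each predictor's fitted spline maximum height measures its total
  contribution, and matrix permutations give importance and p;
* commonality analysis — the full-model R^2 is partitioned into unique
  and shared components over all predictor subsets, complemented by
  structure coefficients, Pratt measures and Johnson relative weights,
  with site-bootstrap confidence intervals.

Because the C(S,2) pairs from S sites are not independent, plain OLS
p-values are reported as the literature convention but site-bootstrap
CIs are available as the honest uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline

log = logging.getLogger(__name__)

__all__ = [
    "FitReport",
    "GdmFit",
    "CommonalityReport",
    "linearized_gdist",
    "pairwise_fst",
    "single_factor_ols",
    "rls_fit",
    "ISplineBasis",
    "gdm_fit",
    "gdm_region_contrast",
    "windows_in_regions",
    "commonality_analysis",
]

DEFAULT_PREDICTORS = ["D_gcc", "D_csl", "D_lat", "dSST_max", "dSST_min", "dSST_med"]


# ---------------------------------------------------------------------------
# Genetic distance


def linearized_gdist(fst) -> np.ndarray | float:
    """Rousset's linearized genetic distance FST/(1-FST)."""
    arr = np.asarray(fst, dtype=float)
    if np.any(arr >= 1.0):
        raise ValueError("FST = 1 gives infinite genetic distance")
    out = arr / (1.0 - arr)
    return float(out) if np.ndim(fst) == 0 else out


def pairwise_fst(
    hap,
    variants,
    pop_map,
    by: str = "site",
    chrom_weighted: bool = True,
) -> pd.DataFrame:
    """Weir-Cockerham FST for every unordered pair of sites (or populations).

    FST is computed as a ratio of sums of variance components within each
    chromosome and the per-chromosome values averaged weighted by SNP
    count (``chrom_weighted=True``), mirroring chromosome-wise estimation
    followed by genome averaging.  Returns columns site_a, site_b, fst.
    """
    from .genotype_io import PopulationMap
    from .popgen_stats import wc_fst

    groups = pop_map.sites() if by == "site" else pop_map.populations()
    getter = pop_map.samples_at_site if by == "site" else pop_map.samples_in_population
    chrom_ids = variants["chrom"].to_numpy()
    chroms = variants["chrom"].unique()
    rows = []
    for ga, gb in combinations(groups, 2):
        samples = getter(ga) + getter(gb)
        sub = hap.subset_samples(samples)
        pm = PopulationMap(
            site_of={s: ("A" if s in getter(ga) else "B") for s in samples},
            population_of={s: ("A" if s in getter(ga) else "B") for s in samples},
        )
        comp = wc_fst(sub, pm, "A", "B")
        a = comp["a"].to_numpy()
        abc = (comp["a"] + comp["b"] + comp["c"]).to_numpy()
        if chrom_weighted and len(chroms) > 1:
            vals, weights = [], []
            for c in chroms:
                m = chrom_ids == c
                denom = abc[m].sum()
                if denom > 0:
                    vals.append(a[m].sum() / denom)
                    weights.append(m.sum())
            fst = float(np.average(vals, weights=weights))
        else:
            fst = float(a.sum() / abc.sum())
        rows.append({"site_a": ga, "site_b": gb, "fst": fst})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fit reports


@dataclass
class FitReport:
    """A regression summary with the standard Gaussian-likelihood metrics."""

    params: pd.DataFrame  # term, coef, se, t, p
    r2: float
    r2_adj: float
    loglik: float
    aic: float
    bic: float
    model_p: float
    n: int
    sse: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(orient="records"),
            "r2": self.r2, "r2_adj": self.r2_adj, "loglik": self.loglik,
            "aic": self.aic, "bic": self.bic, "model_p": self.model_p,
            "n": self.n, "sse": self.sse,
        }


def single_factor_ols(pairs: pd.DataFrame, predictor: str,
                      response: str = "gdist") -> FitReport:
    """OLS of genetic distance on a single predictor plus intercept."""
    import statsmodels.api as sm

    if len(pairs) < 4:
        raise ValueError("need >= 4 site pairs")
    x = pairs[predictor].to_numpy(float)
    if x.std() == 0:
        raise ValueError(f"predictor {predictor} has zero variance")
    y = pairs[response].to_numpy(float)
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    params = pd.DataFrame({
        "term": ["intercept", predictor],
        "coef": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues,
    })
    return FitReport(params, float(res.rsquared), float(res.rsquared_adj),
                     float(res.llf), float(res.aic), float(res.bic),
                     float(res.f_pvalue), int(res.nobs),
                     sse=float(res.ssr))


def _gaussian_metrics(y: np.ndarray, yhat: np.ndarray, k: int):
    n = len(y)
    sse = float(((y - yhat) ** 2).sum())
    ll = -0.5 * n * (np.log(2 * np.pi * sse / n) + 1.0)
    return sse, ll, 2 * k - 2 * ll, k * np.log(n) - 2 * ll


def rls_fit(
    pairs: pd.DataFrame,
    predictors: list[str] = tuple(DEFAULT_PREDICTORS),
    response: str = "gdist",
    alpha_mix: float = 0.5,
    cv: int = 5,
    seed: int = 0,
) -> tuple[FitReport, FitReport]:
    """Two-stage regularized least squares.

    Stage 1: LASSO with cross-validated penalty discards predictors with
    zero coefficient.  Stage 2: elastic net (l1 mixing ``alpha_mix``)
    refit on the survivors.  Predictors are z-scored and the response
    centred, so coefficients are standardized.  SE/t/p follow the
    post-selection OLS-refit convention (dropped predictors get coef 0,
    p = 1).  Returns (lasso_report, enet_report).
    """
    from sklearn.linear_model import ElasticNetCV, LassoCV

    predictors = list(predictors)
    X = pairs[predictors].to_numpy(float)
    y = pairs[response].to_numpy(float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    yc = y - y.mean()
    n = len(y)

    lasso = LassoCV(cv=cv, random_state=seed).fit(Xs, yc)
    survivors = [p for p, c in zip(predictors, lasso.coef_) if c != 0.0]
    if not survivors:
        raise ValueError("no informative predictor survives LASSO selection")
    enet = ElasticNetCV(l1_ratio=alpha_mix, cv=cv, random_state=seed).fit(
        Xs[:, [predictors.index(p) for p in survivors]], yc)

    def _report(coefs: dict[str, float], yhat: np.ndarray, intercept: float) -> FitReport:
        import statsmodels.api as sm

        cols = [predictors.index(p) for p in survivors]
        refit = sm.OLS(yc, sm.add_constant(Xs[:, cols])).fit()
        se = {p: float(refit.bse[i + 1]) for i, p in enumerate(survivors)}
        rows = [{"term": "intercept", "coef": intercept,
                 "se": float(refit.bse[0]),
                 "t": intercept / float(refit.bse[0]),
                 "p": float(2 * stats.t.sf(abs(intercept / refit.bse[0]), n - len(cols) - 1))}]
        for p in predictors:
            c = coefs.get(p, 0.0)
            if p in survivors:
                tval = c / se[p]
                pval = float(2 * stats.t.sf(abs(tval), n - len(cols) - 1))
                rows.append({"term": p, "coef": c, "se": se[p], "t": tval, "p": pval})
            else:
                rows.append({"term": p, "coef": 0.0, "se": np.nan, "t": 0.0, "p": 1.0})
        k = len(survivors) + 1
        sse, ll, aic, bic = _gaussian_metrics(yc, yhat, k)
        sst = float((yc ** 2).sum())
        r2 = 1.0 - sse / sst
        r2_adj = 1.0 - (1 - r2) * (n - 1) / (n - k)
        fstat = (r2 / (k - 1)) / ((1 - r2) / (n - k)) if r2 < 1 else np.inf
        model_p = float(stats.f.sf(fstat, k - 1, n - k))
        params = pd.DataFrame(rows)
        return FitReport(params, r2, r2_adj, ll, aic, bic, model_p, n, sse=sse)

    lasso_rep = _report({p: float(c) for p, c in zip(predictors, lasso.coef_) if c != 0},
                        lasso.predict(Xs), float(lasso.intercept_))
    cols = [predictors.index(p) for p in survivors]
    enet_rep = _report({p: float(c) for p, c in zip(survivors, enet.coef_)},
                       enet.predict(Xs[:, cols]), float(enet.intercept_))
    return lasso_rep, enet_rep


# ---------------------------------------------------------------------------
# Generalized dissimilarity modelling


class ISplineBasis:
    """Three monotone I-spline basis functions on [min, max] of site values.

    Built as normalized antiderivatives of degree-1 B-splines with knots
    at the minimum, median and maximum of the observed site values; each
    basis rises monotonically from 0 to 1.
    """

    def __init__(self, values: np.ndarray):
        v = np.asarray(values, float)
        q1, q2, q3 = np.min(v), np.median(v), np.max(v)
        if q3 - q1 <= 0:
            raise ValueError("constant predictor; spline basis undefined")
        eps = 1e-9 * (q3 - q1)
        q2 = min(max(q2, q1 + eps), q3 - eps)
        self.knots = (q1, q2, q3)
        t = np.array([q1, q1, q2, q3, q3])
        self._funcs = []
        for i in range(3):
            c = np.zeros(3)
            c[i] = 1.0
            b = BSpline(t, c, 1, extrapolate=False)
            ib = b.antiderivative()
            total = ib(q3) - ib(q1)
            self._funcs.append((ib, float(total)))
        self.lo, self.hi = q1, q3

    def __call__(self, x) -> np.ndarray:
        """Evaluate the 3 basis functions; returns shape (..., 3)."""
        x = np.clip(np.asarray(x, float), self.lo, self.hi)
        cols = [np.nan_to_num((ib(x) - ib(self.lo))) / tot for ib, tot in self._funcs]
        return np.stack(cols, axis=-1)


@dataclass
class GdmFit:
    predictors: list[str]
    intercept: float
    coefs: dict[str, np.ndarray]  # predictor -> 3 non-negative I-spline coefs
    bases: dict[str, ISplineBasis]
    deviance_explained: float  # percent
    scale_factor: float
    importance: dict[str, float] = field(default_factory=dict)
    perm_p: dict[str, float] = field(default_factory=dict)

    @property
    def max_height(self) -> dict[str, float]:
        """Fitted spline maximum height per predictor (sum of its coefs)."""
        return {p: float(np.sum(c)) for p, c in self.coefs.items()}

    def spline_curve(self, predictor: str, n: int = 200):
        b = self.bases[predictor]
        x = np.linspace(b.lo, b.hi, n)
        y = b(x) @ self.coefs[predictor]
        return x, y

    def predict(self, site_values: pd.DataFrame, pairs: pd.DataFrame) -> np.ndarray:
        X = _gdm_design(pairs, site_values, self.predictors, self.bases)
        beta = np.concatenate([[self.intercept]]
                              + [self.coefs[p] for p in self.predictors])
        eta = np.column_stack([np.ones(X.shape[0]), X]) @ beta
        return 1.0 - np.exp(-eta)


def _gdm_design(pairs: pd.DataFrame, site_values: pd.DataFrame,
                predictors: list[str], bases: dict[str, ISplineBasis]) -> np.ndarray:
    cols = []
    for p in predictors:
        vals = site_values[p]
        ia = bases[p](vals.loc[pairs["site_a"]].to_numpy())
        ib = bases[p](vals.loc[pairs["site_b"]].to_numpy())
        cols.append(np.abs(ia - ib))
    return np.concatenate(cols, axis=1)


def _nnls_link_fit(X: np.ndarray, d: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 100) -> tuple[np.ndarray, float]:
    """Minimize sum (d - (1 - exp(-X beta)))^2 s.t. beta >= 0.

    Iteratively reweighted NNLS on the link scale (Gauss-Newton with
    non-negativity at each step).  Returns (beta, deviance).
    """
    eta0 = -np.log(np.clip(1.0 - d, 1e-10, 1.0))
    beta, _ = optimize.nnls(X, eta0)
    dev_prev = np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 - np.exp(-eta)
        dev = float(((d - mu) ** 2).sum())
        if abs(dev_prev - dev) < tol:
            break
        dev_prev = dev
        w = np.exp(-eta)  # d mu / d eta
        z = eta + (d - mu) / np.maximum(w, 1e-10)
        beta, _ = optimize.nnls(X * w[:, None], z * w)
    eta = X @ beta
    dev = float(((d - (1.0 - np.exp(-eta))) ** 2).sum())
    return beta, dev


def gdm_fit(
    pairs: pd.DataFrame,
    site_values: pd.DataFrame,
    predictors: list[str],
    response: str = "gdist",
    n_perm: int = 5000,
    seed: int = 0,
    compute_importance: bool = True,
) -> GdmFit:
    """Fit a generalized dissimilarity model.

    ``site_values`` is indexed by site id and holds one column per
    predictor (site-level values: e.g. a coastline coordinate, latitude,
    or the site's SST summary); the pair term for basis j is
    |I_j(x_a) - I_j(x_b)|.  The response is max-normalized to [0, 1) and
    regressed through d = 1 - exp(-eta) by iterated non-negative least
    squares.  Importance of a predictor = mean percent decrease in
    deviance explained when its site values are permuted (``n_perm``
    matrix permutations); p = fraction of permutations whose deviance
    explained matches or beats the observed fit.
    """
    rng = np.random.default_rng(seed)
    predictors = list(predictors)
    y = pairs[response].to_numpy(float)
    scale = 1.01 * np.max(np.abs(y)) if np.max(np.abs(y)) > 0 else 1.0
    d = np.clip(y / scale, 0.0, 1.0 - 1e-9)

    bases = {}
    kept = []
    for p in predictors:
        try:
            bases[p] = ISplineBasis(site_values[p].to_numpy())
            kept.append(p)
        except ValueError:
            log.warning("GDM predictor %r constant; dropped", p)
    if not kept:
        raise ValueError("no usable GDM predictor")
    predictors = kept

    def _fit(sv: pd.DataFrame) -> tuple[np.ndarray, float]:
        X = _gdm_design(pairs, sv, predictors, bases)
        Xd = np.column_stack([np.ones(X.shape[0]), X])
        beta, dev = _nnls_link_fit(Xd, d)
        null_dev = float(((d - d.mean()) ** 2).sum())
        de = 100.0 * (1.0 - dev / null_dev) if null_dev > 0 else 0.0
        return beta, de

    beta, dev_expl = _fit(site_values)
    coefs = {p: beta[1 + 3 * i: 4 + 3 * i] for i, p in enumerate(predictors)}
    fit = GdmFit(predictors, float(beta[0]), coefs, bases, dev_expl, scale)

    if compute_importance and n_perm > 0:
        sites = list(site_values.index)
        for p in predictors:
            drops = []
            beats = 0
            for _ in range(n_perm):
                sv = site_values.copy()
                sv[p] = sv[p].to_numpy()[rng.permutation(len(sites))]
                _, de_perm = _fit(sv)
                drops.append(dev_expl - de_perm)
                if de_perm >= dev_expl:
                    beats += 1
            fit.importance[p] = float(np.mean(drops))
            fit.perm_p[p] = (1 + beats) / (1 + n_perm)
    return fit


def windows_in_regions(windows: pd.DataFrame, regions) -> np.ndarray:
    """Boolean mask: window overlaps any region by >= 1 bp."""
    mask = np.zeros(len(windows), dtype=bool)
    for i, w in enumerate(windows.itertuples()):
        for r in regions:
            if r.chrom == w.chrom and w.start <= r.end and w.end >= r.start:
                mask[i] = True
                break
    return mask


def gdm_region_contrast(
    pair_components: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]],
    windows: pd.DataFrame,
    regions,
    site_values: pd.DataFrame,
    predictors: list[str],
    pairs_template: pd.DataFrame | None = None,
    n_perm: int = 0,
    seed: int = 0,
) -> tuple[GdmFit, GdmFit]:
    """Refit the GDM separately inside and outside selection regions.

    ``pair_components`` maps each (site_a, site_b) pair to per-window
    Weir-Cockerham numerator and denominator sums (a_w, abc_w); genetic
    distance for a genome division is the ratio-of-sums over that
    division's windows, linearized as FST/(1-FST).  Returns
    (region-restricted fit, complement fit).
    """
    if not regions:
        raise ValueError("empty region list")
    inside = windows_in_regions(windows, regions)
    if inside.sum() < 5 or (~inside).sum() < 5:
        raise ValueError("a genome division has < 5 windows")

    def _pairs(mask: np.ndarray) -> pd.DataFrame:
        rows = []
        for (sa, sb), (a_w, abc_w) in pair_components.items():
            denom = abc_w[mask].sum()
            if denom <= 0:
                raise ValueError(f"no informative windows for pair {sa}-{sb}")
            fst = min(a_w[mask].sum() / denom, 0.999999)
            rows.append({"site_a": sa, "site_b": sb,
                         "gdist": linearized_gdist(max(fst, 0.0))})
        return pd.DataFrame(rows)

    fit_in = gdm_fit(_pairs(inside), site_values, predictors,
                     n_perm=n_perm, seed=seed, compute_importance=n_perm > 0)
    fit_out = gdm_fit(_pairs(~inside), site_values, predictors,
                      n_perm=n_perm, seed=seed, compute_importance=n_perm > 0)
    return fit_in, fit_out


# ---------------------------------------------------------------------------
# Commonality analysis and relative weights


def _subset_r2(Xs: np.ndarray, yc: np.ndarray, cols: tuple[int, ...]) -> float:
    X = Xs[:, list(cols)]
    beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(yc)), X]), yc, rcond=None)
    yhat = np.column_stack([np.ones(len(yc)), X]) @ beta
    sst = float((yc ** 2).sum())
    return 1.0 - float(((yc - yhat) ** 2).sum()) / sst


def _commonality_components(Xs: np.ndarray, yc: np.ndarray, p: int) -> dict[tuple, float]:
    """Solve R^2(A) = sum over {S : S intersects A} C(S) for all subsets."""
    subsets = []
    for size in range(1, p + 1):
        subsets.extend(combinations(range(p), size))
    r2 = np.array([_subset_r2(Xs, yc, s) for s in subsets])
    M = np.zeros((len(subsets), len(subsets)))
    for i, A in enumerate(subsets):
        sa = set(A)
        for j, S in enumerate(subsets):
            if sa & set(S):
                M[i, j] = 1.0
    C = np.linalg.solve(M, r2)
    return dict(zip(subsets, C))


def _johnson_relative_weights(Xs: np.ndarray, yc: np.ndarray) -> np.ndarray:
    """Johnson's epsilon via the orthogonal-approximation decomposition."""
    n = len(yc)
    Rxx = (Xs.T @ Xs) / n
    rxy = (Xs.T @ yc) / n / yc.std()
    evals, evecs = np.linalg.eigh(Rxx)
    evals = np.maximum(evals, 1e-12)
    lam = evecs @ np.diag(np.sqrt(evals)) @ evecs.T  # Rxx^(1/2)
    beta_star = np.linalg.solve(lam, rxy)
    return (lam ** 2) @ (beta_star ** 2)


@dataclass
class CommonalityReport:
    table: pd.DataFrame  # per predictor: beta, r_xy, structure, structure_sq, pratt, unique, common, rel_weight
    components: dict[tuple, float]  # all 2^p - 1 commonality components
    r2: float
    diff_structure_sq: pd.DataFrame
    diff_rel_weight: pd.DataFrame
    ci: pd.DataFrame | None = None  # bootstrap percentile CIs


def commonality_analysis(
    pairs: pd.DataFrame,
    predictors: list[str] = tuple(DEFAULT_PREDICTORS),
    response: str = "gdist",
    n_boot: int = 5000,
    seed: int = 0,
) -> CommonalityReport:
    """Partition the full-model R^2 and rank predictors under collinearity.

    Computes standardized betas, structure coefficients (correlation of
    each predictor with the fitted response), Pratt measures, the
    unique/common commonality partition over all 2^p - 1 subsets, and
    Johnson relative weights; plus pairwise-difference matrices of the
    squared structure coefficients and relative weights.  Percentile
    bootstrap CIs are obtained by resampling sites and rebuilding the
    pair table each draw (``n_boot`` draws; 0 to skip).
    """
    predictors = list(predictors)
    p = len(predictors)
    if len(pairs) < p + 2:
        raise ValueError("too few pairs for commonality analysis")
    X = pairs[predictors].to_numpy(float)
    corr = np.corrcoef(X.T)
    off = np.abs(corr - np.eye(p))
    if off.max() >= 1 - 1e-12:
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(f"predictors {predictors[i]} and {predictors[j]} are "
                         "perfectly correlated")

    def _stats(df: pd.DataFrame):
        Xm = df[predictors].to_numpy(float)
        y = df[response].to_numpy(float)
        Xs = (Xm - Xm.mean(axis=0)) / Xm.std(axis=0)
        yc = y - y.mean()
        beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(yc)), Xs]), yc,
                                   rcond=None)
        yhat = np.column_stack([np.ones(len(yc)), Xs]) @ beta
        sst = float((yc ** 2).sum())
        r2 = 1.0 - float(((yc - yhat) ** 2).sum()) / sst
        beta_std = beta[1:] / yc.std()
        r_xy = np.array([np.corrcoef(Xs[:, j], yc)[0, 1] for j in range(p)])
        structure = np.array([np.corrcoef(Xs[:, j], yhat)[0, 1] for j in range(p)])
        pratt = beta_std * r_xy
        rw = _johnson_relative_weights(Xs, yc)
        return r2, beta_std, r_xy, structure, pratt, rw, Xs, yc

    r2, beta_std, r_xy, structure, pratt, rw, Xs, yc = _stats(pairs)
    comps = _commonality_components(Xs, yc, p)
    unique = np.array([comps[(j,)] for j in range(p)])
    totals = np.zeros(p)
    for S, c in comps.items():
        for j in S:
            totals[j] += c
    common = totals - unique

    table = pd.DataFrame({
        "predictor": predictors, "beta": beta_std, "r_xy": r_xy,
        "structure": structure, "structure_sq": structure ** 2,
        "pratt": pratt, "unique": unique, "common": common,
        "total": totals, "rel_weight": rw,
    })
    diff_ssq = pd.DataFrame(structure[:, None] ** 2 - structure[None, :] ** 2,
                            index=predictors, columns=predictors)
    diff_rw = pd.DataFrame(rw[:, None] - rw[None, :],
                           index=predictors, columns=predictors)

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        sites = sorted(set(pairs["site_a"]) | set(pairs["site_b"]))
        lookup = {frozenset((r.site_a, r.site_b)): i
                  for i, r in enumerate(pairs.itertuples())}
        boots_rw = []
        boots_ssq = []
        for _ in range(n_boot):
            draw = [sites[k] for k in rng.integers(0, len(sites), len(sites))]
            rows = []
            for a, b in combinations(range(len(draw)), 2):
                key = frozenset((draw[a], draw[b]))
                if len(key) == 2 and key in lookup:
                    rows.append(lookup[key])
            if len(rows) < p + 2:
                continue
            sub = pairs.iloc[rows]
            if any(sub[q].std() == 0 for q in predictors):
                continue
            try:
                _, _, _, s_b, _, rw_b, _, _ = _stats(sub)
            except (np.linalg.LinAlgError, ValueError):
                continue
            boots_rw.append(rw_b)
            boots_ssq.append(s_b ** 2)
        if boots_rw:
            brw = np.array(boots_rw)
            bssq = np.array(boots_ssq)
            ci = pd.DataFrame({
                "predictor": predictors,
                "rel_weight_lo": np.percentile(brw, 2.5, axis=0),
                "rel_weight_hi": np.percentile(brw, 97.5, axis=0),
                "structure_sq_lo": np.percentile(bssq, 2.5, axis=0),
                "structure_sq_hi": np.percentile(bssq, 97.5, axis=0),
            })
    return CommonalityReport(table, comps, r2, diff_ssq, diff_rw, ci)
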