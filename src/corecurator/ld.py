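"""Linkage disequilibrium: r^2, Fisher exact tests, the unlinked-pair
significance threshold, distance-binned decay profiles, and a
structure-corrected logistic-regression LD scan.

Inbred accessions are treated as haplotypes, so r^2 is the squared allelic
correlation on pairwise-complete calls. The significance threshold for
"LD beyond chance" is the parametric 99th percentile of r^2 among random
inter-chromosomal (unlinked) marker pairs after a Box-Cox power transform
toward normality. The logistic scan regresses one marker on another with
leading principal components as covariates, so its p-value measures LD
free of the confounding effect of population structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import inv_boxcox

from .containers import GeneticMap, GenotypeMatrix
from .curation import allele_frequencies
from .structure import PCAResult

NEG_LOG10_CEILING = 320.0


# -------------------------------------------------------------- pairwise r2

def pair_r2(x, y) -> tuple[float, int]:
    """Squared allelic correlation of two binary call vectors.

    Computed on pairwise-complete observations; returns (nan, n) when a
    marker is monomorphic on that subset (r^2 undefined, flagged).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    both = ~np.isnan(x) & ~np.isnan(y)
    n = int(both.sum())
    if n < 2:
        return (np.nan, n)
    xa, yb = x[both], y[both]
    pa, pb = xa.mean(), yb.mean()
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom == 0:
        return (np.nan, n)
    d = (xa * yb).mean() - pa * pb
    return (float(d * d / denom), n)


def r2_pairs(calls: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, chunk: int = 4000):
    """Vectorized r^2 for many marker pairs; returns (r2, n) arrays."""
    O = ~np.isnan(calls)
    X0 = np.where(O, calls, 0.0)
    n_pairs = len(idx_a)
    r2 = np.full(n_pairs, np.nan)
    nn = np.zeros(n_pairs, dtype=int)
    for s in range(0, n_pairs, chunk):
        ia = idx_a[s : s + chunk]
        ib = idx_b[s : s + chunk]
        both = O[:, ia] & O[:, ib]
        n = both.sum(axis=0).astype(float)
        xa = X0[:, ia] * both
        xb = X0[:, ib] * both
        with np.errstate(invalid="ignore", divide="ignore"):
            pa = xa.sum(axis=0) / n
            pb = xb.sum(axis=0) / n
            pab = (xa * xb).sum(axis=0) / n
            d = pab - pa * pb
            denom = pa * (1 - pa) * pb * (1 - pb)
            val = np.where(denom > 0, d * d / np.where(denom > 0, denom, 1), np.nan)
        val[n < 2] = np.nan
        r2[s : s + chunk] = val
        nn[s : s + chunk] = n.astype(int)
    return r2, nn


def pair_fisher_p(x, y) -> float:
    """Two-sided Fisher exact p from the 2x2 joint call table."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    both = ~np.isnan(x) & ~np.isnan(y)
    xa, yb = x[both], y[both]
    table = np.array(
        [
            [np.sum((xa == 0) & (yb == 0)), np.sum((xa == 0) & (yb == 1))],
            [np.sum((xa == 1) & (yb == 0)), np.sum((xa == 1) & (yb == 1))],
        ]
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("degenerate 2x2 table: empty row or column")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ----------------------------------------------------- significance threshold

@dataclass
class LDThreshold:
    n_pairs: int
    boxcox_lambda: float
    percentile: float
    threshold: float
    epsilon: float = 1e-6

    def __post_init__(self):
        if not (0 <= self.threshold <= 1):
            raise ValueError("threshold must lie in [0,1]")


def _maf_filter_indices(G: GenotypeMatrix, maf_min: float) -> np.ndarray:
    af = allele_frequencies(G)
    return np.where(af["maf"].to_numpy() >= maf_min)[0]


def unlinked_threshold(
    G: GenotypeMatrix,
    genetic_map: GeneticMap,
    subset=None,
    n_pairs: int = 100_000,
    percentile: float = 99.0,
    maf_min: float = 0.05,
    seed: int | None = None,
) -> LDThreshold:
    """Parametric percentile of r^2 among random inter-chromosomal pairs.

    r^2 values are shifted by epsilon=1e-6, Box-Cox transformed with the
    maximum-likelihood lambda, and the threshold is the inverse transform
    of mean + z_percentile * sd of the transformed values.
    """
    if not (0 < percentile < 100):
        raise ValueError("percentile must lie in (0,100)")
    Gs = G if subset is None else G.subset(accession_idx=G.accession_index(subset))
    keep = _maf_filter_indices(Gs, maf_min)
    pos = genetic_map.positions(G.markers)
    chrom = pos["chrom"].to_numpy()[keep]
    if len(pd.unique(chrom)) < 2:
        raise ValueError("need >= 2 chromosomes for unlinked pairs")
    rng = np.random.default_rng(seed)
    ia = np.empty(n_pairs, dtype=int)
    ib = np.empty(n_pairs, dtype=int)
    filled = 0
    while filled < n_pairs:
        need = n_pairs - filled
        a = rng.integers(0, len(keep), size=2 * need)
        b = rng.integers(0, len(keep), size=2 * need)
        ok = chrom[a] != chrom[b]
        take = min(need, ok.sum())
        ia[filled : filled + take] = keep[a[ok][:take]]
        ib[filled : filled + take] = keep[b[ok][:take]]
        filled += take
    r2, _ = r2_pairs(Gs.calls, ia, ib)
    r2 = r2[~np.isnan(r2)]
    eps = 1e-6
    # lambda chosen to maximize normality of the transformed sample
    # (probability-plot correlation); the likelihood-based lambda fits the
    # bulk but leaves the upper tail light, biasing the percentile upward.
    try:
        lam = float(stats.boxcox_normmax(r2 + eps, method="pearsonr"))
    except Exception:
        lam = float(stats.boxcox(r2 + eps)[1])
    transformed = stats.boxcox(r2 + eps, lmbda=lam)
    z = stats.norm.ppf(percentile / 100.0)
    thr = float(inv_boxcox(transformed.mean() + z * transformed.std(ddof=1), lam) - eps)
    return LDThreshold(
        n_pairs=len(r2),
        boxcox_lambda=float(lam),
        percentile=percentile,
        threshold=float(np.clip(thr, 0.0, 1.0)),
        epsilon=eps,
    )


# ------------------------------------------------------------- decay profile

def decay_profile(
    G: GenotypeMatrix,
    genetic_map: GeneticMap,
    subset=None,
    max_distance_cM: float = 50.0,
    bin_width_cM: float = 1.0,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Mean r^2 of intra-chromosomal pairs per distance bin, per chromosome."""
    Gs = G if subset is None else G.subset(accession_idx=G.accession_index(subset))
    keep = _maf_filter_indices(Gs, maf_min)
    pos = genetic_map.positions(G.markers)
    rows = []
    edges = np.arange(0, max_distance_cM + bin_width_cM, bin_width_cM)
    for chrom in genetic_map.chromosomes():
        on = keep[pos["chrom"].to_numpy()[keep] == chrom]
        cm = pos["cM"].to_numpy()[on]
        order = np.argsort(cm)
        on, cm = on[order], cm[order]
        ia, ib, dist = [], [], []
        j_hi = 0
        for a in range(len(on)):
            b = a + 1
            while b < len(on) and cm[b] - cm[a] <= max_distance_cM:
                ia.append(on[a])
                ib.append(on[b])
                dist.append(cm[b] - cm[a])
                b += 1
        if ia:
            r2, _ = r2_pairs(Gs.calls, np.array(ia), np.array(ib))
        else:
            r2 = np.array([])
        dist = np.asarray(dist)
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (dist >= lo) & (dist < hi)
            vals = r2[sel]
            vals = vals[~np.isnan(vals)]
            rows.append(
                (chrom, lo, hi, len(vals), float(vals.mean()) if len(vals) else np.nan)
            )
    return pd.DataFrame(rows, columns=["chrom", "bin_lo_cM", "bin_hi_cM", "n_pairs", "mean_r2"])


# ------------------------------------------- structure-corrected logistic LD

def _firth_logit(y: np.ndarray, X: np.ndarray, max_iter: int = 50, tol: float = 1e-8):
    """Firth bias-reduced logistic fit; returns (beta, penalized loglik)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    w = mu * (1 - mu)
    sign, logdet = np.linalg.slogdet((X.T * w) @ X)
    return beta, ll + 0.5 * logdet


def _ml_logit(y: np.ndarray, X: np.ndarray):
    """Plain ML logistic via statsmodels; returns loglik or None on failure."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, method="newton")
        except Exception:
            return None
        if not res.mle_retvals.get("converged", False):
            return None
        if np.max(np.abs(res.params)) > 25:  # quasi-separation
            return None
        return float(res.llf)


def logistic_pair_p(y_calls, x_calls, covariates=None) -> tuple[float, str]:
    """Likelihood-ratio p for marker x predicting marker y given covariates.

    Fits allele(y) ~ 1 + allele(x) + covariates on pairwise-complete
    accessions. Falls back to a Firth-penalized fit (flag "firth") when the
    ML fit separates or fails to converge.
    """
    y = np.asarray(y_calls, float)
    x = np.asarray(x_calls, float)
    n = len(y)
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    both = ~np.isnan(y) & ~np.isnan(x)
    if C.size:
        both &= ~np.isnan(C).any(axis=1)
    y, x, C = y[both], x[both], C[both]
    if len(y) < 3 or len(np.unique(y)) < 2:
        return (np.nan, "degenerate")
    ones = np.ones((len(y), 1))
    X_full = np.column_stack([ones, x.reshape(-1, 1), C])
    X_red = np.column_stack([ones, C])
    ll_full = _ml_logit(y, X_full)
    ll_red = _ml_logit(y, X_red)
    method = "ml"
    if ll_full is None or ll_red is None:
        _, ll_full = _firth_logit(y, X_full)
        _, ll_red = _firth_logit(y, X_red)
        method = "firth"
    lr = max(0.0, 2.0 * (ll_full - ll_red))
    p = float(stats.chi2.sf(lr, df=1))
    return (p, method)


def neg_log10(p: float) -> float:
    if np.isnan(p):
        return np.nan
    if p <= 0:
        return NEG_LOG10_CEILING
    return float(min(-np.log10(p), NEG_LOG10_CEILING))


def logistic_ld_scan(
    G: GenotypeMatrix,
    genetic_map: GeneticMap,
    pca: PCAResult,
    n_pcs: int = 11,
    window: tuple = (1.0, 2.0),
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Structure-corrected LD along chromosomes.

    For each response marker M0 and every regressor in the half-open
    distance window [lo, hi) cM downstream on the same chromosome, the
    logistic model allele(M0) ~ allele(M) + PC1..PCn is fit and the
    likelihood-ratio p of the regressor reported as -log10(p) keyed to
    M0's position. M0 is always the leftmost marker of a pair, so each
    pair appears once.
    """
    lo, hi = window
    if not (0 <= lo < hi):
        raise ValueError("window must satisfy 0 <= lo < hi")
    cols = [c for c in pca.scores.columns if c.startswith("PC")][:n_pcs]
    if len(cols) < n_pcs:
        raise ValueError(f"PCA has only {len(cols)} components; need {n_pcs}")
    covars = pca.scores.reindex(G.accessions)[cols].to_numpy()
    keep = _maf_filter_indices(G, maf_min)
    pos = genetic_map.positions(G.markers)
    chrom_all = pos["chrom"].to_numpy()
    cm_all = pos["cM"].to_numpy()
    rows = []
    for chrom in genetic_map.chromosomes():
        on = keep[chrom_all[keep] == chrom]
        cm = cm_all[on]
        order = np.argsort(cm)
        on, cm = on[order], cm[order]
        for a in range(len(on)):
            d = cm - cm[a]
            regs = np.where((d >= lo) & (d < hi))[0]
            for b in regs:
                p, method = logistic_pair_p(G.calls[:, on[a]], G.calls[:, on[b]], covars)
                rows.append(
                    (
                        G.markers[on[a]], G.markers[on[b]], chrom,
                        cm[a], cm[b], d[b],
                        p, neg_log10(p), method,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "marker_a", "marker_b", "chrom", "cM_a", "cM_b", "dist_cM",
            "p_logistic", "neg_log10_p", "fit",
        ],
    )


def min_p_per_response(scan: pd.DataFrame) -> pd.DataFrame:
    """Optional per-M0 summary: the most significant regressor in the window."""
    idx = scan.groupby("marker_a")["p_logistic"].idxmin()
    return scan.loc[idx.dropna()].reset_index(drop=True)
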