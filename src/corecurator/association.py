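"""Q+K mixed-linear-model association scan with kinship and BH-FDR.

The model is y = mu + Q*a + x b + u + e with a polygenic random effect
u ~ N(0, sg^2 K) and residual e ~ N(0, se^2 I). Variance components are
estimated once by REML on the no-marker model through the eigendecomposition
of K (the P3D/EMMAX shortcut), then every marker is tested by generalized
least squares in the rotated coordinates. Multiple testing is controlled by
Benjamini-Hochberg step-up q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GeneticMap, GenotypeMatrix, MembershipMatrix
from .curation import allele_frequencies


@dataclass
class KinshipMatrix:
    accessions: list
    values: np.ndarray
    n_markers: int
    maf_min: float

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        n = len(self.accessions)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")
        ev = np.linalg.eigvalsh(self.values)
        if ev.min() < -1e-8 * max(ev.max(), 1.0):
            raise ValueError("kinship not positive semidefinite")


def kinship(G: GenotypeMatrix, maf_min: float = 0.01) -> KinshipMatrix:
    """Centered cross-product genomic relationship matrix on 0/1 calls.

    With mean-imputed calls X and per-marker allele-1 frequency p:
    W = X - p and K = W W^T / sum_m p_m (1 - p_m).
    """
    if G.n_accessions < 2:
        raise ValueError("need >= 2 accessions")
    af = allele_frequencies(G)
    keep = np.where(af["maf"].to_numpy() >= maf_min)[0]
    if len(keep) == 0:
        raise ValueError("no markers pass the kinship MAF filter")
    X = G.calls[:, keep].copy()
    p = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    X[nan] = np.broadcast_to(p, X.shape)[nan]
    W = X - p
    denom = float(np.sum(p * (1 - p)))
    K = (W @ W.T) / denom
    return KinshipMatrix(list(G.accessions), K, n_markers=len(keep), maf_min=maf_min)


def _reml_delta(y_r, X_r, eigvals, bounds=(-8.0, 8.0)):
    """Profile REML of log10(delta), delta = se^2/sg^2, in rotated coords."""
    n, p = X_r.shape

    def neg_reml(log_delta):
        delta = 10.0**log_delta
        w = 1.0 / (eigvals + delta)
        Xw = X_r * w[:, None]
        A = X_r.T @ Xw
        try:
            beta = np.linalg.solve(A, Xw.T @ y_r)
        except np.linalg.LinAlgError:
            return 1e12
        r = y_r - X_r @ beta
        rss = float(np.sum(w * r * r))
        sg2 = rss / (n - p)
        _, logdet_A = np.linalg.slogdet(A)
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * sg2)
            + (n - p)
            + np.sum(np.log(eigvals + delta))
            + logdet_A
        )
        return -ll

    res = optimize.minimize_scalar(neg_reml, bounds=bounds, method="bounded")
    if not res.success:
        raise RuntimeError(f"REML did not converge: {res.message}")
    return 10.0**res.x


def genomic_inflation(p_values) -> float:
    """lambda_GC: median association chi-square over its null expectation."""
    p = np.asarray(p_values, float)
    p = p[~np.isnan(p)]
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.isf(0.5, df=1))


def mlm_scan(
    G: GenotypeMatrix,
    y: pd.Series,
    Q: MembershipMatrix | None,
    K: KinshipMatrix,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """Single-marker Q+K mixed-model scan (P3D variance components).

    Returns a table with the minor-allele effect estimate, MAF, Wald/F
    p-value and BH-FDR q per tested marker.
    """
    acc = [a for a in G.accessions if a in set(y.index) and a in set(K.accessions)]
    if Q is not None:
        qset = set(Q.accessions)
        acc = [a for a in acc if a in qset]
    if len(acc) < 3:
        raise ValueError("too few accessions shared by genotypes, phenotype, Q and K")
    Gs = G.subset(accession_idx=G.accession_index(acc))
    yv = y.reindex(acc).to_numpy(float)
    if np.nanstd(yv) == 0:
        raise ValueError("phenotype is constant")
    kidx = [K.accessions.index(a) for a in acc]
    Kv = K.values[np.ix_(kidx, kidx)]

    fixed = [np.ones((len(acc), 1))]
    if Q is not None:
        q = Q.reindex(acc).q
        fixed.append(q[:, :-1])  # drop last column: rows sum to 1
    Xf = np.column_stack(fixed)
    # drop collinear fixed-effect columns (e.g. a degenerate Q)
    qr_r = np.linalg.qr(Xf, mode="r")
    keep_cols = np.abs(np.diag(qr_r)) > 1e-10 * max(1.0, np.abs(qr_r[0, 0]))
    if not keep_cols.all():
        Xf = Xf[:, keep_cols]

    eigvals, U = np.linalg.eigh(Kv)
    eigvals = np.clip(eigvals, 0.0, None)
    y_r = U.T @ yv
    Xf_r = U.T @ Xf
    delta = _reml_delta(y_r, Xf_r, eigvals)
    w = 1.0 / (eigvals + delta)

    af = allele_frequencies(Gs)
    test = np.where(af["maf"].to_numpy() >= maf_min)[0]
    Xm = Gs.calls[:, test].copy()
    pm = np.nanmean(Xm, axis=0)
    nan = np.isnan(Xm)
    Xm[nan] = np.broadcast_to(pm, Xm.shape)[nan]
    Xm_r = U.T @ Xm

    p_fix = Xf_r.shape[1]
    n = len(acc)
    Xfw = Xf_r * w[:, None]
    A11 = Xf_r.T @ Xfw
    A11_inv = np.linalg.inv(A11)
    b1 = Xfw.T @ y_r
    rss0 = float(np.sum(w * (y_r - Xf_r @ (A11_inv @ b1)) ** 2))

    a12 = Xfw.T @ Xm_r  # p x M
    a22 = np.sum(w[:, None] * Xm_r**2, axis=0)
    b2 = Xm_r.T @ (w * y_r)
    t1 = A11_inv @ a12
    s_m = a22 - np.sum(a12 * t1, axis=0)  # Schur complement per marker
    c_m = b2 - t1.T @ b1
    df = n - p_fix - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(s_m > 1e-12, c_m / np.where(s_m > 1e-12, s_m, 1), np.nan)
        rss = rss0 - np.where(s_m > 1e-12, c_m**2 / np.where(s_m > 1e-12, s_m, 1), 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / s_m)
        tstat = beta / se
    p_vals = 2 * stats.t.sf(np.abs(tstat), df)
    p_vals[~np.isfinite(tstat)] = np.nan

    # report the minor-allele effect
    flip = pm > 0.5
    eff = np.where(flip, -beta, beta)
    allele = np.where(flip, "0", "1")
    maf = np.minimum(pm, 1 - pm)

    out = pd.DataFrame(
        {
            "marker": [Gs.markers[j] for j in test],
            "effect": eff,
            "allele": allele,
            "maf": maf,
            "p": p_vals,
            "n": n,
        }
    )
    ok = out["p"].notna()
    qv = np.full(len(out), np.nan)
    qv[ok.to_numpy()] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out["q"] = qv
    with np.errstate(divide="ignore"):
        out["neg_log10_q"] = -np.log10(out["q"])
    out.attrs["delta"] = delta
    out.attrs["lambda_gc"] = genomic_inflation(out["p"])
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(p, float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0,1] and be non-missing")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def manhattan_table(results: pd.DataFrame, genetic_map: GeneticMap, alpha: float = 0.05) -> pd.DataFrame:
    """Join scan results to map positions, ordered by (chrom, cM, marker).

    Markers absent from the map are emitted last with missing positions and
    flagged. Significance uses strict q < alpha.
    """
    mapped = genetic_map.frame.set_index("marker")
    out = results.copy()
    out["chrom"] = out["marker"].map(mapped["chrom"])
    out["cM"] = out["marker"].map(mapped["cM"])
    out["unmapped"] = out["chrom"].isna()
    out["significant"] = out["q"] < alpha
    out = out.sort_values(
        ["unmapped", "chrom", "cM", "marker"], na_position="last"
    ).reset_index(drop=True)
    cols = [
        "marker", "chrom", "cM", "effect", "allele", "maf",
        "p", "q", "neg_log10_q", "significant", "unmapped",
    ]
    return out[cols]
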