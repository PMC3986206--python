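"""Population structure: genotype PCA, Evanno delta-k, membership assignment.

Admixture inference itself (STRUCTURE) is an external tool: this module
consumes its membership (Q) matrices and LnP(D) series and implements the
bespoke parts — the Evanno second-difference statistic used to choose k,
the >0.8 membership threshold that defines the "admixed" class, and a
genotype PCA matching common practice (mean imputation, centering, no
scaling, SVD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GeneticMap, GenotypeMatrix, MembershipMatrix
from .curation import allele_frequencies

ADMIXED = "admixed"


@dataclass
class PCAResult:
    scores: pd.DataFrame  # accessions x components ("PC1"..)
    variance_explained: np.ndarray  # fraction per kept component
    marker_means: pd.Series  # centering means per marker used

    def __post_init__(self):
        ve = np.asarray(self.variance_explained, float)
        if (np.diff(ve) > 1e-12).any():
            raise ValueError("variance fractions must be non-increasing")
        if ve.sum() > 1 + 1e-9:
            raise ValueError("variance fractions sum above 1")


def pca_genotypes(G: GenotypeMatrix, n_components: int, maf_min: float = 0.01) -> PCAResult:
    """PCA of the call matrix after MAF filtering and mean imputation.

    Missing calls are imputed to the marker mean, columns centered (no
    unit-variance scaling), scores taken from the SVD. Component sign is
    fixed so each component's largest-magnitude loading is positive.
    """
    af = allele_frequencies(G)
    if (af["n_observed"] == 0).any():
        raise ValueError("marker with no observed calls; QC first")
    keep = np.where(af["maf"].to_numpy() >= maf_min)[0]
    if len(keep) < n_components:
        raise ValueError(
            f"only {len(keep)} markers pass MAF >= {maf_min}; need {n_components}"
        )
    X = G.calls[:, keep].copy()
    means = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    X[nan] = np.broadcast_to(means, X.shape)[nan]
    Xc = X - means
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_components = min(n_components, len(s))
    # sign convention: largest-|loading| entry of each component positive
    for c in range(n_components):
        peak = np.argmax(np.abs(Vt[c]))
        if Vt[c, peak] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    scores = U[:, :n_components] * s[:n_components]
    total_var = (s**2).sum()
    ve = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=G.accessions, columns=cols),
        variance_explained=ve,
        marker_means=pd.Series(means, index=[G.markers[j] for j in keep]),
    )


def evanno_delta_k(lnpd: pd.DataFrame) -> pd.DataFrame:
    """Evanno's delta-k from replicate LnP(D) runs.

    delta_k(k) = |mean L(k+1) - 2 mean L(k) + mean L(k-1)| / sd_runs L(k),
    defined for interior k only. A zero run-to-run sd with a nonzero second
    difference yields +inf (flagged, not an exception).
    """
    need = {"k", "run", "lnpd"}
    if not need.issubset(lnpd.columns):
        raise ValueError(f"LnP(D) table needs columns {sorted(need)}")
    by_k = lnpd.groupby("k")["lnpd"]
    counts = by_k.count()
    if (counts < 3).any():
        raise ValueError("need >= 3 runs per k for delta-k")
    ks = np.sort(lnpd["k"].unique())
    if len(ks) < 3:
        raise ValueError("need >= 3 k values for delta-k")
    if not np.array_equal(ks, np.arange(ks[0], ks[-1] + 1)):
        raise ValueError("k range must be contiguous")
    mean = by_k.mean()
    sd = by_k.std(ddof=1)
    rows = []
    for k in ks[1:-1]:
        second = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
        if sd[k] == 0:
            dk = np.inf if second > 0 else 0.0
        else:
            dk = second / sd[k]
        rows.append((int(k), dk, mean[k], sd[k]))
    return pd.DataFrame(rows, columns=["k", "delta_k", "mean_lnpd", "sd_lnpd"]).set_index("k")


def assign_subpopulations(Q: MembershipMatrix, threshold: float = 0.8) -> pd.Series:
    """Label each accession by arg-max membership if it exceeds the threshold.

    The boundary is strict: a maximum coefficient equal to the threshold is
    "admixed", matching the convention of assigning only membership
    probabilities greater than 0.80.
    """
    best = Q.q.argmax(axis=1)
    labels = np.where(
        Q.q.max(axis=1) > threshold,
        [f"subpop{b + 1}" for b in best],
        ADMIXED,
    )
    return pd.Series(labels, index=Q.accessions, name="subpopulation")


def label_counts(labels: pd.Series) -> pd.DataFrame:
    """Per-subpopulation accession counts (cluster-composition table schema)."""
    c = labels.value_counts().rename_axis("cluster").to_frame("n_accessions")
    return c.sort_index()


def thin_one_per_bin(G: GenotypeMatrix, genetic_map: GeneticMap) -> GenotypeMatrix:
    """Keep one marker per identical-position map bin (the least-missing one)."""
    bins = genetic_map.bins()
    miss = np.isnan(G.calls).mean(axis=0)
    frame = pd.DataFrame(
        {"marker": G.markers, "bin": bins.reindex(G.markers).to_numpy(), "miss": miss}
    )
    keep_names = (
        frame.sort_values(["bin", "miss", "marker"]).groupby("bin").head(1)["marker"]
    )
    keep = sorted(G.marker_index(keep_names))
    return G.subset(marker_idx=keep)
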