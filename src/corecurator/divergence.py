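"""Per-SNP divergence between subpopulations via one-level AMOVA (Phi_PT).

Phi_PT = V_AP / (V_AP + V_WP) partitions the variance of a binary SNP call
among and within labeled groups using squared-difference distances — the
ploidy-free analogue of F_ST appropriate for inbred 0/1 calls. Significance
comes from permuting group labels across accessions. The one-vs-rest scan
pools every non-focal group and reports Phi_PT^10 as a display column that
spreads the top of the scale (the convention of the differentiation plots
this module reproduces).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GeneticMap, GenotypeMatrix
from .structure import ADMIXED


@dataclass
class PhiResult:
    marker: str
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    ms_among: float
    ms_within: float
    n0: float
    v_ap: float
    v_wp: float
    phi_raw: float
    phi_pt: float
    n_per_group: dict
    p_perm: float | None = None

    @property
    def phi_pow10(self) -> float:
        return self.phi_pt**10


def _group_indicator(labels: np.ndarray) -> tuple[np.ndarray, list]:
    groups = sorted(pd.unique(labels))
    Z = np.stack([(labels == g).astype(float) for g in groups])
    return Z, groups


def _phi_from_counts(n_g: np.ndarray, s_g: np.ndarray):
    """Vectorized AMOVA over markers from per-group observed counts/sums.

    n_g, s_g: (groups x markers). Groups with fewer than two observed calls
    at a marker are dropped there; markers left with fewer than two
    qualifying groups are invalid (NaN).
    """
    qual = n_g >= 2
    g_eff = qual.sum(axis=0)
    n_q = np.where(qual, n_g, 0.0)
    s_q = np.where(qual, s_g, 0.0)
    N = n_q.sum(axis=0)
    T = s_q.sum(axis=0)
    valid = g_eff >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ss_total = T - T**2 / N
        ss_within = np.where(qual, s_q - s_q**2 / np.where(n_q > 0, n_q, 1), 0.0).sum(axis=0)
        ss_among = ss_total - ss_within
        df_a = g_eff - 1.0
        df_w = N - g_eff
        ms_a = ss_among / df_a
        ms_w = ss_within / df_w
        n0 = (N - (n_q**2).sum(axis=0) / N) / df_a
        v_wp = ms_w
        v_ap = (ms_a - ms_w) / n0
        denom_raw = v_ap + v_wp
        phi_raw = np.where(denom_raw != 0, v_ap / np.where(denom_raw != 0, denom_raw, 1), 0.0)
        v_ap_c = np.maximum(v_ap, 0.0)
        denom = v_ap_c + v_wp
        phi = np.where(denom > 0, v_ap_c / np.where(denom > 0, denom, 1), 0.0)
    bad = ~valid
    for arr in (ss_among, ss_within, ms_a, ms_w, n0, v_ap, v_wp, phi_raw, phi):
        arr[bad] = np.nan
    return {
        "ss_among": ss_among, "ss_within": ss_within,
        "df_among": df_a, "df_within": df_w,
        "ms_among": ms_a, "ms_within": ms_w, "n0": n0,
        "v_ap": v_ap, "v_wp": v_wp, "phi_raw": phi_raw, "phi_pt": phi,
        "valid": valid,
    }


def _counts(Z: np.ndarray, calls: np.ndarray):
    O = (~np.isnan(calls)).astype(float)
    X0 = np.where(np.isnan(calls), 0.0, calls)
    return Z @ O, Z @ X0


def phi_pt_single(calls: np.ndarray, labels) -> PhiResult:
    """AMOVA Phi_PT for one marker; missing calls dropped per group."""
    calls = np.asarray(calls, dtype=float).reshape(1, -1).T  # accessions x 1
    labels = np.asarray(labels)
    Z, groups = _group_indicator(labels)
    n_g, s_g = _counts(Z, calls)
    r = _phi_from_counts(n_g, s_g)
    if not r["valid"][0]:
        raise ValueError("fewer than 2 groups with >= 2 non-missing calls")
    n_per_group = {g: int(n_g[i, 0]) for i, g in enumerate(groups) if n_g[i, 0] >= 2}
    return PhiResult(
        marker="",
        ss_among=float(r["ss_among"][0]), ss_within=float(r["ss_within"][0]),
        df_among=int(r["df_among"][0]), df_within=int(r["df_within"][0]),
        ms_among=float(r["ms_among"][0]), ms_within=float(r["ms_within"][0]),
        n0=float(r["n0"][0]), v_ap=float(r["v_ap"][0]), v_wp=float(r["v_wp"][0]),
        phi_raw=float(r["phi_raw"][0]), phi_pt=float(r["phi_pt"][0]),
        n_per_group=n_per_group,
    )


def phi_pt_scan(
    calls: np.ndarray,
    labels,
    n_perm: int = 0,
    seed: int | None = None,
    batch: int = 200,
) -> pd.DataFrame:
    """Vectorized Phi_PT over all markers, with optional permutation p-values.

    One set of label permutations is drawn per scan and reused across
    markers; p = (1 + #{phi_perm >= phi_obs}) / (1 + n_perm), so a null
    marker can never receive p = 0.
    """
    calls = np.asarray(calls, dtype=float)
    labels = np.asarray(labels)
    Z, groups = _group_indicator(labels)
    n_g, s_g = _counts(Z, calls)
    obs = _phi_from_counts(n_g, s_g)
    out = pd.DataFrame({k: v for k, v in obs.items() if k != "valid"})
    out["valid"] = obs["valid"]
    for i, g in enumerate(groups):
        out[f"n_{g}"] = n_g[i].astype(int)
    if n_perm:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        n_acc = calls.shape[0]
        phi_obs = obs["phi_pt"]
        count_ge = np.zeros(calls.shape[1])
        done = 0
        O = (~np.isnan(calls)).astype(float)
        X0 = np.where(np.isnan(calls), 0.0, calls)
        while done < n_perm:
            b = min(batch, n_perm - done)
            perms = np.stack([rng.permutation(n_acc) for _ in range(b)])
            for p in perms:
                Zp = Z[:, p]
                r = _phi_from_counts(Zp @ O, Zp @ X0)
                with np.errstate(invalid="ignore"):
                    count_ge += np.where(
                        np.isnan(r["phi_pt"]), 0.0, (r["phi_pt"] >= phi_obs - 1e-12)
                    )
            done += b
        out["p_perm"] = (1.0 + count_ge) / (1.0 + n_perm)
        out.loc[~out["valid"], "p_perm"] = np.nan
    out["phi_pow10"] = out["phi_pt"] ** 10
    return out


def multilocus_phi(scan: pd.DataFrame) -> float:
    """Combined Phi_PT over markers: ratio of summed variance components.

    The AMOVA convention for combining loci sums V_AP and V_WP across
    markers before forming the ratio; unlike the arithmetic mean of
    per-marker ratios, this estimator converges to the generating F of a
    Balding-Nichols population.
    """
    ok = scan["valid"] if "valid" in scan else scan["phi_pt"].notna()
    v_ap = np.maximum(scan.loc[ok, "v_ap"], 0).sum()
    v_wp = scan.loc[ok, "v_wp"].sum()
    if v_ap + v_wp <= 0:
        return 0.0
    return float(v_ap / (v_ap + v_wp))


def phi_pt_permutation(calls: np.ndarray, labels, n_perm: int = 1000, seed: int | None = None) -> float:
    """Permutation p-value for a single marker."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    res = phi_pt_scan(np.asarray(calls, float).reshape(-1, 1), labels, n_perm=n_perm, seed=seed)
    if not res["valid"].iloc[0]:
        raise ValueError("phi_pt undefined for observed labels")
    return float(res["p_perm"].iloc[0])


def one_vs_rest_scan(
    G: GenotypeMatrix,
    labels: pd.Series,
    focal_label: str,
    genetic_map: GeneticMap | None = None,
    n_perm: int = 0,
    seed: int | None = None,
    include_admixed: bool = False,
) -> pd.DataFrame:
    """Phi_PT per marker for one subpopulation against all others pooled.

    Admixed accessions are excluded by default (only confidently assigned
    accessions enter the divergence scan). Output is sorted by map position
    when a map is given and carries the phi_pt^10 display column.
    """
    labels = labels.reindex(G.accessions)
    use = labels.notna()
    if not include_admixed:
        use &= labels != ADMIXED
    lab = labels[use]
    if focal_label not in set(lab):
        raise ValueError(f"focal label {focal_label!r} absent")
    pooled = np.where(lab == focal_label, focal_label, "rest")
    idx = G.accession_index(lab.index)
    res = phi_pt_scan(G.calls[idx], pooled, n_perm=n_perm, seed=seed)
    res.insert(0, "marker", G.markers)
    if genetic_map is not None:
        pos = genetic_map.positions(G.markers)
        res.insert(1, "chrom", pos["chrom"].to_numpy())
        res.insert(2, "cM", pos["cM"].to_numpy())
        res = res.sort_values(["chrom", "cM", "marker"]).reset_index(drop=True)
    return res
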