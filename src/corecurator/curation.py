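"""Genotype QC and detection of genetically identical accessions.

The curation pipeline for an inbred SNP panel: mask heterozygous calls to
missing, drop markers then accessions exceeding a missing-call threshold,
and flag duplicate accessions as groups sharing all alleles on their
co-observed markers (simple-matching similarity exactly 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

log = logging.getLogger(__name__)


def _require_masked(G: GenotypeMatrix):
    if G.het_mask is not None and (G.calls == 0.5).any():
        raise ValueError("heterozygous calls present: run mask_heterozygotes first")


def mask_heterozygotes(G: GenotypeMatrix) -> GenotypeMatrix:
    """Convert every het-flagged call to missing; other calls untouched."""
    if G.het_mask is None:
        raise ValueError("no het flags present")
    calls = G.calls.copy()
    calls[G.het_mask] = np.nan
    return GenotypeMatrix(G.accessions, G.markers, calls, np.zeros_like(G.het_mask))


def qc_filter(
    G: GenotypeMatrix,
    max_marker_missing: float = 0.10,
    max_accession_missing: float = 0.10,
) -> GenotypeMatrix:
    """Drop markers then accessions whose missing fraction exceeds the threshold.

    Order is fixed: markers first (assay-level failures), then accessions
    evaluated over the surviving markers.
    """
    _require_masked(G)
    for t in (max_marker_missing, max_accession_missing):
        if not (0 <= t <= 1):
            raise ValueError("thresholds must lie in [0,1]")
    miss = np.isnan(G.calls)
    keep_mk = np.where(miss.mean(axis=0) <= max_marker_missing)[0]
    log.info("qc_filter: dropped %d/%d markers", G.n_markers - len(keep_mk), G.n_markers)
    if len(keep_mk) == 0:
        raise ValueError("no markers survive QC: review max_marker_missing")
    miss2 = miss[:, keep_mk]
    keep_acc = np.where(miss2.mean(axis=1) <= max_accession_missing)[0]
    log.info(
        "qc_filter: dropped %d/%d accessions", G.n_accessions - len(keep_acc), G.n_accessions
    )
    if len(keep_acc) == 0:
        raise ValueError("no accessions survive QC: review max_accession_missing")
    return G.subset(keep_acc, keep_mk)


def allele_frequencies(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker frequency of allele 1 and MAF over non-missing calls.

    Markers with zero observed calls get NaN frequency and ``observed`` 0.
    """
    _require_masked(G)
    obs = G.observed
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_obs > 0, np.nansum(G.calls, axis=0) / np.maximum(n_obs, 1), np.nan)
    maf = np.minimum(freq, 1 - freq)
    return pd.DataFrame(
        {"marker": G.markers, "freq": freq, "maf": maf, "n_observed": n_obs}
    ).set_index("marker")


def simple_matching_similarity(G: GenotypeMatrix, i, j) -> tuple[float, int]:
    """Simple-matching coefficient between two accessions on co-observed markers."""
    if isinstance(i, str):
        i = G.accessions.index(i)
    if isinstance(j, str):
        j = G.accessions.index(j)
    if i == j:
        raise ValueError("i and j must differ")
    a, b = G.calls[i], G.calls[j]
    both = ~np.isnan(a) & ~np.isnan(b)
    n = int(both.sum())
    if n == 0:
        return (np.nan, 0)
    return (float((a[both] == b[both]).mean()), n)


@dataclass
class DuplicateReport:
    """Groups of genetically identical accessions and the retention decision."""

    sets: list  # list of frozensets of accession ids
    pair_overlaps: pd.DataFrame  # columns acc_a, acc_b, n_compared
    retained: list = field(default_factory=list)
    removed: pd.DataFrame | None = None  # columns accession, set_id, reason

    def __post_init__(self):
        seen = set()
        for s in self.sets:
            if len(s) < 2:
                raise ValueError("duplicate sets must have >= 2 members")
            if seen & s:
                raise ValueError("duplicate sets must be disjoint")
            seen |= s


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def find_duplicates(G: GenotypeMatrix, min_overlap_fraction: float = 0.5) -> DuplicateReport:
    """Connected components of the exact-match graph.

    A pair is an edge when its simple-matching similarity is exactly 1 and
    the co-observed marker count is at least ``min_overlap_fraction`` of
    the panel size. Match/mismatch counts come from matrix products, so the
    scan is O(n^2 m) in BLAS rather than Python loops.
    """
    _require_masked(G)
    X = G.calls
    obs = G.observed.astype(float)
    A = np.where(np.isnan(X), 0.0, X)  # allele-1 indicator on observed
    B = obs - A  # allele-0 indicator on observed
    matches = A @ A.T + B @ B.T
    co = obs @ obs.T
    mismatches = co - matches
    min_co = min_overlap_fraction * G.n_markers
    edge = (mismatches < 0.5) & (co >= min_co)
    np.fill_diagonal(edge, False)

    uf = _UnionFind(G.n_accessions)
    ii, jj = np.nonzero(np.triu(edge, 1))
    for i, j in zip(ii, jj):
        uf.union(int(i), int(j))
    comps = {}
    for i in range(G.n_accessions):
        comps.setdefault(uf.find(i), []).append(i)
    sets, rows = [], []
    for members in comps.values():
        if len(members) < 2:
            continue
        sets.append(frozenset(G.accessions[i] for i in members))
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                rows.append((G.accessions[i], G.accessions[j], int(co[i, j])))
    overlaps = pd.DataFrame(rows, columns=["acc_a", "acc_b", "n_compared"])
    log.info("find_duplicates: %d sets covering %d accessions",
             len(sets), sum(len(s) for s in sets))
    return DuplicateReport(sets=sorted(sets, key=lambda s: sorted(s)[0]), pair_overlaps=overlaps)


def resolve_duplicates(
    report: DuplicateReport,
    G: GenotypeMatrix,
    metadata: pd.DataFrame | None = None,
    policy: str = "keep-most-complete",
) -> list:
    """Retain one accession per duplicate set; return the full retained list.

    ``keep-first`` keeps the lexicographically first id; ``keep-most-complete``
    keeps the member with the fewest missing calls (ties to the first id).
    Sets whose members disagree on metadata fields are annotated, not resolved.
    """
    if policy not in ("keep-first", "keep-most-complete"):
        raise ValueError(f"unknown policy {policy!r}")
    missing_per_acc = dict(zip(G.accessions, np.isnan(G.calls).sum(axis=1)))
    in_any_set = set().union(*report.sets) if report.sets else set()
    retained = [a for a in G.accessions if a not in in_any_set]
    removed_rows = []
    for sid, s in enumerate(report.sets):
        members = sorted(s)
        if policy == "keep-first":
            keep = members[0]
        else:
            keep = min(members, key=lambda a: (missing_per_acc[a], a))
        conflict = ""
        if metadata is not None:
            sub = metadata.reindex(members).dropna(how="all")
            if len(sub) and any(sub[c].nunique(dropna=True) > 1 for c in sub.columns):
                conflict = "metadata conflict"
        retained.append(keep)
        for a in members:
            if a != keep:
                reason = f"duplicate of {keep} (set {sid})"
                if conflict:
                    reason += f"; {conflict}"
                removed_rows.append((a, sid, reason))
        log.info("set %d: retained %s%s", sid, keep, f" [{conflict}]" if conflict else "")
    report.retained = [a for a in G.accessions if a in set(retained)]
    report.removed = pd.DataFrame(removed_rows, columns=["accession", "set_id", "reason"])
    return report.retained
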