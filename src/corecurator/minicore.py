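"""Stepwise PIC-maximization ranking and mini-core selection.

Accessions are removed one at a time, always the one whose removal yields
the highest average polymorphism information content (PIC) of the retained
set over the mapped markers. While redundant accessions remain, removals do
not decrease the average PIC; the first removal that would decrease it
marks the peak set size — the smallest subset still carrying the panel's
diversity. Accessions are ranked by how long they survive the process, and
a mini-core is the top-ranked slice (conventionally 10%).

PIC here defaults to the gene-diversity form 1 - sum p_i^2 (maximum 0.5
for a biallelic SNP); the full Botstein form is available via
``pic_form="botstein"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

log = logging.getLogger(__name__)

PIC_FORMS = ("gene-diversity", "botstein")


def pic_per_marker(freqs, form: str = "gene-diversity") -> float:
    """PIC of one marker from its allele frequencies."""
    p = np.asarray(freqs, float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("allele frequencies must sum to 1")
    if form == "gene-diversity":
        return float(1.0 - np.sum(p**2))
    if form == "botstein":
        cross = np.sum(np.outer(p**2, p**2)) - np.sum(p**4)
        return float(1.0 - np.sum(p**2) - cross)
    raise ValueError(f"unknown PIC form {form!r}")


def _pic_from_freq(p: np.ndarray, form: str) -> np.ndarray:
    """Vectorized biallelic PIC from allele-1 frequency array."""
    q = 1.0 - p
    base = 1.0 - p**2 - q**2
    if form == "gene-diversity":
        return base
    if form == "botstein":
        return base - 2.0 * p**2 * q**2
    raise ValueError(f"unknown PIC form {form!r}")


def average_pic(
    G: GenotypeMatrix,
    subset=None,
    marker_mask=None,
    form: str = "gene-diversity",
) -> float:
    """Mean per-marker PIC over a subset of accessions.

    Frequencies use the subset's non-missing calls only; markers with no
    observed call in the subset are excluded from the average.
    """
    idx = (
        np.arange(G.n_accessions)
        if subset is None
        else G.accession_index(subset)
    )
    if len(idx) < 2:
        raise ValueError("subset must have >= 2 accessions")
    calls = G.calls[idx]
    if marker_mask is not None:
        calls = calls[:, np.asarray(marker_mask, bool)]
    obs = ~np.isnan(calls)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(calls, axis=0) / np.where(n_obs > 0, n_obs, 1)
    pic = _pic_from_freq(p, form)
    valid = n_obs > 0
    if not valid.any():
        raise ValueError("no marker observed in the subset")
    return float(pic[valid].mean())


@dataclass
class PICRanking:
    """Removal-order ranking with the average-PIC trajectory and its peak."""

    removal_order: list  # first-removed .. last-removed
    ranks: pd.Series  # rank 1 = highest contribution (last remaining)
    trajectory: pd.Series  # retained-set size -> average PIC after reaching it
    peak_size: int
    pic_form: str = "gene-diversity"
    n_markers: int = 0
    remaining: list = field(default_factory=list)

    def ranking_table(self) -> pd.DataFrame:
        steps = {a: i + 1 for i, a in enumerate(self.removal_order)}
        n = len(self.ranks)
        rows = []
        for acc, rank in self.ranks.sort_values().items():
            step = steps.get(acc, np.nan)
            size_after = n - step if acc in steps else len(self.remaining)
            avg = self.trajectory.get(size_after, np.nan)
            rows.append((acc, int(rank), step, avg))
        return pd.DataFrame(
            rows, columns=["accession", "rank", "removal_step", "avg_pic_after_removal"]
        )


def rank_accessions(
    G: GenotypeMatrix,
    marker_mask=None,
    min_size: int = 2,
    form: str = "gene-diversity",
) -> PICRanking:
    """Greedy stepwise ranking by contribution to the average PIC.

    At each step every single-accession removal is scored and the one
    leaving the highest average PIC is applied (ties broken by accession-id
    order). The engine keeps per-marker allele counts so each candidate is
    scored in O(markers); the trajectory and the peak retained-set size are
    recorded. Ranking continues past the peak down to ``min_size`` so every
    accession receives a rank.
    """
    n = G.n_accessions
    if n < min_size + 1:
        raise ValueError(f"need more than min_size={min_size} accessions")
    calls = G.calls
    if marker_mask is not None:
        calls = calls[:, np.asarray(marker_mask, bool)]
    m = calls.shape[1]
    obs = (~np.isnan(calls)).astype(float)
    x1 = np.where(np.isnan(calls), 0.0, calls)

    ids = np.array(G.accessions, dtype=object)
    order_key = np.argsort(ids)  # lexicographic tie-break
    tie_rank = np.empty(n, int)
    tie_rank[order_key] = np.arange(n)

    active = np.ones(n, dtype=bool)
    n1 = x1.sum(axis=0)
    nobs = obs.sum(axis=0)

    def avg_of(counts1, counts_obs):
        valid = counts_obs > 0
        with np.errstate(invalid="ignore"):
            p = counts1 / np.where(valid, counts_obs, 1)
        pic = _pic_from_freq(p, form)
        s = (pic * valid).sum(axis=-1)
        cnt = valid.sum(axis=-1)
        return np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)

    trajectory = {n: float(avg_of(n1, nobs))}
    removal_order = []
    while active.sum() > min_size:
        cand = np.where(active)[0]
        n1_new = n1[None, :] - x1[cand]
        nobs_new = nobs[None, :] - obs[cand]
        scores = avg_of(n1_new, nobs_new)
        best = scores.max()
        winners = cand[scores >= best - 1e-15]
        pick = winners[np.argmin(tie_rank[winners])]
        active[pick] = False
        n1 = n1 - x1[pick]
        nobs = nobs - obs[pick]
        removal_order.append(str(ids[pick]))
        trajectory[int(active.sum())] = float(best)

    remaining = sorted(str(a) for a in ids[active])
    best_to_worst = remaining + removal_order[::-1]
    ranks = pd.Series(
        {acc: r + 1 for r, acc in enumerate(best_to_worst)}, name="rank"
    ).reindex([str(a) for a in ids])

    traj = pd.Series(trajectory).sort_index(ascending=False)
    peak_size = int(traj.idxmax())  # earliest (largest size) if tied
    log.info("rank_accessions: n=%d, peak at retained size %d", n, peak_size)
    return PICRanking(
        removal_order=removal_order,
        ranks=ranks,
        trajectory=traj,
        peak_size=peak_size,
        pic_form=form,
        n_markers=m,
        remaining=remaining,
    )


@dataclass
class MiniCore:
    accessions: list
    size: int
    peak_size: int
    below_peak_warning: bool


def select_minicore(ranking: PICRanking, size: int | None = None, fraction: float | None = None) -> MiniCore:
    """Top-ranked accessions as a mini-core.

    Selecting fewer accessions than the PIC-peak set size is flagged: a
    subset smaller than the peak discards diversity-carrying accessions.
    """
    n = len(ranking.ranks)
    if (size is None) == (fraction is None):
        raise ValueError("give exactly one of size or fraction")
    if fraction is not None:
        size = max(1, int(round(fraction * n)))
    if size > n:
        raise ValueError("size exceeds number of ranked accessions")
    chosen = list(ranking.ranks.sort_values().index[:size])
    warn = size < ranking.peak_size
    if warn:
        log.warning(
            "mini-core of %d is smaller than the PIC peak size %d; "
            "selection below the peak is not recommended",
            size, ranking.peak_size,
        )
    return MiniCore(chosen, size, ranking.peak_size, warn)


def group_restricted_ranking(
    G: GenotypeMatrix,
    group,
    marker_mask=None,
    min_size: int = 2,
    form: str = "gene-diversity",
) -> PICRanking:
    """PIC ranking within one accession group (frequencies computed in-group)."""
    idx = G.accession_index(group)
    if len(idx) < 3:
        raise ValueError("group must have >= 3 accessions")
    return rank_accessions(G.subset(accession_idx=idx), marker_mask, min_size, form)
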