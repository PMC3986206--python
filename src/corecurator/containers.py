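"""Core in-memory containers shared by every analysis stage.

Genotypes are biallelic calls on inbred accessions coded 0/1 with ``nan``
for missing; heterozygous raw calls carry a boolean flag so that masking
is an explicit, auditable step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = np.nan


def _check_unique(ids, what):
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")


@dataclass
class GenotypeMatrix:
    """Accessions x markers call matrix with values in {0, 1, missing}.

    Parameters
    ----------
    accessions, markers : ordered unique identifier lists.
    calls : float array (n_accessions, n_markers); missing is ``nan``.
    het_mask : optional bool array flagging raw heterozygous calls
        (before they are masked to missing).
    """

    accessions: list
    markers: list
    calls: np.ndarray
    het_mask: np.ndarray | None = None

    def __post_init__(self):
        self.accessions = list(self.accessions)
        self.markers = list(self.markers)
        _check_unique(self.accessions, "accession")
        _check_unique(self.markers, "marker")
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.accessions), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.accessions)} accessions x {len(self.markers)} markers"
            )
        ok = np.isnan(self.calls) | (self.calls == 0) | (self.calls == 1)
        if self.het_mask is not None:
            self.het_mask = np.asarray(self.het_mask, dtype=bool)
            if self.het_mask.shape != self.calls.shape:
                raise ValueError("het_mask shape mismatch")
            # raw heterozygous calls are held as 0.5 until masked to missing
            ok |= self.het_mask & (self.calls == 0.5)
        if not ok.all():
            raise ValueError("calls must be 0, 1 or missing (0.5 only where het-flagged)")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.calls)

    def accession_index(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accessions)}
        return np.array([lookup[a] for a in ids], dtype=int)

    def marker_index(self, ids) -> np.ndarray:
        lookup = {m: j for j, m in enumerate(self.markers)}
        return np.array([lookup[m] for m in ids], dtype=int)

    def subset(self, accession_idx=None, marker_idx=None) -> "GenotypeMatrix":
        acc = np.arange(self.n_accessions) if accession_idx is None else np.asarray(accession_idx)
        mk = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        het = None if self.het_mask is None else self.het_mask[np.ix_(acc, mk)]
        return GenotypeMatrix(
            [self.accessions[i] for i in acc],
            [self.markers[j] for j in mk],
            self.calls[np.ix_(acc, mk)],
            het,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.accessions, columns=self.markers)


@dataclass
class GeneticMap:
    """Per-marker chromosome and centimorgan position."""

    frame: pd.DataFrame  # columns: marker, chrom, cM

    def __post_init__(self):
        need = {"marker", "chrom", "cM"}
        if not need.issubset(self.frame.columns):
            raise ValueError(f"map needs columns {sorted(need)}")
        _check_unique(list(self.frame["marker"]), "map marker")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def markers(self) -> list:
        return list(self.frame["marker"])

    def positions(self, markers) -> pd.DataFrame:
        return self.frame.set_index("marker").loc[list(markers)].reset_index()

    def chromosomes(self) -> list:
        return list(pd.unique(self.frame["chrom"]))

    def bins(self) -> pd.Series:
        """Group id per marker: markers sharing (chrom, cM) fall in one bin."""
        key = self.frame["chrom"].astype(str) + ":" + self.frame["cM"].round(6).astype(str)
        return pd.Series(pd.factorize(key)[0], index=self.frame["marker"])

    def window(self, chrom, lo_cM, hi_cM) -> list:
        f = self.frame
        sel = (f["chrom"] == chrom) & (f["cM"] >= lo_cM) & (f["cM"] < hi_cM)
        return list(f.loc[sel, "marker"])


@dataclass
class MembershipMatrix:
    """Accessions x k admixture membership coefficients (rows sum to 1)."""

    accessions: list
    q: np.ndarray
    source: str = "external"

    def __post_init__(self):
        self.accessions = list(self.accessions)
        _check_unique(self.accessions, "accession")
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[0] != len(self.accessions):
            raise ValueError("Q shape inconsistent with accession list")
        if (self.q < -1e-9).any() or (self.q > 1 + 1e-9).any():
            raise ValueError("Q coefficients must lie in [0,1]")
        rows = self.q.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1 within 1e-6")

    @property
    def k(self) -> int:
        return self.q.shape[1]

    def reindex(self, accessions) -> "MembershipMatrix":
        lookup = {a: i for i, a in enumerate(self.accessions)}
        idx = [lookup[a] for a in accessions]
        return MembershipMatrix(list(accessions), self.q[idx], self.source)
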