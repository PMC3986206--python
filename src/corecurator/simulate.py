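"""Synthetic structured-genotype generator.

Emulates a genebank core collection of inbred barley-like accessions: five
admixed subpopulations whose allele frequencies follow the Balding–Nichols
model around ancestral frequencies, markers laid out on a seven-chromosome
genetic map (1,113 cM total), distance-decaying linkage disequilibrium from
a first-order copy chain, planted exact-duplicate accessions, planted QTL
for quantitative/binary traits, and independent missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GeneticMap, GenotypeMatrix, MembershipMatrix

# Consensus-map chromosome lengths (cM) of the barley study this package
# emulates; they sum to 1,113 cM over 7 chromosomes.
DEFAULT_CHROM_LENGTHS = [145.0, 181.0, 164.0, 130.0, 185.0, 139.0, 169.0]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    The defaults mirror the structure of a genotyped genebank core
    collection: k=5 subpopulations of unequal size plus a large admixed
    class, thousands of mapped SNPs, moderate differentiation, and
    low missingness.
    """

    n_subpops: int = 5
    n_per_subpop: list = field(default_factory=lambda: [50, 68, 68, 52, 22])
    n_admixed: int = 205
    dirichlet_alpha: float = 0.5
    n_markers: int = 2000
    n_chromosomes: int = 7
    chrom_lengths_cM: list = field(default_factory=lambda: list(DEFAULT_CHROM_LENGTHS))
    fst_per_subpop: list = field(default_factory=lambda: [0.15, 0.15, 0.15, 0.15, 0.15])
    ancestral_maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.02
    ld_decay_cM: float = 2.0
    duplicate_sets: list = field(default_factory=list)  # list of set sizes
    qtl_spec: list = field(default_factory=list)  # list of (marker index, effect)
    heritability: float = 0.5
    seed: int = 0

    def validate(self):
        if self.n_chromosomes != len(self.chrom_lengths_cM):
            raise ValueError("chrom_lengths_cM length must equal n_chromosomes")
        if any(l <= 0 for l in self.chrom_lengths_cM):
            raise ValueError("chromosome lengths must be positive")
        if sum(self.chrom_lengths_cM) <= 0:
            raise ValueError("total map length must be positive")
        if len(self.n_per_subpop) != self.n_subpops:
            raise ValueError("n_per_subpop length must equal n_subpops")
        if len(self.fst_per_subpop) != self.n_subpops:
            raise ValueError("fst_per_subpop length must equal n_subpops")
        if any(not (0 < f < 1) for f in self.fst_per_subpop):
            raise ValueError("each subpopulation F must lie in (0,1)")
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0,1)")
        if self.ld_decay_cM < 0:
            raise ValueError("ld_decay_cM must be non-negative")
        if self.n_markers < self.n_chromosomes:
            raise ValueError("need at least one marker per chromosome")
        if not (0 <= self.heritability <= 1):
            raise ValueError("heritability must lie in [0,1]")
        return self


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a simulated genotype matrix."""

    true_q: MembershipMatrix
    duplicate_sets: list  # list of frozensets of accession ids
    qtl_markers: list
    subpop_freqs: np.ndarray  # k x m Balding–Nichols frequencies
    labels: list  # generating subpopulation label per accession ("admixed" for Dirichlet rows)


def generate_map(config: SimulationConfig) -> GeneticMap:
    """Lay markers on chromosomes proportionally to map length.

    Marker counts per chromosome follow a largest-remainder apportionment
    of ``n_markers`` by chromosome length (at least one per chromosome);
    positions are uniform draws sorted within each chromosome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths = np.asarray(config.chrom_lengths_cM, dtype=float)
    quota = config.n_markers * lengths / lengths.sum()
    counts = np.maximum(np.floor(quota).astype(int), 1)
    # distribute the remainder to the largest fractional parts
    rem = config.n_markers - counts.sum()
    order = np.argsort(-(quota - np.floor(quota)))
    i = 0
    while rem > 0:
        counts[order[i % len(counts)]] += 1
        rem -= 1
        i += 1
    while rem < 0:  # possible when the min-1 floor over-allocated
        j = np.argmax(counts)
        counts[j] -= 1
        rem += 1

    rows = []
    mid = 0
    for c, (n_c, length) in enumerate(zip(counts, lengths), start=1):
        pos = np.sort(rng.uniform(0.0, length, size=n_c))
        for p in pos:
            rows.append((f"snp{mid:05d}", f"{c}H", float(p)))
            mid += 1
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "cM"]))


def _membership(config: SimulationConfig, rng) -> tuple[np.ndarray, list, list]:
    k = config.n_subpops
    q_rows, labels, ids = [], [], []
    for s, n_s in enumerate(config.n_per_subpop):
        for _ in range(n_s):
            row = np.zeros(k)
            row[s] = 1.0
            q_rows.append(row)
            labels.append(f"subpop{s + 1}")
    for _ in range(config.n_admixed):
        q_rows.append(rng.dirichlet(np.full(k, config.dirichlet_alpha)))
        labels.append("admixed")
    ids = [f"acc{i:04d}" for i in range(len(q_rows))]
    return np.array(q_rows), labels, ids


def generate_genotypes(
    config: SimulationConfig, genetic_map: GeneticMap
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Draw a structured genotype matrix and its ground truth.

    Per marker an ancestral frequency is drawn uniformly from
    ``ancestral_maf_range``; subpopulation frequencies follow
    Balding–Nichols Beta(p(1-F)/F, (1-p)(1-F)/F). Each accession's call is
    Bernoulli(sum_k q_ik p_kj), except that with probability exp(-d/lambda)
    a call copies the previous marker's call on the same chromosome, which
    imposes distance-decaying LD. Duplicate rows are copied before
    missingness so duplicates agree on co-observed calls without being
    bitwise-identical rows.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    m = config.n_markers
    k = config.n_subpops

    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    subpop_freqs = np.empty((k, m))
    for s, f in enumerate(config.fst_per_subpop):
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        subpop_freqs[s] = rng.beta(a, b)

    q, labels, ids = _membership(config, rng)
    n = len(ids)
    pi = q @ subpop_freqs  # n x m success probabilities

    fresh = (rng.random((n, m)) < pi).astype(float)
    calls = fresh.copy()
    if config.ld_decay_cM > 0:
        mf = genetic_map.frame
        chrom = mf["chrom"].to_numpy()
        pos = mf["cM"].to_numpy()
        same = np.empty(m, dtype=bool)
        same[0] = False
        same[1:] = chrom[1:] == chrom[:-1]
        d = np.empty(m)
        d[0] = np.inf
        d[1:] = np.where(same[1:], pos[1:] - pos[:-1], np.inf)
        p_copy = np.exp(-d / config.ld_decay_cM)
        copy = rng.random((n, m)) < p_copy[None, :]
        for j in range(1, m):
            if p_copy[j] > 0:
                cj = copy[:, j]
                calls[cj, j] = calls[cj, j - 1]

    # plant duplicates: overwrite victims' rows with a template's row
    dup_sets = []
    if config.duplicate_sets:
        need = sum(config.duplicate_sets)
        if need > n:
            raise ValueError("more duplicate members than accessions")
        chosen = rng.choice(n, size=need, replace=False)
        off = 0
        for size in config.duplicate_sets:
            if size < 2:
                raise ValueError("duplicate set size must be >= 2")
            members = chosen[off : off + size]
            off += size
            template = members[0]
            for v in members[1:]:
                calls[v] = calls[template]
                q[v] = q[template]
                labels[v] = labels[template]
            dup_sets.append(frozenset(ids[i] for i in members))

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        calls[miss] = np.nan

    markers = genetic_map.markers
    if len(markers) != m:
        raise ValueError("map marker count must equal n_markers")
    G = GenotypeMatrix(ids, markers, calls)
    truth = SyntheticTruth(
        true_q=MembershipMatrix(ids, q, source="synthetic-truth"),
        duplicate_sets=dup_sets,
        qtl_markers=[markers[j] for j, _ in config.qtl_spec],
        subpop_freqs=subpop_freqs,
        labels=labels,
    )
    return G, truth


def generate_phenotype(
    G: GenotypeMatrix,
    truth: SyntheticTruth,
    config: SimulationConfig,
    binary: bool = False,
) -> pd.Series:
    """Additive phenotype from the planted QTL at the configured heritability.

    y = sum(effect * call) + e, with the noise variance set so that the
    genetic share of the total variance equals ``heritability`` (missing
    calls are mean-imputed for simulation only). ``binary=True`` thresholds
    y at its median.
    """
    h2 = config.heritability
    effects = config.qtl_spec
    if h2 >= 1 and effects:
        raise ValueError("heritability must be < 1 when QTL effects are non-zero")
    rng = np.random.default_rng(config.seed + 2)
    n = G.n_accessions
    g = np.zeros(n)
    if h2 > 0 and effects:
        for j, eff in effects:
            x = G.calls[:, j].copy()
            mu = np.nanmean(x)
            x[np.isnan(x)] = mu
            g += eff * x
        var_g = g.var()
        var_e = var_g * (1 - h2) / h2 if var_g > 0 else 1.0
    else:
        g = np.zeros(n)
        var_e = 1.0
    y = g + rng.normal(0.0, np.sqrt(var_e), size=n)
    if binary:
        y = (y > np.median(y)).astype(float)
    return pd.Series(y, index=G.accessions, name="phenotype")
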