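# Methods

This note documents the models, estimators and numerical choices used by
`corecurator`, and the rationale behind the defaults. Defaults live in
`corecurator.pipeline.DEFAULTS` and are shared by the pipeline, the analysis
scripts and the acceptance script, so the numbers quoted here are the ones
actually run.

## Synthetic panel

The generator (`corecurator.simulate`) produces a panel meant to resemble a
diverse collection of inbred cereal lines genotyped on a mapped SNP array.

**Genetic map.** `n_markers` (default 2,000) biallelic SNPs spread over 7
chromosomes with realistic genetic lengths; positions are uniform within each
chromosome and sorted.

**Population model.** Allele frequencies follow a Balding–Nichols model:
each marker has an ancestral frequency drawn uniformly from
`ancestral_maf_range` (0.05–0.5), and each of `n_subpops` (5) subpopulations
draws its own frequency from a Beta distribution with divergence parameter
F = `fst_per_subpop` (0.15 each by default). Accessions are fully inbred, so
a genotype call is a single draw per locus coded 0/1 (minor-allele dosage on
a haploid scale); heterozygous calls never arise from the model and are
masked if present in real input.

**Admixture.** Besides `n_per_subpop` pure members per subpopulation
(50, 68, 68, 52, 22), `n_admixed` (205) accessions draw membership vectors
from a symmetric Dirichlet(0.5) and sample each locus from the mixture of
subpopulation frequencies. The true membership matrix Q is returned as
ground truth.

**Linkage disequilibrium.** Within a chromosome, genotypes are generated by
a copy chain: an accession copies its allele state at marker *j* from marker
*j−1* with probability exp(−d/λ), where *d* is the map distance in cM and
λ = `ld_decay_cM` (2.0); otherwise it draws fresh from its frequency model.
This produces monotone r² decay with distance while leaving
inter-chromosomal pairs unlinked.

**Planted structure for validation.** `duplicate_sets` (sizes 3, 2, 2)
selects existing accessions and overwrites them with copies of one source
row (the accession count is unchanged); independent 2% missingness is then
applied per copy, so duplicates agree wherever both are observed but are
not byte-identical. `qtl_spec` assigns additive effects to three markers
(indices 300, 900, 1500, effect 1.0 each) and the phenotype adds Gaussian
noise scaled so narrow-sense heritability equals `heritability` (0.5).

**Scope and limits.** The generator is deliberately simple: no mutation,
no crossing-over pedigrees, no genotyping batch effects, and LD is a
first-order chain rather than a coalescent. It is sufficient to give every
downstream method a known answer (duplicates, Q, QTL, unlinked pairs) while
staying fast enough to re-simulate inside tests.

## Curation

`qc_filter` masks heterozygous calls, then drops markers with more than
`max_marker_missing` (10%) missing calls, then accessions with more than
`max_accession_missing` (10%) missing over the retained markers — in that
order, matching common array-QC practice. Because the accession filter is
evaluated after the marker filter, the guarantee is that every retained
accession meets the bound *over retained markers*; the two-step filter is
not idempotent in general.

`find_duplicates` links two accessions when their genotypes agree at every
marker where both are observed, requiring at least `min_overlap` (50%) of
markers co-observed so that heavily missing profiles cannot match
vacuously; connected components form duplicate sets. `resolve_duplicates`
keeps one representative per set (`keep-most-complete` by default).

## Population structure

PCA operates on the mean-imputed, frequency-standardized genotype matrix;
the default 11 components cover the subpopulation axes plus slack.
Membership-based assignment labels an accession with its majority
subpopulation when max membership ≥ 0.8, otherwise *admixed* — the
conventional cutoff for declaring a line "pure" in germplasm panels.

The Evanno Δk statistic summarizes an externally supplied table of model
log-probabilities L(k) over replicate runs:
Δk = |L(k+1) − 2L(k) + L(k−1)| / sd(L(k)), with the sample standard
deviation (ddof = 1) across replicates. A perfectly linear L(k) gives
Δk = 0 everywhere; zero variance gives +inf by convention. The package
does not implement the Bayesian clustering itself — Δk consumes any
run-table, and `synthetic_lnpd` provides one for self-contained studies.

## Divergence (Φ_PT)

One-level AMOVA partitions squared haploid distances into among- and
within-population components; Φ_PT = V_AP / (V_AP + V_WP). Two estimators
are exposed deliberately:

- **per-marker scan** — φ for each SNP, with permutation p-values
  (labels permuted, ≥999 permutations by default, p = (1+#{φ* ≥ φ})/(1+n));
- **multilocus Φ** — the ratio of the *summed* variance components over
  markers, not the mean of per-marker ratios.

The distinction matters: the mean of per-marker ratios is biased downward
(each ratio is noisy and bounded), whereas the multilocus ratio is a
consistent estimate of the model divergence — at simulated F = 0.5 the
multilocus Φ recovers ≈ 0.5 while the mean of per-marker φ sits near 0.28.
Study summaries therefore report the multilocus value.

## LD landscape

**Background threshold.** r² is computed for `n_unlinked_pairs` (100,000)
random inter-chromosomal pairs among low-admixture accessions
(max membership > 0.2 filter by default). Values are shifted by ε = 1e−6
(Box–Cox requires positivity), transformed with the Box–Cox λ that
maximizes the probability-plot correlation with the normal
(`scipy.stats.boxcox_normmax(..., method="pearsonr")`), and the threshold is
the inverse transform of mean + z₉₉ · sd, minus ε. The PPCC λ is used
instead of the maximum-likelihood λ because the likelihood fit matches the
bulk of the distribution but leaves the upper tail light, inflating the
percentile. Even with the PPCC λ the transformed sample is slightly
platykurtic, so the parametric 99th percentile sits a little above the
empirical one and the construction is mildly conservative: the fraction of
fresh unlinked pairs exceeding the threshold is close to, and typically
just above, the nominal 1% when the full 100,000-pair sample is used.
Using far fewer pairs makes the sd estimate noisy and — because the
threshold is convex in sd — biases the threshold upward, so the default
pair count should not be reduced for speed.

**Decay.** Mean r² per map-distance bin (1 cM bins to 50 cM) per
chromosome; the pooled profile's first bin below the background threshold
gives the decay distance.

**Structure-corrected LD.** For marker pairs in a distance window
(half-open in cM, e.g. [1, 2)), a logistic regression of one marker's
allele on the other's, with the leading PCs as covariates, tests association
by likelihood-ratio; Firth-style fallback handles separation. Comparing
−log₁₀ p with and without PC covariates separates genuine linkage from
structure-generated LD: PCs deflate the signal for unlinked pairs in a
structured panel while close pairs stay strongly significant.

## Association

The mixed linear model uses the P3D/EMMAX approximation: variance
components (σ²_g for the kinship K = WW'/Σ2p(1−p) on standardized
genotypes, σ²_e residual) are estimated once under the null with Q
covariates, then each marker is tested by GLS with the fixed
V = σ²_g K + σ²_e I. Effects are reported on the minor allele. Genomic
inflation λ_GC is the median χ² over its null median; with Q+K in a
structured panel it is typically ≤ 1 (the model is conservative by
design). Multiple testing uses Benjamini–Hochberg step-up q-values, and
the Manhattan table flags q < 0.05.

## Mini-core

PIC is 1 − Σp² (gene diversity) per marker by default (the Botstein form
is also available), averaged over markers with at least one observed call
in the subset. Mini-core construction ranks accessions by stepwise
removal: at each step remove the accession whose removal maximizes the
remaining panel's average PIC (ties broken lexicographically by accession
id), using incremental allele-count updates so the full ranking is
O(accessions² × markers) rather than re-scoring from scratch. The
trajectory of average PIC versus retained size typically rises as
redundant accessions leave and falls once removal starts erasing alleles;
`peak_size` is the global argmax of that trajectory (the trajectory is not
strictly unimodal — greedy removal produces small wobbles either side of
the peak, so the peak is defined as the maximum, not a turning point).
Selecting below the peak triggers a warning since further removal is
already destroying diversity. The default core is the top 10% of the
ranking, which in the study retains ~95% of peak PIC and exceeds the
average PIC of essentially all random same-size subsets.

## Pipeline, seeding, reproducibility

`pipeline.run` executes simulate → QC → dedup → structure → Φ_PT → LD →
GWAS → mini-core from one validated YAML config (unknown keys and
out-of-range values are reported by name, all errors at once). Every stage
writes TSVs into the run directory and registers path, sha256, parameters
and stage seed in `manifest.json`. Per-stage seeds derive from the global
seed by stable hashing of the stage name (CRC-32, reduced mod 2³¹−1), so
adding a stage never perturbs earlier stages' randomness and reruns are
byte-identical. External genotype/map/phenotype inputs can replace the
simulation stage. `scripts/acceptance.py` uses the same derivation from its
`--seed` argument, so every number it reports is a pure function of that
seed.
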