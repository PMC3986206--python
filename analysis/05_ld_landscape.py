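"""LD landscape: the unlinked-pair significance threshold, distance-binned
decay, and the structure-corrected logistic LD scan in two distance windows."""

import runpy
import sys
from pathlib import Path

import numpy as np
import pandas as pd

cfg_mod = runpy.run_path(str(Path(__file__).with_name("00_config.py")))
SEED, DATA, RESULTS = cfg_mod["SEED"], cfg_mod["DATA"], cfg_mod["RESULTS"]

from corecurator import genio, ld, structure  # noqa: E402


def main():
    G = genio.read_matrix_tsv(DATA / "genotypes_curated.tsv")
    gm = genio.read_map_tsv(DATA / "map.tsv")
    Q = genio.read_q_tsv(DATA / "truth_q.tsv").reindex(G.accessions)
    # the LD analyses exclude accessions with admixture above 80%
    keep = [a for a, mx in zip(Q.accessions, Q.q.max(axis=1)) if mx > 0.2]
    print(f"admixture filter: {len(keep)}/{G.n_accessions} accessions kept")

    thr = ld.unlinked_threshold(G, gm, subset=keep, n_pairs=100000, seed=SEED)
    pd.DataFrame([thr.__dict__]).to_csv(RESULTS / "ld_threshold.tsv", sep="\t", index=False)
    print(f"unlinked r2 threshold (99th pct): {thr.threshold:.4f} "
          f"(Box-Cox lambda {thr.boxcox_lambda:.3f}, {thr.n_pairs} pairs)")

    prof = ld.decay_profile(G, gm, subset=keep, max_distance_cM=50.0, bin_width_cM=1.0)
    prof["threshold"] = thr.threshold
    prof.to_csv(RESULTS / "ld_decay.tsv", sep="\t", index=False)
    pooled = prof.groupby("bin_lo_cM").apply(
        lambda d: np.nansum(d["mean_r2"] * d["n_pairs"]) / max(d["n_pairs"].sum(), 1),
        include_groups=False,
    )
    below = pooled[pooled < thr.threshold]
    if len(below):
        print(f"pooled decay falls below the threshold near {below.index[0]:.0f} cM")

    pca = structure.pca_genotypes(G, 11)
    for lo, hi in ((1.0, 2.0), (4.0, 5.0)):
        scan = ld.logistic_ld_scan(G, gm, pca, n_pcs=11, window=(lo, hi))
        scan.to_csv(RESULTS / f"ld_logistic_{lo:g}_{hi:g}cM.tsv", sep="\t", index=False)
        print(f"logistic LD window [{lo},{hi}) cM: {len(scan)} pairs, "
              f"median -log10(p) {scan['neg_log10_p'].median():.2f}")


if __name__ == "__main__":
    sys.exit(main())
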