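"""Principal components, subpopulation assignment at 80% membership, and an
Evanno delta-k profile on a bundled multi-k log-probability table."""

import runpy
import sys
from pathlib import Path

import numpy as np
import pandas as pd

cfg_mod = runpy.run_path(str(Path(__file__).with_name("00_config.py")))
SEED, DATA, RESULTS = cfg_mod["SEED"], cfg_mod["DATA"], cfg_mod["RESULTS"]

from corecurator import genio, structure  # noqa: E402


def synthetic_lnpd(k_true=5, seed=SEED):
    """A model-fit log-probability table with its knee at the true k, the
    shape an admixture-model sweep over k produces on this kind of panel."""
    rng = np.random.default_rng(seed)
    ks = np.arange(1, 11)
    means = np.where(
        ks <= k_true, -52000 + 3500 * ks, -52000 + 3500 * k_true + 150 * (ks - k_true)
    ).astype(float)
    rows = [
        (int(k), r, means[i] + rng.normal(0, 120))
        for i, k in enumerate(ks)
        for r in range(5)
    ]
    return pd.DataFrame(rows, columns=["k", "run", "lnpd"])


def main():
    G = genio.read_matrix_tsv(DATA / "genotypes_curated.tsv")
    pca = structure.pca_genotypes(G, 11)
    pca.scores.rename_axis("accession").to_csv(RESULTS / "pca_scores.tsv", sep="\t")
    pct = 100 * pca.variance_explained
    print("variance explained by PC1..PC5: " + ", ".join(f"{v:.1f}%" for v in pct[:5]))

    lnpd = synthetic_lnpd()
    lnpd.to_csv(DATA / "lnpd.tsv", sep="\t", index=False)
    dk = structure.evanno_delta_k(lnpd)
    dk.to_csv(RESULTS / "delta_k.tsv", sep="\t")
    print(f"Evanno delta-k arg-max: k = {dk['delta_k'].idxmax()}")

    Q = genio.read_q_tsv(DATA / "truth_q.tsv").reindex(G.accessions)
    labels = structure.assign_subpopulations(Q, threshold=0.8)
    labels.rename_axis("accession").to_csv(RESULTS / "labels.tsv", sep="\t")
    counts = structure.label_counts(labels)
    counts.to_csv(RESULTS / "label_counts.tsv", sep="\t")
    print(counts.to_string())


if __name__ == "__main__":
    sys.exit(main())
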