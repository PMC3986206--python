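"""Per-SNP one-vs-rest Phi_PT scans with permutation p-values, plus the
combined multilocus Phi_PT per subpopulation."""

import runpy
import sys
from pathlib import Path

import pandas as pd

cfg_mod = runpy.run_path(str(Path(__file__).with_name("00_config.py")))
SEED, DATA, RESULTS = cfg_mod["SEED"], cfg_mod["DATA"], cfg_mod["RESULTS"]

from corecurator import divergence, genio  # noqa: E402


def main():
    G = genio.read_matrix_tsv(DATA / "genotypes_curated.tsv")
    gm = genio.read_map_tsv(DATA / "map.tsv")
    labels = pd.read_csv(RESULTS / "labels.tsv", sep="\t", index_col=0).iloc[:, 0]

    summary = []
    for focal in sorted(l for l in labels.unique() if l != "admixed"):
        scan = divergence.one_vs_rest_scan(
            G, labels, focal, gm, n_perm=1000, seed=SEED
        )
        scan.to_csv(RESULTS / f"phipt_{focal}_vs_rest.tsv", sep="\t", index=False)
        top = scan.loc[scan["phi_pt"].idxmax()]
        summary.append(
            {
                "focal": focal,
                "multilocus_phi": divergence.multilocus_phi(scan),
                "n_sig_p005": int((scan["p_perm"] < 0.05).sum()),
                "top_marker": top["marker"],
                "top_phi": top["phi_pt"],
            }
        )
    out = pd.DataFrame(summary)
    out.to_csv(RESULTS / "phipt_summary.tsv", sep="\t", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
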