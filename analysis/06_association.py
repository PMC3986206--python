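"""Q+K mixed-model association scan of the simulated phenotype, with
kinship, genomic inflation, and the BH-FDR Manhattan table."""

import runpy
import sys
from pathlib import Path

import pandas as pd

cfg_mod = runpy.run_path(str(Path(__file__).with_name("00_config.py")))
DATA, RESULTS = cfg_mod["DATA"], cfg_mod["RESULTS"]

from corecurator import association, genio  # noqa: E402


def main():
    G = genio.read_matrix_tsv(DATA / "genotypes_curated.tsv")
    gm = genio.read_map_tsv(DATA / "map.tsv")
    y = genio.read_phenotype_tsv(DATA / "phenotype.tsv")
    Q = genio.read_q_tsv(DATA / "truth_q.tsv")

    K = association.kinship(G)
    res = association.mlm_scan(G, y, Q, K)
    table = association.manhattan_table(res, gm)
    table.to_csv(RESULTS / "gwas.tsv", sep="\t", index=False)

    print(f"lambda_GC = {res.attrs['lambda_gc']:.3f}")
    sig = table[table["significant"]]
    print(f"{len(sig)} markers significant at q < 0.05")
    qtl = pd.read_csv(DATA / "truth_qtl.tsv", sep="\t")["marker"]
    hit = table.set_index("marker").loc[qtl, ["q", "significant"]]
    print("planted QTL markers:")
    print(hit.to_string())


if __name__ == "__main__":
    sys.exit(main())
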