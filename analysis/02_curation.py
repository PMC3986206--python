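"""Missingness QC, then detection and resolution of duplicated accessions."""

import runpy
import sys
from pathlib import Path

import pandas as pd

cfg_mod = runpy.run_path(str(Path(__file__).with_name("00_config.py")))
DATA, RESULTS = cfg_mod["DATA"], cfg_mod["RESULTS"]

from corecurator import curation, genio  # noqa: E402


def main():
    G = genio.read_matrix_tsv(DATA / "genotypes.tsv")
    G = curation.qc_filter(G, 0.10, 0.10)
    print(f"after QC: {G.n_accessions} accessions x {G.n_markers} markers")

    report = curation.find_duplicates(G)
    retained = curation.resolve_duplicates(report, G, policy="keep-most-complete")
    print(f"duplicate sets: {len(report.sets)}; retained {len(retained)} accessions")

    truth = pd.read_csv(DATA / "truth_duplicates.tsv", sep="\t")
    found = {";".join(sorted(s)) for s in report.sets}
    planted = set(truth["members"])
    print(f"planted sets recovered: {len(found & planted)}/{len(planted)}")

    pd.DataFrame(
        [{"set_id": i, "members": ";".join(sorted(s))} for i, s in enumerate(report.sets)]
    ).to_csv(RESULTS / "duplicate_sets.tsv", sep="\t", index=False)
    Gd = G.subset(accession_idx=G.accession_index(retained))
    genio.write_matrix_tsv(Gd, DATA / "genotypes_curated.tsv")
    print(f"wrote {RESULTS / 'duplicate_sets.tsv'} and curated genotypes")


if __name__ == "__main__":
    sys.exit(main())
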