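"""Generate the synthetic study panel: genetic map, genotypes with planted
duplicates, true admixture proportions, and a heritable phenotype."""

import runpy
import sys
from pathlib import Path

cfg_mod = runpy.run_path(str(Path(__file__).with_name("00_config.py")))
SEED, DATA = cfg_mod["SEED"], cfg_mod["DATA"]

from corecurator import genio, pipeline, simulate as sim  # noqa: E402


def main():
    sc = dict(pipeline.DEFAULTS["simulate"])
    sc["ancestral_maf_range"] = tuple(sc["ancestral_maf_range"])
    sc["qtl_spec"] = [tuple(x) for x in sc["qtl_spec"]]
    cfg = sim.SimulationConfig(seed=SEED, **sc)
    gm = sim.generate_map(cfg)
    G, truth = sim.generate_genotypes(cfg, gm)
    y = sim.generate_phenotype(G, truth, cfg)

    genio.write_map_tsv(gm, DATA / "map.tsv")
    genio.write_matrix_tsv(G, DATA / "genotypes.tsv")
    genio.write_q_tsv(truth.true_q, DATA / "truth_q.tsv")
    genio.write_phenotype_tsv(y, DATA / "phenotype.tsv")
    with open(DATA / "truth_duplicates.tsv", "w") as fh:
        fh.write("set_id\tmembers\n")
        for i, s in enumerate(sorted(truth.duplicate_sets, key=sorted)):
            fh.write(f"{i}\t{';'.join(sorted(s))}\n")
    with open(DATA / "truth_qtl.tsv", "w") as fh:
        fh.write("marker\teffect\n")
        for j, eff in cfg.qtl_spec:
            fh.write(f"{G.markers[j]}\t{eff}\n")

    print(f"panel: {G.n_accessions} accessions x {G.n_markers} markers")
    print(f"planted duplicate sets: {len(truth.duplicate_sets)}")
    print(f"QTL markers: {[G.markers[j] for j, _ in cfg.qtl_spec]}")
    print(f"wrote {DATA}")


if __name__ == "__main__":
    sys.exit(main())
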