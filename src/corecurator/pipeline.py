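"""End-to-end orchestration: simulate -> QC -> dedup -> structure -> Phi_PT
-> LD -> GWAS -> mini-core, from a single validated config.

Every stage writes TSV outputs into the run directory and registers them in
a manifest (path, sha256, parameters, stage seed). The global seed derives
per-stage seeds by stable hashing of the stage name, so adding a stage does
not perturb earlier stages' randomness.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, curation, divergence, genio, ld, minicore, simulate, structure

log = logging.getLogger(__name__)

DEFAULTS = {
    "seed": 0,
    "inputs": {
        # empty path -> the stage simulates its input
        "genotypes": "", "genotype_format": "matrix-tsv",
        "map": "", "q": "", "lnpd": "", "phenotype": "",
    },
    "simulate": {
        "n_subpops": 5,
        "n_per_subpop": [50, 68, 68, 52, 22],
        "n_admixed": 205,
        "dirichlet_alpha": 0.5,
        "n_markers": 2000,
        "n_chromosomes": 7,
        "chrom_lengths_cM": list(simulate.DEFAULT_CHROM_LENGTHS),
        "fst_per_subpop": [0.15, 0.15, 0.15, 0.15, 0.15],
        "ancestral_maf_range": [0.05, 0.5],
        "missing_rate": 0.02,
        "ld_decay_cM": 2.0,
        "duplicate_sets": [3, 2, 2],
        "qtl_spec": [[300, 1.0], [900, 1.0], [1500, 1.0]],
        "heritability": 0.5,
    },
    "qc": {"max_marker_missing": 0.10, "max_accession_missing": 0.10},
    "dedup": {"min_overlap": 0.5, "policy": "keep-most-complete"},
    "structure": {"threshold": 0.8, "n_components": 11, "maf_min": 0.01,
                  "thin_one_per_bin": False},
    "phipt": {"n_perm": 1000, "focal": []},  # [] -> every subpopulation in turn
    "ld": {
        "maf_min": 0.05, "max_admixture": 0.8, "n_pcs": 11,
        "windows": [[1.0, 2.0], [4.0, 5.0]],
        "n_unlinked_pairs": 100000, "percentile": 99.0,
        "max_distance_cM": 50.0, "bin_width_cM": 1.0,
        "logistic_pairs_cap": 200,
    },
    "gwas": {"maf_min": 0.01},
    "minicore": {"fraction": 0.10, "pic_form": "gene-diversity"},
}

_RANGES = {
    ("qc", "max_marker_missing"): (0, 1),
    ("qc", "max_accession_missing"): (0, 1),
    ("dedup", "min_overlap"): (0, 1),
    ("structure", "threshold"): (0, 1),
    ("ld", "maf_min"): (0, 0.5),
    ("ld", "max_admixture"): (0, 1),
    ("ld", "percentile"): (0, 100),
    ("gwas", "maf_min"): (0, 0.5),
    ("minicore", "fraction"): (0, 1),
    ("simulate", "missing_rate"): (0, 1),
    ("simulate", "heritability"): (0, 1),
}


@dataclass
class PipelineConfig:
    data: dict

    def __getitem__(self, key):
        return self.data[key]

    def serialize(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=True)


def validate_config(source) -> PipelineConfig:
    """Fill defaults, reject unknown keys, and range-check all thresholds.

    ``source`` may be a path to a YAML file, a YAML string, or a dict.
    """
    if isinstance(source, PipelineConfig):
        user = copy.deepcopy(source.data)
    elif isinstance(source, dict):
        user = copy.deepcopy(source)
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        user = yaml.safe_load(text) or {}
    if not isinstance(user, dict):
        raise ValueError("config must be a mapping")

    errors = []
    cfg = copy.deepcopy(DEFAULTS)
    for section, value in user.items():
        if section not in cfg:
            errors.append(f"unknown config section {section!r}")
            continue
        if section == "seed":
            cfg["seed"] = int(value)
            continue
        if not isinstance(value, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        for key, v in value.items():
            if key not in cfg[section]:
                errors.append(f"unknown key {section}.{key}")
            else:
                cfg[section][key] = v
    for (section, key), (lo, hi) in _RANGES.items():
        v = cfg[section][key]
        if not (lo <= float(v) <= hi):
            errors.append(f"{section}.{key}={v} outside [{lo}, {hi}]")
    if cfg["dedup"]["policy"] not in ("keep-first", "keep-most-complete"):
        errors.append(f"dedup.policy={cfg['dedup']['policy']!r} unknown")
    if cfg["minicore"]["pic_form"] not in minicore.PIC_FORMS:
        errors.append(f"minicore.pic_form={cfg['minicore']['pic_form']!r} unknown")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return PipelineConfig(cfg)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: PipelineConfig):
        self.outdir = outdir
        self.entries = []
        self.config = config

    def add(self, stage: str, path: Path, **params):
        self.entries.append(
            {
                "stage": stage,
                "file": path.name,
                "sha256": _sha256(path),
                "params": params,
            }
        )

    def write(self) -> Path:
        out = self.outdir / "manifest.json"
        payload = {
            "seed": self.config["seed"],
            "config": self.config.data,
            "outputs": self.entries,
        }
        out.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
        return out


def run_pipeline(config, outdir) -> dict:
    """Run every stage in dependency order; halt naming the failing stage."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, cfg)
    state = {}
    stages = [
        ("simulate", _stage_simulate),
        ("qc", _stage_qc),
        ("dedup", _stage_dedup),
        ("structure", _stage_structure),
        ("phipt", _stage_phipt),
        ("ld", _stage_ld),
        ("gwas", _stage_gwas),
        ("minicore", _stage_minicore),
    ]
    for name, fn in stages:
        log.info("pipeline stage: %s", name)
        try:
            fn(cfg, state, outdir, manifest)
        except Exception as exc:
            manifest.write()
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    path = manifest.write()
    log.info("pipeline complete: %d outputs, manifest %s", len(manifest.entries), path)
    return {"manifest": str(path), "outputs": [e["file"] for e in manifest.entries]}


def _stage_simulate(cfg, state, outdir, manifest):
    inputs = cfg["inputs"]
    if inputs["genotypes"]:
        state["map"] = genio.read_map_tsv(inputs["map"])
        state["G_raw"] = genio.read_genotypes(inputs["genotypes"], inputs["genotype_format"])
        state["truth"] = None
        if inputs["q"]:
            state["Q"] = genio.read_q_tsv(inputs["q"])
        if inputs["phenotype"]:
            state["pheno"] = genio.read_phenotype_tsv(inputs["phenotype"])
        return
    sc = dict(cfg["simulate"])
    sc["ancestral_maf_range"] = tuple(sc["ancestral_maf_range"])
    sc["qtl_spec"] = [tuple(x) for x in sc["qtl_spec"]]
    sim = simulate.SimulationConfig(seed=stage_seed(cfg["seed"], "simulate"), **sc)
    gm = simulate.generate_map(sim)
    G, truth = simulate.generate_genotypes(sim, gm)
    y = simulate.generate_phenotype(G, truth, sim)
    state.update(map=gm, G_raw=G, truth=truth, Q=truth.true_q, pheno=y, sim=sim)
    genio.write_map_tsv(gm, outdir / "map.tsv")
    genio.write_matrix_tsv(G, outdir / "genotypes.tsv")
    genio.write_q_tsv(truth.true_q, outdir / "truth_q.tsv")
    genio.write_phenotype_tsv(y, outdir / "phenotype.tsv")
    for f in ("map.tsv", "genotypes.tsv", "truth_q.tsv", "phenotype.tsv"):
        manifest.add("simulate", outdir / f, seed=sim.seed)


def _stage_qc(cfg, state, outdir, manifest):
    G = state["G_raw"]
    if G.het_mask is not None:
        G = curation.mask_heterozygotes(G)
    G = curation.qc_filter(G, cfg["qc"]["max_marker_missing"], cfg["qc"]["max_accession_missing"])
    state["G_qc"] = G
    genio.write_matrix_tsv(G, outdir / "genotypes_qc.tsv")
    manifest.add("qc", outdir / "genotypes_qc.tsv", **cfg["qc"])


def _stage_dedup(cfg, state, outdir, manifest):
    G = state["G_qc"]
    report = curation.find_duplicates(G, cfg["dedup"]["min_overlap"])
    retained = curation.resolve_duplicates(report, G, policy=cfg["dedup"]["policy"])
    state["G"] = G.subset(accession_idx=G.accession_index(retained))
    rows = [
        {"set_id": i, "members": ";".join(sorted(s))} for i, s in enumerate(report.sets)
    ]
    pd.DataFrame(rows, columns=["set_id", "members"]).to_csv(
        outdir / "duplicates.tsv", sep="\t", index=False
    )
    pd.Series(retained, name="accession").to_csv(
        outdir / "retained_accessions.tsv", sep="\t", index=False
    )
    manifest.add("dedup", outdir / "duplicates.tsv", **cfg["dedup"])
    manifest.add("dedup", outdir / "retained_accessions.tsv", **cfg["dedup"])


def _stage_structure(cfg, state, outdir, manifest):
    G = state["G"]
    sc = cfg["structure"]
    Gp = structure.thin_one_per_bin(G, state["map"]) if sc["thin_one_per_bin"] else G
    pca = structure.pca_genotypes(Gp, sc["n_components"], sc["maf_min"])
    state["pca"] = pca
    pca.scores.rename_axis("accession").to_csv(outdir / "pca_scores.tsv", sep="\t")
    manifest.add("structure", outdir / "pca_scores.tsv", **sc)
    Q = state.get("Q")
    if Q is not None:
        Q = Q.reindex(G.accessions)
        state["Q"] = Q
        labels = structure.assign_subpopulations(Q, sc["threshold"])
        state["labels"] = labels
        labels.rename_axis("accession").to_csv(outdir / "labels.tsv", sep="\t")
        structure.label_counts(labels).to_csv(outdir / "label_counts.tsv", sep="\t")
        manifest.add("structure", outdir / "labels.tsv", threshold=sc["threshold"])
        manifest.add("structure", outdir / "label_counts.tsv")
    if cfg["inputs"]["lnpd"]:
        dk = structure.evanno_delta_k(genio.read_lnpd_tsv(cfg["inputs"]["lnpd"]))
        dk.to_csv(outdir / "delta_k.tsv", sep="\t")
        manifest.add("structure", outdir / "delta_k.tsv")


def _stage_phipt(cfg, state, outdir, manifest):
    if "labels" not in state:
        log.info("phipt: no membership labels available; stage skipped")
        return
    G, labels = state["G"], state["labels"]
    focal = cfg["phipt"]["focal"] or sorted(
        l for l in labels.unique() if l != structure.ADMIXED
    )
    seed = stage_seed(cfg["seed"], "phipt")
    for f in focal:
        res = divergence.one_vs_rest_scan(
            G, labels, f, state["map"], n_perm=cfg["phipt"]["n_perm"], seed=seed
        )
        path = outdir / f"phipt_{f}_vs_rest.tsv"
        res.to_csv(path, sep="\t", index=False)
        manifest.add("phipt", path, focal=f, n_perm=cfg["phipt"]["n_perm"], seed=seed)


def _stage_ld(cfg, state, outdir, manifest):
    G, gm = state["G"], state["map"]
    lc = cfg["ld"]
    seed = stage_seed(cfg["seed"], "ld")
    # admixture filter: keep accessions whose largest membership > 1 - max_admixture
    subset = None
    if "Q" in state:
        q = state["Q"].reindex(G.accessions)
        subset = [a for a, mx in zip(q.accessions, q.q.max(axis=1)) if mx > 1 - lc["max_admixture"]]
        if len(subset) < 10:
            subset = None
    thr = ld.unlinked_threshold(
        G, gm, subset, n_pairs=lc["n_unlinked_pairs"], percentile=lc["percentile"],
        maf_min=lc["maf_min"], seed=seed,
    )
    pd.DataFrame([thr.__dict__]).to_csv(outdir / "ld_threshold.tsv", sep="\t", index=False)
    manifest.add("ld", outdir / "ld_threshold.tsv", seed=seed, **{k: v for k, v in lc.items()})
    prof = ld.decay_profile(
        G, gm, subset, lc["max_distance_cM"], lc["bin_width_cM"], lc["maf_min"]
    )
    prof["threshold"] = thr.threshold
    prof.to_csv(outdir / "ld_decay.tsv", sep="\t", index=False)
    manifest.add("ld", outdir / "ld_decay.tsv")
    pca = state["pca"]
    for lo, hi in lc["windows"]:
        scan = ld.logistic_ld_scan(G, gm, pca, lc["n_pcs"], (lo, hi), lc["maf_min"])
        cap = lc["logistic_pairs_cap"]
        if cap and len(scan) > cap:
            rng = np.random.default_rng(seed)
            scan = scan.iloc[np.sort(rng.choice(len(scan), cap, replace=False))]
        path = outdir / f"ld_logistic_{lo:g}_{hi:g}cM.tsv"
        scan.to_csv(path, sep="\t", index=False)
        manifest.add("ld", path, window=[lo, hi], n_pcs=lc["n_pcs"])


def _stage_gwas(cfg, state, outdir, manifest):
    if "pheno" not in state:
        log.info("gwas: no phenotype available; stage skipped")
        return
    G = state["G"]
    K = association.kinship(G, cfg["gwas"]["maf_min"])
    res = association.mlm_scan(G, state["pheno"], state.get("Q"), K, cfg["gwas"]["maf_min"])
    table = association.manhattan_table(res, state["map"])
    table.to_csv(outdir / "gwas.tsv", sep="\t", index=False)
    manifest.add(
        "gwas", outdir / "gwas.tsv",
        maf_min=cfg["gwas"]["maf_min"],
        lambda_gc=res.attrs["lambda_gc"],
    )
    state["gwas"] = table


def _stage_minicore(cfg, state, outdir, manifest):
    G = state["G"]
    mapped = np.isin(G.markers, state["map"].markers)
    ranking = minicore.rank_accessions(G, mapped, form=cfg["minicore"]["pic_form"])
    sel = minicore.select_minicore(ranking, fraction=cfg["minicore"]["fraction"])
    ranking.ranking_table().to_csv(outdir / "minicore_ranking.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"accession": sel.accessions}
    ).assign(peak_size=sel.peak_size, below_peak=sel.below_peak_warning).to_csv(
        outdir / "minicore_selection.tsv", sep="\t", index=False
    )
    manifest.add("minicore", outdir / "minicore_ranking.tsv", **cfg["minicore"])
    manifest.add(
        "minicore", outdir / "minicore_selection.tsv",
        size=sel.size, peak_size=sel.peak_size,
    )
    state["minicore"] = sel
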