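"""Readers and writers for genotype, map, membership and phenotype tables.

Three genotype dialects are supported:

* plain matrix TSV — first column accession id, header row of marker ids,
  calls in {0, 1, NA};
* HapMap tab format — 11 metadata columns then one column per accession,
  diploid letter codes (het = two different letters, ``NN`` missing);
* VCF — biallelic SNPs with a GT field (read through cyvcf2), ``./.``
  missing, heterozygous GT flagged.

All genotype readers return a :class:`~corecurator.containers.GenotypeMatrix`
with heterozygous raw calls held as 0.5 under ``het_mask`` so that masking
is a separate, explicit step.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import GeneticMap, GenotypeMatrix, MembershipMatrix

log = logging.getLogger(__name__)

HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


# ---------------------------------------------------------------- matrix TSV

def read_matrix_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    accessions = list(df.index.astype(str))
    markers = list(df.columns.astype(str))
    raw = df.to_numpy()
    calls = np.full(raw.shape, np.nan)
    het = np.zeros(raw.shape, dtype=bool)
    valid = {"0": 0.0, "1": 1.0, "NA": np.nan, "": np.nan, "nan": np.nan}
    for code, value in valid.items():
        calls[raw == code] = value
    bad = ~np.isin(raw, list(valid)) & ~pd.isna(raw)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"unknown call {raw[i, j]!r} at accession {accessions[i]}, marker {markers[j]}"
        )
    return GenotypeMatrix(accessions, markers, calls, het)


def write_matrix_tsv(G: GenotypeMatrix, path) -> None:
    out = pd.DataFrame(G.calls, index=G.accessions, columns=G.markers)
    out = out.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "accession"
    out.to_csv(path, sep="\t")


# ------------------------------------------------------------------- HapMap

def read_hapmap(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:11]) != HAPMAP_META:
        raise ValueError("not a HapMap file: unexpected metadata columns")
    accessions = list(df.columns[11:])
    markers = list(df["rs#"].astype(str))
    n, m = len(accessions), len(markers)
    calls = np.full((n, m), np.nan)
    het = np.zeros((n, m), dtype=bool)
    for j, (_, row) in enumerate(df.iterrows()):
        a0, _, a1 = row["alleles"].partition("/")
        codes = {
            a0 + a0: 0.0,
            a1 + a1: 1.0,
            "NN": np.nan,
            a0 + a1: 0.5,
            a1 + a0: 0.5,
        }
        for i, acc in enumerate(accessions):
            cell = row[acc]
            if cell not in codes:
                raise ValueError(
                    f"unknown HapMap call {cell!r} at marker {markers[j]}, accession {acc}"
                )
            calls[i, j] = codes[cell]
            if codes[cell] == 0.5:
                het[i, j] = True
    return GenotypeMatrix(accessions, markers, calls, het)


def write_hapmap(G: GenotypeMatrix, genetic_map: GeneticMap | None = None, path=None) -> None:
    """Write calls as HapMap with alleles A/C (0 -> AA, 1 -> CC, het -> AC)."""
    pos = None
    if genetic_map is not None:
        pos = genetic_map.positions(G.markers).set_index("marker")
    rows = []
    for j, mk in enumerate(G.markers):
        chrom = str(pos.loc[mk, "chrom"]) if pos is not None else "1"
        cm = f"{pos.loc[mk, 'cM']:.4f}" if pos is not None else "0"
        meta = [mk, "A/C", chrom, cm, "+", "NA", "NA", "NA", "NA", "NA", "NA"]
        col = G.calls[:, j]
        hets = G.het_mask[:, j] if G.het_mask is not None else np.zeros(len(col), bool)
        cells = []
        for v, h in zip(col, hets):
            if h:
                cells.append("AC")
            elif np.isnan(v):
                cells.append("NN")
            else:
                cells.append("AA" if v == 0 else "CC")
        rows.append(meta + cells)
    out = pd.DataFrame(rows, columns=HAPMAP_META + list(G.accessions))
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------- VCF

def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF; multi-allelic records are skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    markers, cols, hets = [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = np.asarray(var.gt_types)
        col = np.full(len(accessions), np.nan)
        col[gt == 0] = 0.0
        col[gt == 3] = 1.0
        col[gt == 1] = 0.5
        markers.append(var.ID or f"{var.CHROM}:{var.POS}")
        cols.append(col)
        hets.append(gt == 1)
    if n_multi:
        log.info("skipped %d multi-allelic VCF records", n_multi)
    calls = np.column_stack(cols) if cols else np.empty((len(accessions), 0))
    het = np.column_stack(hets) if hets else np.empty((len(accessions), 0), bool)
    return GenotypeMatrix(accessions, markers, calls, het)


def write_vcf(G: GenotypeMatrix, genetic_map: GeneticMap | None = None, path=None) -> None:
    """Write a minimal VCF 4.2 (REF=A, ALT=C; inbred calls 0/0 and 1/1)."""
    pos = None
    if genetic_map is not None:
        pos = genetic_map.positions(G.markers).set_index("marker")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pos["chrom"].unique() if pos is not None else ["1"]
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, G.accessions))
            + "\n"
        )
        for j, mk in enumerate(G.markers):
            chrom = str(pos.loc[mk, "chrom"]) if pos is not None else "1"
            # cM scaled to an integer coordinate: VCF needs a bp-like POS
            p = int(round(float(pos.loc[mk, "cM"]) * 10000)) + 1 if pos is not None else j + 1
            hets = G.het_mask[:, j] if G.het_mask is not None else np.zeros(G.n_accessions, bool)
            gts = []
            for v, h in zip(G.calls[:, j], hets):
                if h:
                    gts.append("0/1")
                elif np.isnan(v):
                    gts.append("./.")
                else:
                    gts.append("0/0" if v == 0 else "1/1")
            fh.write(f"{chrom}\t{p}\t{mk}\tA\tC\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


# ------------------------------------------------------------ generic entry

def read_genotypes(path, format: str) -> GenotypeMatrix:
    """Dispatch on dialect name: matrix-tsv, hapmap or vcf."""
    readers = {"matrix-tsv": read_matrix_tsv, "hapmap": read_hapmap, "vcf": read_vcf}
    if format not in readers:
        raise ValueError(f"unknown genotype format {format!r}; choose from {sorted(readers)}")
    return readers[format](path)


# -------------------------------------------------------------- side tables

def read_map_tsv(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    df["cM"] = df["cM"].astype(float)
    return GeneticMap(df)


def write_map_tsv(genetic_map: GeneticMap, path) -> None:
    genetic_map.frame.to_csv(path, sep="\t", index=False)


def read_q_tsv(path) -> MembershipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return MembershipMatrix(list(df.index.astype(str)), df.to_numpy(float))


def write_q_tsv(q: MembershipMatrix, path) -> None:
    cols = [f"Q{i + 1}" for i in range(q.k)]
    pd.DataFrame(q.q, index=q.accessions, columns=cols).rename_axis("accession").to_csv(
        path, sep="\t"
    )


def read_phenotype_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float)


def write_phenotype_tsv(y: pd.Series, path) -> None:
    y.rename_axis("accession").to_frame("value").to_csv(path, sep="\t")


def read_lnpd_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"k", "run", "lnpd"}
    if not need.issubset(df.columns):
        raise ValueError(f"LnP(D) table needs columns {sorted(need)}")
    return df
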