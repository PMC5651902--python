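"""Plain-text readers and writers for cohorts, maps and result tables.

Matrices are tab-delimited with features as rows and a header row of sample
ids; genotypes are additionally exportable as a minimal VCF (GT field only).
A simulated cohort pair round-trips through a directory layout of

    <out>/<role>/genotypes.tsv  snps.tsv  methylation.tsv  cpgs.tsv
                 covariates.tsv [probe_dosages.tsv]
    <out>/truth.tsv
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .simulate import Cohort, PlantedEffect, TruthRegistry

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_vcf",
    "write_cohort",
    "read_cohort",
    "write_truth",
    "read_truth",
]


def write_matrix(path, values: np.ndarray, sample_ids, feature_ids) -> None:
    """(samples x features) values written as features-in-rows TSV."""
    df = pd.DataFrame(
        np.asarray(values).T, index=pd.Index(feature_ids, name="id"), columns=sample_ids
    )
    df.to_csv(path, sep="\t", na_rep="NA")


def read_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Returns (values samples x features, sample_ids, feature_ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    return df.to_numpy().T, list(df.columns), list(df.index)


def write_vcf(path, genotypes: np.ndarray, snp_map: pd.DataFrame, sample_ids) -> None:
    """Minimal VCF 4.2 with GT genotypes (alleles A/B placeholders)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for j, (snp, row) in enumerate(snp_map.iterrows()):
            calls = "\t".join(gt_codes[int(g)] for g in genotypes[:, j])
            chrom = str(row["chrom"]).removeprefix("chr")
            fh.write(f"{chrom}\t{int(row['bp'])}\t{snp}\tA\tB\t.\tPASS\t.\tGT\t{calls}\n")


def write_cohort(outdir, cohort: Cohort, vcf: bool = False) -> None:
    os.makedirs(outdir, exist_ok=True)
    samples = list(cohort.covariates.index)
    geno = cohort.genotypes.astype(int)
    write_matrix(os.path.join(outdir, "genotypes.tsv"), geno, samples, cohort.snp_ids)
    cohort.snp_map.to_csv(os.path.join(outdir, "snps.tsv"), sep="\t")
    write_matrix(
        os.path.join(outdir, "methylation.tsv"),
        cohort.methylation_beta,
        samples,
        cohort.cpg_ids,
    )
    cohort.cpg_map.to_csv(os.path.join(outdir, "cpgs.tsv"), sep="\t")
    cohort.covariates.to_csv(os.path.join(outdir, "covariates.tsv"), sep="\t")
    if cohort.probe_dosages:
        ids = sorted(cohort.probe_dosages)
        mat = np.column_stack([cohort.probe_dosages[c] for c in ids])
        write_matrix(os.path.join(outdir, "probe_dosages.tsv"), mat, samples, ids)
    if vcf:
        write_vcf(os.path.join(outdir, "genotypes.vcf"), geno, cohort.snp_map, samples)


def read_cohort(indir, role: str) -> Cohort:
    geno, samples, snp_ids = read_matrix(os.path.join(indir, "genotypes.tsv"))
    geno = np.nan_to_num(geno, nan=-1).astype(np.int8)
    snp_map = pd.read_csv(os.path.join(indir, "snps.tsv"), sep="\t", index_col=0)
    snp_map = snp_map.loc[snp_ids]
    beta, _, cpg_ids = read_matrix(os.path.join(indir, "methylation.tsv"))
    cpg_map = pd.read_csv(os.path.join(indir, "cpgs.tsv"), sep="\t", index_col=0)
    cpg_map = cpg_map.loc[cpg_ids]
    cov = pd.read_csv(os.path.join(indir, "covariates.tsv"), sep="\t", index_col=0)
    cov = cov.loc[samples]
    probe = {}
    dos_path = os.path.join(indir, "probe_dosages.tsv")
    if os.path.exists(dos_path):
        mat, _, ids = read_matrix(dos_path)
        probe = {c: mat[:, k] for k, c in enumerate(ids)}
    return Cohort(
        role=role,
        genotypes=geno,
        snp_map=snp_map,
        methylation_beta=beta,
        cpg_map=cpg_map,
        covariates=cov,
        probe_dosages=probe,
    )


def write_truth(path, truth: TruthRegistry) -> None:
    rows = []
    for e, r2, scale in zip(truth.effects, truth.realized_r2, truth.scales):
        rows.append(
            {
                "cpg_id": e.cpg_id,
                "kind": e.kind,
                "snp_ids": ",".join(e.snp_ids),
                "target_r2": e.target_r2,
                "realized_r2": r2,
                "scale": scale,
            }
        )
    pd.DataFrame(
        rows, columns=["cpg_id", "kind", "snp_ids", "target_r2", "realized_r2", "scale"]
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> TruthRegistry:
    df = pd.read_csv(path, sep="\t")
    effects, r2s, scales = [], [], []
    for _, row in df.iterrows():
        snps = tuple(str(row["snp_ids"]).split(",")) if pd.notna(row["snp_ids"]) else ()
        if snps == ("nan",) or snps == ("",):
            snps = ()
        effects.append(
            PlantedEffect(
                cpg_id=row["cpg_id"],
                kind=row["kind"],
                snp_ids=snps,
                target_r2=float(row["target_r2"]),
            )
        )
        r2s.append(float(row["realized_r2"]))
        scales.append(float(row["scale"]))
    truth = TruthRegistry(effects=effects, realized_r2=r2s, scales=scales)
    truth.spurious_pairs = [
        (e.cpg_id, e.snp_ids[1], e.snp_ids[2])
        for e in effects
        if e.kind == "spurious_ld_triad"
    ]
    return truth
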