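"""SNP quality filters and LD pruning.

Two keep-sets are produced in the pipeline: a stringent, LD-pruned *scan*
set for the exhaustive interaction search (adds a minimum genotype-group
size and pruning at r^2 > 0.95) and a larger *modeling* set for per-CpG
joint modelling (MAF/HWE/missingness only).  Every criterion must hold in
both cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import Cohort

__all__ = ["QCThresholds", "SNPKeepSet", "compute_maf", "hwe_exact_test",
           "filter_snps", "ld_prune"]


@dataclass
class QCThresholds:
    maf_min: float = 0.02
    hwe_p_min: float = 0.001
    miss_max: float = 0.01
    min_genotype_group: int = 15  # scan set only
    prune_window: int = 50  # SNPs per window
    prune_step: int = 5
    prune_r2: float = 0.95

    def validate(self) -> None:
        for name in ("maf_min", "hwe_p_min", "miss_max", "prune_r2"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.min_genotype_group < 1 or self.prune_window < 2 or self.prune_step < 1:
            raise ValueError("counts must be positive (window >= 2)")


@dataclass
class SNPKeepSet:
    kept: list[str]
    stats: pd.DataFrame  # per-SNP QC statistics for both cohorts
    label: str  # scan | modeling


def compute_maf(genotype_vector) -> float:
    """Minor-allele frequency from 0/1/2 dosages; missing coded < 0 or NaN."""
    g = np.asarray(genotype_vector, dtype=float)
    g = g[(g >= 0) & ~np.isnan(g)]
    if g.size == 0:
        raise ValueError("all genotypes missing")
    f = g.mean() / 2.0
    return float(min(f, 1.0 - f))


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test (sum of configurations no more
    probable than the observed heterozygote count, given the allele counts).

    Monomorphic input returns 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("empty sample")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # log-probability of each compatible heterozygote count (same parity)
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    rare_homs = (n_rare - hets) // 2
    common_homs = n - hets - rare_homs
    from scipy.special import gammaln

    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(rare_homs + 1)
        - gammaln(common_homs + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = int(np.nonzero(hets == n_Aa)[0][0])
    return float(min(1.0, p[p <= p[obs] * (1 + 1e-12)].sum()))


def _snp_stats(genotypes: np.ndarray) -> pd.DataFrame:
    miss = genotypes < 0
    n = genotypes.shape[0]
    n_AA = ((genotypes == 0)).sum(axis=0)
    n_Aa = ((genotypes == 1)).sum(axis=0)
    n_aa = ((genotypes == 2)).sum(axis=0)
    n_obs = n_AA + n_Aa + n_aa
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (n_Aa + 2 * n_aa) / (2 * n_obs)
    maf = np.minimum(f, 1 - f)
    hwe = np.array(
        [hwe_exact_test(int(a), int(h), int(b)) if t > 0 else np.nan
         for a, h, b, t in zip(n_AA, n_Aa, n_aa, n_obs)]
    )
    min_group = np.minimum(np.minimum(n_AA, n_Aa), n_aa)
    return pd.DataFrame(
        {
            "maf": maf,
            "hwe_p": hwe,
            "miss_rate": miss.sum(axis=0) / n,
            "min_group": min_group,
        }
    )


def filter_snps(
    discovery: Cohort,
    replication: Cohort,
    thresholds: QCThresholds,
    set_label: str = "scan",
) -> SNPKeepSet:
    """Keep SNPs passing MAF, HWE and missingness in BOTH cohorts.

    The minimum genotype-group-size criterion applies to the scan set only.
    """
    thresholds.validate()
    if set_label not in ("scan", "modeling"):
        raise ValueError("set_label must be 'scan' or 'modeling'")
    if not discovery.snp_map.index.equals(replication.snp_map.index):
        raise ValueError("cohorts must share the SNP map")
    stats = {}
    keep = np.ones(len(discovery.snp_map), dtype=bool)
    for cohort in (discovery, replication):
        s = _snp_stats(cohort.genotypes)
        s.index = cohort.snp_map.index
        stats[cohort.role] = s
        ok = (
            (s["maf"] > thresholds.maf_min)
            & (s["hwe_p"] > thresholds.hwe_p_min)
            & (s["miss_rate"] < thresholds.miss_max)
        )
        if set_label == "scan":
            ok &= s["min_group"] >= thresholds.min_genotype_group
        keep &= ok.fillna(False).to_numpy()
    merged = stats["discovery"].join(stats["replication"], lsuffix="_disc", rsuffix="_rep")
    merged["kept"] = keep
    kept_ids = list(discovery.snp_map.index[keep])
    return SNPKeepSet(kept=kept_ids, stats=merged, label=set_label)


def ld_prune(
    genotypes: np.ndarray,
    snp_map: pd.DataFrame,
    thresholds: QCThresholds,
) -> SNPKeepSet:
    """Sliding-window LD pruning on dosage r^2, decided on one cohort's data.

    Windows of ``prune_window`` SNPs advance by ``prune_step``; within a
    window, while any kept pair exceeds ``prune_r2`` the later-positioned SNP
    of the worst pair is removed.  SNPs must be sorted by (chrom, bp).
    """
    thresholds.validate()
    pos = snp_map[["chrom", "bp"]]
    for _, grp in pos.groupby("chrom", sort=False):
        if not grp["bp"].is_monotonic_increasing:
            raise ValueError("SNP map must be sorted by (chrom, bp)")
    removed: set[int] = set()
    g = genotypes.astype(float)
    g[g < 0] = np.nan
    chrom_codes = pos["chrom"].to_numpy()
    for chrom in pd.unique(chrom_codes):
        idx = np.nonzero(chrom_codes == chrom)[0]
        start = 0
        while start < idx.size:
            window = idx[start : start + thresholds.prune_window]
            _prune_window(g, window, removed, thresholds.prune_r2)
            if start + thresholds.prune_window >= idx.size:
                break
            start += thresholds.prune_step
    keep_mask = np.array([i not in removed for i in range(len(snp_map))])
    stats = pd.DataFrame({"kept": keep_mask}, index=snp_map.index)
    return SNPKeepSet(kept=list(snp_map.index[keep_mask]), stats=stats, label="scan")


def _prune_window(
    g: np.ndarray, window: np.ndarray, removed: set[int], prune_r2: float
) -> None:
    from .ld import _pairwise_r2_matrix

    while True:
        live = [i for i in window if i not in removed]
        if len(live) < 2:
            return
        r2 = _pairwise_r2_matrix(g[:, live])
        np.fill_diagonal(r2, 0.0)
        worst = np.nanmax(r2)
        if not np.isfinite(worst) or worst <= prune_r2:
            return
        i, j = np.unravel_index(np.nanargmax(r2), r2.shape)
        # remove the later-positioned SNP (columns are in map order)
        removed.add(live[max(i, j)])
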