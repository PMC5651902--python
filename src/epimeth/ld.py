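"""Pairwise linkage disequilibrium and the empirical epistasis/LD r^2 threshold.

LD is measured as the squared Pearson correlation of unphased genotype
dosages (composite LD): it needs no haplotype phase and is the same statistic
the downstream classification applies to interacting SNP pairs.  The
threshold separating "plausibly in LD" from "effectively independent" is
calibrated empirically as an upper quantile of r^2 between random
cross-chromosome SNP pairs, which for independent loci follows
approximately chi-square(1)/n, giving ~0.02 at n = 533 samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LDThresholdResult", "genotype_r2", "empirical_ld_threshold"]


@dataclass
class LDThresholdResult:
    threshold_r2: float
    quantile: float
    n_pairs: int
    seed: int
    null_summary: dict[str, float]


def genotype_r2(a, b) -> float:
    """Squared Pearson correlation of two dosage vectors (pairwise-complete)."""
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    if aa.shape != bb.shape:
        raise ValueError("vectors must share samples")
    ok = (aa >= 0) & (bb >= 0) & ~np.isnan(aa) & ~np.isnan(bb)
    aa, bb = aa[ok], bb[ok]
    if aa.size < 3:
        raise ValueError("need >= 3 complete genotype pairs")
    if aa.std() == 0 or bb.std() == 0:
        raise ValueError("monomorphic genotype vector")
    r = np.corrcoef(aa, bb)[0, 1]
    return float(r * r)


def _pairwise_r2_matrix(g: np.ndarray) -> np.ndarray:
    """All-pairs dosage r^2 for a (samples x snps) float matrix with NaN missing.

    Complete-case per matrix (missing entries are mean-imputed per SNP first,
    a negligible distortion at sub-percent missingness); used by LD pruning.
    """
    x = g.copy()
    mu = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(mu, idx[1])
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.nan
    c = (x.T @ x) / x.shape[0]
    r = c / np.outer(sd, sd)
    return r * r


def empirical_ld_threshold(
    genotypes: np.ndarray,
    snp_map: pd.DataFrame,
    n_pairs: int = 10_000,
    quantile: float = 0.999,
    seed: int = 0,
) -> LDThresholdResult:
    """Upper quantile of r^2 between random cross-chromosome SNP pairs.

    Samples ``n_pairs`` (SNP, SNP-on-another-chromosome) pairs uniformly with
    replacement and returns the empirical ``quantile`` of their dosage r^2 —
    the value above which observed LD is unlikely (p < 1 - quantile) between
    physically unlinked loci.
    """
    chroms = snp_map["chrom"].to_numpy()
    if len(pd.unique(chroms)) < 2:
        raise ValueError("need SNPs on at least 2 chromosomes")
    rng = np.random.default_rng(seed)
    n_snps = genotypes.shape[1]
    r2s = np.empty(n_pairs)
    filled = 0
    while filled < n_pairs:
        i = int(rng.integers(n_snps))
        j = int(rng.integers(n_snps))
        if chroms[i] == chroms[j]:
            continue
        try:
            r2s[filled] = genotype_r2(genotypes[:, i], genotypes[:, j])
        except ValueError:
            continue
        filled += 1
    thr = float(np.quantile(r2s, quantile))
    summary = {
        "mean": float(r2s.mean()),
        "q50": float(np.quantile(r2s, 0.5)),
        "q95": float(np.quantile(r2s, 0.95)),
        "q99": float(np.quantile(r2s, 0.99)),
    }
    return LDThresholdResult(
        threshold_r2=thr,
        quantile=quantile,
        n_pairs=n_pairs,
        seed=seed,
        null_summary=summary,
    )
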