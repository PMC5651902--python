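"""Replication-phase triple filter for discovery-scan interaction hits.

A hit survives only if, in the independent replication cohort, it passes

* an adaptive per-CpG Bonferroni threshold, ``alpha / (n_unique_cpgs +
  n_hits_on_this_cpg)``, applied to the exact interaction p-value;
* the same threshold applied to a permutation *empirical* p-value (the CpG
  signal permuted across samples with genotypes fixed, guarding against a
  few extreme observations landing in a small genotype cell);
* a sign test: Pearson correlation > 0.85 between the 9 genotype-cell mean
  methylation levels of the two cohorts,

plus a minimum genotype-cell occupancy (> 3) in both cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
from scipy import stats

from .scan import CellSummary, ScanHit, cell_summaries, exact_interaction_anova

__all__ = [
    "ReplicationConfig",
    "ReplicationVerdict",
    "per_cpg_threshold",
    "empirical_interaction_p",
    "sign_test_r",
    "replicate_hits",
]


@dataclass
class ReplicationConfig:
    alpha: float = 0.05
    n_permutations: int = 1000
    min_cell: int = 3  # strict: cells must exceed this in both cohorts
    sign_r_min: float = 0.85
    seed: int = 0
    early_stop: bool = False
    pooled_per_cpg_null: bool = False


@dataclass
class ReplicationVerdict:
    hit: ScanHit
    per_cpg_threshold: float
    p_rep: float
    p_emp: float
    sign_r: float
    pass_bonferroni: bool
    pass_empirical: bool
    pass_sign: bool
    pass_min_cell: bool

    @property
    def pass_all(self) -> bool:
        return (
            self.pass_bonferroni
            and self.pass_empirical
            and self.pass_sign
            and self.pass_min_cell
        )


def per_cpg_threshold(n_unique_cpgs: int, n_hits_this_cpg: int, alpha: float = 0.05) -> float:
    """Adaptive per-CpG Bonferroni: alpha / (unique-CpG baseline + hits on CpG)."""
    if n_unique_cpgs < 1 or n_hits_this_cpg < 1:
        raise ValueError("counts must be >= 1")
    return alpha / (n_unique_cpgs + n_hits_this_cpg)


def _perm_F(geno_a, geno_b, Y_perm: np.ndarray) -> np.ndarray:
    """Exact interaction F for many response columns at fixed genotypes.

    Vectorised over columns of ``Y_perm`` via cell-indicator and
    main-effects-projection matmuls; matches
    :func:`epimeth.scan.exact_interaction_anova` on complete data.
    """
    ga = np.asarray(geno_a).astype(int)
    gb = np.asarray(geno_b).astype(int)
    n = ga.size
    cell = ga * 3 + gb
    onehot = np.zeros((9, n))
    onehot[cell, np.arange(n)] = 1.0
    counts = onehot.sum(axis=1)
    if (counts == 0).any():
        raise ValueError("all 9 genotype cells must be occupied")
    X = np.column_stack(
        [np.ones(n), ga == 1, ga == 2, gb == 1, gb == 2]
    ).astype(float)
    Q, _ = np.linalg.qr(X)
    ss_y = (Y_perm * Y_perm).sum(axis=0)
    proj = Q.T @ Y_perm
    rss_main = ss_y - (proj * proj).sum(axis=0)
    cell_sums = onehot @ Y_perm
    rss_sat = ss_y - (cell_sums * cell_sums / counts[:, None]).sum(axis=0)
    rss_sat = np.maximum(rss_sat, 0.0)
    df2 = n - 9
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (rss_main - rss_sat) / 4.0 / (rss_sat / df2)
    return np.maximum(np.nan_to_num(F, posinf=np.inf), 0.0)


def empirical_interaction_p(
    geno_a,
    geno_b,
    y,
    F_obs: float,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
    early_stop: bool = False,
    stop_threshold: float | None = None,
) -> float:
    """Permutation p-value of the exact interaction F (add-one estimator).

    The response is permuted across samples with the genotype pair fixed;
    ``p = (1 + #{F_perm >= F_obs}) / (B + 1)``.  With ``early_stop`` the
    permutation loop is abandoned once the Clopper-Pearson lower bound of the
    running p exceeds 10x ``stop_threshold`` (the hit cannot pass anyway).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ga = np.asarray(geno_a, dtype=float)
    gb = np.asarray(geno_b, dtype=float)
    yy = np.asarray(y, dtype=float)
    ok = (ga >= 0) & (gb >= 0) & ~np.isnan(yy)
    ga, gb, yy = ga[ok].astype(int), gb[ok].astype(int), yy[ok]
    n = yy.size
    exceed = 0
    done = 0
    batch = 250
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        Y_perm = yy[np.argsort(rng.random((b, n)), axis=1)].T  # (n, b)
        F = _perm_F(ga, gb, Y_perm)
        exceed += int((F >= F_obs).sum())
        done += b
        if early_stop and stop_threshold is not None:
            lower = stats.beta.ppf(0.005, exceed, done - exceed + 1) if exceed else 0.0
            if lower > 10 * stop_threshold:
                break
    return (1 + exceed) / (done + 1)


def sign_test_r(cells_discovery: CellSummary, cells_replication: CellSummary) -> float:
    """Pearson correlation of the two cohorts' 9 genotype-cell mean vectors."""
    if not (cells_discovery.all_cells_present and cells_replication.all_cells_present):
        raise ValueError("all 9 cells must be occupied in both cohorts")
    a = cells_discovery.means.ravel()
    b = cells_replication.means.ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance among cell means")
    return float(np.corrcoef(a, b)[0, 1])


def replicate_hits(
    hits: list[ScanHit],
    discovery_genotypes: np.ndarray,
    discovery_Y: np.ndarray,
    replication_genotypes: np.ndarray,
    replication_Y: np.ndarray,
    snp_ids,
    cpg_ids,
    config: ReplicationConfig | None = None,
) -> list[ReplicationVerdict]:
    """Run the full triple filter over a list of discovery hits.

    Permutation streams are shared per CpG (the same permuted signals are
    reused across all SNP pairs of one CpG), matching a per-CpG empirical
    null while retaining pair-level p-values.
    """
    config = config or ReplicationConfig()
    snp_pos = {s: i for i, s in enumerate(snp_ids)}
    cpg_pos = {c: j for j, c in enumerate(cpg_ids)}
    hits_per_cpg = Counter(h.cpg_id for h in hits)
    n_unique = len(hits_per_cpg)
    cpg_rngs = {
        c: np.random.default_rng([config.seed, 51, j])
        for j, c in enumerate(sorted(hits_per_cpg))
    }
    verdicts = []
    for hit in hits:
        ai, bi = snp_pos[hit.snp_a], snp_pos[hit.snp_b]
        cj = cpg_pos[hit.cpg_id]
        thr = per_cpg_threshold(n_unique, hits_per_cpg[hit.cpg_id], config.alpha)
        cells_d = cell_summaries(
            discovery_genotypes[:, ai], discovery_genotypes[:, bi], discovery_Y[:, cj]
        )
        cells_r = cell_summaries(
            replication_genotypes[:, ai],
            replication_genotypes[:, bi],
            replication_Y[:, cj],
        )
        pass_min_cell = (
            cells_d.min_cell > config.min_cell and cells_r.min_cell > config.min_cell
        )
        if cells_r.all_cells_present:
            F_rep, p_rep, _ = exact_interaction_anova(
                replication_genotypes[:, ai],
                replication_genotypes[:, bi],
                replication_Y[:, cj],
            )
            p_emp = empirical_interaction_p(
                replication_genotypes[:, ai],
                replication_genotypes[:, bi],
                replication_Y[:, cj],
                F_rep,
                n_permutations=config.n_permutations,
                seed=cpg_rngs[hit.cpg_id],
                early_stop=config.early_stop,
                stop_threshold=thr,
            )
        else:
            p_rep, p_emp = 1.0, 1.0
        try:
            r = sign_test_r(cells_d, cells_r)
            pass_sign = r > config.sign_r_min
        except ValueError:
            r, pass_sign = float("nan"), False
        verdicts.append(
            ReplicationVerdict(
                hit=hit,
                per_cpg_threshold=thr,
                p_rep=p_rep,
                p_emp=p_emp,
                sign_r=r,
                pass_bonferroni=p_rep < thr,
                pass_empirical=p_emp < thr,
                pass_sign=pass_sign,
                pass_min_cell=pass_min_cell,
            )
        )
    return verdicts
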