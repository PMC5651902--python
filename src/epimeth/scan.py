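"""Exhaustive discovery-phase scan for two-locus (SNP x SNP) effects on CpG signals.

The scan statistic family mirrors the classic 9-genotype-cell ANOVA used in
fast exhaustive interaction searches: an 8-df joint test of the combined
two-locus genetic effect, a 4-df approximate interaction test obtained by
subtracting count-weighted additive+dominance marginal means from the cell
means, and an exact 4-df factorial-ANOVA interaction test (main-effects model
vs. saturated cell-means model) used to recalculate promising pairs.

The approximate test equals the exact test whenever the two genotype factors
are orthogonal (e.g. balanced designs or independent SNPs); under LD or strong
main effects it is only an upper-bound-ish screen and every pair passing the
F filter is recomputed exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CellSummary",
    "ScanHit",
    "cell_summaries",
    "approx_two_locus_test",
    "exact_interaction_anova",
    "exhaustive_scan",
    "count_exhaustive_tests",
    "bonferroni_threshold",
    "bonferroni_matched_f_filter",
    "interaction_power",
]

#: Smallest p-value we report; tails below this are flagged, not zeroed.
MIN_P = 5e-324


@dataclass
class CellSummary:
    """Per-cell statistics of a 3x3 two-locus genotype cross.

    ``means`` is NaN for empty cells.  ``ss_within`` is the pooled
    within-cell sum of squares of the response.
    """

    counts: np.ndarray  # (3, 3) int
    means: np.ndarray  # (3, 3) float, NaN where count == 0
    n_total: int
    ss_within: float
    grand_mean: float

    @property
    def min_cell(self) -> int:
        return int(self.counts.min())

    @property
    def all_cells_present(self) -> bool:
        return bool((self.counts > 0).all())


@dataclass
class ScanHit:
    """One candidate interaction surviving the discovery-phase filters."""

    cpg_id: str
    snp_a: str
    snp_b: str
    F8: float
    F4_approx: float
    F_exact: float
    p_exact: float
    df: tuple[int, int]
    min_cell_discovery: int
    min_cell_replication: int | None
    all_cells_present: bool
    p_underflow: bool = field(default=False)


def cell_summaries(geno_a, geno_b, y) -> CellSummary:
    """Summarise a response over the 9 cells of two genotype vectors.

    Missing genotypes (coded negative or NaN) and missing responses are
    removed listwise.  Raises ``ValueError`` with fewer than 10 complete
    observations.
    """
    ga = np.asarray(geno_a, dtype=float)
    gb = np.asarray(geno_b, dtype=float)
    yy = np.asarray(y, dtype=float)
    if not (ga.shape == gb.shape == yy.shape):
        raise ValueError("geno_a, geno_b and y must have equal length")
    ok = (ga >= 0) & (gb >= 0) & ~np.isnan(ga) & ~np.isnan(gb) & ~np.isnan(yy)
    ga, gb, yy = ga[ok].astype(int), gb[ok].astype(int), yy[ok]
    n = yy.size
    if n < 10:
        raise ValueError(f"only {n} complete observations (need >= 10)")
    cell = ga * 3 + gb
    counts = np.bincount(cell, minlength=9).reshape(3, 3)
    sums = np.bincount(cell, weights=yy, minlength=9).reshape(3, 3)
    sums2 = np.bincount(cell, weights=yy * yy, minlength=9).reshape(3, 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    grand_mean = yy.mean()
    ss_within = float((sums2 - np.where(counts > 0, sums * means, 0.0)).sum())
    ss_within = max(ss_within, 0.0)
    return CellSummary(
        counts=counts,
        means=means,
        n_total=int(n),
        ss_within=ss_within,
        grand_mean=float(grand_mean),
    )


def approx_two_locus_test(cells: CellSummary) -> tuple[float, float]:
    """Fast 8-df joint and 4-df approximate interaction F statistics.

    The joint statistic compares the 9 cell means against the grand mean.
    The interaction approximation predicts each cell mean by
    ``r_i + c_j - mu`` where ``r_i``/``c_j`` are the count-weighted marginal
    means of the two genotype factors, and tests the residual cell deviation.
    Empty cells are skipped (callers filter on ``all_cells_present``).
    """
    n = cells.n_total
    if n <= 9:
        raise ValueError("need more than 9 observations")
    if cells.ss_within <= 0:
        raise ValueError("zero within-cell variance")
    counts = cells.counts.astype(float)
    means = np.where(cells.counts > 0, cells.means, 0.0)
    mu = cells.grand_mean
    row_n = counts.sum(axis=1)
    col_n = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(row_n > 0, (counts * means).sum(axis=1) / row_n, mu)
        c = np.where(col_n > 0, (counts * means).sum(axis=0) / col_n, mu)
    pred = r[:, None] + c[None, :] - mu
    occ = cells.counts > 0
    ss_joint = float((counts * (means - mu) ** 2)[occ].sum())
    ss_int = float((counts * (means - pred) ** 2)[occ].sum())
    mse = cells.ss_within / (n - 9)
    return ss_joint / 8.0 / mse, ss_int / 4.0 / mse


def exact_interaction_anova(geno_a, geno_b, y) -> tuple[float, float, tuple[int, int]]:
    """Exact 4-df interaction test: main-effects factors vs. saturated cells.

    Fits the two SNPs as 3-level factors (2 df each) and compares against the
    9-cell-means model by a partial F test with (4, n-9) df.  All 9 cells must
    be occupied.  Returns ``(F, p, (4, n - 9))``; p-values beneath the
    smallest positive double are clamped to it.
    """
    cells = cell_summaries(geno_a, geno_b, y)
    if not cells.all_cells_present:
        raise ValueError("all 9 genotype cells must be occupied")
    ga = np.asarray(geno_a, dtype=float)
    gb = np.asarray(geno_b, dtype=float)
    yy = np.asarray(y, dtype=float)
    ok = (ga >= 0) & (gb >= 0) & ~np.isnan(ga) & ~np.isnan(gb) & ~np.isnan(yy)
    ga, gb, yy = ga[ok].astype(int), gb[ok].astype(int), yy[ok]
    n = yy.size
    X = np.column_stack(
        [
            np.ones(n),
            ga == 1,
            ga == 2,
            gb == 1,
            gb == 2,
        ]
    ).astype(float)
    beta, _, rank, _ = np.linalg.lstsq(X, yy, rcond=None)
    resid = yy - X @ beta
    rss_main = float(resid @ resid)
    rss_sat = cells.ss_within
    df1, df2 = 4, n - 9
    if rss_sat <= 0:
        # Saturated model interpolates the data; any interaction deviation
        # is infinitely significant relative to zero residual noise.
        if rss_main - rss_sat > 1e-12 * max(1.0, float(yy @ yy)):
            return math.inf, MIN_P, (df1, df2)
        return 0.0, 1.0, (df1, df2)
    F = (rss_main - rss_sat) / df1 / (rss_sat / df2)
    F = max(F, 0.0)
    p = float(np.exp(stats.f.logsf(F, df1, df2)))
    p = min(max(p, MIN_P), 1.0)
    return float(F), p, (df1, df2)


def count_exhaustive_tests(n_cpgs: int, n_snps: int) -> int:
    """Number of (CpG, unordered SNP pair) tests: ``n_cpgs * C(n_snps, 2)``."""
    if n_cpgs < 0 or n_snps < 0:
        raise ValueError("counts must be non-negative")
    if n_snps < 2:
        return 0
    return n_cpgs * (n_snps * (n_snps - 1) // 2)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold ``alpha / n_tests``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def bonferroni_matched_f_filter(
    alpha: float, n_tests: int, n_samples: int, df1: int = 4
) -> float:
    """Screening F threshold whose (df1, n-9) tail mass equals alpha/n_tests.

    The fast scan discards pairs below this approximate-F value before exact
    recalculation; tying it to the Bonferroni threshold keeps the screen
    "close to Bonferroni" at any problem scale (at full epigenome scale,
    ~2e5 SNPs x 4e5 CpGs, it evaluates to ~23.5, the neighbourhood of the
    classic filter value 22).
    """
    df2 = n_samples - 9
    if df2 <= 0:
        raise ValueError("need more than 9 samples")
    target = math.log(bonferroni_threshold(alpha, n_tests))
    lo, hi = 0.0, 1e6
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if stats.f.logsf(mid, df1, df2) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def interaction_power(
    r: float, n: int, alpha: float, df1: int = 4, df2: int | None = None
) -> float:
    """Power of the df1-df interaction F test for an effect of correlation r.

    The noncentrality is ``n * r^2 / (1 - r^2)``, i.e. the effect explains a
    fraction r^2 of residual variance.  df2 defaults to ``n - 9`` (two-locus
    cell-means model).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 <= r < 1:
        raise ValueError("r must be in [0, 1)")
    if df2 is None:
        df2 = n - 9
    if n <= df1 + 5 or df2 <= 0:
        raise ValueError("sample size too small for the requested test")
    nc = n * r * r / (1.0 - r * r)
    crit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, nc))


# ---------------------------------------------------------------------------
# Vectorised exhaustive scan


def _onehot(geno: np.ndarray) -> np.ndarray:
    """(n, 3) indicator of genotype classes; missing rows are all-zero."""
    n = geno.shape[0]
    out = np.zeros((n, 3))
    for g in range(3):
        out[:, g] = geno == g
    return out


def scan_statistics_block(
    genotypes: np.ndarray,
    Y: np.ndarray,
    a: int,
    b_idx: np.ndarray,
) -> dict:
    """All-pairs (a, b) x all-CpG approximate statistics, vectorised.

    ``genotypes`` is (n_samples, n_snps) with missing < 0, ``Y`` is a
    complete (n_samples, n_cpgs) response matrix.  Returns per (b, cpg)
    arrays of F4_approx plus per-b cell counts; semantics match
    :func:`cell_summaries` + :func:`approx_two_locus_test` with listwise
    deletion over the genotype pair.
    """
    ga = genotypes[:, a]
    B = genotypes[:, b_idx]
    n, n_cpg = Y.shape
    nb = b_idx.size
    oh_a = _onehot(ga)
    # (n, 3*nb) indicator of b-genotypes
    oh_b = np.zeros((n, 3 * nb))
    for g in range(3):
        oh_b[:, g::3] = B == g
    Y2 = np.concatenate([Y, Y * Y], axis=1)
    counts = np.empty((3, 3, nb))
    sums = np.empty((3, 3, nb, n_cpg))
    sums2 = np.empty((3, 3, nb, n_cpg))
    for i in range(3):
        rows = oh_a[:, i] > 0
        sub = oh_b[rows]
        counts[i] = sub.sum(axis=0).reshape(nb, 3).T
        block = sub.T @ Y2[rows]  # (3*nb, 2*n_cpg)
        block = block.reshape(nb, 3, 2 * n_cpg).transpose(1, 0, 2)
        sums[i] = block[:, :, :n_cpg]
        sums2[i] = block[:, :, n_cpg:]
    n_tot = counts.sum(axis=(0, 1))  # (nb,)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts[..., None]
    means = np.nan_to_num(means)
    tot_sum = sums.sum(axis=(0, 1))  # (nb, n_cpg)
    mu = tot_sum / n_tot[:, None]
    ss_within = sums2.sum(axis=(0, 1)) - np.where(
        counts[..., None] > 0, sums * means, 0.0
    ).sum(axis=(0, 1))
    ss_within = np.maximum(ss_within, 0.0)
    row_n = counts.sum(axis=1)  # (3, nb)
    col_n = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (counts[..., None] * means).sum(axis=1) / row_n[..., None]
        c = (counts[..., None] * means).sum(axis=0) / col_n[..., None]
    r = np.where(row_n[..., None] > 0, r, mu[None])
    c = np.where(col_n[..., None] > 0, c, mu[None])
    pred = r[:, None] + c[None, :] - mu[None, None]
    dev = np.where(counts[..., None] > 0, means - pred, 0.0)
    ss_int = (counts[..., None] * dev * dev).sum(axis=(0, 1))
    devj = np.where(counts[..., None] > 0, means - mu[None, None], 0.0)
    ss_joint = (counts[..., None] * devj * devj).sum(axis=(0, 1))
    df2 = n_tot - 9
    with np.errstate(invalid="ignore", divide="ignore"):
        mse = ss_within / df2[:, None]
        F4 = ss_int / 4.0 / mse
        F8 = ss_joint / 8.0 / mse
    return {
        "F4": F4,
        "F8": F8,
        "counts": counts,
        "min_cell": counts.min(axis=(0, 1)).astype(int),
        "n_total": n_tot.astype(int),
    }


def exhaustive_scan(
    genotypes: np.ndarray,
    Y: np.ndarray,
    snp_ids,
    cpg_ids,
    f_filter: float = 22.0,
    alpha: float = 0.05,
    genotypes_replication: np.ndarray | None = None,
    n_tests: int | None = None,
    use_direct_bonferroni: bool = False,
    progress=None,
) -> list[ScanHit]:
    """Exhaustive approximate-then-exact scan over all (CpG, SNP pair) tests.

    Every unordered SNP pair is screened per CpG with the 4-df approximation;
    pairs with all 9 cells occupied and ``F4 > f_filter`` are recalculated
    with the exact factorial ANOVA, and hits are kept when the exact p falls
    below the Bonferroni threshold for the full test count.  With
    ``use_direct_bonferroni`` the F filter is bypassed and the Bonferroni
    decision is applied to the approximate statistic's own p-value before
    recalculation (the sanity-check variant of the two-step procedure).

    ``Y`` must be complete (no NaN): the vectorised kernel handles missing
    genotypes listwise but not response missingness.
    """
    genotypes = np.asarray(genotypes)
    Y = np.asarray(Y, dtype=float)
    if np.isnan(Y).any():
        raise ValueError("scan requires a complete response matrix")
    snp_ids = list(snp_ids)
    cpg_ids = list(cpg_ids)
    n_snps = len(snp_ids)
    if n_tests is None:
        n_tests = count_exhaustive_tests(len(cpg_ids), n_snps)
    threshold = bonferroni_threshold(alpha, max(n_tests, 1))
    hits: list[ScanHit] = []
    for a in range(n_snps - 1):
        b_idx = np.arange(a + 1, n_snps)
        block = scan_statistics_block(genotypes, Y, a, b_idx)
        F4 = block["F4"]
        all_present = (block["counts"] > 0).all(axis=(0, 1))
        if use_direct_bonferroni:
            df2 = block["n_total"] - 9
            with np.errstate(invalid="ignore"):
                p_approx = stats.f.sf(F4, 4, df2[:, None])
            cand = np.nonzero(all_present[:, None] & (p_approx < threshold))
        else:
            cand = np.nonzero(all_present[:, None] & (F4 > f_filter))
        for bi, ci in zip(*cand):
            b = int(b_idx[bi])
            F_exact, p_exact, df = exact_interaction_anova(
                genotypes[:, a], genotypes[:, b], Y[:, ci]
            )
            if p_exact >= threshold:
                continue
            min_rep = None
            if genotypes_replication is not None:
                rep_counts = _pair_counts(
                    genotypes_replication[:, a], genotypes_replication[:, b]
                )
                min_rep = int(rep_counts.min())
            hits.append(
                ScanHit(
                    cpg_id=cpg_ids[ci],
                    snp_a=snp_ids[a],
                    snp_b=snp_ids[b],
                    F8=float(block["F8"][bi, ci]),
                    F4_approx=float(F4[bi, ci]),
                    F_exact=F_exact,
                    p_exact=p_exact,
                    df=df,
                    min_cell_discovery=int(block["min_cell"][bi]),
                    min_cell_replication=min_rep,
                    all_cells_present=True,
                    p_underflow=p_exact <= MIN_P,
                )
            )
        if progress is not None:
            progress(a + 1, n_snps)
    hits.sort(key=lambda h: (h.cpg_id, h.p_exact, h.snp_a, h.snp_b))
    return hits


def _pair_counts(geno_a: np.ndarray, geno_b: np.ndarray) -> np.ndarray:
    ok = (geno_a >= 0) & (geno_b >= 0)
    cell = geno_a[ok].astype(int) * 3 + geno_b[ok].astype(int)
    return np.bincount(cell, minlength=9).reshape(3, 3)
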