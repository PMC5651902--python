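"""Per-CpG joint modelling of SNP main and interaction effects.

This stage guards against the classic spurious-interaction mechanism: two
SNPs in LD with a third SNP carrying a strong main effect can mimic an
interaction.  For each CpG with surviving scan hits we assemble candidate
main-effect SNPs (cis windows around the CpG and around interacting SNPs,
plus genome-wide-significant mains) and candidate pairs (the hits plus all
pairs among LD partners of the interacting SNPs), then run a dual-cohort
stepwise-forward regression: mains enter first in ascending discovery
p-value, then interactions; a term is kept only if its partial F-test beats
``alpha / (n_mains_tested + n_pairs_tested)`` in BOTH cohorts.

Interaction terms are encoded as the four genotype-cell contrasts
orthogonalised against both SNPs' additive+dominance (factor) margins, so a
kept interaction carries interaction-only variance and the variance
decomposition (best single main / all mains / mains+interactions) separates
cleanly.  Kept pairs are finally classified as LD-block associated
(discovery r^2 above the empirically calibrated threshold) versus epistatic,
and by cis/trans location relative to the CpG.

The module also hosts the proximal main-effect-first search: a +/- 3.5 MB
window scan for replicated 2-df main effects, followed by interaction tests
restricted to CpGs with at least two significant mains.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld import genotype_r2
from .scan import cell_summaries, exact_interaction_anova

__all__ = [
    "ModelTerm",
    "CpGModel",
    "CandidateSet",
    "main_effect_scan",
    "assemble_candidates",
    "forward_select",
    "classify_pairs",
    "variance_decomposition",
    "proximal_main_scan",
    "proximal_interaction_scan",
]

CIS_WINDOW = 500_000


@dataclass
class ModelTerm:
    kind: str  # main | interaction
    snps: tuple[str, ...]
    df: int
    p_discovery: float
    p_replication: float
    entry_order: int
    ld_r2: float | None = None  # interaction only
    ld_class: str | None = None  # epistatic | ld_block
    cis_trans: str | None = None  # both_cis | one_cis | both_trans


@dataclass
class CpGModel:
    cpg_id: str
    terms: list[ModelTerm] = field(default_factory=list)
    n_main_tested: int = 0
    n_int_tested: int = 0
    threshold: float = float("nan")
    r2_components: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def main_terms(self) -> list[ModelTerm]:
        return [t for t in self.terms if t.kind == "main"]

    @property
    def interaction_terms(self) -> list[ModelTerm]:
        return [t for t in self.terms if t.kind == "interaction"]


@dataclass
class CandidateSet:
    cpg_id: str
    mains: list[str]
    pairs: list[tuple[str, str]]


# ---------------------------------------------------------------------------
# elementary builders


def _geno_col(genotypes: np.ndarray, idx: int) -> np.ndarray:
    g = genotypes[:, idx].astype(float)
    g[g < 0] = np.nan
    return g


def _main_columns(g: np.ndarray) -> np.ndarray:
    """2-df factor encoding (het / rare-hom dummies); missing rows mean-filled."""
    d = np.column_stack([(g == 1), (g == 2)]).astype(float)
    miss = np.isnan(g)
    if miss.any():
        d[miss] = d[~miss].mean(axis=0)
    return d


def _interaction_columns(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """4 cell contrasts orthogonal to both SNPs' factor margins."""
    prod = np.column_stack(
        [
            (ga == 1) & (gb == 1),
            (ga == 1) & (gb == 2),
            (ga == 2) & (gb == 1),
            (ga == 2) & (gb == 2),
        ]
    ).astype(float)
    margins = np.column_stack(
        [np.ones(ga.size), _main_columns(ga), _main_columns(gb)]
    )
    miss = np.isnan(ga) | np.isnan(gb)
    if miss.any():
        prod[miss] = prod[~miss].mean(axis=0)
    Q, _ = np.linalg.qr(margins)
    return prod - Q @ (Q.T @ prod)


def _partial_f(X0: np.ndarray, cols: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Partial F-test of adding ``cols`` to the design ``X0``.

    Returns (F, p, q) where q is the effective rank added; q = 0 signals a
    fully collinear (skippable) term.
    """
    n = y.size
    Q0, _ = np.linalg.qr(X0)
    r0 = y - Q0 @ (Q0.T @ y)
    rss0 = float(r0 @ r0)
    C = cols - Q0 @ (Q0.T @ cols)
    Qc, Rc = np.linalg.qr(C)
    keep = np.abs(np.diag(Rc)) > 1e-8 * max(1.0, np.abs(np.diag(Rc)).max())
    q = int(keep.sum())
    if q == 0:
        return 0.0, 1.0, 0
    Qc = Qc[:, keep]
    r1 = r0 - Qc @ (Qc.T @ r0)
    rss1 = float(r1 @ r1)
    p_full = X0.shape[1] + q
    df2 = n - p_full
    if df2 <= 0 or rss1 <= 0:
        return float("inf"), 0.0, q
    F = (rss0 - rss1) / q / (rss1 / df2)
    return float(max(F, 0.0)), float(stats.f.sf(max(F, 0.0), q, df2)), q


def main_effect_scan(genotypes: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """2-df (3-level genotype factor) ANOVA of every SNP column on y.

    Vectorised over SNPs; missing genotypes are dropped per SNP.  Returns a
    frame with F, p and the df actually available (SNPs observed in fewer
    than 2 genotype groups get p = NaN).
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("response must be complete")
    n, m = genotypes.shape
    counts = np.empty((3, m))
    sums = np.empty((3, m))
    sums2 = np.empty((3, m))
    y2 = y * y
    for g in range(3):
        ind = (genotypes == g).astype(float)
        counts[g] = ind.sum(axis=0)
        sums[g] = ind.T @ y
        sums2[g] = ind.T @ y2
    n_inc = counts.sum(axis=0)
    tot = sums.sum(axis=0)
    tot2 = sums2.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ss_groups = np.where(counts > 0, sums * sums / counts, 0.0).sum(axis=0)
        ss_between = ss_groups - tot * tot / n_inc
        ss_within = tot2 - ss_groups
    groups = (counts > 0).sum(axis=0)
    df1 = groups - 1
    df2 = n_inc - groups
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
    F = np.where((df1 >= 1) & (df2 >= 1) & (ss_within > 0), F, np.nan)
    p = np.full(m, np.nan)
    okm = ~np.isnan(F)
    p[okm] = stats.f.sf(F[okm], df1[okm], df2[okm])
    return pd.DataFrame({"F": F, "p": p, "df1": df1, "df2": df2, "n": n_inc})


# ---------------------------------------------------------------------------
# candidate assembly and forward selection


def assemble_candidates(
    cpg_id: str,
    hit_pairs: list[tuple[str, str]],
    snp_map: pd.DataFrame,
    cpg_map: pd.DataFrame,
    genotypes_discovery: np.ndarray,
    y_discovery: np.ndarray,
    ld_threshold: float,
    genomewide_alpha: float = 0.05,
    cis_window: int = CIS_WINDOW,
) -> CandidateSet:
    """Candidate mains and pairs for one CpG's joint model.

    Mains: SNPs within ``cis_window`` of the CpG, SNPs within the window of
    any interacting SNP, and genome-wide-significant main effects at
    ``genomewide_alpha / n_snps``.  Pairs: the surviving hit pairs plus all
    pairs among SNPs in LD (r^2 above threshold) with an interacting SNP.
    """
    if not hit_pairs:
        raise ValueError("CpG must have at least one surviving hit")
    snp_ids = list(snp_map.index)
    pos = {s: i for i, s in enumerate(snp_ids)}
    hit_snps = sorted({s for pair in hit_pairs for s in pair})
    chrom_c = cpg_map.loc[cpg_id, "chrom"]
    bp_c = int(cpg_map.loc[cpg_id, "bp"])
    mains: set[str] = set()
    near = (snp_map["chrom"] == chrom_c) & (abs(snp_map["bp"] - bp_c) <= cis_window)
    mains.update(snp_map.index[near])
    for s in hit_snps:
        chrom_s = snp_map.loc[s, "chrom"]
        bp_s = int(snp_map.loc[s, "bp"])
        near = (snp_map["chrom"] == chrom_s) & (abs(snp_map["bp"] - bp_s) <= cis_window)
        mains.update(snp_map.index[near])
    gw = main_effect_scan(genotypes_discovery, y_discovery)
    gw_thr = genomewide_alpha / len(snp_ids)
    mains.update(np.array(snp_ids)[np.nan_to_num(gw["p"], nan=1.0) < gw_thr])
    partners: set[str] = set(hit_snps)
    for s in snp_ids:
        if s in partners:
            continue
        for h in hit_snps:
            try:
                if genotype_r2(
                    _geno_col(genotypes_discovery, pos[s]),
                    _geno_col(genotypes_discovery, pos[h]),
                ) > ld_threshold:
                    partners.add(s)
                    break
            except ValueError:
                continue
    pairs = {tuple(sorted(p)) for p in hit_pairs}
    pairs.update(tuple(sorted(p)) for p in itertools.combinations(sorted(partners), 2))
    return CandidateSet(cpg_id=cpg_id, mains=sorted(mains), pairs=sorted(pairs))


def forward_select(
    candidates: CandidateSet,
    genotypes_discovery: np.ndarray,
    y_discovery: np.ndarray,
    genotypes_replication: np.ndarray,
    y_replication: np.ndarray,
    snp_ids,
    alpha: float = 0.05,
    min_cell: int = 3,
) -> CpGModel:
    """Dual-cohort stepwise-forward selection of main and interaction terms.

    Entry order: mains ascending by discovery marginal 2-df p, then pairs
    ascending by discovery marginal exact-interaction p.  Each candidate's
    partial F-test (against the model of previously kept terms, refit with
    identical structure in each cohort) must beat
    ``alpha / (n_mains_tested + n_pairs_tested)`` in both cohorts.
    Interaction candidates additionally require all 9 genotype cells with
    more than ``min_cell`` observations in both cohorts.
    """
    snp_ids = list(snp_ids)
    pos = {s: i for i, s in enumerate(snp_ids)}
    y_d = np.asarray(y_discovery, dtype=float)
    y_r = np.asarray(y_replication, dtype=float)
    n_main = len(candidates.mains)
    n_int = len(candidates.pairs)
    model = CpGModel(
        cpg_id=candidates.cpg_id, n_main_tested=n_main, n_int_tested=n_int
    )
    if n_main + n_int == 0:
        return model
    thr = alpha / (n_main + n_int)
    model.threshold = thr

    # marginal discovery p-values for ordering
    main_p = {}
    if candidates.mains:
        idx = [pos[s] for s in candidates.mains]
        res = main_effect_scan(genotypes_discovery[:, idx], y_d)
        for s, p in zip(candidates.mains, res["p"]):
            main_p[s] = float(p) if np.isfinite(p) else 1.0
    pair_p = {}
    pair_ok = {}
    for a, b in candidates.pairs:
        ok = True
        for geno, y in (
            (genotypes_discovery, y_d),
            (genotypes_replication, y_r),
        ):
            cells = cell_summaries(geno[:, pos[a]], geno[:, pos[b]], y)
            if not cells.all_cells_present or cells.min_cell <= min_cell:
                ok = False
        pair_ok[(a, b)] = ok
        if ok:
            try:
                _, p, _ = exact_interaction_anova(
                    genotypes_discovery[:, pos[a]], genotypes_discovery[:, pos[b]], y_d
                )
            except ValueError:
                p, ok = 1.0, False
                pair_ok[(a, b)] = False
        else:
            p = 1.0
        pair_p[(a, b)] = p

    X_d = [np.ones((y_d.size, 1))]
    X_r = [np.ones((y_r.size, 1))]
    order = 0
    for s in sorted(candidates.mains, key=lambda s: (main_p[s], s)):
        cols_d = _main_columns(_geno_col(genotypes_discovery, pos[s]))
        cols_r = _main_columns(_geno_col(genotypes_replication, pos[s]))
        _, p_d, q_d = _partial_f(np.hstack(X_d), cols_d, y_d)
        _, p_r, q_r = _partial_f(np.hstack(X_r), cols_r, y_r)
        if q_d == 0 or q_r == 0:
            continue  # collinear with the kept model
        if p_d < thr and p_r < thr:
            X_d.append(cols_d)
            X_r.append(cols_r)
            model.terms.append(
                ModelTerm(
                    kind="main",
                    snps=(s,),
                    df=q_d,
                    p_discovery=p_d,
                    p_replication=p_r,
                    entry_order=order,
                )
            )
            order += 1
    for a, b in sorted(candidates.pairs, key=lambda p: (pair_p[p], p)):
        if not pair_ok[(a, b)]:
            continue
        cols_d = _interaction_columns(
            _geno_col(genotypes_discovery, pos[a]), _geno_col(genotypes_discovery, pos[b])
        )
        cols_r = _interaction_columns(
            _geno_col(genotypes_replication, pos[a]),
            _geno_col(genotypes_replication, pos[b]),
        )
        _, p_d, q_d = _partial_f(np.hstack(X_d), cols_d, y_d)
        _, p_r, q_r = _partial_f(np.hstack(X_r), cols_r, y_r)
        if q_d == 0 or q_r == 0:
            continue
        if p_d < thr and p_r < thr:
            X_d.append(cols_d)
            X_r.append(cols_r)
            model.terms.append(
                ModelTerm(
                    kind="interaction",
                    snps=(a, b),
                    df=q_d,
                    p_discovery=p_d,
                    p_replication=p_r,
                    entry_order=order,
                )
            )
            order += 1
    return model


def classify_pairs(
    model: CpGModel,
    genotypes_discovery: np.ndarray,
    snp_ids,
    snp_map: pd.DataFrame,
    cpg_map: pd.DataFrame,
    ld_threshold: float,
    cis_window: int = CIS_WINDOW,
) -> CpGModel:
    """Label kept pairs LD-block vs. epistatic and cis/trans vs. the CpG."""
    pos = {s: i for i, s in enumerate(snp_ids)}
    chrom_c = cpg_map.loc[model.cpg_id, "chrom"]
    bp_c = int(cpg_map.loc[model.cpg_id, "bp"])

    def is_cis(s: str) -> bool:
        return (
            snp_map.loc[s, "chrom"] == chrom_c
            and abs(int(snp_map.loc[s, "bp"]) - bp_c) <= cis_window
        )

    for term in model.interaction_terms:
        a, b = term.snps
        try:
            r2 = genotype_r2(
                _geno_col(genotypes_discovery, pos[a]),
                _geno_col(genotypes_discovery, pos[b]),
            )
        except ValueError:
            r2 = float("nan")
        term.ld_r2 = r2
        term.ld_class = "ld_block" if r2 > ld_threshold else "epistatic"
        n_cis = int(is_cis(a)) + int(is_cis(b))
        term.cis_trans = ("both_trans", "one_cis", "both_cis")[n_cis]
    return model


def _model_r2(X: np.ndarray, y: np.ndarray) -> float:
    Q, _ = np.linalg.qr(np.column_stack([np.ones(y.size), X]) if X.ndim == 2 else X)
    resid = y - Q @ (Q.T @ y)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(resid @ resid) / ss_tot


def variance_decomposition(
    model: CpGModel,
    genotypes: np.ndarray,
    y: np.ndarray,
    snp_ids,
    cohort_label: str,
) -> dict[str, float]:
    """R^2 of the best single main, all mains, and the full kept model.

    Stored on ``model.r2_components[cohort_label]`` and returned.  The
    interaction contribution is the difference of the last two components.
    """
    pos = {s: i for i, s in enumerate(snp_ids)}
    y = np.asarray(y, dtype=float)
    mains = model.main_terms
    comp = {
        "most_significant_main": 0.0,
        "all_mains": 0.0,
        "all_mains_plus_interactions": 0.0,
    }
    main_cols = [
        _main_columns(_geno_col(genotypes, pos[t.snps[0]])) for t in mains
    ]
    if mains:
        best = min(mains, key=lambda t: t.p_discovery)
        comp["most_significant_main"] = _model_r2(
            _main_columns(_geno_col(genotypes, pos[best.snps[0]])), y
        )
        comp["all_mains"] = _model_r2(np.hstack(main_cols), y)
    int_cols = [
        _interaction_columns(
            _geno_col(genotypes, pos[t.snps[0]]), _geno_col(genotypes, pos[t.snps[1]])
        )
        for t in model.interaction_terms
    ]
    all_cols = main_cols + int_cols
    if all_cols:
        comp["all_mains_plus_interactions"] = _model_r2(np.hstack(all_cols), y)
    comp["interactions"] = comp["all_mains_plus_interactions"] - comp["all_mains"]
    model.r2_components[cohort_label] = comp
    return comp


# ---------------------------------------------------------------------------
# proximal (main-effect-first) search


def proximal_main_scan(
    cpg_id: str,
    genotypes_discovery: np.ndarray,
    y_discovery: np.ndarray,
    genotypes_replication: np.ndarray,
    y_replication: np.ndarray,
    snp_map: pd.DataFrame,
    cpg_map: pd.DataFrame,
    window_bp: float = 3.5e6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Replicated 2-df main effects of SNPs within a window around the CpG.

    Discovery: per-CpG Bonferroni over the number of window SNPs tested.
    Replication: kept SNPs re-tested, corrected for the number re-tested.
    """
    if window_bp <= 0:
        raise ValueError("window must be positive")
    chrom_c = cpg_map.loc[cpg_id, "chrom"]
    bp_c = int(cpg_map.loc[cpg_id, "bp"])
    in_win = (snp_map["chrom"] == chrom_c) & (abs(snp_map["bp"] - bp_c) <= window_bp)
    idx = np.nonzero(in_win.to_numpy())[0]
    if idx.size == 0:
        return pd.DataFrame(columns=["snp_id", "p_discovery", "p_replication"]).set_index("snp_id")
    res_d = main_effect_scan(genotypes_discovery[:, idx], y_discovery)
    testable = np.nan_to_num(res_d["p"].to_numpy(), nan=1.0)
    n_tested_d = int(np.isfinite(res_d["p"]).sum())
    if n_tested_d == 0:
        return pd.DataFrame(columns=["snp_id", "p_discovery", "p_replication"]).set_index("snp_id")
    keep1 = testable < alpha / n_tested_d
    idx_kept = idx[keep1]
    if idx_kept.size == 0:
        return pd.DataFrame(columns=["snp_id", "p_discovery", "p_replication"]).set_index("snp_id")
    res_r = main_effect_scan(genotypes_replication[:, idx_kept], y_replication)
    n_tested_r = int(np.isfinite(res_r["p"]).sum())
    p_r = np.nan_to_num(res_r["p"].to_numpy(), nan=1.0)
    keep2 = p_r < alpha / max(n_tested_r, 1)
    rows = pd.DataFrame(
        {
            "snp_id": snp_map.index[idx_kept][keep2],
            "p_discovery": testable[keep1][keep2],
            "p_replication": p_r[keep2],
        }
    ).set_index("snp_id")
    return rows


def proximal_interaction_scan(
    cpg_id: str,
    significant_mains: list[str],
    genotypes_discovery: np.ndarray,
    y_discovery: np.ndarray,
    genotypes_replication: np.ndarray,
    y_replication: np.ndarray,
    snp_ids,
    alpha: float = 0.05,
    min_cell: int = 3,
) -> list[tuple[str, str]]:
    """Interactions among a CpG's significant main-effect SNPs, both cohorts.

    Requires at least two significant mains; all pairs are tested by the
    exact interaction ANOVA with minimum cell occupancy > ``min_cell`` in
    both cohorts and a per-CpG Bonferroni over the pairs tested, applied in
    both cohorts.
    """
    if len(significant_mains) < 2:
        return []
    pos = {s: i for i, s in enumerate(snp_ids)}
    pairs = list(itertools.combinations(sorted(significant_mains), 2))
    results = []
    n_tested = 0
    for a, b in pairs:
        ok = True
        ps = []
        for geno, y in (
            (genotypes_discovery, y_discovery),
            (genotypes_replication, y_replication),
        ):
            try:
                cells = cell_summaries(geno[:, pos[a]], geno[:, pos[b]], y)
            except ValueError:
                ok = False
                break
            if not cells.all_cells_present or cells.min_cell <= min_cell:
                ok = False
                break
            _, p, _ = exact_interaction_anova(geno[:, pos[a]], geno[:, pos[b]], y)
            ps.append(p)
        if not ok:
            continue
        n_tested += 1
        results.append(((a, b), ps))
    if n_tested == 0:
        return []
    thr = alpha / n_tested
    return [pair for pair, ps in results if all(p < thr for p in ps)]
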