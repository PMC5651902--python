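"""Annotation and expression enrichment of interaction-bearing CpGs.

Hit CpGs are first collapsed into clusters of correlated probes (single
linkage at Pearson r > 0.8, connected components) and one representative per
cluster enters the enrichment tests, so locally redundant CpGs do not count
repeatedly.  Enrichment against genomic feature sets (CpG islands, TFBS,
DNase I hypersensitivity sites, expression association) is a plain 2x2
Pearson chi-square of representative CpGs versus all remaining CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "CpGCluster",
    "EnrichmentRow",
    "cluster_cpgs",
    "read_bed",
    "annotate_cpgs",
    "chi2_enrichment",
    "expression_association",
]


@dataclass
class CpGCluster:
    members: list[str]
    representative: str
    max_pairwise_bp: int | None  # same-chromosome span; None if multi-chrom


@dataclass
class EnrichmentRow:
    feature: str
    expected_pct: float
    observed_pct: float
    chi2: float
    p: float
    low_expected: bool = False


def cluster_cpgs(
    methylation: np.ndarray,
    cpg_ids: list[str],
    cpg_map: pd.DataFrame | None = None,
    r_threshold: float = 0.8,
    seed: int = 0,
) -> list[CpGCluster]:
    """Single-linkage clusters of CpGs with pairwise Pearson r > threshold.

    ``methylation`` is (samples x hit CpGs), columns aligned with
    ``cpg_ids``.  One representative is drawn uniformly per cluster.
    """
    if len(cpg_ids) == 0:
        raise ValueError("need at least one CpG")
    rng = np.random.default_rng(seed)
    X = np.asarray(methylation, dtype=float)
    mu = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mu, idx[1])
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(X.T)
    R = np.atleast_2d(np.nan_to_num(R))
    adj = csr_matrix(R > r_threshold)
    n_comp, labels = connected_components(adj, directed=False)
    clusters = []
    for k in range(n_comp):
        members = [cpg_ids[i] for i in np.nonzero(labels == k)[0]]
        rep = members[int(rng.integers(len(members)))]
        span = None
        if cpg_map is not None:
            sub = cpg_map.loc[members]
            if sub["chrom"].nunique() == 1:
                span = int(sub["bp"].max() - sub["bp"].min())
        clusters.append(CpGCluster(members=members, representative=rep, max_pairwise_bp=span))
    return clusters


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader: chrom, start, end (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"],
        comment="#",
    )
    return df


def annotate_cpgs(
    cpg_map: pd.DataFrame, interval_sets: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Membership flags per CpG per named feature set.

    CpG positions in the map are 1-based; intervals are 0-based half-open
    ``[start, end)``, so a CpG at map position p occupies 0-based coordinate
    p - 1.  Unknown chromosomes yield False with a warning.
    """
    import warnings

    flags = pd.DataFrame(index=cpg_map.index)
    for name, bed in interval_sets.items():
        col = np.zeros(len(cpg_map), dtype=bool)
        by_chrom = {c: g for c, g in bed.groupby("chrom")}
        known = set(by_chrom)
        missing_chroms = set(cpg_map["chrom"]) - known
        if missing_chroms and len(bed):
            warnings.warn(
                f"feature {name!r}: no intervals on {sorted(missing_chroms)}"
            )
        for chrom, grp in by_chrom.items():
            rows = np.nonzero((cpg_map["chrom"] == chrom).to_numpy())[0]
            if rows.size == 0:
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            pos0 = cpg_map["bp"].to_numpy()[rows] - 1  # 1-based map -> 0-based
            j = np.searchsorted(starts, pos0, side="right")
            hit = np.zeros(rows.size, dtype=bool)
            # scan backwards over candidate intervals (handles overlaps)
            for k, (p, jj) in enumerate(zip(pos0, j)):
                t = jj - 1
                while t >= 0 and not hit[k]:
                    if ends[t] > p:
                        hit[k] = True
                    t -= 1
            col[rows] = hit
        flags[name] = col
    return flags


def chi2_enrichment(hit_flags, background_flags, feature: str = "") -> EnrichmentRow:
    """2x2 Pearson chi-square (no continuity correction) of feature membership."""
    h = np.asarray(hit_flags, dtype=bool)
    b = np.asarray(background_flags, dtype=bool)
    if h.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    table = np.array(
        [[h.sum(), h.size - h.sum()], [b.sum(), b.size - b.sum()]], dtype=float
    )
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    low = bool((expected < 1).any())
    if (expected == 0).any():
        chi2, p = 0.0, 1.0
    else:
        chi2 = float(((table - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(chi2, 1))
    return EnrichmentRow(
        feature=feature,
        expected_pct=100.0 * b.mean(),
        observed_pct=100.0 * h.mean(),
        chi2=chi2,
        p=min(max(p, 0.0), 1.0) if p > 0 else 5e-324,
        low_expected=low,
    )


def expression_association(
    methylation: np.ndarray,
    expression: np.ndarray,
    cpg_map: pd.DataFrame,
    transcript_map: pd.DataFrame,
    alpha: float = 0.05,
    cis_window: int = 500_000,
    n_cpgs_total: int | None = None,
) -> pd.DataFrame:
    """Per-CpG expression-association flags (genome-wide and cis Bonferroni).

    Pearson correlation p-values per CpG-transcript pair; genome-wide
    significance at ``alpha / (n_cpgs_total * n_transcripts)``, cis
    significance at ``alpha / n_local_transcripts`` for transcripts within
    ``cis_window`` of the CpG.  A CpG counts as associated if either
    criterion fires for any transcript; the top transcript is the smallest p.
    """
    M = np.asarray(methylation, dtype=float)
    E = np.asarray(expression, dtype=float)
    if M.shape[0] != E.shape[0]:
        raise ValueError("methylation and expression must share samples")
    n = M.shape[0]
    n_cpgs = M.shape[1]
    n_tx = E.shape[1]
    if n_cpgs_total is None:
        n_cpgs_total = n_cpgs
    Ms = (M - M.mean(axis=0)) / M.std(axis=0)
    sd = E.std(axis=0)
    constant = sd == 0
    sd[constant] = 1.0
    Es = (E - E.mean(axis=0)) / sd
    R = (Ms.T @ Es) / n  # (n_cpgs, n_tx)
    R = np.clip(R, -0.999999999, 0.999999999)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / (1 - R * R))
    P = 2.0 * stats.t.sf(np.abs(t), n - 2)
    P[:, constant] = 1.0
    gw_thr = alpha / (n_cpgs_total * n_tx)
    tx_chrom = transcript_map["chrom"].to_numpy()
    tx_bp = transcript_map["bp"].to_numpy()
    rows = []
    for i, cpg in enumerate(cpg_map.index):
        local = (tx_chrom == cpg_map.loc[cpg, "chrom"]) & (
            np.abs(tx_bp - int(cpg_map.loc[cpg, "bp"])) <= cis_window
        )
        n_local = int(local.sum())
        gw_sig = bool((P[i] < gw_thr).any())
        cis_sig = bool(n_local > 0 and (P[i, local] < alpha / n_local).any())
        top = int(np.argmin(P[i]))
        rows.append(
            {
                "cpg_id": cpg,
                "genomewide_significant": gw_sig,
                "cis_significant": cis_sig,
                "associated": gw_sig or cis_sig,
                "top_transcript": transcript_map.index[top],
                "top_p": float(P[i, top]),
                "n_local_transcripts": n_local,
            }
        )
    return pd.DataFrame(rows).set_index("cpg_id")
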