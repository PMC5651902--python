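"""End-to-end orchestration: preprocess -> QC -> scan -> replicate -> model.

Thin glue over the stage modules so the whole discovery/replication chain
can be run on a cohort pair with one call; each stage remains usable on its
own.  Returns every intermediate artifact for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model as model_mod
from .ld import empirical_ld_threshold
from .preprocess import PreprocessConfig, filter_cpgs, preprocess_cohort
from .qc import QCThresholds, filter_snps, ld_prune
from .replication import ReplicationConfig, replicate_hits
from .scan import bonferroni_matched_f_filter, count_exhaustive_tests, exhaustive_scan
from .simulate import Cohort

__all__ = ["ChainConfig", "ChainResult", "run_chain"]


def _panel_scale_preprocess() -> PreprocessConfig:
    # PC removal targets array-scale technical axes; on a small synthetic CpG
    # panel the top PCs align with individual probes and would strip the very
    # signals under study, so the chain default regresses none.
    return PreprocessConfig(n_pcs_discovery=0, n_pcs_replication=0)


@dataclass
class ChainConfig:
    qc: QCThresholds = field(default_factory=QCThresholds)
    preprocess: PreprocessConfig = field(default_factory=_panel_scale_preprocess)
    replication: ReplicationConfig = field(default_factory=ReplicationConfig)
    f_filter: float | None = None  # None -> Bonferroni-matched at this scale
    alpha: float = 0.05
    ld_threshold: float | None = None  # None -> calibrate empirically
    ld_quantile: float = 0.999
    ld_n_pairs: int = 2_000
    prune: bool = True
    model_alpha: float = 0.05
    seed: int = 0


@dataclass
class ChainResult:
    cpg_ids: list[str]
    scan_snp_ids: list[str]
    modeling_snp_ids: list[str]
    M_discovery: np.ndarray
    M_replication: np.ndarray
    ld_threshold: float
    hits: list
    verdicts: list
    surviving: list
    models: dict


def run_chain(
    discovery: Cohort, replication: Cohort, config: ChainConfig | None = None
) -> ChainResult:
    """Run the full exhaustive-search pipeline on a cohort pair."""
    cfg = config or ChainConfig()

    cpg_ids = filter_cpgs(discovery, replication, cfg.preprocess)
    M_d, _ = preprocess_cohort(discovery, cfg.preprocess, cpg_ids)
    M_r, _ = preprocess_cohort(replication, cfg.preprocess, cpg_ids)

    scan_set = filter_snps(discovery, replication, cfg.qc, "scan")
    kept = scan_set.kept
    if cfg.prune and len(kept) >= 2:
        cols = [discovery.snp_index(s) for s in kept]
        sub_map = discovery.snp_map.loc[kept]
        pruned = ld_prune(discovery.genotypes[:, cols], sub_map, cfg.qc)
        kept = pruned.kept
    modeling_set = filter_snps(discovery, replication, cfg.qc, "modeling")

    scan_cols = [discovery.snp_index(s) for s in kept]
    geno_d = discovery.genotypes[:, scan_cols]
    geno_r = replication.genotypes[:, scan_cols]

    if cfg.ld_threshold is None:
        if discovery.snp_map["chrom"].nunique() >= 2:
            ld_thr = empirical_ld_threshold(
                discovery.genotypes.astype(float),
                discovery.snp_map,
                n_pairs=cfg.ld_n_pairs,
                quantile=cfg.ld_quantile,
                seed=cfg.seed,
            ).threshold_r2
        else:
            ld_thr = 0.021
    else:
        ld_thr = cfg.ld_threshold

    f_filter = cfg.f_filter
    if f_filter is None:
        n_tests = count_exhaustive_tests(len(cpg_ids), len(kept))
        f_filter = bonferroni_matched_f_filter(
            cfg.alpha, max(n_tests, 1), discovery.n_samples
        )
    hits = exhaustive_scan(
        geno_d,
        M_d,
        kept,
        cpg_ids,
        f_filter=f_filter,
        alpha=cfg.alpha,
        genotypes_replication=geno_r,
    )
    verdicts = replicate_hits(
        hits, geno_d, M_d, geno_r, M_r, kept, cpg_ids, cfg.replication
    )
    surviving = [v for v in verdicts if v.pass_all]

    mod_cols = [discovery.snp_index(s) for s in modeling_set.kept]
    geno_dm = discovery.genotypes[:, mod_cols]
    geno_rm = replication.genotypes[:, mod_cols]
    mod_map = discovery.snp_map.loc[modeling_set.kept]
    models = {}
    by_cpg: dict[str, list[tuple[str, str]]] = {}
    for v in surviving:
        by_cpg.setdefault(v.hit.cpg_id, []).append((v.hit.snp_a, v.hit.snp_b))
    cpg_pos = {c: j for j, c in enumerate(cpg_ids)}
    for cpg, pairs in by_cpg.items():
        pairs = [p for p in pairs if p[0] in mod_map.index and p[1] in mod_map.index]
        if not pairs:
            continue
        j = cpg_pos[cpg]
        cand = model_mod.assemble_candidates(
            cpg,
            pairs,
            mod_map,
            discovery.cpg_map,
            geno_dm,
            M_d[:, j],
            ld_thr,
        )
        m = model_mod.forward_select(
            cand, geno_dm, M_d[:, j], geno_rm, M_r[:, j],
            modeling_set.kept, alpha=cfg.model_alpha,
        )
        model_mod.classify_pairs(
            m, geno_dm, modeling_set.kept, mod_map, discovery.cpg_map, ld_thr
        )
        model_mod.variance_decomposition(
            m, geno_dm, M_d[:, j], modeling_set.kept, "discovery"
        )
        model_mod.variance_decomposition(
            m, geno_rm, M_r[:, j], modeling_set.kept, "replication"
        )
        models[cpg] = m
    return ChainResult(
        cpg_ids=cpg_ids,
        scan_snp_ids=kept,
        modeling_snp_ids=modeling_set.kept,
        M_discovery=M_d,
        M_replication=M_r,
        ld_threshold=ld_thr,
        hits=hits,
        verdicts=verdicts,
        surviving=surviving,
        models=models,
    )
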