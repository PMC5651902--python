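"""Per-CpG joint modelling: candidate assembly, forward selection, LD-aware
classification, variance decomposition, and the proximal search."""

import numpy as np
import pandas as pd
import pytest

import epimeth as em
from epimeth.model import (
    CandidateSet,
    assemble_candidates,
    classify_pairs,
    forward_select,
    main_effect_scan,
    proximal_interaction_scan,
    proximal_main_scan,
    variance_decomposition,
)
from epimeth.preprocess import PreprocessConfig, preprocess_cohort

PC0 = PreprocessConfig(n_pcs_discovery=0, n_pcs_replication=0)


def _adjusted(cohort):
    M, _ = preprocess_cohort(cohort, PC0)
    return M


class TestMainEffectScan:
    def test_matches_scipy_oneway_anova(self, rng):
        from scipy import stats

        geno = rng.binomial(2, 0.4, (200, 5)).astype(np.int8)
        y = rng.standard_normal(200) + geno[:, 2] * 0.4
        res = main_effect_scan(geno, y)
        for j in range(5):
            groups = [y[geno[:, j] == g] for g in range(3) if (geno[:, j] == g).any()]
            F, p = stats.f_oneway(*groups)
            assert res["F"].iloc[j] == pytest.approx(F, rel=1e-10)
            assert res["p"].iloc[j] == pytest.approx(p, rel=1e-8)

    def test_missing_genotypes_dropped_per_snp(self, rng):
        geno = rng.binomial(2, 0.4, (100, 1)).astype(np.int8)
        geno[:10, 0] = -1
        y = rng.standard_normal(100)
        res = main_effect_scan(geno, y)
        assert res["n"].iloc[0] == 90


class TestForwardSelect:
    def test_no_candidates_gives_intercept_only(self, small_pair):
        disc, rep, _ = small_pair
        M_d, M_r = _adjusted(disc), _adjusted(rep)
        model = forward_select(
            CandidateSet("cg00003", [], []),
            disc.genotypes, M_d[:, 3], rep.genotypes, M_r[:, 3], disc.snp_ids,
        )
        assert model.terms == []

    def test_planted_main_and_interaction_recovered(self, small_pair):
        disc, rep, truth = small_pair
        M_d, M_r = _adjusted(disc), _adjusted(rep)
        j = disc.cpg_index("cg00001")
        cand = CandidateSet(
            "cg00001",
            mains=["snp00010", "snp00050", "snp00020"],
            pairs=[("snp00010", "snp00050"), ("snp00020", "snp00060")],
        )
        model = forward_select(
            cand, disc.genotypes, M_d[:, j], rep.genotypes, M_r[:, j], disc.snp_ids
        )
        kept_pairs = [t.snps for t in model.interaction_terms]
        assert ("snp00010", "snp00050") in kept_pairs
        assert ("snp00020", "snp00060") not in kept_pairs
        assert model.main_terms == []  # interaction-only planted signal

    def test_null_candidates_rarely_kept(self):
        """Dual-cohort thresholding controls false inclusion on null data."""
        kept = 0
        for s in range(40):
            cfg = em.SimulationConfig(n_snps=30, n_cpgs=2, seed=700 + s)
            disc, rep, _ = em.simulate_cohort_pair(cfg)
            M_d, M_r = _adjusted(disc), _adjusted(rep)
            cand = CandidateSet(
                "cg00000", mains=disc.snp_ids[:10],
                pairs=[(disc.snp_ids[0], disc.snp_ids[5])],
            )
            model = forward_select(
                cand, disc.genotypes, M_d[:, 0], rep.genotypes, M_r[:, 0],
                disc.snp_ids,
            )
            kept += bool(model.terms)
        assert kept <= 2

    def test_triad_interaction_rejected_once_main_is_modelled(self, triad):
        disc, rep, _ = triad
        M_d, M_r = _adjusted(disc), _adjusted(rep)
        model = forward_select(
            CandidateSet("cg_triad", ["snp_A", "snp_C", "snp_B"], [("snp_A", "snp_B")]),
            disc.genotypes, M_d[:, 0], rep.genotypes, M_r[:, 0], disc.snp_ids,
        )
        assert any(t.snps == ("snp_C",) for t in model.main_terms)
        assert model.interaction_terms == []


class TestAssembleCandidates:
    def test_isolated_hit_snps_give_hit_pairs_only(self, small_pair):
        disc, _, _ = small_pair
        M_d = _adjusted(disc)
        j = disc.cpg_index("cg00001")
        cand = assemble_candidates(
            "cg00001", [("snp00010", "snp00050")],
            disc.snp_map, disc.cpg_map, disc.genotypes, M_d[:, j],
            ld_threshold=0.021,
        )
        assert ("snp00010", "snp00050") in cand.pairs
        # pairs only among LD partners of the two hit SNPs
        partners = {s for p in cand.pairs for s in p}
        assert partners  # non-empty, includes the hit SNPs
        assert {"snp00010", "snp00050"} <= partners

    def test_triad_window_includes_partner_main(self, triad):
        disc, _, _ = triad
        M_d = _adjusted(disc)
        cand = assemble_candidates(
            "cg_triad", [("snp_A", "snp_B")],
            disc.snp_map, disc.cpg_map, disc.genotypes, M_d[:, 0],
            ld_threshold=0.021,
        )
        assert "snp_C" in cand.mains  # within 500 KB of the CpG and the hits
        # C is in LD with both hit SNPs, so C-pairs enter the candidate pairs
        assert ("snp_A", "snp_C") in cand.pairs or ("snp_C", "snp_B") in cand.pairs

    def test_requires_a_hit(self, small_pair):
        disc, _, _ = small_pair
        with pytest.raises(ValueError):
            assemble_candidates(
                "cg00001", [], disc.snp_map, disc.cpg_map,
                disc.genotypes, np.zeros(disc.n_samples), 0.021,
            )


class TestClassifyPairs:
    def _model_with_pair(self, a, b):
        from epimeth.model import CpGModel, ModelTerm

        m = CpGModel(cpg_id="cg_triad")
        m.terms.append(
            ModelTerm(
                kind="interaction", snps=(a, b), df=4,
                p_discovery=1e-9, p_replication=1e-7, entry_order=0,
            )
        )
        return m

    def test_high_ld_pair_is_ld_block(self, triad):
        disc, _, _ = triad
        m = self._model_with_pair("snp_A", "snp_C")
        classify_pairs(m, disc.genotypes, disc.snp_ids, disc.snp_map,
                       disc.cpg_map, ld_threshold=0.021)
        t = m.interaction_terms[0]
        assert t.ld_class == "ld_block" and t.ld_r2 > 0.021
        assert t.cis_trans == "both_cis"

    def test_threshold_boundary_is_strict(self, triad):
        disc, _, _ = triad
        m = self._model_with_pair("snp_A", "snp_B")
        from epimeth.ld import genotype_r2

        r2 = genotype_r2(
            disc.genotypes[:, 0].astype(float), disc.genotypes[:, 2].astype(float)
        )
        classify_pairs(m, disc.genotypes, disc.snp_ids, disc.snp_map,
                       disc.cpg_map, ld_threshold=r2)
        assert m.interaction_terms[0].ld_class == "epistatic"


class TestVarianceDecomposition:
    def test_components_are_nested_and_recover_truth(self, small_pair):
        disc, rep, truth = small_pair
        M_d, M_r = _adjusted(disc), _adjusted(rep)
        j = disc.cpg_index("cg00001")
        cand = CandidateSet("cg00001", ["snp00010", "snp00050"],
                            [("snp00010", "snp00050")])
        model = forward_select(
            cand, disc.genotypes, M_d[:, j], rep.genotypes, M_r[:, j], disc.snp_ids
        )
        comp = variance_decomposition(
            model, disc.genotypes, M_d[:, j], disc.snp_ids, "discovery"
        )
        assert comp["most_significant_main"] <= comp["all_mains"] + 1e-12
        assert comp["all_mains"] <= comp["all_mains_plus_interactions"] + 1e-12
        planted = truth.realized_r2[0]
        assert comp["interactions"] == pytest.approx(planted, abs=0.05)

    def test_no_interactions_means_zero_contribution(self, small_pair):
        disc, rep, _ = small_pair
        M_d, M_r = _adjusted(disc), _adjusted(rep)
        j = disc.cpg_index("cg00002")  # planted main effect only
        cand = CandidateSet("cg00002", ["snp00030"], [])
        model = forward_select(
            cand, disc.genotypes, M_d[:, j], rep.genotypes, M_r[:, j], disc.snp_ids
        )
        comp = variance_decomposition(
            model, disc.genotypes, M_d[:, j], disc.snp_ids, "discovery"
        )
        assert comp["interactions"] == pytest.approx(0.0, abs=1e-12)
        assert comp["all_mains"] > 0.2  # planted target 0.3


class TestProximalSearch:
    def test_single_snp_window_uses_nominal_alpha(self, rng):
        geno_d = rng.binomial(2, 0.4, (400, 1)).astype(np.int8)
        geno_r = rng.binomial(2, 0.4, (300, 1)).astype(np.int8)
        y_d = rng.standard_normal(400) + geno_d[:, 0] * 0.25
        y_r = rng.standard_normal(300) + geno_r[:, 0] * 0.25
        snp_map = pd.DataFrame({"chrom": ["chr1"], "bp": [1000]}, index=["s0"])
        cpg_map = pd.DataFrame({"chrom": ["chr1"], "bp": [2000]}, index=["cg0"])
        res = proximal_main_scan(
            "cg0", geno_d, y_d, geno_r, y_r, snp_map, cpg_map
        )
        assert list(res.index) == ["s0"]

    def test_planted_cis_main_detected_and_replicated(self, small_pair):
        disc, rep, _ = small_pair
        M_d, M_r = _adjusted(disc), _adjusted(rep)
        j = disc.cpg_index("cg00002")
        res = proximal_main_scan(
            "cg00002", disc.genotypes, M_d[:, j], rep.genotypes, M_r[:, j],
            disc.snp_map, disc.cpg_map,
        )
        assert "snp00030" in res.index

    def test_null_window_rarely_yields_survivors(self):
        survivors = 0
        for s in range(30):
            cfg = em.SimulationConfig(n_snps=50, n_cpgs=2, seed=900 + s)
            disc, rep, _ = em.simulate_cohort_pair(cfg)
            M_d, M_r = _adjusted(disc), _adjusted(rep)
            res = proximal_main_scan(
                disc.cpg_ids[0], disc.genotypes, M_d[:, 0],
                rep.genotypes, M_r[:, 0], disc.snp_map, disc.cpg_map,
            )
            survivors += len(res)
        assert survivors <= 3  # ~ alpha-level false positives after 2 stages

    def test_fewer_than_two_mains_gives_no_pairs(self, small_pair):
        disc, rep, _ = small_pair
        M_d, M_r = _adjusted(disc), _adjusted(rep)
        assert proximal_interaction_scan(
            "cg00002", ["snp00030"], disc.genotypes, M_d[:, 0],
            rep.genotypes, M_r[:, 0], disc.snp_ids,
        ) == []

    def test_planted_interaction_between_mains_recovered(self):
        cfg = em.SimulationConfig(n_snps=40, n_cpgs=3, seed=31, block_rho=0.0,
                                  maf_range=(0.3, 0.5))
        effects = [
            em.PlantedEffect("cg00000", "main_additive", ("snp00005",), 0.2),
            em.PlantedEffect("cg00000", "main_additive", ("snp00020",), 0.2),
            em.PlantedEffect("cg00000", "epistatic", ("snp00005", "snp00020"), 0.12),
        ]
        disc, rep, _ = em.simulate_cohort_pair(cfg, effects)
        M_d, M_r = _adjusted(disc), _adjusted(rep)
        pairs = proximal_interaction_scan(
            "cg00000", ["snp00005", "snp00020"], disc.genotypes, M_d[:, 0],
            rep.genotypes, M_r[:, 0], disc.snp_ids,
        )
        assert ("snp00005", "snp00020") in pairs

    def test_independent_mains_yield_no_interaction(self):
        hits = 0
        for s in range(20):
            cfg = em.SimulationConfig(n_snps=40, n_cpgs=2, seed=950 + s,
                                      block_rho=0.0, maf_range=(0.3, 0.5))
            effects = [
                em.PlantedEffect("cg00000", "main_additive", ("snp00005",), 0.2),
                em.PlantedEffect("cg00000", "main_additive", ("snp00020",), 0.2),
            ]
            disc, rep, _ = em.simulate_cohort_pair(cfg, effects)
            M_d, M_r = _adjusted(disc), _adjusted(rep)
            pairs = proximal_interaction_scan(
                "cg00000", ["snp00005", "snp00020"], disc.genotypes, M_d[:, 0],
                rep.genotypes, M_r[:, 0], disc.snp_ids,
            )
            hits += len(pairs)
        assert hits <= 1
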