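"""Two-locus scan statistics: cell summaries, approximate and exact tests."""

import numpy as np
import pytest
from scipy import stats

from epimeth.scan import (
    approx_two_locus_test,
    bonferroni_threshold,
    cell_summaries,
    count_exhaustive_tests,
    exact_interaction_anova,
    exhaustive_scan,
    interaction_power,
    scan_statistics_block,
)


def _balanced_design(per_cell=10):
    ga = np.repeat([0, 1, 2], 3 * per_cell)
    gb = np.tile(np.repeat([0, 1, 2], per_cell), 3)
    return ga, gb


class TestCellSummaries:
    def test_constant_response_has_zero_within_ss(self):
        ga, gb = _balanced_design(2)
        cells = cell_summaries(ga, gb, np.ones(ga.size))
        assert cells.ss_within == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(cells.means, 1.0)

    def test_means_match_direct_averaging(self):
        ga, gb = _balanced_design(2)
        y = np.arange(ga.size, dtype=float)
        cells = cell_summaries(ga, gb, y)
        for i in range(3):
            for j in range(3):
                direct = y[(ga == i) & (gb == j)].mean()
                assert cells.means[i, j] == pytest.approx(direct)
        assert cells.counts.sum() == ga.size

    def test_anova_identity_within_plus_between_is_total(self, rng):
        ga = rng.integers(0, 3, 200)
        gb = rng.integers(0, 3, 200)
        y = rng.standard_normal(200)
        cells = cell_summaries(ga, gb, y)
        occ = cells.counts > 0
        between = (cells.counts[occ] * (cells.means[occ] - cells.grand_mean) ** 2).sum()
        total = ((y - y.mean()) ** 2).sum()
        assert cells.ss_within + between == pytest.approx(total, abs=1e-9)

    def test_listwise_deletion_of_missing(self):
        ga = np.array([0, 1, 2, -1, 0, 1, 2, 0, 1, 2, 0, 1])
        gb = np.array([0, 1, 2, 0, -1, 1, 2, 0, 1, 2, 0, 1])
        y = np.arange(12.0)
        cells = cell_summaries(ga, gb, y)
        assert cells.n_total == 10

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="complete observations"):
            cell_summaries([0, 1, 2], [0, 1, 2], [1.0, 2.0, 3.0])


class TestApproxTest:
    def test_zero_margin_pattern_fully_interaction(self):
        """A cell-mean table with zero marginal means leaves the whole signal
        to the interaction term: predictions vanish and the numerator SS is
        the count-weighted sum of squared cell means."""
        ga, gb = _balanced_design(4)
        pattern = np.array([[1.0, -1.0, 0.0], [-1.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
        y = pattern[ga, gb] + 0.0
        # add within-cell noise with zero cell-mean distortion
        noise = np.tile([0.5, -0.5], ga.size // 2)
        y = y + noise
        cells = cell_summaries(ga, gb, y)
        F8, F4 = approx_two_locus_test(cells)
        counts = cells.counts
        expected_ss = (counts * pattern**2).sum()
        mse = cells.ss_within / (ga.size - 9)
        assert F4 * 4 * mse == pytest.approx(expected_ss, rel=1e-9)

    def test_equals_exact_on_balanced_orthogonal_design(self, rng):
        ga, gb = _balanced_design(6)
        y = rng.standard_normal(ga.size)
        _, F4 = approx_two_locus_test(cell_summaries(ga, gb, y))
        F_exact, _, _ = exact_interaction_anova(ga, gb, y)
        assert F4 == pytest.approx(F_exact, abs=1e-8)

    def test_overestimates_under_correlated_snps_with_additive_truth(self):
        """With LD between the SNPs and a purely additive signal, the
        marginal-subtraction approximation leaves main-effect remnants in the
        interaction numerator, so it exceeds the exact statistic in almost
        all replicates."""
        wins = total = 0
        for rep in range(200):
            r = np.random.default_rng(rep)
            h1 = r.random(400) < 0.3
            ga = h1.astype(int) + (r.random(400) < 0.3).astype(int)
            hb = np.where(h1, r.random(400) < 0.5, r.random(400) < 0.2)
            gb = hb.astype(int) + (r.random(400) < 0.25).astype(int)
            y = ga + gb + r.standard_normal(400)
            cells = cell_summaries(ga, gb, y)
            if not cells.all_cells_present:
                continue
            _, F4 = approx_two_locus_test(cells)
            F_exact, _, _ = exact_interaction_anova(ga, gb, y)
            total += 1
            wins += F4 >= F_exact
        assert total > 150
        assert wins / total > 0.95

    def test_joint_ss_bounds_interaction_ss(self, rng):
        ga = rng.integers(0, 3, 300)
        gb = rng.integers(0, 3, 300)
        y = rng.standard_normal(300) + 0.3 * ga
        cells = cell_summaries(ga, gb, y)
        F8, F4 = approx_two_locus_test(cells)
        assert F8 * 8 >= F4 * 4 - 1e-9


class TestExactTest:
    def test_saturated_interpolation_gives_minimal_p(self):
        ga, gb = _balanced_design(2)
        pattern = np.array([[1.0, -1.0, 0.0], [-1.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
        y = pattern[ga, gb]
        F, p, df = exact_interaction_anova(ga, gb, y)
        assert np.isinf(F) and p <= 5e-324

    def test_matches_two_model_ols_oracle(self, rng):
        """Independent oracle: explicit OLS of main-effects vs cell-means
        design matrices, F from the two RSS values."""
        n = 90
        ga = rng.integers(0, 3, n)
        gb = rng.integers(0, 3, n)
        if not (np.bincount(ga * 3 + gb, minlength=9) > 0).all():
            pytest.skip("unlucky draw left a cell empty")
        y = rng.standard_normal(n) + 0.5 * ga - 0.2 * gb
        X_main = np.column_stack(
            [np.ones(n), ga == 1, ga == 2, gb == 1, gb == 2]
        ).astype(float)
        X_sat = np.zeros((n, 9))
        X_sat[np.arange(n), ga * 3 + gb] = 1.0
        rss = []
        for X in (X_main, X_sat):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            rss.append(r @ r)
        F_oracle = (rss[0] - rss[1]) / 4 / (rss[1] / (n - 9))
        F, p, df = exact_interaction_anova(ga, gb, y)
        assert F == pytest.approx(F_oracle, abs=1e-8)
        assert df == (4, n - 9)

    def test_null_p_values_are_uniform(self):
        ps = []
        for rep in range(400):
            r = np.random.default_rng(1000 + rep)
            ga = r.integers(0, 3, 180)
            gb = r.integers(0, 3, 180)
            y = ga + gb + r.standard_normal(180) * 2  # additive truth
            try:
                _, p, _ = exact_interaction_anova(ga, gb, y)
            except ValueError:
                continue
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_missing_cell_is_an_error(self):
        ga = np.repeat([0, 1], 20)
        gb = np.tile([0, 1], 20)
        with pytest.raises(ValueError, match="cells"):
            exact_interaction_anova(ga, gb, np.random.default_rng(0).standard_normal(40))


class TestExhaustiveScan:
    def test_vectorised_block_matches_per_pair_loop(self, rng):
        geno = rng.integers(0, 3, (150, 6)).astype(np.int8)
        geno[rng.random((150, 6)) < 0.02] = -1
        Y = rng.standard_normal((150, 3))
        blk = scan_statistics_block(geno, Y, 0, np.arange(1, 6))
        for bi, b in enumerate(range(1, 6)):
            for c in range(3):
                cells = cell_summaries(geno[:, 0], geno[:, b], Y[:, c])
                F8, F4 = approx_two_locus_test(cells)
                assert blk["F4"][bi, c] == pytest.approx(F4, abs=1e-10)
                assert blk["F8"][bi, c] == pytest.approx(F8, abs=1e-10)
                assert blk["min_cell"][bi] == cells.min_cell or c > 0

    def test_infinite_filter_returns_no_hits(self, rng):
        geno = rng.integers(0, 3, (100, 8)).astype(np.int8)
        Y = rng.standard_normal((100, 2))
        hits = exhaustive_scan(
            geno, Y, [f"s{i}" for i in range(8)], ["c0", "c1"], f_filter=np.inf
        )
        assert hits == []

    def test_planted_interaction_is_recovered(self, small_pair):
        disc, rep, truth = small_pair
        from epimeth.preprocess import PreprocessConfig, preprocess_cohort

        pc = PreprocessConfig(n_pcs_discovery=0, n_pcs_replication=0)
        M, _ = preprocess_cohort(disc, pc)
        from epimeth.scan import bonferroni_matched_f_filter, count_exhaustive_tests

        f_filter = bonferroni_matched_f_filter(
            0.05,
            count_exhaustive_tests(len(disc.cpg_ids), len(disc.snp_ids)),
            disc.n_samples,
        )
        hits = exhaustive_scan(
            disc.genotypes, M, disc.snp_ids, disc.cpg_ids,
            f_filter=f_filter,
            genotypes_replication=rep.genotypes,
        )
        assert any(
            h.cpg_id == "cg00001" and {h.snp_a, h.snp_b} == {"snp00010", "snp00050"}
            for h in hits
        )

    def test_hit_order_independent_of_snp_enumeration(self, rng):
        geno = rng.integers(0, 3, (200, 10)).astype(np.int8)
        y = (geno[:, 2] == 1) * (geno[:, 7] == 1) * 3.0 + rng.standard_normal(200)
        Y = y[:, None]
        ids = [f"s{i}" for i in range(10)]
        hits = exhaustive_scan(geno, Y, ids, ["c0"], f_filter=5, alpha=0.9)
        perm = rng.permutation(10)
        hits_p = exhaustive_scan(
            geno[:, perm], Y, [ids[i] for i in perm], ["c0"], f_filter=5, alpha=0.9
        )
        key = lambda h: (h.cpg_id, tuple(sorted((h.snp_a, h.snp_b))))
        assert sorted(map(key, hits)) == sorted(map(key, hits_p))


class TestCounting:
    @pytest.mark.parametrize(
        "n_cpgs,n_snps,expected",
        [(1, 3, 3), (2, 2, 2), (5, 1, 0), (3, 0, 0)],
    )
    def test_small_counts(self, n_cpgs, n_snps, expected):
        assert count_exhaustive_tests(n_cpgs, n_snps) == expected

    def test_study_scale_test_count(self):
        n = count_exhaustive_tests(395431, 192955)
        assert n == pytest.approx(7.36e15, rel=5e-3)

    def test_study_scale_bonferroni(self):
        thr = bonferroni_threshold(0.05, count_exhaustive_tests(395431, 192955))
        assert thr == pytest.approx(6.8e-18, rel=0.05)

    def test_replication_scale_bonferroni(self):
        assert bonferroni_threshold(0.05, 8_608_567) == pytest.approx(5.8e-9, rel=0.05)

    def test_single_test_threshold(self):
        assert bonferroni_threshold(0.05, 1) == 0.05


class TestPower:
    def test_null_limit_equals_alpha(self):
        assert interaction_power(1e-9, 533, 0.05) == pytest.approx(0.05, abs=1e-3)

    def test_monotone_in_n_and_r(self):
        grid_n = [100, 300, 533, 1000]
        powers = [interaction_power(0.3, n, 1e-5) for n in grid_n]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        grid_r = [0.1, 0.2, 0.3, 0.5]
        powers = [interaction_power(r, 533, 1e-5) for r in grid_r]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_matches_monte_carlo_rejection_rate(self):
        """Simulation oracle: plant a zero-margin interaction pattern with
        variance fraction r^2 and count rejections of the exact test."""
        r_target, n, alpha = 0.3, 300, 1e-3
        pattern = np.array([[1.0, -1.0, 0.0], [-1.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
        rejections = reps = 0
        for rep in range(600):
            rng = np.random.default_rng(rep)
            ga = rng.integers(0, 3, n)
            gb = rng.integers(0, 3, n)
            t = pattern[ga, gb]
            t = t - t.mean()
            # project out realised margins so the planted term is interaction-only
            X = np.column_stack([np.ones(n), ga == 1, ga == 2, gb == 1, gb == 2]).astype(float)
            beta, *_ = np.linalg.lstsq(X, t, rcond=None)
            t = t - X @ beta
            sd = t.std()
            if sd == 0:
                continue
            f = r_target**2 / (1 - r_target**2)
            y = t * np.sqrt(f) / sd + rng.standard_normal(n)
            try:
                _, p, _ = exact_interaction_anova(ga, gb, y)
            except ValueError:
                continue
            reps += 1
            rejections += p < alpha
        predicted = interaction_power(r_target, n, alpha)
        assert rejections / reps == pytest.approx(predicted, abs=0.05)
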