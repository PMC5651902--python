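# Methods

This note documents the models, numerical choices and limitations behind
`epimeth`. It is the package's own account; every empirical number quoted
here is one the test suite or `scripts/acceptance.py` computes.

## Synthetic cohorts

### Genotypes

Genotypes are simulated by thresholding Gaussian haplotype latents. SNPs are
laid out on chromosomes in blocks (block length uniform on
`block_length = (4, 12)` SNPs by default); within a block the latents follow
an AR(1) process with correlation `block_rho` (default 0.8), and each of the
two haplotypes per individual is drawn independently. A haplotype carries
the minor allele when its latent falls below the normal quantile of the
SNP's MAF (drawn uniformly from `maf_range`, default (0.05, 0.5));
genotypes are the two-haplotype sum. This gives continuous control of
pairwise dosage r² without simulating recombination — the downstream
stages only ever consume pairwise LD, not haplotype structure. Blocks are
separated by 100–300 kb gaps so that pruning windows and cis windows are
non-trivial. Missing genotypes are injected completely at random at rate
0.2%, enough to exercise the missingness filter without confounding.
Discovery and replication cohorts (defaults 533 and 319 samples, matching
a realistic paired-cohort design) share the SNP map and MAFs but use
independent draws.

### Methylation

Signals are composed on the M scale (log2 logit) as

    M = baseline + plate offsets + sex·b_sex + (age − mean age)·b_age
        + Σ planted effect terms + N(0, noise_sd²)

with per-CpG nuisance coefficients drawn once per simulation
(`baseline_sd = 1.5`, `plate_sd = 0.3`, `sex_sd = 0.2`,
`age_slope_sd = 0.02`, `noise_sd = 1`, all in M-value units). Beta-values
are the inverse M transform clipped to [1e-6, 1 − 1e-6] so the forward
transform stays finite.

Planted effect kinds: additive dosage mains, heterozygote-deviation
(dominance) mains, 3×3 epistatic deviation patterns, the spurious LD-triad
(below), and probe-artifact dosages. Each term is scaled so that its
variance fraction of the final per-CpG signal matches `target_r2`:
coefficients are fitted on the discovery cohort and reused verbatim for
replication, so both cohorts carry the same biology. The truth registry
records the realised fraction; across 50 planted effects the regression
slope of realised on target is within [0.8, 1.2] (tested).

Epistatic patterns are random 3×3 matrices double-centred under
Hardy–Weinberg genotype weights, so in expectation they induce no additive
or dominance main effect; at simulation time the realised per-sample term is
additionally projected onto the orthogonal complement of both SNPs' factor
margins in-sample, making the planted signal interaction-only in the drawn
cohort, not just in expectation. The marginal-free property is verified by
simulation (2-df main-effect p-values uniform at n = 2000).

### The LD-triad (spurious interaction) scenario

Three SNPs A, C, B with target pairwise r² of r²(C,A) = 0.55,
r²(C,B) = 0.25, r²(A,B) = 0.024, and a strong additive main effect of C
only (default 50% of variance) on one CpG. These r² targets are *not*
jointly reachable with equal MAFs — C's strong LD with both partners
forces A and B together — so the triad is sampled from an exact 8-cell
haplotype frequency table (the three-way term is the one free parameter;
the midpoint of its non-negativity window is used) with MAFs
A = 0.375, B = 0.275, C = 0.475. These MAFs were chosen, when the scenario
was designed, to maximise the variance of E[g_C | g_A, g_B] beyond the A/B
factor margins (the quantity that makes the naive A×B interaction test
fire) subject to every A×B genotype cell being populated at n = 319. With
that design the naive A×B exact interaction test is nominally significant
and forward selection containing C's main effect rejects the interaction
term in ~99% of replicates (acceptance script).

### Expression

Optionally, CpGs carrying planted effects are coupled to one cis transcript
each (within 500 kb) at a configurable shared-variance fraction; remaining
transcripts are independent noise. This provides the test bed for the
CpG–expression association stage.

## Genotype QC

Thresholds (defaults): MAF > 0.02, exact-HWE p > 0.001, missing rate < 0.01
per SNP, all required **in both cohorts**; the scan set additionally
requires the smallest genotype group ≥ 15 in both cohorts. HWE uses the
exact enumeration test (sum of heterozygote configurations no more probable
than the observed one, given allele counts) rather than the chi-square
approximation — robust at MAF near 2% with small groups; verified against
a brute-force enumeration oracle. LD pruning runs a 50-SNP window advanced
by 5 SNPs on discovery data: while any kept pair in the window exceeds
r² = 0.95, the later-positioned SNP of the worst pair is removed
(deterministic, order-independent tie-break). Pruning decisions are made on
discovery data only and applied to both cohorts.

## Methylation preprocessing

Order is fixed: (1) M transform, (2) per-plate z-scoring, (3) PC removal,
(4) sex/age residualisation, (5) 50-mer probe-variant correction. Missing
entries are mean-imputed within CpG for the regression steps and re-masked
on output; CpGs missing ≥ 1% in either cohort, or on the exclusion list,
are dropped before modelling.

PC removal deserves a note. The config defaults (8 components in discovery,
7 in replication) are appropriate for array-scale data, where the top axes
of a PCA over ~4×10⁵ probes capture batch structure and cell-composition
variation. On a synthetic panel of tens of CpGs the top components instead
align with individual probes and strip the very signals under study (we
measured an exact interaction F dropping from 25 to 8.9 when 2 of 5 CpGs'
axes were removed). The pipeline orchestrator therefore defaults to zero
components for panel-scale runs; the PCA operation itself is validated by
its own test (a planted global batch axis is eliminated with k = 1). This
means chain-level results on synthetic panels say nothing about how well
PC removal separates technical from biological variance on real arrays.

The probe-variant correction regresses a CpG's signal on the dosages of
variants inside its 50-mer probe sequence (columns with MAF < 0.03%
removed) and keeps the residuals only when the model R² strictly exceeds
0.1%; it runs independently per cohort.

## Interaction scan

The scan enumerates unordered SNP pairs per CpG. A vectorised kernel
computes 9-cell counts and response sums/sums-of-squares for a whole
(SNP, all-later-SNPs × all-CpGs) block via indicator matrix products, with
listwise deletion of missing genotypes; it is verified to match the
per-pair scalar path to 1e-10. Statistics:

- `F8` — joint 9-cell deviation from the grand mean (8 df);
- `F4_approx` — cell deviation from count-weighted additive+dominance
  margin predictions (4 df). Exact under orthogonality (equal to the exact
  test to 1e-8 on balanced designs, tested on 1,000 random designs), an
  overestimate under LD with main effects (≥ the exact statistic in > 95%
  of simulated correlated-SNP replicates);
- `F_exact` — partial F of the saturated cell-means model against the
  two-factor main-effects model, on complete cases, with all 9 cells
  required.

Pairs with all cells present and `F4_approx` above an F screen are
recalculated exactly; survivors are kept when the exact p beats
`alpha / (n_cpgs · C(n_snps, 2))`. The classic screen value 22 corresponds
to the full epigenome scale — its (4, 524)-df tail mass is 8.4e-17,
essentially the Bonferroni threshold there — so the orchestrator instead
derives the screen from the Bonferroni threshold of the *actual* problem
size (`bonferroni_matched_f_filter`); a fixed value and the
direct-Bonferroni-on-approximate-p variant are both available. p-values are
computed on the log scale and clamped at the smallest positive double with
an underflow flag, since thresholds like 6.8e-18 approach the F-tail's
representable range.

The power calculator uses the noncentral F distribution with
noncentrality n·r²/(1 − r²) (df 4, n − 9) and matches a Monte-Carlo
rejection-rate oracle within 0.02.

## Replication filter

A discovery hit survives only if in the replication cohort it passes all
of: (1) exact-ANOVA p below the adaptive per-CpG threshold
`alpha / (n_unique_cpgs + n_hits_on_this_cpg)`; (2) a permutation empirical
p below the same threshold, with the CpG signal permuted across samples and
genotypes fixed, `p = (1 + #{F_perm ≥ F_obs}) / (B + 1)` (add-one avoids
zero p-values; B defaults to 1,000, with optional Clopper–Pearson early
stopping); (3) the sign test, Pearson r > 0.85 between the two cohorts'
9-cell mean vectors — plus minimum cell occupancy > 3 in both cohorts.
Permutation streams are shared per CpG (the same permuted signals are
reused across that CpG's pairs), matching a per-CpG empirical null while
keeping pair-level p-values; a pooled-per-CpG null is available as an
option. Under Gaussian nulls the empirical p is uniform (KS p > 0.01 over
2,000 replicates at B = 500) and rank-agrees with the parametric p
(Spearman ρ > 0.95).

The sign test is the power bottleneck for moderate effects: with nine cell
means and a replication cohort of 319, a planted interaction explaining 15%
of variance yields an expected cell-mean correlation near 0.93 with
substantial spread (nine points, per-cell signal-to-noise ≈ 6), so the
r > 0.85 bar passes only ~84% of truly replicating effects. End-to-end
recovery of planted r² = 0.15 epistasis through scan + replication +
forward selection is therefore ~83% — real power of the published filter
chain at that effect size, not an implementation artifact. Recovery
scenarios use common SNPs (MAF 0.48–0.5): with rarer alleles the 3×3
rare-rare cell is empty or below the occupancy filter at n = 319, i.e.
outside the regime the cell-based scan addresses by construction.

## Per-CpG modelling

Candidates per hit-bearing CpG: mains from the 500 kb window around the
CpG, the 500 kb windows around each interacting SNP, and genome-wide
significant mains (`alpha / n_modeling_snps`); pairs from the surviving
hits plus all pairs among SNPs in LD (r² above the calibrated threshold)
with an interacting SNP.

Forward selection enters mains first (ascending discovery marginal 2-df p),
then interactions (ascending discovery marginal exact-interaction p). Each
candidate is tested by a sequential partial F-test against the model of
previously kept terms, refit with identical structure in each cohort, and
kept only when both cohorts' p-values beat
`alpha / (n_mains_tested + n_pairs_tested)`. Main terms are 3-level factor
encodings (2 df; missing genotypes mean-imputed in the dummy columns);
interaction terms are the four genotype-cell product contrasts
orthogonalised against both SNPs' factor margins, so a kept interaction
carries interaction-only variance and the decomposition below separates
cleanly. Rank-deficient additions are skipped. Interaction candidates
require all 9 cells with occupancy > 3 in both cohorts.

Kept pairs are classified LD-block associated when their discovery dosage
r² strictly exceeds the threshold calibrated as the 0.999 quantile of
cross-chromosome null r² (≈ χ²₁(0.999)/n ≈ 0.020 at n = 533; composite
dosage-correlation LD, since data are unphased and the classification only
needs a consistent statistic). Cis/trans labels use a 500 kb window around
the CpG. Variance decomposition reports R² of the best single main, the
mains-only model, and the full kept model, identically per cohort, on the
adjusted M signal (the modelled quantity throughout); the interaction
contribution is the difference of the last two. Note the planted truth is
measured on the raw M signal, so after nuisance removal the recovered
interaction fraction runs slightly above target (the denominator shrinks);
mean absolute deviation is ~0.02–0.04 at target 0.15.

The proximal search tests every SNP within ±3.5 Mb of a CpG by 2-df ANOVA
in discovery (per-CpG Bonferroni over SNPs tested), re-tests survivors in
replication (Bonferroni over survivors), and, for CpGs with ≥ 2 replicated
mains, tests all pairs among them by exact interaction ANOVA (occupancy
> 3, per-CpG Bonferroni over pairs, both cohorts), feeding survivors into
the same forward-selection machinery.

## Enrichment

Hit CpGs are clustered by single linkage at Pearson r > 0.8 (connected
components of the correlation graph; representative drawn uniformly with a
seed). Annotation uses 0-based half-open BED intervals against 1-based CpG
map positions (converted internally); membership is checked against a
brute-force interval scan in tests. Enrichment is a 2×2 Pearson chi-square
(1 df, no continuity correction) of representatives versus all remaining
CpGs, with a low-expected-count warning flag. Expression association flags
a CpG when any transcript passes either the genome-wide Bonferroni
(`alpha / (n_cpgs · n_transcripts)`) or the cis criterion
(`alpha / n_local_transcripts` within 500 kb); the union definition is a
package choice — both flags are emitted separately so either convention
can be recovered.

## Problem sizes and determinism

Chain-level analyses in the test suite and acceptance script run at desk
scale: null calibration on 50 CpGs × ~300 scan SNPs across 20 seeds,
spurious-triad reproduction across 200 replicates, recovery across 50
replicates with three planted effects each, permutation uniformity across
2,000 replicates at B = 500. All randomness flows through
`numpy.random.default_rng` seeded from explicit integers; identical
configuration and seed reproduce cohorts bitwise.

## Known limitations

- No coalescent or recombination realism, no phasing, no real 450K manifest
  emulation; LD is pairwise-correct only.
- The generator's nuisance structure (plate shifts, one batch axis, sex/age)
  is far simpler than real array data; passing chain tests demonstrates the
  statistics and filter logic, not robustness to real-world normalisation
  problems (cell composition, dye bias, probe cross-hybridisation).
- Imputation is out of scope: the 50-mer correction consumes simulated
  dosages directly.
- The scan is vectorised but desk-scale; no GPU kernel or bit-sliced
  genotype encodings.
- The sign-test power ceiling discussed above means moderate planted
  effects (r² ≈ 0.15) replicate at ~83%, so recovery-rate guarantees near
  80% are tight by nature.
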