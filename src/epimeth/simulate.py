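"""Synthetic paired discovery/replication cohorts with a known genetic architecture.

Genotypes are drawn by thresholding per-block Gaussian haplotype latents with
AR(1) within-block correlation, which gives continuous control over pairwise
LD (r^2) without simulating recombination.  Methylation is built on the
M-value (log2 logit) scale as a sum of planted genetic terms, covariate
nuisance terms and Gaussian noise, then mapped back to beta-values.  Every
planted effect is recorded in a :class:`TruthRegistry` together with the
variance fraction it actually realises, so downstream detection stages can be
scored for parameter recovery.

Planted effect kinds
--------------------
``main_additive``      dosage-linear effect of one SNP
``main_dominance``     heterozygote deviation of one SNP
``epistatic``          3x3 cell-deviation pattern orthogonal to both SNPs'
                       additive+dominance margins (interaction-only by
                       construction)
``spurious_ld_triad``  a strong main effect of SNP C that is in LD with two
                       scanned SNPs A and B, mimicking an A x B interaction
``probe_artifact``     a variant dosage inside the 50-mer probe sequence
                       leaking into the measured signal
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimulationConfig",
    "PlantedEffect",
    "TruthRegistry",
    "Cohort",
    "simulate_genotypes",
    "simulate_methylation",
    "simulate_cohort_pair",
    "make_ld_triad_scenario",
    "simulate_expression",
    "make_epistatic_delta",
    "beta_from_m",
]

_BETA_EPS = 1e-6


@dataclass
class SimulationConfig:
    """Study-design parameters for the paired-cohort generator.

    Defaults mirror the reference study design: a discovery cohort of 533
    and a replication cohort of 319 healthy adults, methylation noise on the
    M-value (log2 logit) scale.
    """

    n_discovery: int = 533
    n_replication: int = 319
    n_snps: int = 300
    n_cpgs: int = 50
    n_chromosomes: int = 2
    block_length: tuple[int, int] = (4, 12)  # uniform SNPs-per-block range
    block_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    plate_count: int = 6
    sex_fraction: float = 0.5
    age_range: tuple[float, float] = (18.0, 35.0)
    noise_sd: float = 1.0
    missing_rate: float = 0.002
    plate_sd: float = 0.3
    sex_sd: float = 0.2
    age_slope_sd: float = 0.02
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_discovery < 10 or self.n_replication < 10:
            raise ValueError("cohort sizes must be >= 10")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must be in [0, 1)")
        if self.block_length[0] < 1 or self.block_length[1] < self.block_length[0]:
            raise ValueError("invalid block_length range")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate out of range")
        if self.n_chromosomes < 1 or self.n_snps < 1 or self.n_cpgs < 1:
            raise ValueError("counts must be positive")
        if self.plate_count < 1 or not 0 <= self.sex_fraction <= 1:
            raise ValueError("invalid covariate settings")


@dataclass
class PlantedEffect:
    """One planted genetic (or artifact) influence on a single CpG."""

    cpg_id: str
    kind: str  # main_additive | main_dominance | epistatic | spurious_ld_triad | probe_artifact
    snp_ids: tuple[str, ...]
    target_r2: float
    delta: np.ndarray | float | None = None  # 3x3 pattern (epistatic) or scalar

    def __post_init__(self) -> None:
        kinds = {
            "main_additive",
            "main_dominance",
            "epistatic",
            "spurious_ld_triad",
            "probe_artifact",
        }
        if self.kind not in kinds:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if not 0 <= self.target_r2 < 1:
            raise ValueError("target_r2 must be in [0, 1)")
        n_snps = {"main_additive": 1, "main_dominance": 1, "epistatic": 2,
                  "spurious_ld_triad": 3, "probe_artifact": 0}[self.kind]
        if self.kind != "probe_artifact" and len(self.snp_ids) != n_snps:
            raise ValueError(f"{self.kind} needs {n_snps} SNP ids")


@dataclass
class TruthRegistry:
    """Ledger of planted effects with the variance fraction each realised."""

    effects: list[PlantedEffect]
    realized_r2: list[float] = field(default_factory=list)
    scales: list[float] = field(default_factory=list)
    spurious_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    def for_cpg(self, cpg_id: str) -> list[PlantedEffect]:
        return [e for e in self.effects if e.cpg_id == cpg_id]


@dataclass
class Cohort:
    """Genotypes, methylation and covariates for one sample set."""

    role: str  # discovery | replication
    genotypes: np.ndarray  # (n_samples, n_snps) int8, missing = -1
    snp_map: pd.DataFrame  # index snp_id; columns chrom, bp, maf
    methylation_beta: np.ndarray  # (n_samples, n_cpgs) in (0, 1)
    cpg_map: pd.DataFrame  # index cpg_id; columns chrom, bp
    covariates: pd.DataFrame  # sex, age, plate, batch
    probe_dosages: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_map.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.cpg_map.index)

    def snp_index(self, snp_id: str) -> int:
        return int(self.snp_map.index.get_loc(snp_id))

    def cpg_index(self, cpg_id: str) -> int:
        return int(self.cpg_map.index.get_loc(cpg_id))


# ---------------------------------------------------------------------------
# genotype simulation


def _snp_layout(config: SimulationConfig) -> pd.DataFrame:
    """SNP map shared by both cohorts: chromosome, position, block id, MAF."""
    rng = np.random.default_rng([config.seed, 101])
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    rows = []
    snp_i = 0
    for chrom_i, n_on_chrom in enumerate(per_chrom, start=1):
        bp = 0
        placed = 0
        block_id = 0
        while placed < n_on_chrom:
            blen = int(rng.integers(config.block_length[0], config.block_length[1] + 1))
            blen = min(blen, n_on_chrom - placed)
            for _ in range(blen):
                bp += int(rng.integers(1_000, 20_000))
                rows.append(
                    {
                        "snp_id": f"snp{snp_i:05d}",
                        "chrom": f"chr{chrom_i}",
                        "bp": bp,
                        "block": f"chr{chrom_i}_b{block_id}",
                        "maf": float(rng.uniform(*config.maf_range)),
                    }
                )
                snp_i += 1
                placed += 1
            bp += int(rng.integers(100_000, 300_000))  # inter-block gap
            block_id += 1
    return pd.DataFrame(rows).set_index("snp_id")


def _draw_block_genotypes(
    rng: np.random.Generator, n: int, mafs: np.ndarray, rho: float
) -> np.ndarray:
    """Threshold AR(1) Gaussian haplotype latents at each SNP's MAF quantile."""
    m = mafs.size
    geno = np.zeros((n, m), dtype=np.int8)
    thresh = stats.norm.ppf(mafs)
    for _hap in range(2):
        z = np.empty((n, m))
        z[:, 0] = rng.standard_normal(n)
        if m > 1:
            eps = rng.standard_normal((n, m - 1))
            for k in range(1, m):
                z[:, k] = rho * z[:, k - 1] + np.sqrt(1 - rho * rho) * eps[:, k - 1]
        geno += (z < thresh[None, :]).astype(np.int8)
    return geno


def simulate_genotypes(
    config: SimulationConfig, role: str
) -> tuple[np.ndarray, pd.DataFrame]:
    """Genotype matrix (minor-allele dosage 0/1/2, missing -1) + shared SNP map.

    Both roles use the same SNP layout and MAFs but independent draws; the
    random stream is derived from ``(config.seed, role)`` so the pair is
    reproducible jointly and separately.
    """
    config.validate()
    if role not in ("discovery", "replication"):
        raise ValueError("role must be 'discovery' or 'replication'")
    snp_map = _snp_layout(config)
    n = config.n_discovery if role == "discovery" else config.n_replication
    rng = np.random.default_rng([config.seed, 1 if role == "discovery" else 2])
    geno = np.empty((n, len(snp_map)), dtype=np.int8)
    start = 0
    for _, block in snp_map.groupby("block", sort=False):
        idx = snp_map.index.get_indexer(block.index)
        geno[:, idx] = _draw_block_genotypes(
            rng, n, block["maf"].to_numpy(), config.block_rho
        )
        start += len(block)
    if config.missing_rate > 0:
        miss = rng.random(geno.shape) < config.missing_rate
        geno[miss] = -1
    return geno, snp_map.drop(columns="block")


# ---------------------------------------------------------------------------
# planted-effect machinery


def make_epistatic_delta(
    rng: np.random.Generator, maf_a: float, maf_b: float
) -> np.ndarray:
    """Random 3x3 interaction pattern with zero weighted row/column margins.

    The margins are taken under Hardy-Weinberg genotype frequencies implied
    by each SNP's MAF, so in expectation the pattern induces no additive or
    dominance main effect at either locus.
    """
    wa = np.array([(1 - maf_a) ** 2, 2 * maf_a * (1 - maf_a), maf_a**2])
    wb = np.array([(1 - maf_b) ** 2, 2 * maf_b * (1 - maf_b), maf_b**2])
    d = rng.standard_normal((3, 3))
    # weighted double centering removes both margins exactly (product weights)
    row = (d * wb[None, :]).sum(axis=1) / wb.sum()
    col = (d * wa[:, None]).sum(axis=0) / wa.sum()
    grand = float((wa[:, None] * wb[None, :] * d).sum() / (wa.sum() * wb.sum()))
    return d - row[:, None] - col[None, :] + grand


def _effect_raw_term(
    effect: PlantedEffect,
    genotypes: np.ndarray,
    snp_map: pd.DataFrame,
    probe_dosage: np.ndarray | None,
) -> np.ndarray:
    """Unscaled per-sample effect signal; missing genotypes contribute 0."""
    n = genotypes.shape[0]

    def dosage(snp_id: str) -> np.ndarray:
        g = genotypes[:, snp_map.index.get_loc(snp_id)].astype(float)
        g[g < 0] = np.nan
        return g

    if effect.kind in ("main_additive", "spurious_ld_triad"):
        target_snp = effect.snp_ids[0]
        g = dosage(target_snp)
        t = g - np.nanmean(g)
    elif effect.kind == "main_dominance":
        g = dosage(effect.snp_ids[0])
        t = (g == 1).astype(float) - np.nanmean(g == 1)
        t[np.isnan(g)] = np.nan
    elif effect.kind == "epistatic":
        ga = dosage(effect.snp_ids[0])
        gb = dosage(effect.snp_ids[1])
        t = np.full(n, np.nan)
        ok = ~np.isnan(ga) & ~np.isnan(gb)
        t[ok] = np.asarray(effect.delta)[ga[ok].astype(int), gb[ok].astype(int)]
        # project out in-sample additive+dominance margins so the planted
        # signal is interaction-only in the realised cohort, not just in
        # expectation
        X = np.column_stack(
            [np.ones(ok.sum()), ga[ok] == 1, ga[ok] == 2, gb[ok] == 1, gb[ok] == 2]
        ).astype(float)
        beta, *_ = np.linalg.lstsq(X, t[ok], rcond=None)
        t[ok] = t[ok] - X @ beta
    elif effect.kind == "probe_artifact":
        if probe_dosage is None:
            raise ValueError("probe_artifact effect needs a probe dosage vector")
        t = probe_dosage - probe_dosage.mean()
    else:  # pragma: no cover
        raise AssertionError(effect.kind)
    return np.nan_to_num(t)


def simulate_methylation(
    genotypes: np.ndarray,
    effects: list[PlantedEffect],
    covariates: pd.DataFrame,
    config: SimulationConfig,
    snp_map: pd.DataFrame,
    cpg_map: pd.DataFrame,
    role: str = "discovery",
    reuse_scales: list[float] | None = None,
    probe_dosages: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, TruthRegistry]:
    """Beta-value matrix with planted effects, plus the truth registry.

    The signal is composed on the M scale; each planted term is scaled so its
    variance fraction of the final per-CpG signal approximates ``target_r2``
    (scales fitted here, or reused from the discovery call via
    ``reuse_scales`` so both cohorts carry the same coefficients).  Dosage
    vectors generated for ``probe_artifact`` effects are added to the
    ``probe_dosages`` mapping when the caller supplies one.
    """
    for e in effects:
        for s in e.snp_ids:
            if s not in snp_map.index:
                raise ValueError(f"planted effect references unknown SNP {s}")
        if e.cpg_id not in cpg_map.index:
            raise ValueError(f"planted effect references unknown CpG {e.cpg_id}")
    per_cpg_r2 = pd.Series(0.0, index=cpg_map.index)
    for e in effects:
        per_cpg_r2[e.cpg_id] += e.target_r2
    if (per_cpg_r2 >= 1).any():
        raise ValueError("target_r2 sums per CpG must stay below 1")

    n, n_cpgs = genotypes.shape[0], len(cpg_map)
    rng = np.random.default_rng([config.seed, 11 if role == "discovery" else 12])
    rng_shared = np.random.default_rng([config.seed, 13])  # per-CpG coefficients

    sex = covariates["sex"].to_numpy(float)
    age = covariates["age"].to_numpy(float)
    plate = covariates["plate"].to_numpy(int)
    base = rng_shared.normal(0.0, config.baseline_sd, n_cpgs)
    sex_beta = rng_shared.normal(0.0, config.sex_sd, n_cpgs)
    age_beta = rng_shared.normal(0.0, config.age_slope_sd, n_cpgs)
    plate_off = rng_shared.normal(0.0, config.plate_sd, (config.plate_count, n_cpgs))

    M = (
        base[None, :]
        + sex[:, None] * sex_beta[None, :]
        + (age - age.mean())[:, None] * age_beta[None, :]
        + plate_off[plate % config.plate_count, :]
        + rng.normal(0.0, config.noise_sd, (n, n_cpgs))
    )
    nuisance_var = M.var(axis=0)

    truth = TruthRegistry(effects=list(effects))
    if probe_dosages is None:
        probe_dosages = {}
    for k, e in enumerate(effects):
        j = int(cpg_map.index.get_loc(e.cpg_id))
        if e.kind == "probe_artifact" and e.cpg_id not in probe_dosages:
            maf = float(rng_shared.uniform(0.1, 0.4))
            probe_dosages[e.cpg_id] = rng.binomial(2, maf, n).astype(float)
        if e.kind == "epistatic" and e.delta is None:
            e.delta = make_epistatic_delta(
                rng_shared,
                float(snp_map.loc[e.snp_ids[0], "maf"]),
                float(snp_map.loc[e.snp_ids[1], "maf"]),
            )
        t = _effect_raw_term(e, genotypes, snp_map, probe_dosages.get(e.cpg_id))
        v_t = t.var()
        if reuse_scales is not None:
            scale = reuse_scales[k]
        else:
            if v_t <= 0:
                raise ValueError(f"degenerate planted term for {e.cpg_id}")
            frac = e.target_r2 / (1.0 - per_cpg_r2[e.cpg_id])
            scale = float(np.sqrt(frac * nuisance_var[j] / v_t))
        term = scale * t
        M[:, j] += term
        truth.scales.append(float(scale))
        total_var = M[:, j].var()
        truth.realized_r2.append(float(term.var() / total_var) if total_var > 0 else 0.0)
        if e.kind == "spurious_ld_triad":
            truth.spurious_pairs.append((e.cpg_id, e.snp_ids[1], e.snp_ids[2]))
    beta = beta_from_m(M)
    return beta, truth


def beta_from_m(M: np.ndarray) -> np.ndarray:
    """Inverse M transform: beta = 2^M / (1 + 2^M), clipped inside (0, 1)."""
    with np.errstate(over="ignore"):
        beta = 1.0 / (1.0 + np.exp2(-np.asarray(M, dtype=float)))
    return np.clip(beta, _BETA_EPS, 1.0 - _BETA_EPS)


def _make_covariates(config: SimulationConfig, role: str) -> pd.DataFrame:
    n = config.n_discovery if role == "discovery" else config.n_replication
    rng = np.random.default_rng([config.seed, 21 if role == "discovery" else 22])
    sex = (rng.random(n) < config.sex_fraction).astype(int)
    age = rng.uniform(*config.age_range, n)
    plate = rng.permutation(np.arange(n) % config.plate_count)
    batch = plate % 2  # plates processed in two batches
    return pd.DataFrame(
        {"sex": sex, "age": age, "plate": plate, "batch": batch},
        index=[f"{role[:4]}_{i:04d}" for i in range(n)],
    )


def _cpg_layout(config: SimulationConfig, snp_map: pd.DataFrame) -> pd.DataFrame:
    """CpG map interleaved with the SNP map so cis windows are non-trivial."""
    rng = np.random.default_rng([config.seed, 102])
    chroms = snp_map["chrom"].unique()
    rows = []
    for i in range(config.n_cpgs):
        chrom = chroms[i % len(chroms)]
        span = int(snp_map.loc[snp_map["chrom"] == chrom, "bp"].max())
        rows.append(
            {
                "cpg_id": f"cg{i:05d}",
                "chrom": chrom,
                "bp": int(rng.integers(1, span + 100_000)),
            }
        )
    return pd.DataFrame(rows).set_index("cpg_id")


def simulate_cohort_pair(
    config: SimulationConfig, effects: list[PlantedEffect] | None = None
) -> tuple[Cohort, Cohort, TruthRegistry]:
    """Paired discovery/replication cohorts sharing maps, MAFs and effect scales."""
    config.validate()
    effects = list(effects or [])
    geno_d, snp_map = simulate_genotypes(config, "discovery")
    geno_r, _ = simulate_genotypes(config, "replication")
    cpg_map = _cpg_layout(config, snp_map)
    cov_d = _make_covariates(config, "discovery")
    cov_r = _make_covariates(config, "replication")
    probes_d: dict[str, np.ndarray] = {}
    probes_r: dict[str, np.ndarray] = {}
    beta_d, truth = simulate_methylation(
        geno_d, effects, cov_d, config, snp_map, cpg_map,
        role="discovery", probe_dosages=probes_d,
    )
    beta_r, _ = simulate_methylation(
        geno_r, effects, cov_r, config, snp_map, cpg_map,
        role="replication", reuse_scales=truth.scales, probe_dosages=probes_r,
    )
    disc = Cohort("discovery", geno_d, snp_map, beta_d, cpg_map, cov_d, probes_d)
    rep = Cohort("replication", geno_r, snp_map, beta_r, cpg_map, cov_r, probes_r)
    return disc, rep, truth


# ---------------------------------------------------------------------------
# LD-triad (spurious interaction) scenario


def _triad_haplotype_probs(
    maf_a: float, maf_b: float, maf_c: float, r2_ca: float, r2_cb: float, r2_ab: float
) -> np.ndarray:
    """Haplotype frequencies over {0,1}^3 matching three pairwise r^2 targets.

    With all three allele frequencies and pairwise joint frequencies fixed,
    the 8-cell haplotype distribution has exactly one free parameter (the
    three-way term); any value inside its non-negativity window works, and
    the midpoint is used.  Raises when the targets are incompatible with the
    chosen MAFs (strong C-A and C-B correlation forces A-B together, so the
    low A-B target is only reachable for suitably unequal MAFs).
    """
    pA, pB, pC = maf_a, maf_b, maf_c
    sA, sB, sC = (np.sqrt(p * (1 - p)) for p in (pA, pB, pC))
    qAB = pA * pB + np.sqrt(r2_ab) * sA * sB
    qAC = pA * pC + np.sqrt(r2_ca) * sA * sC
    qBC = pB * pC + np.sqrt(r2_cb) * sB * sC
    lo = max(0.0, qAB + qAC - pA, qAB + qBC - pB, qAC + qBC - pC)
    hi = min(qAB, qAC, qBC, 1 - pA - pB - pC + qAB + qAC + qBC)
    if lo >= hi:
        raise ValueError(
            f"LD targets unreachable for MAFs ({pA}, {pB}, {pC}): "
            f"three-way window [{lo:.4f}, {hi:.4f}] is empty"
        )
    t = 0.5 * (lo + hi)  # P(A=1, B=1, C=1)
    p = np.empty(8)  # index bits: (A, B, C)
    p[0b111] = t
    p[0b110] = qAB - t
    p[0b101] = qAC - t
    p[0b011] = qBC - t
    p[0b100] = pA - qAB - qAC + t
    p[0b010] = pB - qAB - qBC + t
    p[0b001] = pC - qAC - qBC + t
    p[0b000] = 1 - p[1:].sum()
    assert (p > -1e-12).all()
    return np.clip(p, 0.0, None) / p.sum()


def make_ld_triad_scenario(
    n_discovery: int = 533,
    n_replication: int = 319,
    seed: int = 0,
    main_r2: float = 0.5,
    mafs: tuple[float, float, float] = (0.375, 0.275, 0.475),  # A, B, C
    r2_ca: float = 0.55,
    r2_cb: float = 0.25,
    r2_ab: float = 0.024,
    noise_sd: float = 1.0,
    max_retries: int = 5,
) -> tuple[Cohort, Cohort, TruthRegistry]:
    """Three-SNP scenario where a strong main effect mimics an interaction.

    SNP C carries the only true (main, additive) effect on one CpG; SNPs A
    and B each sit in LD with C (target pair r^2 of 0.55 and 0.25) but are in
    low LD with each other (0.024).  A naive A x B interaction test on the
    CpG is then spuriously significant, while joint modelling that includes
    C's main effect explains it away — the triad mechanism the per-CpG
    modelling stage must neutralise.  Haplotypes for the triad are sampled
    from an exact 8-cell frequency table matching the pairwise r^2 targets.
    """
    if min(n_discovery, n_replication) < 200:
        raise ValueError("need at least 200 samples per cohort")
    maf_a, maf_b, maf_c = mafs
    probs = _triad_haplotype_probs(maf_a, maf_b, maf_c, r2_ca, r2_cb, r2_ab)
    # order on the chromosome: A, C, B (C between its two LD partners)
    snp_map = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "bp": [1_000_000, 1_020_000, 1_040_000],
            "maf": [maf_a, maf_c, maf_b],
        },
        index=["snp_A", "snp_C", "snp_B"],
    )
    snp_map.index.name = "snp_id"
    cpg_map = pd.DataFrame({"chrom": ["chr1"], "bp": [1_010_000]}, index=["cg_triad"])
    cpg_map.index.name = "cpg_id"

    def draw(rng: np.random.Generator, n: int) -> np.ndarray:
        geno = np.zeros((n, 3), dtype=np.int8)
        for _ in range(2):
            cells = rng.choice(8, size=n, p=probs)
            # bits: (A, B, C) -> columns (A, C, B)
            geno[:, 0] += (cells >> 2) & 1
            geno[:, 1] += cells & 1
            geno[:, 2] += (cells >> 1) & 1
        return geno.astype(np.int8)

    last_err = None
    for attempt in range(max_retries):
        rng_d = np.random.default_rng([seed, 31, attempt])
        rng_r = np.random.default_rng([seed, 32, attempt])
        geno_d = draw(rng_d, n_discovery)
        geno_r = draw(rng_r, n_replication)
        emp = np.corrcoef(geno_d.T) ** 2
        if abs(emp[0, 1] - r2_ca) < 0.12 and abs(emp[1, 2] - r2_cb) < 0.12:
            break
        last_err = (
            f"empirical LD r2 (C,A)={emp[0, 1]:.3f}, (C,B)={emp[1, 2]:.3f} "
            f"missed targets ({r2_ca}, {r2_cb})"
        )
    else:
        raise RuntimeError(f"LD targets unreachable after {max_retries} draws: {last_err}")

    cfg = SimulationConfig(
        n_discovery=n_discovery,
        n_replication=n_replication,
        n_snps=3,
        n_cpgs=1,
        noise_sd=noise_sd,
        missing_rate=0.0,
        seed=seed,
    )
    effect = PlantedEffect(
        cpg_id="cg_triad",
        kind="spurious_ld_triad",
        snp_ids=("snp_C", "snp_A", "snp_B"),
        target_r2=main_r2,
    )
    cov_d = _make_covariates(cfg, "discovery")
    cov_r = _make_covariates(cfg, "replication")
    beta_d, truth = simulate_methylation(
        geno_d, [effect], cov_d, cfg, snp_map, cpg_map, role="discovery"
    )
    beta_r, _ = simulate_methylation(
        geno_r, [effect], cov_r, cfg, snp_map, cpg_map,
        role="replication", reuse_scales=truth.scales,
    )
    disc = Cohort("discovery", geno_d, snp_map, beta_d, cpg_map, cov_d)
    rep = Cohort("replication", geno_r, snp_map, beta_r, cpg_map, cov_r)
    return disc, rep, truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    methylation_m: np.ndarray,
    cpg_map: pd.DataFrame,
    truth: TruthRegistry,
    n_transcripts: int,
    coupling_r2: float,
    seed: int = 0,
    cis_window: int = 500_000,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Expression matrix with cis transcripts coupled to controlled CpGs.

    CpGs carrying planted genetic effects are preferentially coupled: each
    gets one transcript within ``cis_window`` of its position whose values
    share a fraction ``coupling_r2`` of variance with the (M-scale)
    methylation signal.  Remaining transcripts are independent noise placed
    uniformly over the CpG map's span.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    if not 0 <= coupling_r2 < 1:
        raise ValueError("coupling_r2 must be in [0, 1)")
    rng = np.random.default_rng([seed, 41])
    n = methylation_m.shape[0]
    controlled = [e.cpg_id for e in truth.effects if e.kind != "probe_artifact"]
    controlled = list(dict.fromkeys(controlled))[:n_transcripts]
    expr = rng.standard_normal((n, n_transcripts))
    rows = []
    chroms = cpg_map["chrom"].unique()
    span = int(cpg_map["bp"].max()) + cis_window
    for t in range(n_transcripts):
        if coupling_r2 > 0 and t < len(controlled):
            cpg = controlled[t]
            j = int(cpg_map.index.get_loc(cpg))
            sig = methylation_m[:, j]
            sig = (sig - sig.mean()) / max(sig.std(), 1e-12)
            expr[:, t] = np.sqrt(coupling_r2) * sig + np.sqrt(1 - coupling_r2) * (
                rng.standard_normal(n)
            )
            offset = int(rng.integers(-cis_window // 2, cis_window // 2))
            bp = max(1, int(cpg_map.loc[cpg, "bp"]) + offset)
            rows.append(
                {
                    "transcript_id": f"tx{t:05d}",
                    "chrom": cpg_map.loc[cpg, "chrom"],
                    "bp": bp,
                    "coupled_cpg": cpg,
                }
            )
        else:
            rows.append(
                {
                    "transcript_id": f"tx{t:05d}",
                    "chrom": str(rng.choice(chroms)),
                    "bp": int(rng.integers(1, span)),
                    "coupled_cpg": "",
                }
            )
    tx_map = pd.DataFrame(rows).set_index("transcript_id")
    return expr, tx_map
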