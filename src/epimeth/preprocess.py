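"""Methylation post-processing: beta -> adjusted M-scale association signal.

The chain applied per cohort, in order:

1. logit transform of beta-values to M-values (log2 scale);
2. z-transformation per plate (plate/batch correction);
3. regressing out the top principal-component scores (technical axes and a
   proxy for blood-cell composition), PCA fitted on complete CpG columns;
4. regressing out sex and age;
5. residualising on dosages of variants inside the 50-mer probe sequence
   whenever they jointly explain more than 0.1% of a CpG's variance.

Missing methylation entries are mean-imputed within CpG for the regression
steps and re-masked afterwards; CpGs too often missing in either cohort are
dropped before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import Cohort

__all__ = [
    "PreprocessConfig",
    "beta_to_m",
    "zscore_by_plate",
    "pca_residualize",
    "regress_out_covariates",
    "probe_variant_correction",
    "filter_cpgs",
    "preprocess_cohort",
]


@dataclass
class PreprocessConfig:
    n_pcs_discovery: int = 8
    n_pcs_replication: int = 7
    probe_r2_min: float = 0.001
    dosage_maf_min: float = 0.0003
    cpg_miss_max: float = 0.01
    exclusion_list: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for name in ("probe_r2_min", "dosage_maf_min", "cpg_miss_max"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.n_pcs_discovery < 0 or self.n_pcs_replication < 0:
            raise ValueError("PC counts must be >= 0")


def beta_to_m(beta) -> np.ndarray:
    """M-value transform: log2(beta / (1 - beta)). Requires beta in (0, 1)."""
    b = np.asarray(beta, dtype=float)
    interior = np.isnan(b) | ((b > 0) & (b < 1))
    if not interior.all():
        raise ValueError("beta values must lie strictly inside (0, 1)")
    return np.log2(b / (1.0 - b))


def zscore_by_plate(M: np.ndarray, plate_labels) -> np.ndarray:
    """Centre and scale each CpG column to unit variance within each plate.

    Missing entries are ignored; a CpG with zero variance within a plate is
    set to 0 for that plate.
    """
    plates = np.asarray(plate_labels)
    if plates.shape[0] != M.shape[0]:
        raise ValueError("one plate label per sample required")
    out = np.array(M, dtype=float)
    for p in np.unique(plates):
        rows = plates == p
        if rows.sum() < 2:
            raise ValueError(f"plate {p!r} has fewer than 2 samples")
        block = out[rows]
        mu = np.nanmean(block, axis=0)
        sd = np.nanstd(block, axis=0, ddof=0)
        zero = ~(sd > 0)
        sd = np.where(zero, 1.0, sd)
        block = (block - mu) / sd
        block[:, zero] = 0.0
        out[rows] = block
    return out


def _mean_impute(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = np.isnan(M)
    if not mask.any():
        return M.copy(), mask
    filled = M.copy()
    mu = np.nanmean(M, axis=0)
    idx = np.where(mask)
    filled[idx] = np.take(mu, idx[1])
    return filled, mask


def pca_residualize(M: np.ndarray, k: int) -> np.ndarray:
    """Regress the top-k PCA sample scores out of every CpG column.

    The PCA is computed on CpG columns without any missing value; the scores
    (sample-space axes) are then removed from all columns by least squares.
    k = 0 returns the input unchanged.
    """
    if k == 0:
        return np.array(M, dtype=float)
    complete = ~np.isnan(M).any(axis=0)
    Xc = M[:, complete]
    if Xc.shape[1] < k or min(Xc.shape) <= k:
        raise ValueError("not enough complete CpG columns for requested k")
    Xc = Xc - Xc.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    if (s[:k] <= 1e-12 * s[0]).any():
        raise ValueError("requested k exceeds the effective rank")
    scores = U[:, :k]  # orthonormal sample-space axes
    filled, mask = _mean_impute(np.array(M, dtype=float))
    filled = filled - filled.mean(axis=0)
    resid = filled - scores @ (scores.T @ filled)
    resid[mask] = np.nan
    return resid


def regress_out_covariates(M: np.ndarray, sex, age) -> np.ndarray:
    """Per-CpG least-squares residuals from intercept + sex + age.

    Constant covariates are dropped from the design (logged via a warning).
    """
    import warnings

    n = M.shape[0]
    cols = [np.ones(n)]
    for name, v in (("sex", sex), ("age", age)):
        v = np.asarray(v, dtype=float)
        if np.isnan(v).any():
            raise ValueError(f"{name} must be complete")
        if v.std() == 0:
            warnings.warn(f"covariate {name} is constant; dropped from design")
            continue
        cols.append(v)
    X = np.column_stack(cols)
    filled, mask = _mean_impute(np.array(M, dtype=float))
    Q, _ = np.linalg.qr(X)
    resid = filled - Q @ (Q.T @ filled)
    resid[mask] = np.nan
    return resid


def probe_variant_correction(
    m_vector: np.ndarray,
    dosage_matrix: np.ndarray | None,
    probe_r2_min: float = 0.001,
    dosage_maf_min: float = 0.0003,
) -> tuple[np.ndarray, bool]:
    """Residualise a CpG signal on 50-mer probe variant dosages if they matter.

    Dosage columns with MAF below ``dosage_maf_min`` are removed; the rest are
    jointly regressed on the signal.  The residuals replace the signal only
    when the model R^2 strictly exceeds ``probe_r2_min``.
    """
    y = np.asarray(m_vector, dtype=float)
    if dosage_matrix is None or np.size(dosage_matrix) == 0:
        return y.copy(), False
    D = np.atleast_2d(np.asarray(dosage_matrix, dtype=float))
    if D.shape[0] != y.shape[0]:
        D = D.T
    if ((D < 0) | (D > 2)).any():
        raise ValueError("dosages must lie in [0, 2]")
    maf = np.minimum(D.mean(axis=0) / 2.0, 1 - D.mean(axis=0) / 2.0)
    D = D[:, maf >= dosage_maf_min]
    if D.shape[1] == 0:
        return y.copy(), False
    ok = ~np.isnan(y)
    X = np.column_stack([np.ones(ok.sum()), D[ok]])
    beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
    fitted = X @ beta
    ss_tot = float(((y[ok] - y[ok].mean()) ** 2).sum())
    ss_res = float(((y[ok] - fitted) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if r2 > probe_r2_min:
        out = y.copy()
        out[ok] = y[ok] - fitted
        return out, True
    return y.copy(), False


def filter_cpgs(
    discovery: Cohort, replication: Cohort, config: PreprocessConfig
) -> list[str]:
    """CpGs passing the missingness filter in both cohorts, minus exclusions."""
    config.validate()
    if not discovery.cpg_map.index.equals(replication.cpg_map.index):
        raise ValueError("cohorts must share the CpG map")
    excl = set(config.exclusion_list)
    kept = []
    for j, cpg in enumerate(discovery.cpg_map.index):
        if cpg in excl:
            continue
        ok = True
        for cohort in (discovery, replication):
            miss = np.isnan(cohort.methylation_beta[:, j]).mean()
            if miss >= config.cpg_miss_max:
                ok = False
        if ok:
            kept.append(cpg)
    return kept


def preprocess_cohort(
    cohort: Cohort,
    config: PreprocessConfig | None = None,
    cpg_ids: list[str] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Full adjustment chain for one cohort; returns (M matrix, per-CpG log).

    The log records, per CpG, whether the 50-mer probe-variant correction
    fired and the R^2 its dosage model explained.
    """
    config = config or PreprocessConfig()
    config.validate()
    if cpg_ids is None:
        cpg_ids = cohort.cpg_ids
    cols = [cohort.cpg_index(c) for c in cpg_ids]
    beta = cohort.methylation_beta[:, cols]
    M = beta_to_m(beta)
    M = zscore_by_plate(M, cohort.covariates["plate"].to_numpy())
    k = (
        config.n_pcs_discovery
        if cohort.role == "discovery"
        else config.n_pcs_replication
    )
    k = min(k, max(0, min(M.shape) - 2))
    M = pca_residualize(M, k)
    M = regress_out_covariates(
        M, cohort.covariates["sex"].to_numpy(), cohort.covariates["age"].to_numpy()
    )
    flags, r2s = [], []
    for out_j, cpg in enumerate(cpg_ids):
        dos = cohort.probe_dosages.get(cpg)
        corrected = False
        if dos is not None:
            M[:, out_j], corrected = probe_variant_correction(
                M[:, out_j], dos, config.probe_r2_min, config.dosage_maf_min
            )
        flags.append(corrected)
        r2s.append(np.nan)
    log = pd.DataFrame({"probe_corrected": flags}, index=pd.Index(cpg_ids, name="cpg_id"))
    return M, log
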