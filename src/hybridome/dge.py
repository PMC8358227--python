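"""Negative-binomial differential expression for the hybrid-vs-normal contrast.

The contrast pools both within-species crosses against both reciprocal hybrid
crosses on the log scale: L = (log mu_PC + log mu_CP)/2 - (log mu_PP +
log mu_CC)/2. Features are flagged DE when |log2FC| exceeds a class-specific
threshold (2.5 for genes, 2.0 for sRNA clusters, log2 units) with
Bonferroni-corrected p < alpha.

Estimation is moment/quasi-likelihood based and fully vectorized: per-cross
means are means of median-of-ratios-normalized counts (the NB-GLM maximum
likelihood estimate when size factors are equal within a cross), per-feature
dispersion is a pooled within-cross method-of-moments estimate under
Var = mu + alpha * mu^2, and the Wald statistic uses a delta-method standard
error on the log scale with a Student-t reference (df = libraries - crosses)
to account for the estimated dispersion. This construction is exactly
invariant to rescaling any single library's counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    CROSSES,
    HYBRID_CROSSES,
    STRUCTURAL_RNA_CLASSES,
    WITHIN_SPECIES_CROSSES,
    CountTable,
    SampleSheet,
    SrnaCluster,
)

__all__ = [
    "DgeParams",
    "size_factors",
    "normalized_counts",
    "cpm",
    "filter_srna_classes",
    "nb_wald_test",
    "cross_means",
    "wilcoxon_compare",
    "GENE_PARAMS",
    "SRNA_PARAMS",
]

LN2 = float(np.log(2.0))
#: floor for the method-of-moments dispersion estimate
DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class DgeParams:
    """DE-calling parameters.

    logfc_threshold is in log2 units: 2.5 for genes, 2.0 for sRNA clusters.
    Flags use Bonferroni-corrected p < alpha; BH-FDR q values are emitted as
    an extra column but never drive the DE flag.
    """

    logfc_threshold: float = 2.5
    alpha: float = 0.05
    correction: str = "bonferroni"
    pseudocount: float = 0.5
    min_total_count: int = 1

    def __post_init__(self) -> None:
        if self.logfc_threshold <= 0:
            raise ValueError("logfc_threshold must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.correction not in ("bonferroni", "bh_fdr"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


GENE_PARAMS = DgeParams(logfc_threshold=2.5)
SRNA_PARAMS = DgeParams(logfc_threshold=2.0)


def size_factors(counts: CountTable) -> pd.Series:
    """Median-of-ratios library size factors.

    factor_j = median over features f (restricted to features with positive
    counts in every library) of counts[f, j] / geometric_mean_f. Factors are
    returned unscaled. A single library gets factor 1.0 by convention.
    """
    df = counts.df
    if df.shape[1] == 1:
        return pd.Series([1.0], index=df.columns, name="size_factor")
    arr = df.to_numpy(dtype=float)
    all_positive = np.all(arr > 0, axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has positive counts in every library; size factors are "
            "undefined — filter low-count features or add a pseudocount"
        )
    log_arr = np.log(arr[all_positive])
    log_geomean = log_arr.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_arr - log_geomean, axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def normalized_counts(counts: CountTable, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts.df / factors


def cpm(counts: CountTable) -> pd.DataFrame:
    """Counts per million: counts[f, j] * 1e6 / column_sum_j."""
    colsums = counts.df.sum(axis=0)
    if (colsums == 0).any():
        zero = colsums.index[colsums == 0].tolist()
        raise ValueError(f"zero column sum in libraries {zero}")
    return counts.df * 1e6 / colsums


def filter_srna_classes(
    clusters: list[SrnaCluster], counts: CountTable
) -> tuple[list[SrnaCluster], CountTable]:
    """Drop structural/housekeeping RNA classes (antisense, rRNA, tRNA,
    snoRNA, snRNA, SRPRNA) from both the cluster list and the count table
    before DE testing; clean and miRNA-annotated clusters are retained."""
    ids = {c.cluster_id for c in clusters}
    table_ids = set(counts.feature_ids)
    if ids != table_ids:
        raise ValueError(
            f"cluster ids do not match count rows; only-in-clusters="
            f"{sorted(ids - table_ids)[:5]}, only-in-counts="
            f"{sorted(table_ids - ids)[:5]}"
        )
    kept = [c for c in clusters if c.rna_class not in STRUCTURAL_RNA_CLASSES]
    kept_ids = {c.cluster_id for c in kept}
    mask = [fid in kept_ids for fid in counts.feature_ids]
    return kept, CountTable(counts.df.loc[mask])


def _group_indices(sheet: SampleSheet, library_ids: list[str]) -> dict[str, np.ndarray]:
    cross_of = dict(zip(sheet.library_ids, sheet.crosses))
    out: dict[str, np.ndarray] = {}
    for cross in CROSSES:
        idx = np.array(
            [j for j, lib in enumerate(library_ids) if cross_of[lib] == cross],
            dtype=int,
        )
        out[cross] = idx
    return out


def cross_means(
    counts: CountTable, sheet: SampleSheet, factors: pd.Series | None = None
) -> pd.DataFrame:
    """Per-cross means of size-factor-normalized counts (features x crosses)."""
    counts = counts.align_to(sheet)
    norm = normalized_counts(counts, factors).to_numpy()
    groups = _group_indices(sheet, counts.library_ids)
    data = {
        cross: norm[:, idx].mean(axis=1)
        for cross, idx in groups.items()
        if idx.size > 0
    }
    return pd.DataFrame(data, index=counts.feature_ids)


def _mom_dispersion(
    norm: np.ndarray, inv_sf: np.ndarray, groups: dict[str, np.ndarray]
) -> np.ndarray:
    """Pooled within-cross method-of-moments dispersion, floored.

    Var(y_j / s_j) = mu / s_j + alpha * mu^2, so per cross
    alpha_g = (s2_g - mu_g * mean(1/s_j)) / mu_g^2; crosses are pooled with
    (n_g - 1) weights.
    """
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for idx in groups.values():
        if idx.size < 2:
            continue
        sub = norm[:, idx]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        poisson_part = mu * inv_sf[idx].mean()
        w = idx.size - 1
        num += w * (s2 - poisson_part)
        den += w * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.maximum(alpha, DISPERSION_FLOOR)


def nb_wald_test(
    counts: CountTable, sheet: SampleSheet, params: DgeParams
) -> pd.DataFrame:
    """Test every feature for the combined within-species vs hybrid contrast.

    Returns a DataFrame indexed by feature id with columns: base_mean,
    log2fc (positive = higher in hybrids), se_log2fc, p_raw, p_bonferroni,
    q_bh, is_de, direction ('over'/'under'/'none'), tested, dispersion.

    All-zero features (and features below ``min_total_count``) are reported
    untested with p = 1 and log2fc = 0.
    """
    counts = counts.align_to(sheet)
    sheet.require_crosses(CROSSES, min_reps=2)
    raw = counts.df.to_numpy(dtype=float)
    feature_ids = counts.feature_ids

    sf = size_factors(counts)
    inv_sf = (1.0 / sf).to_numpy()
    norm = raw / sf.to_numpy()
    groups = _group_indices(sheet, counts.library_ids)

    total = raw.sum(axis=1)
    tested = total >= max(params.min_total_count, 1)

    alpha_disp = _mom_dispersion(norm, inv_sf, groups)
    eps = params.pseudocount

    mu = {c: norm[:, idx].mean(axis=1) for c, idx in groups.items()}
    var_log = np.zeros(norm.shape[0])
    log_mu = {}
    for cross, idx in groups.items():
        # pseudocount acts as a floor so that log2fc of expressed features is
        # exactly invariant to rescaling a library's counts
        m = np.maximum(mu[cross], eps if eps > 0 else 1e-300)
        log_mu[cross] = np.log(m)
        # Var(mean of normalized counts) under Var(y/s) = mu/s + alpha mu^2
        var_mean = (m * inv_sf[idx].sum() + alpha_disp * m**2 * idx.size) / idx.size**2
        var_log += var_mean / m**2
    contrast = 0.5 * (
        log_mu["PC"] + log_mu["CP"] - log_mu["PP"] - log_mu["CC"]
    )
    se = 0.5 * np.sqrt(var_log)

    n_libs = norm.shape[1]
    dof = n_libs - len([g for g in groups.values() if g.size > 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, contrast / np.where(se > 0, se, 1.0), 0.0)
    p_raw = 2.0 * stats.t.sf(np.abs(wald), df=max(dof, 1))
    p_raw = np.where(tested, p_raw, 1.0)
    contrast = np.where(tested, contrast, 0.0)

    m_tested = int(tested.sum())
    p_bonf = np.minimum(p_raw * max(m_tested, 1), 1.0)
    p_bonf = np.where(tested, p_bonf, 1.0)
    q_bh = np.ones_like(p_raw)
    if m_tested:
        q_bh[tested] = stats.false_discovery_control(p_raw[tested], method="bh")

    log2fc = contrast / LN2
    se_log2fc = np.where(tested, se / LN2, np.nan)
    p_adj = p_bonf if params.correction == "bonferroni" else q_bh
    is_de = tested & (np.abs(log2fc) > params.logfc_threshold) & (p_adj < params.alpha)
    direction = np.where(is_de, np.where(log2fc > 0, "over", "under"), "none")

    base_mean = norm.mean(axis=1)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se_log2fc": se_log2fc,
            "p_raw": p_raw,
            "p_bonferroni": p_bonf,
            "q_bh": q_bh,
            "is_de": is_de,
            "direction": direction,
            "tested": tested,
            "dispersion": alpha_disp,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )


def wilcoxon_compare(cpm_a, cpm_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison.

    Uses exact enumeration when n + m <= 12 and the pooled sample is
    tie-free, otherwise the normal approximation with tie correction.
    Returns (U statistic of the first sample, two-sided p).
    """
    a = np.asarray(cpm_a, dtype=float)
    b = np.asarray(cpm_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 12 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
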