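"""Expression normalisation and negative-binomial differential expression.

FPKM and RPM follow the textbook definitions (library size = column sum
unless supplied).  Differential expression between two replicate groups is a
negative-binomial Wald test: counts are normalised by median-of-ratios size
factors, the NB dispersion is estimated per feature by method of moments
pooled across the two groups and stabilised by shrinkage toward the
across-feature trend, and the Wald statistic on the log2 fold change uses a
delta-method standard error under NB variance.  Significance follows the
|log2FC| > 1 and Benjamini-Hochberg adjusted p < 0.05 convention.

This is a self-contained re-implementation of the standard NB-Wald recipe;
its gene lists will be close to, but not identical with, tools that add
fold-change shrinkage or outlier handling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import ValidationError
from .containers import ExpressionMatrix

DISPERSION_FLOOR = 1e-8
DEFAULT_PRIOR_DF = 50.0

DE_COLUMNS = ["feature_id", "comparison", "mean_a", "mean_b",
              "log2fc", "p", "padj", "significant"]


# ------------------------------------------------------------ normalisation

def _library_sizes(matrix: ExpressionMatrix) -> pd.Series:
    lib = matrix.values.sum(axis=0)
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ValidationError(f"zero library size for samples: {zero}")
    return lib


def fpkm(counts: ExpressionMatrix, lengths: dict[str, int] | pd.Series
         ) -> ExpressionMatrix:
    """Fragments per kilobase per million: counts * 1e9 / (length * libsize)."""
    if counts.unit != "counts":
        raise ValidationError(f"fpkm expects counts, got {counts.unit}")
    lengths = pd.Series(lengths).reindex(counts.values.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValidationError(f"features without length: {missing[:10]}")
    if (lengths <= 0).any():
        raise ValidationError("feature lengths must be positive")
    lib = _library_sizes(counts)
    values = counts.values.mul(1e9).div(lengths, axis=0).div(lib, axis=1)
    return ExpressionMatrix(values=values, unit="FPKM",
                            sample_meta=counts.sample_meta)


def rpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Reads per million mapped reads: counts * 1e6 / libsize."""
    if counts.unit != "counts":
        raise ValidationError(f"rpm expects counts, got {counts.unit}")
    lib = _library_sizes(counts)
    values = counts.values.mul(1e6).div(lib, axis=1)
    return ExpressionMatrix(values=values, unit="RPM",
                            sample_meta=counts.sample_meta)


# ------------------------------------------------------------ size factors

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Falls back to column-sum ratios when no feature is positive in every
    sample (e.g. tiny or very sparse matrices).
    """
    positive = counts.loc[(counts > 0).all(axis=1)]
    if len(positive) == 0:
        lib = counts.sum(axis=0)
        if (lib == 0).any():
            raise ValidationError("zero library size; cannot normalise")
        return lib / stats.gmean(lib)
    log_geo = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geo, axis=0)
    return np.exp(ratios.median(axis=0))


# ------------------------------------------------------------ DE test

def _moment_dispersion(norm: np.ndarray, idx_a, idx_b) -> np.ndarray:
    """Per-feature MoM dispersion, pooled across the two groups.

    phi solves var = mu + phi mu^2 with the within-group pooled variance and
    the grand mean of normalised counts.
    """
    a, b = norm[:, idx_a], norm[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    pooled_var = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    mu = norm[:, list(idx_a) + list(idx_b)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (pooled_var - mu) / mu**2
    phi = np.where(np.isfinite(phi), phi, 0.0)
    return np.maximum(phi, 0.0)


def _shrink_dispersion(phi: np.ndarray, df_per_feature: int,
                       prior_df: float) -> np.ndarray:
    """Shrink per-feature dispersions toward the across-feature mean.

    With three replicates per group the raw MoM estimate has ~4 df and a
    Wald test built on it is badly anti-conservative; borrowing strength
    across features (the same idea as dispersion-trend fitting in the
    standard NB-DE tools) restores near-nominal type-I error.  The mean is
    used as the central value (the MoM estimate is roughly unbiased, so the
    across-feature mean tracks the common dispersion; a median would sit
    systematically low at few degrees of freedom), and the prior weight is
    deliberately heavy: with two or three replicates the per-feature
    estimate carries almost no information, and features with extreme
    chance fold changes also show deceptively small within-group variance,
    so weak pooling lets exactly those features reach spuriously small
    standard errors.
    """
    if len(phi) < 2 or prior_df <= 0:
        return phi
    central = float(np.mean(phi))
    w = df_per_feature / (df_per_feature + prior_df)
    return w * phi + (1.0 - w) * central


def de_test(counts: ExpressionMatrix, group_a: list[str], group_b: list[str],
            comparison: str | None = None, pseudo: float = 0.5,
            lfc_threshold: float = 1.0, alpha: float = 0.05,
            prior_df: float = DEFAULT_PRIOR_DF) -> pd.DataFrame:
    """NB-Wald differential expression of group_b over group_a.

    Returns one row per feature with columns
    ``feature_id, comparison, mean_a, mean_b, log2fc, p, padj, significant``.
    Features that are all-zero in both groups get log2fc 0 and p 1.
    """
    if counts.unit != "counts":
        raise ValidationError(f"de_test expects counts, got {counts.unit}")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)}")
    unknown = (set(group_a) | set(group_b)) - set(counts.values.columns)
    if unknown:
        raise ValidationError(f"unknown sample ids: {sorted(unknown)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least two samples")
    if comparison is None:
        stage = counts.sample_meta["stage"]
        comparison = f"{stage[group_a[0]]}_vs_{stage[group_b[0]]}"

    sub = counts.values[list(group_a) + list(group_b)]
    sf = size_factors(sub)
    norm = (sub / sf).to_numpy(dtype=float)
    na, nb = len(group_a), len(group_b)
    idx_a = np.arange(na)
    idx_b = np.arange(na, na + nb)

    mean_a = norm[:, idx_a].mean(axis=1)
    mean_b = norm[:, idx_b].mean(axis=1)
    log2fc = np.log2((mean_b + pseudo) / (mean_a + pseudo))

    phi = _moment_dispersion(norm, idx_a, idx_b)
    phi = _shrink_dispersion(phi, df_per_feature=na + nb - 2,
                             prior_df=prior_df)
    phi = np.maximum(phi, DISPERSION_FLOOR)

    # delta method: Var(log2 (mean+pseudo)) = Var(mean) / ((mean+pseudo) ln2)^2
    # with Var(mean_g) = (mu_g + phi mu_g^2) / n_g under NB sampling.
    ln2sq = np.log(2.0) ** 2
    var_a = (mean_a + phi * mean_a**2) / na
    var_b = (mean_b + phi * mean_b**2) / nb
    se_sq = (var_a / (mean_a + pseudo) ** 2
             + var_b / (mean_b + pseudo) ** 2) / ln2sq
    all_zero = (mean_a == 0) & (mean_b == 0)
    se = np.sqrt(np.maximum(se_sq, 1e-300))
    z = np.where(all_zero, 0.0, log2fc / se)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(all_zero, 1.0, p)
    log2fc = np.where(all_zero, 0.0, log2fc)

    padj = adjust_bh(p)
    significant = (np.abs(log2fc) > lfc_threshold) & (padj < alpha)
    return pd.DataFrame({
        "feature_id": counts.values.index,
        "comparison": comparison,
        "mean_a": mean_a, "mean_b": mean_b,
        "log2fc": log2fc, "p": p, "padj": padj,
        "significant": significant,
    }).reset_index(drop=True)


def de_adjacent_stages(counts: ExpressionMatrix, **kwargs) -> pd.DataFrame:
    """Run de_test for every adjacent stage pair, concatenated."""
    stages = counts.stages
    frames = []
    for s1, s2 in zip(stages, stages[1:]):
        frames.append(de_test(
            counts, counts.samples_of_stage(s1), counts.samples_of_stage(s2),
            comparison=f"{s1}_vs_{s2}", **kwargs))
    return pd.concat(frames, ignore_index=True)


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
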