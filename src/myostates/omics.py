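"""Differential-expression and PTM z-score statistics for abundance matrices.

Implements the TMT-style proteome workflow: log2 transform, a valid-value
filter (a feature is dropped when any group has fewer than two observed
values), MinProb-style left-censored imputation (per-sample downshifted
Gaussian with shift 1.8 and width 0.3 in units of the sample SD), per-feature
two-sample t-tests with Benjamini-Hochberg FDR control, and the standard
significance rule: FDR < 0.05 and fold change >= 2 (|log2FC| >= 1).
PTM sites are summarized as across-sample z-scores, with z > 0 read as
hyper- and z < 0 as hypo-modification in a condition.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "preprocess",
    "differential_expression",
    "benjamini_hochberg",
    "ptm_zscores",
    "pca_samples",
]

logger = logging.getLogger(__name__)

MINPROB_SHIFT = 1.8  # downshift in sample-SD units
MINPROB_WIDTH = 0.3  # draw SD in sample-SD units
FC_THRESHOLD = 2.0
FDR_THRESHOLD = 0.05


def preprocess(
    matrix: pd.DataFrame,
    groups: pd.Series,
    min_valid_per_group: int = 2,
    already_log2: bool = True,
    shift: float = MINPROB_SHIFT,
    width: float = MINPROB_WIDTH,
    seed=0,
) -> pd.DataFrame:
    """Filter and impute an abundance matrix (features x samples).

    Raw positive abundances are log2-transformed unless ``already_log2``.
    Features where any group has fewer than ``min_valid_per_group`` observed
    values are excluded.  Remaining missing cells are imputed per sample by
    draws from a downshifted Gaussian, N(sample_mean - shift*sample_SD,
    (width*sample_SD)^2), computed from that sample's observed values —
    the left-censored regime where sub-detection intensities live.  Seeded,
    hence reproducible.
    """
    if not matrix.columns.equals(groups.index):
        groups = groups.reindex(matrix.columns)
        if groups.isna().any():
            raise ValueError("group labels do not cover all samples")
    data = matrix.astype(float)
    if not already_log2:
        if (data <= 0).any().any():
            raise ValueError("raw abundances must be positive for log2 transform")
        data = np.log2(data)

    if data.isna().all(axis=0).any():
        bad = data.columns[data.isna().all(axis=0)].tolist()
        raise ValueError(f"sample(s) with no observed values: {bad}")

    valid = data.notna()
    keep = pd.Series(True, index=data.index)
    for g in groups.unique():
        cols = groups.index[groups == g]
        keep &= valid[cols].sum(axis=1) >= min_valid_per_group
    dropped = int((~keep).sum())
    if dropped:
        logger.info("excluded %d features with < %d valid values in a group",
                    dropped, min_valid_per_group)
    data = data.loc[keep].copy()

    rng = np.random.default_rng(seed)
    for col in data.columns:
        observed = data[col].dropna()
        n_missing = int(data[col].isna().sum())
        if n_missing == 0:
            continue
        mu, sd = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(mu - shift * sd, width * sd, size=n_missing)
        data.loc[data[col].isna(), col] = draws
    return data


def benjamini_hochberg(p):
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def differential_expression(
    matrix: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    equal_var: bool = False,
    fc_threshold: float = FC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Per-feature differential expression of group b versus group a.

    Unpaired t-tests per feature (Welch by default; ``equal_var=True`` for
    pooled variance), log2 fold change mean_b - mean_a, Benjamini-Hochberg
    FDR.  A feature is ``significant`` iff FDR < ``fdr_threshold`` and
    |log2FC| >= log2(``fc_threshold``).  Zero-variance features get their
    p-value from a small variance floor and are flagged in ``qc_flag``.
    """
    cols_a = groups.index[groups == group_a]
    cols_b = groups.index[groups == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both groups need at least two samples")
    a = matrix[cols_a].to_numpy(float)
    b = matrix[cols_b].to_numpy(float)

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = mean_b - mean_a

    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
    if degenerate.any():
        # variance floor: identical groups -> p = 1; distinct constants -> ~0
        p = np.where(degenerate & (log2fc == 0), 1.0, p)
        p = np.where(degenerate & (log2fc != 0), np.finfo(float).tiny, p)
        t_floor = np.where(log2fc == 0, 0.0, np.where(log2fc > 0, np.inf, -np.inf))
        t = np.where(degenerate, t_floor, t)

    fdr = benjamini_hochberg(p)
    significant = (fdr < fdr_threshold) & (np.abs(log2fc) >= np.log2(fc_threshold))
    out = pd.DataFrame(
        {
            "log2_fc": log2fc,
            "t": t,
            "p_value": p,
            "fdr": fdr,
            "significant": significant,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "qc_flag": np.where(degenerate, "ZERO_VARIANCE", ""),
        },
        index=matrix.index,
    )
    out.index.name = "feature"
    return out


def ptm_zscores(site_matrix: pd.DataFrame, groups: pd.Series) -> tuple:
    """Across-sample z-scores per PTM site, with per-condition calls.

    Each site's quantifications are standardized across all samples (mean 0,
    unit sample SD); sites with zero SD are excluded with a warning.  Returns
    ``(zscores, condition_summary)`` where the summary holds each site's mean
    z per condition and a ``hyper``/``hypo`` call from its sign.
    """
    data = site_matrix.astype(float)
    sd = data.std(axis=1, ddof=1)
    degenerate = (sd == 0) | sd.isna()
    if degenerate.any():
        logger.warning("excluding %d site(s) with zero variance: %s",
                       int(degenerate.sum()), list(data.index[degenerate])[:5])
        data = data.loc[~degenerate]
        sd = sd[~degenerate]
    z = data.sub(data.mean(axis=1), axis=0).div(sd, axis=0)

    rows = []
    for g in groups.unique():
        cols = groups.index[groups == g]
        mean_z = z[cols].mean(axis=1)
        rows.append(
            pd.DataFrame(
                {
                    "site": z.index,
                    "condition": g,
                    "mean_z": mean_z.to_numpy(),
                    "call": np.where(mean_z > 0, "hyper", "hypo"),
                }
            )
        )
    return z, pd.concat(rows, ignore_index=True)


def pca_samples(matrix: pd.DataFrame, n_components: int = 2, scale: bool = False):
    """PCA of samples on the preprocessed matrix (features x samples).

    Samples are observations; features are centered (and optionally scaled to
    unit variance).  Returns ``(scores, explained_pct)``: per-sample scores on
    the first ``n_components`` components and percent variance explained.
    """
    from sklearn.decomposition import PCA

    x = matrix.to_numpy(float).T  # samples x features
    rank = min(x.shape[0], x.shape[1])
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank <= {rank}")
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd == 0, 1.0, sd)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    out = pd.DataFrame(
        scores,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return out, 100.0 * pca.explained_variance_ratio_
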