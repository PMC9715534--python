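"""Transcriptome-atlas statistics over normalized counts.

Expressed-gene calling against a fixed normalized-count threshold (the
bimodal log2 distribution of normalized counts motivates a default of 4),
expression breadth across tissues, gene variability (coefficient of
variation across samples; tau tissue-specificity across tissue means),
constitutive-gene discovery, and Spearman sample-sample similarity.

tau is 0 for a gene expressed uniformly across tissues and 1 for a gene
expressed in a single tissue:

    tau = sum_i (1 - x_i / max(x)) / (N - 1)

computed over the N per-tissue mean expression values of the gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_EXPRESSION_THRESHOLD = 4.0
DEFAULT_CV_MAX = 0.15


def call_expressed(tissue_mean: pd.DataFrame, threshold: float = DEFAULT_EXPRESSION_THRESHOLD) -> pd.DataFrame:
    """Boolean gene x tissue calls: expressed iff tissue mean >= threshold."""
    if threshold <= 0:
        raise ValueError("expression threshold must be positive")
    return tissue_mean >= threshold


def expression_breadth(calls: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Number of tissues each gene is expressed in, plus the histogram.

    The histogram is indexed 0..N_tissues and sums to the gene count
    (genes expressed nowhere occupy bin 0).
    """
    if calls.shape[0] == 0 or calls.shape[1] == 0:
        raise ValueError("empty call matrix")
    breadth = calls.sum(axis=1).astype(int)
    breadth.name = "breadth"
    n_tissues = calls.shape[1]
    hist = breadth.value_counts().reindex(range(n_tissues + 1), fill_value=0)
    hist.index.name = "breadth"
    hist.name = "n_genes"
    return breadth, hist


def coefficient_of_variation(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean, sample sd (n-1 denominator) and CV across all samples.

    Genes with zero mean get CV = NaN (undefined) and are excluded from
    constitutive candidacy downstream.
    """
    if normalized.shape[1] < 2:
        raise ValueError("CV needs at least 2 samples")
    mean = normalized.mean(axis=1)
    sd = normalized.std(axis=1, ddof=1)
    cv = sd / mean.where(mean > 0)
    out = pd.DataFrame({"mean": mean, "sd": sd, "cv": cv})
    out.index.name = normalized.index.name
    return out


def tau_index(tissue_mean: pd.DataFrame) -> pd.Series:
    """Tau tissue-specificity index per gene over per-tissue means.

    NaN for genes with all-zero tissue means (specificity undefined).
    """
    if tissue_mean.shape[1] < 2:
        raise ValueError("tau needs at least 2 tissues")
    x = tissue_mean.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("tissue means must be non-negative")
    xmax = x.max(axis=1)
    n = x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        xhat = x / xmax[:, None]
        tau = (1.0 - xhat).sum(axis=1) / (n - 1)
    tau = np.where(xmax > 0, tau, np.nan)
    return pd.Series(tau, index=tissue_mean.index, name="tau")


def gene_variability_stats(normalized: pd.DataFrame, tissue_mean: pd.DataFrame,
                           threshold: float = DEFAULT_EXPRESSION_THRESHOLD) -> pd.DataFrame:
    """Combined per-gene table: mean, sd, CV, tau and expression breadth."""
    stats_df = coefficient_of_variation(normalized)
    stats_df["tau"] = tau_index(tissue_mean)
    calls = call_expressed(tissue_mean, threshold)
    stats_df["breadth"], _ = expression_breadth(calls)
    return stats_df


def find_constitutive_genes(stats_df: pd.DataFrame, cv_max: float = DEFAULT_CV_MAX,
                            tau_max: float | None = None) -> pd.DataFrame:
    """Genes with defined CV <= cv_max, sorted ascending by CV.

    tau is carried along as supporting annotation; only when ``tau_max`` is
    given does it become a second filter (tau < tau_max).
    """
    if cv_max <= 0:
        raise ValueError("cv_max must be positive")
    keep = stats_df["cv"].notna() & (stats_df["cv"] <= cv_max)
    if tau_max is not None:
        keep &= stats_df["tau"].notna() & (stats_df["tau"] < tau_max)
    out = stats_df.loc[keep].sort_values("cv", kind="mergesort")
    return out


def sample_similarity(normalized: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank-correlation matrix over samples (average ranks for ties).

    A zero-variance sample yields NaN against every other sample; its
    diagonal entry is set to 1 by convention.
    """
    if normalized.shape[1] < 2 or normalized.shape[0] < 2:
        raise ValueError("similarity needs >= 2 samples and >= 2 genes")
    rho = stats.spearmanr(normalized.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    else:
        rho = np.array(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=normalized.columns, columns=normalized.columns)


def log2_expression_histogram(normalized: pd.DataFrame, bins: int = 50) -> pd.DataFrame:
    """Diagnostic histogram of log2(x + 1) normalized counts.

    The pooled distribution is typically bimodal; the valley between the
    low-expression shoulder and the active-transcriptome peak justifies
    the expressed-gene threshold.
    """
    vals = np.log2(normalized.to_numpy(dtype=float).ravel() + 1.0)
    counts, edges = np.histogram(vals, bins=bins)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": counts,
    })
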