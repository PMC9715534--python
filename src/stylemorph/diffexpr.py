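"""Two-group negative-binomial Wald differential expression.

A deliberately transparent NB analogue of the standard count-based DE
workflow: per-gene dispersions by method-of-moments on normalized counts
pooled within groups, then a log-link NB generalized linear model
(variance mu + alpha * mu^2) with size factors as offsets and design
intercept + group indicator, fitted by Fisher-scoring IRLS. The group
coefficient divided by ln 2 is the log2 fold change; a two-sided Wald
p-value against the standard normal is adjusted with Benjamini-Hochberg
over the tested genes. DEG status additionally applies the fold-change
filter: up means log2FC >= lfc_min with padj <= padj_max, down the mirror.

There is no dispersion shrinkage toward a trend, no fold-change
shrinkage, and no outlier or independent filtering; on real data the DEG
lists will therefore differ from shrinkage-based packages even at equal
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CountMatrix, estimate_size_factors, normalize_counts
from .enrichment import bh_adjust

ALPHA_FLOOR = 1e-8
MAX_IRLS_ITER = 100
IRLS_TOL = 1e-8

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class Contrast:
    """Two disjoint sample groups; log2FC is group_a relative to group_b.

    For the floral-morph contrasts group_a is the S-morph and group_b the
    L-morph, so "up-regulated" means higher in S than in L.
    """

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        a, b = set(self.group_a), set(self.group_b)
        if len(a) != len(self.group_a) or len(b) != len(self.group_b):
            raise ValueError("duplicate sample ids within a group")
        if a & b:
            raise ValueError(f"groups overlap: {sorted(a & b)}")
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each contrast group needs at least 2 samples")

    @property
    def samples(self) -> tuple[str, ...]:
        return self.group_a + self.group_b

    def swapped(self) -> "Contrast":
        return Contrast(self.name, self.group_b, self.group_a)


def contrast_from_metadata(metadata: pd.DataFrame, column: str,
                           a_labels, b_labels, name: str | None = None) -> Contrast:
    """Build a contrast by selecting samples whose ``column`` is in each label set."""
    a_labels, b_labels = set(a_labels), set(b_labels)
    col = metadata[column].astype(str)
    group_a = tuple(metadata.index[col.isin(a_labels)])
    group_b = tuple(metadata.index[col.isin(b_labels)])
    if name is None:
        name = f"{'+'.join(sorted(a_labels))}_vs_{'+'.join(sorted(b_labels))}"
    return Contrast(name, group_a, group_b)


def estimate_dispersions(cm: CountMatrix, size_factors: pd.Series,
                         contrast: Contrast) -> pd.DataFrame:
    """Method-of-moments NB dispersion per gene, pooled within groups.

    alpha = max((pooled within-group variance - mean) / mean^2, floor)
    on normalized counts over the contrast's samples. Genes with zero base
    mean are marked untested.
    """
    sub = cm.subset_samples(contrast.samples)
    norm = normalize_counts(sub, size_factors.loc[list(contrast.samples)])
    na, nb = len(contrast.group_a), len(contrast.group_b)
    va = norm[list(contrast.group_a)].var(axis=1, ddof=1)
    vb = norm[list(contrast.group_b)].var(axis=1, ddof=1)
    pooled_var = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    base_mean = norm.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = (pooled_var - base_mean) / base_mean**2
    alpha = alpha.clip(lower=ALPHA_FLOOR).fillna(ALPHA_FLOOR)
    tested = base_mean > 0
    return pd.DataFrame({"base_mean": base_mean, "alpha": alpha, "tested": tested})


def _fit_nb_glm(y: np.ndarray, offset: np.ndarray, x: np.ndarray, alpha: float,
                ) -> tuple[float, float, bool]:
    """Fisher-scoring IRLS for the NB GLM log(mu) = b0 + b1*x + offset.

    Returns (b1, se(b1), converged). Weights are mu / (1 + alpha * mu),
    i.e. the inverse NB variance times (dmu/deta)^2 for the log link.
    """
    mean_a = np.exp(np.log((y[x == 1] / np.exp(offset[x == 1])).mean() + 0.5))
    mean_b = np.exp(np.log((y[x == 0] / np.exp(offset[x == 0])).mean() + 0.5))
    beta = np.array([np.log(mean_b), np.log(mean_a) - np.log(mean_b)])
    design = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    converged = False
    for _ in range(MAX_IRLS_ITER):
        eta = design @ beta + offset
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xtw = design.T * w
        try:
            beta_new = np.linalg.solve(xtw @ design, xtw @ z)
        except np.linalg.LinAlgError:
            return float("nan"), float("nan"), False
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < IRLS_TOL:
            converged = True
            break
    eta = design @ beta + offset
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    w = mu / (1.0 + alpha * mu)
    info = (design.T * w) @ design
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float(beta[1]), float("nan"), False
    return float(beta[1]), float(np.sqrt(cov[1, 1])), converged


def nb_wald_test(cm: CountMatrix, size_factors: pd.Series,
                 dispersions: pd.DataFrame, contrast: Contrast) -> pd.DataFrame:
    """Per-gene NB Wald statistics for a two-group contrast.

    Columns: log2fc, lfc_se, stat, pvalue, tested. Genes with one all-zero
    group get a signed-infinite log2fc and NaN p (untested); genes whose
    IRLS does not converge are flagged untested rather than dropped.
    """
    samples = list(contrast.samples)
    y_all = cm.counts[samples].to_numpy(dtype=float)
    offset = np.log(size_factors.loc[samples].to_numpy(dtype=float))
    x = np.array([1.0 if s in set(contrast.group_a) else 0.0 for s in samples])
    out = pd.DataFrame(
        index=cm.gene_ids,
        data={"log2fc": np.nan, "lfc_se": np.nan, "stat": np.nan,
              "pvalue": np.nan, "tested": False},
    )
    norm = y_all / np.exp(offset)[None, :]
    mean_a = norm[:, x == 1].mean(axis=1)
    mean_b = norm[:, x == 0].mean(axis=1)
    for i, gene in enumerate(cm.gene_ids):
        if not dispersions["tested"].iloc[i]:
            continue
        if mean_a[i] == 0.0 or mean_b[i] == 0.0:
            if mean_a[i] == mean_b[i]:
                continue
            out.iloc[i, out.columns.get_loc("log2fc")] = (
                np.inf if mean_a[i] > mean_b[i] else -np.inf
            )
            continue
        b1, se, ok = _fit_nb_glm(y_all[i], offset, x, float(dispersions["alpha"].iloc[i]))
        if not ok or not np.isfinite(se) or se == 0.0:
            continue
        z = b1 / se
        out.iloc[i, out.columns.get_loc("log2fc")] = b1 / LN2
        out.iloc[i, out.columns.get_loc("lfc_se")] = se / LN2
        out.iloc[i, out.columns.get_loc("stat")] = z
        out.iloc[i, out.columns.get_loc("pvalue")] = 2.0 * stats.norm.sf(abs(z))
        out.iloc[i, out.columns.get_loc("tested")] = True
    return out


def run_de_contrast(cm: CountMatrix, contrast: Contrast, lfc_min: float = 1.0,
                    padj_max: float = 0.05,
                    size_factors: pd.Series | None = None) -> pd.DataFrame:
    """Full DE pipeline for one contrast: size factors -> dispersions ->
    Wald test -> BH over tested genes -> status assignment.

    Status is "up" if log2fc >= lfc_min and padj <= padj_max, "down" for
    the mirrored condition, "not-DE" for other tested genes, "untested"
    otherwise. BH runs over tested genes only.
    """
    sub = cm.subset_samples(contrast.samples)
    if size_factors is None:
        size_factors = estimate_size_factors(sub)
    disp = estimate_dispersions(sub, size_factors, contrast)
    wald = nb_wald_test(sub, size_factors, disp, contrast)
    res = pd.concat([disp[["base_mean", "alpha"]], wald], axis=1)
    tested = res["tested"].to_numpy()
    if not tested.any():
        raise ValueError("no testable genes in the contrast")
    padj = np.full(len(res), np.nan)
    padj[tested] = bh_adjust(res.loc[tested, "pvalue"])
    res["padj"] = padj
    status = np.where(
        ~tested, "untested",
        np.where((res["log2fc"] >= lfc_min) & (res["padj"] <= padj_max), "up",
                 np.where((res["log2fc"] <= -lfc_min) & (res["padj"] <= padj_max),
                          "down", "not-DE")),
    )
    res["status"] = status
    return res


def deg_sets(result: pd.DataFrame) -> dict[str, set[str]]:
    """Up- and down-regulated gene id sets from a DE result table."""
    return {
        "up": set(result.index[result["status"] == "up"]),
        "down": set(result.index[result["status"] == "down"]),
    }
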