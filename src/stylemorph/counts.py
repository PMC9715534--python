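"""Raw count matrices, median-of-ratios size factors, and per-tissue means.

The entry point of the pipeline is a gene x sample matrix of raw
(non-negative, integral) read counts together with per-sample metadata
(tissue, floral morph, species, optional contrast group). Normalization
follows the median-of-ratios convention: each sample is scaled by the
median, over reference genes, of its counts divided by the gene's
geometric mean across samples. Reference genes are those with strictly
positive counts in every sample, so the geometric mean is well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MORPH_CODES = ("L", "S", "pooled", "NA")

METADATA_COLUMNS = ("tissue", "morph", "species", "group")


class NoReferenceGenesError(ValueError):
    """No gene has strictly positive counts in every sample."""


@dataclass
class CountMatrix:
    """Gene x sample raw counts plus per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one integer column per sample.
    metadata
        DataFrame indexed by sample id with columns ``tissue``, ``morph``,
        ``species`` and ``group``. Every sample in ``counts`` must have a
        metadata record; unknown morph is coded ``"NA"``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0 or self.counts.shape[1] == 0:
            raise ValueError("count matrix is empty")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(values < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integral")
        missing = self.counts.columns.difference(self.metadata.index)
        if len(missing) > 0:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        meta_missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if meta_missing:
            raise ValueError(f"metadata lacks columns: {meta_missing}")
        # align metadata to the sample order of the matrix
        self.metadata = self.metadata.loc[self.counts.columns]
        tissues = self.metadata["tissue"]
        if tissues.isna().any() or (tissues.astype(str).str.len() == 0).any():
            raise ValueError("every sample needs a non-empty tissue label")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(self.counts[sample_ids], self.metadata.loc[sample_ids])


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a count TSV (first column ``gene_id``, one column per sample)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    first = df.columns[0]
    if first != "gene_id":
        raise ValueError(f"count TSV must start with a 'gene_id' column, got {first!r}")
    return df.set_index("gene_id")


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata_tsv(path) -> pd.DataFrame:
    """Read sample metadata (sample_id, tissue, morph, species, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError("metadata TSV needs a 'sample_id' column")
    df = df.set_index("sample_id")
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = "NA" if col in ("morph", "group") else ""
    return df


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def load_count_matrix(counts_path, metadata_path) -> CountMatrix:
    return CountMatrix(read_counts_tsv(counts_path), read_metadata_tsv(metadata_path))


def drop_allzero_genes(cm: CountMatrix) -> tuple[CountMatrix, list[str]]:
    """Remove genes with zero counts in all samples, logging the dropped ids."""
    keep = cm.counts.sum(axis=1) > 0
    dropped = list(cm.counts.index[~keep])
    if dropped:
        logger.info("dropping %d all-zero genes of %d", len(dropped), cm.counts.shape[0])
    if keep.sum() == 0:
        raise ValueError("all genes have zero counts in all samples")
    return CountMatrix(cm.counts.loc[keep], cm.metadata), dropped


def estimate_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    s_j = median over reference genes i of K_ij / g_i, where g_i is the
    geometric mean of gene i across samples (computed in log space) and the
    reference set is the genes with all counts > 0. Median ties use midpoint
    interpolation.
    """
    k = cm.counts.to_numpy(dtype=float)
    reference = np.all(k > 0, axis=1)
    if not reference.any():
        raise NoReferenceGenesError(
            "no reference genes: no gene has positive counts in every sample"
        )
    logk = np.log(k[reference])
    log_geomean = logk.mean(axis=1)
    ratios = np.exp(logk - log_geomean[:, None])
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=cm.sample_ids, name="size_factor")


def normalize_counts(cm: CountMatrix, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor (gene/sample order kept)."""
    if set(size_factors.index) != set(cm.sample_ids):
        raise ValueError("size factors do not match the matrix's samples")
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")
    sf = size_factors.loc[cm.sample_ids]
    return cm.counts / sf


def tissue_means(normalized: pd.DataFrame, metadata: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene arithmetic mean of normalized counts over each tissue's replicates.

    Returns the gene x tissue mean matrix and the replicate count per tissue.
    Tissues may have unequal replicate numbers (the atlas design has one
    tissue with two replicates and three elsewhere); each tissue's mean is
    simply over its own samples.
    """
    missing = normalized.columns.difference(metadata.index)
    if len(missing) > 0:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    tissue = metadata.loc[normalized.columns, "tissue"]
    if (tissue.astype(str).str.len() == 0).any() or tissue.isna().any():
        raise ValueError("every sample needs a tissue label")
    grouped = normalized.T.groupby(tissue, sort=True)
    means = grouped.mean().T
    n_rep = grouped.size()
    if (n_rep < 1).any():
        raise ValueError("tissue with zero samples")
    n_rep.name = "n_replicates"
    return means, n_rep
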