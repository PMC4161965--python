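"""Pseudocount, median-of-ratios library-size normalization, set filtering.

The normalization is the classic median-of-ratios scheme: the size factor of
sample *j* is the median over genes of counts[g, j] divided by the geometric
mean of gene *g* across samples. A pseudocount of 1 is added to every entry
first so that all geometric means are defined.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import CountMatrix, GeneSet, GeneSetCollection


@dataclass
class NormalizedMatrix:
    """Pseudocounted, size-factor-scaled expression values (strictly positive)."""

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    size_factors: np.ndarray


def add_pseudocount(counts: CountMatrix, pseudocount: int = 1) -> CountMatrix:
    """Return a copy of ``counts`` with ``pseudocount`` added to every entry."""
    return CountMatrix(
        gene_ids=counts.gene_ids,
        sample_ids=counts.sample_ids,
        counts=counts.counts + pseudocount,
    )


def deseq_size_factors(counts: np.ndarray | CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, one per sample (column).

    Requires strictly positive entries (apply the pseudocount first).
    """
    values = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    if np.any(values <= 0):
        raise ValueError(
            "size factors need strictly positive counts; add the pseudocount first"
        )
    log_values = np.log(values.astype(float))
    log_geo_mean = log_values.mean(axis=1, keepdims=True)
    return np.exp(np.median(log_values - log_geo_mean, axis=0))


def normalize(counts: CountMatrix, pseudocount: int = 1) -> NormalizedMatrix:
    """Pseudocount + median-of-ratios normalization of a raw count matrix."""
    shifted = add_pseudocount(counts, pseudocount)
    factors = deseq_size_factors(shifted)
    return NormalizedMatrix(
        gene_ids=counts.gene_ids,
        sample_ids=counts.sample_ids,
        values=shifted.counts / factors[np.newaxis, :],
        size_factors=factors,
    )


def filter_gene_sets(
    sets: GeneSetCollection,
    data_genes,
    min_size: int = 15,
    max_size: int = 100,
) -> GeneSetCollection:
    """Intersect sets with the measured genes and keep sizes in [min, max].

    The retained sets store the intersected gene lists, so downstream SIZE
    reflects genes actually present in the data. Idempotent.
    """
    if min_size < 1 or max_size < min_size:
        raise ValueError("need 1 <= min_size <= max_size")
    present = set(map(str, data_genes))
    kept: dict[str, GeneSet] = {}
    for name, gs in sets:
        genes = tuple(g for g in gs.genes if g in present)
        if min_size <= len(genes) <= max_size:
            kept[name] = GeneSet(gs.description, genes)
    if not kept:
        warnings.warn(
            f"no gene set has between {min_size} and {max_size} measured genes",
            stacklevel=2,
        )
    return GeneSetCollection(kept)


class MedianOfRatiosNormalizer(BaseEstimator, TransformerMixin):
    """Median-of-ratios normalization as a scikit-learn transformer.

    Follows the sklearn orientation: ``X`` is samples x genes. ``fit`` stores
    the per-gene log geometric mean of the (pseudocounted) training data as
    the reference profile; ``transform`` computes, for each sample, the
    median ratio of its pseudocounted counts to that reference and divides
    the sample by it. ``fit_transform`` on the training matrix therefore
    reproduces the classic normalization exactly.

    Parameters
    ----------
    pseudocount : int, default=1
        Added to every count before taking logs, so zeros are allowed.

    Attributes
    ----------
    reference_log_means_ : ndarray of shape (n_genes,)
        Per-gene mean log pseudocounted count of the training samples.
    size_factors_ : ndarray of shape (n_samples,)
        Size factors of the training samples.
    """

    def __init__(self, pseudocount: int = 1):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("counts must be nonnegative")
        log_shifted = np.log(X + self.pseudocount)
        self.n_features_in_ = X.shape[1]
        self.reference_log_means_ = log_shifted.mean(axis=0)
        self.size_factors_ = np.exp(
            np.median(log_shifted - self.reference_log_means_, axis=1)
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_log_means_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} genes, expected {self.n_features_in_}"
            )
        shifted = X + self.pseudocount
        factors = np.exp(
            np.median(np.log(shifted) - self.reference_log_means_, axis=1)
        )
        return shifted / factors[:, np.newaxis]
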