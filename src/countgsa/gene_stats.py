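"""Per-gene differential expression scores and permutation p-values.

Three gene-level statistics are implemented, all signed with the convention
reference class minus comparison class (``class_order[0] - class_order[1]``):

* ``signal2noise`` — (mean1 - mean2) / (sd1 + sd2), with each class standard
  deviation floored at max(sd, 0.2 * |class mean|, 1e-8). This floor guards
  near-constant genes and follows the convention of the classic enrichment
  tools this statistic comes from.
* ``log2ratio`` — log2(mean1 / mean2); requires strictly positive values,
  which the pseudocount guarantees.
* ``signal2noise_log2ratio`` — sign-preserving geometric mean of the two:
  sign(M) * sqrt(|S| * |M|) with S = signal2noise and M = log2ratio. It is
  antisymmetric under class swap and zero iff either component is zero.

Per-gene empirical p-values are two-sided and pooled per gene: each gene's
observed |score| is compared against that gene's own null of N permutation
scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import PhenotypeLabels
from .preprocess import NormalizedMatrix

GENE_STATS = ("signal2noise", "log2ratio", "signal2noise_log2ratio")

_SD_FLOOR_FRACTION = 0.2
_SD_FLOOR_ABS = 1e-8


@dataclass
class GeneStatResult:
    """Observed and permuted gene-level scores with their empirical p-values.

    ``perm_scores``/``perm_pvalues`` have one column per permutation and may
    be None when no permutations were run.
    """

    gene_ids: np.ndarray
    scores: np.ndarray
    perm_scores: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    perm_pvalues: np.ndarray | None = None

    @property
    def n_permutations(self) -> int:
        return 0 if self.perm_scores is None else self.perm_scores.shape[1]


def _values_and_mask(values, labels):
    if isinstance(values, NormalizedMatrix):
        mat = values.values
    else:
        mat = np.asarray(values, dtype=float)
    if isinstance(labels, PhenotypeLabels):
        mask = labels.mask()
    else:
        mask = np.asarray(labels, dtype=bool)
    if mat.shape[1] != mask.shape[0]:
        raise ValueError("values and labels disagree on the number of samples")
    return mat, mask


def _class_moments(mat: np.ndarray, masks: np.ndarray):
    """Means and ddof-1 standard deviations of both classes.

    ``masks`` is (n_samples, K) boolean, one column per label assignment, so
    the permuted statistics are two matrix products away from the observed
    ones. Returns arrays of shape (n_genes, K).
    """
    masks = masks.astype(float)
    n1 = masks.sum(axis=0)
    n2 = masks.shape[0] - n1
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("each class needs at least 2 samples")
    s1 = mat @ masks
    sq1 = (mat**2) @ masks
    tot = mat.sum(axis=1, keepdims=True)
    sqtot = (mat**2).sum(axis=1, keepdims=True)
    m1 = s1 / n1
    m2 = (tot - s1) / n2
    var1 = np.maximum(sq1 - n1 * m1**2, 0.0) / (n1 - 1)
    var2 = np.maximum((sqtot - sq1) - n2 * m2**2, 0.0) / (n2 - 1)
    return m1, m2, np.sqrt(var1), np.sqrt(var2)


def _floor_sd(sd: np.ndarray, mean: np.ndarray) -> np.ndarray:
    return np.maximum(sd, np.maximum(_SD_FLOOR_FRACTION * np.abs(mean), _SD_FLOOR_ABS))


def _scores_for_masks(mat: np.ndarray, masks: np.ndarray, stat: str) -> np.ndarray:
    m1, m2, sd1, sd2 = _class_moments(mat, masks)
    if stat == "signal2noise":
        return (m1 - m2) / (_floor_sd(sd1, m1) + _floor_sd(sd2, m2))
    if stat == "log2ratio":
        if np.any(m1 <= 0) or np.any(m2 <= 0):
            raise ValueError("log2ratio needs strictly positive values")
        return np.log2(m1 / m2)
    if stat == "signal2noise_log2ratio":
        s = (m1 - m2) / (_floor_sd(sd1, m1) + _floor_sd(sd2, m2))
        if np.any(m1 <= 0) or np.any(m2 <= 0):
            raise ValueError("signal2noise_log2ratio needs strictly positive values")
        m = np.log2(m1 / m2)
        return np.sign(m) * np.sqrt(np.abs(s) * np.abs(m))
    raise ValueError(f"unknown gene statistic {stat!r}; choose from {GENE_STATS}")


def gene_scores(values, labels, stat: str = "signal2noise") -> np.ndarray:
    """Observed per-gene scores for one of the three gene-level statistics."""
    mat, mask = _values_and_mask(values, labels)
    return _scores_for_masks(mat, mask[:, np.newaxis], stat)[:, 0]


def signal2noise(values, labels) -> np.ndarray:
    return gene_scores(values, labels, "signal2noise")


def log2ratio(values, labels) -> np.ndarray:
    return gene_scores(values, labels, "log2ratio")


def signal2noise_log2ratio(values, labels) -> np.ndarray:
    return gene_scores(values, labels, "signal2noise_log2ratio")


def permuted_gene_scores(values, labels, masks: np.ndarray, stat: str) -> np.ndarray:
    """Scores for every permuted label assignment.

    ``masks`` is (n_samples, N) boolean with one column per permutation;
    returns an (n_genes, N) array.
    """
    mat, _ = _values_and_mask(values, labels)
    return _scores_for_masks(mat, masks, stat)


def gene_pvalues(observed: np.ndarray, null: np.ndarray):
    """Two-sided per-gene empirical p-values, pooled per gene.

    The observed and permuted score columns of a gene are treated
    symmetrically: each column is compared, leave-self-out, against the
    other N columns of the pool, so p(column) = #{other columns with
    |score| at least as large} / N. For the observed column this is exactly
    p(g) = #{pi : |null[g, pi]| >= |observed[g]|} / N, and under an
    exchangeable null every column's p-value is uniform on {0, 1/N, ..., 1}.

    Returns ``(pvalues, perm_pvalues)`` of shapes (G,) and (G, N).
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if null.ndim != 2 or null.shape[0] != observed.shape[0]:
        raise ValueError("null must be (n_genes, n_permutations)")
    n = null.shape[1]
    if n < 1:
        raise ValueError("at least one permutation is required")
    pool = np.abs(np.column_stack([observed, null]))
    sorted_pool = np.sort(pool, axis=1)
    p_all = np.empty_like(pool)
    for g in range(pool.shape[0]):
        row = sorted_pool[g]
        # count of pool values >= v includes self; leave-self-out divides by N
        p_all[g] = (n + 1 - np.searchsorted(row, pool[g], side="left") - 1) / n
    return p_all[:, 0], p_all[:, 1:]


def crossgene_pvalues(scores: np.ndarray) -> np.ndarray:
    """One p-value per gene from the cross-gene score distribution.

    Used by the gene-permutation strategy, where no label permutations exist
    to build per-gene nulls: p(g) = #{g' : |s(g')| >= |s(g)|} / G.
    """
    a = np.abs(np.asarray(scores, dtype=float))
    order = np.sort(a)
    g = a.shape[0]
    return (g - np.searchsorted(order, a, side="left")) / g
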