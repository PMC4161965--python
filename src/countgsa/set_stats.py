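"""Gene set association scores (AS): ten set-level statistics.

Three input families:

* score based — ``weighted_ks``, ``l2norm``, ``mean``, ``weighted_sig_ratio``,
  ``sig_ratio`` (the last two also use gene p-values to decide significance);
* p-value based — ``geometric_mean``, ``truncated_product``, ``fisher``,
  ``min_p``;
* rank based — ``rank_sum`` (genes ranked by significance across the whole
  genome, rank 1 = smallest gene p-value, ties by larger |score|, average
  ranks for exact ties).

Each statistic carries a fixed tail: for ``geometric_mean``,
``truncated_product``, ``min_p`` and ``rank_sum`` smaller values are more
significant; for the rest larger values are. ``weighted_ks`` is signed and is
handled with the same-sign convention in :mod:`countgsa.significance`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

GREATER = "greater_is_significant"
SMALLER = "smaller_is_significant"


@dataclass(frozen=True)
class SetStatSpec:
    """Name, input family, significance tail and parameters of a set statistic."""

    name: str
    family: str  # score | pvalue | rank
    tail: str
    signed: bool = False
    ks_exponent: float = 1.0
    alpha: float = 0.05
    tau: float = 0.05


_SPECS = {
    "weighted_ks": SetStatSpec("weighted_ks", "score", GREATER, signed=True),
    "l2norm": SetStatSpec("l2norm", "score", GREATER),
    "mean": SetStatSpec("mean", "score", GREATER),
    "weighted_sig_ratio": SetStatSpec("weighted_sig_ratio", "score", GREATER),
    "sig_ratio": SetStatSpec("sig_ratio", "score", GREATER),
    "geometric_mean": SetStatSpec("geometric_mean", "pvalue", SMALLER),
    "truncated_product": SetStatSpec("truncated_product", "pvalue", SMALLER),
    "fisher": SetStatSpec("fisher", "pvalue", GREATER),
    "min_p": SetStatSpec("min_p", "pvalue", SMALLER),
    "rank_sum": SetStatSpec("rank_sum", "rank", SMALLER),
}

SET_STATS = tuple(_SPECS)

# Statistics whose AS uses gene p-values (for deciding significance or as the
# combined quantity itself); rank_sum needs them to order genes.
_NEEDS_PVALUES = {
    "weighted_sig_ratio",
    "sig_ratio",
    "geometric_mean",
    "truncated_product",
    "fisher",
    "min_p",
    "rank_sum",
}


def get_spec(
    name: str,
    ks_exponent: float = 1.0,
    alpha: float = 0.05,
    tau: float = 0.05,
) -> SetStatSpec:
    try:
        spec = _SPECS[name]
    except KeyError:
        raise ValueError(
            f"unknown set statistic {name!r}; choose from {sorted(_SPECS)}"
        ) from None
    return replace(spec, ks_exponent=ks_exponent, alpha=alpha, tau=tau)


def needs_pvalues(spec: SetStatSpec) -> bool:
    return spec.name in _NEEDS_PVALUES


# ---------------------------------------------------------------------------
# single-set, single-column statistics
# ---------------------------------------------------------------------------


def weighted_ks(
    gene_scores: np.ndarray, member_flags: np.ndarray, weight_exponent: float = 1.0
) -> float:
    """Signed weighted Kolmogorov–Smirnov running-sum statistic.

    Genes are ranked by decreasing score (stable ties); the running sum gains
    |score|^p / sum_set |score|^p at member genes and loses 1/(G - k) at
    non-members; the statistic is the running-sum value of maximal absolute
    deviation from zero.
    """
    s = np.asarray(gene_scores, dtype=float)
    member = np.asarray(member_flags, dtype=bool)
    g = s.shape[0]
    k = int(member.sum())
    if k == 0:
        raise ValueError("empty gene set")
    if k >= g:
        raise ValueError("gene set covers all genes; KS statistic undefined")
    order = np.argsort(-s, kind="stable")
    member_sorted = member[order]
    w = np.abs(s[order]) ** weight_exponent
    hit_w = np.where(member_sorted, w, 0.0)
    total = hit_w.sum()
    if total == 0.0:
        hit = member_sorted / k  # all member weights zero: fall back to equal steps
    else:
        hit = hit_w / total
    miss = (~member_sorted) / (g - k)
    running = np.cumsum(hit - miss)
    mx, mn = running.max(), running.min()
    # maximal absolute deviation, signed; an exact tie goes to the positive side
    return float(mx if mx >= -mn else mn)


def l2norm(set_scores: np.ndarray) -> float:
    s = np.asarray(set_scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty gene set")
    return float(np.sqrt(np.sum(s**2)))


def mean_abs(set_scores: np.ndarray) -> float:
    s = np.asarray(set_scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty gene set")
    return float(np.mean(np.abs(s)))


def sig_ratio(set_pvalues: np.ndarray, alpha: float = 0.05) -> float:
    """Fraction of member genes significant at level ``alpha`` (p <= alpha)."""
    p = np.asarray(set_pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty gene set")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(np.mean(p <= alpha))


def weighted_sig_ratio(
    set_scores: np.ndarray, set_pvalues: np.ndarray, alpha: float = 0.05
) -> float:
    """Significance fraction weighted by |score|: sum_{p<=alpha} |s| / size."""
    s = np.asarray(set_scores, dtype=float)
    p = np.asarray(set_pvalues, dtype=float)
    if s.size == 0:
        raise ValueError("empty gene set")
    if s.shape != p.shape:
        raise ValueError("scores and p-values must align")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(np.sum(np.abs(s)[p <= alpha]) / s.size)


def geometric_mean_p(set_pvalues: np.ndarray, eps: float = 0.0) -> float:
    p = np.asarray(set_pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty gene set")
    p = np.maximum(p, eps) if eps > 0 else p
    if np.any(p <= 0):
        raise ValueError("p-values must be positive (pass eps to clamp zeros)")
    return float(np.exp(np.mean(np.log(p))))


def truncated_product(set_pvalues: np.ndarray, tau: float = 0.05) -> float:
    """Zaykin truncated product: product of member p-values <= tau (1 if none)."""
    p = np.asarray(set_pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty gene set")
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    kept = p[p <= tau]
    return float(np.prod(kept)) if kept.size else 1.0


def fisher_method(set_pvalues: np.ndarray, eps: float = 0.0) -> float:
    p = np.asarray(set_pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty gene set")
    p = np.maximum(p, eps) if eps > 0 else p
    if np.any(p <= 0):
        raise ValueError("p-values must be positive (pass eps to clamp zeros)")
    return float(-2.0 * np.sum(np.log(p)))


def min_p(set_pvalues: np.ndarray) -> float:
    p = np.asarray(set_pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty gene set")
    return float(np.min(p))


def significance_ranks(pvalues: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Genome-wide significance ranks: 1 = most significant.

    Primary key: gene p-value ascending; tie-break: |score| descending; exact
    ties get the average of the positions they span.
    """
    p = np.asarray(pvalues, dtype=float)
    a = np.abs(np.asarray(scores, dtype=float))
    g = p.shape[0]
    order = np.lexsort((-a, p))
    ps, aa = p[order], a[order]
    new_group = np.r_[True, (ps[1:] != ps[:-1]) | (aa[1:] != aa[:-1])]
    group = np.cumsum(new_group) - 1
    positions = np.arange(1, g + 1, dtype=float)
    avg = np.bincount(group, weights=positions) / np.bincount(group)
    ranks = np.empty(g)
    ranks[order] = avg[group]
    return ranks


def rank_sum(global_ranks: np.ndarray, member_flags: np.ndarray) -> float:
    """Sum of the members' genome-wide significance ranks (smaller = stronger)."""
    r = np.asarray(global_ranks, dtype=float)
    member = np.asarray(member_flags, dtype=bool)
    if not member.any():
        raise ValueError("empty gene set")
    return float(r[member].sum())


# ---------------------------------------------------------------------------
# vectorized AS over all sets and all (observed + permuted) columns
# ---------------------------------------------------------------------------


def _ks_all_sets(scores_col, membership, sizes, exponent):
    """Weighted KS for every set on one score column. membership: (m, G) bool."""
    g = scores_col.shape[0]
    order = np.argsort(-scores_col, kind="stable")
    member_sorted = membership[:, order]
    w = np.abs(scores_col[order]) ** exponent
    hit_w = member_sorted * w[np.newaxis, :]
    totals = hit_w.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0.0
    if np.any(zero):
        hit_w[zero] = member_sorted[zero] / sizes[zero, np.newaxis]
        totals[zero] = 1.0
    miss_step = 1.0 / (g - sizes)
    running = np.cumsum(
        hit_w / totals - (~member_sorted) * miss_step[:, np.newaxis], axis=1
    )
    mx = running.max(axis=1)
    mn = running.min(axis=1)
    return np.where(mx >= -mn, mx, mn)


def compute_all_as(
    spec: SetStatSpec,
    scores: np.ndarray,
    pvalues: np.ndarray | None,
    membership: np.ndarray,
    p_floor: float = 0.0,
) -> np.ndarray:
    """AS for every set (rows) and every column of ``scores``/``pvalues``.

    ``scores`` and ``pvalues`` are (n_genes, n_columns); column 0 is normally
    the observed data and the rest are permutations, but every column goes
    through the identical code path. ``membership`` is (n_sets, n_genes)
    boolean. ``p_floor`` clamps p-values before logarithms (geometric mean /
    Fisher), keeping them finite when an empirical gene p-value is exactly 0.
    """
    membership = np.asarray(membership, dtype=bool)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    m, g = membership.shape
    if scores.shape[0] != g:
        raise ValueError("scores and membership disagree on the number of genes")
    sizes = membership.sum(axis=1)
    if np.any(sizes == 0):
        raise ValueError("empty gene set in membership matrix")
    if needs_pvalues(spec):
        if pvalues is None:
            raise ValueError(f"{spec.name} requires gene p-values")
        pvalues = np.atleast_2d(np.asarray(pvalues, dtype=float))
        if pvalues.shape != scores.shape:
            raise ValueError("pvalues must have the same shape as scores")
    mem_f = membership.astype(float)

    if spec.name == "l2norm":
        return np.sqrt(mem_f @ (scores**2))
    if spec.name == "mean":
        return (mem_f @ np.abs(scores)) / sizes[:, np.newaxis]
    if spec.name == "sig_ratio":
        return (mem_f @ (pvalues <= spec.alpha)) / sizes[:, np.newaxis]
    if spec.name == "weighted_sig_ratio":
        return (mem_f @ (np.abs(scores) * (pvalues <= spec.alpha))) / sizes[
            :, np.newaxis
        ]
    if spec.name == "geometric_mean":
        logs = np.log(np.maximum(pvalues, max(p_floor, 1e-300)))
        return np.exp((mem_f @ logs) / sizes[:, np.newaxis])
    if spec.name == "fisher":
        logs = np.log(np.maximum(pvalues, max(p_floor, 1e-300)))
        return -2.0 * (mem_f @ logs)
    if spec.name == "truncated_product":
        logs = np.where(pvalues <= spec.tau, np.log(np.maximum(pvalues, 1e-300)), 0.0)
        return np.exp(mem_f @ logs)
    if spec.name == "min_p":
        out = np.empty((m, scores.shape[1]))
        for i in range(m):
            out[i] = pvalues[membership[i]].min(axis=0)
        return out
    if spec.name == "rank_sum":
        ranks = np.empty_like(scores)
        for c in range(scores.shape[1]):
            ranks[:, c] = significance_ranks(pvalues[:, c], scores[:, c])
        return mem_f @ ranks
    if spec.name == "weighted_ks":
        if np.any(sizes >= g):
            raise ValueError("a gene set covers all genes; KS statistic undefined")
        out = np.empty((m, scores.shape[1]))
        for c in range(scores.shape[1]):
            out[:, c] = _ks_all_sets(scores[:, c], membership, sizes, spec.ks_exponent)
        return out
    raise ValueError(f"unknown set statistic {spec.name!r}")
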