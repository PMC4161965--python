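"""Permutation engine, NAS normalization, empirical p-values, FDR and FWER.

The null distribution of every set-level association score (AS) is built by
permutation: either sample permutation (shuffling phenotype labels, which
preserves gene–gene correlation) or gene permutation (shuffling the observed
gene scores across gene identities). Each AS is normalized by the mean of its
own permutation null (NAS); p-values, FDRs and FWERs are then one-sided on
the statistic's natural scale — larger-is-significant for the score/Fisher
family, smaller-is-significant for the p-value/rank family.

The signed weighted KS statistic is the exception: its NAS, p-value, FDR and
FWER are computed within same-sign groups (positive scores against the
positive part of the null, negative against the negative part), the
convention of the enrichment tools this statistic comes from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneSetCollection, PhenotypeLabels, align
from .gene_stats import (
    crossgene_pvalues,
    gene_pvalues,
    gene_scores,
    permuted_gene_scores,
)
from .io import RESULT_COLUMNS
from .preprocess import filter_gene_sets, normalize
from .set_stats import (
    GREATER,
    SMALLER,
    SetStatSpec,
    compute_all_as,
    get_spec,
    needs_pvalues,
)


@dataclass
class PermutationPlan:
    """N stored index permutations, reproducible from a single seed.

    ``mode="sample"``: each row permutes the sample indices; applying it to
    the label vector yields a shuffled assignment with the original class
    sizes. ``mode="gene"``: each row permutes gene indices; gene scores and
    p-values are shuffled across gene identities while labels stay fixed.
    """

    mode: str
    n_permutations: int
    seed: int
    permutations: np.ndarray  # (N, n_items) integer index vectors

    def masks(self, base_mask: np.ndarray) -> np.ndarray:
        """(n_samples, N) boolean class-membership masks for sample mode."""
        if self.mode != "sample":
            raise ValueError("masks are only defined for sample permutations")
        return np.asarray(base_mask, dtype=bool)[self.permutations].T


def make_permutations(
    n_items: int | PhenotypeLabels,
    mode: str = "sample",
    n_permutations: int = 2000,
    seed: int = 0,
) -> PermutationPlan:
    """Draw ``n_permutations`` uniform index permutations.

    ``n_items`` is the number of samples (sample mode, or pass the labels
    object) or the number of genes (gene mode).
    """
    if mode not in ("sample", "gene"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    if n_permutations < 1:
        raise ValueError("at least one permutation is required")
    if isinstance(n_items, PhenotypeLabels):
        n_items = n_items.n_samples
    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations, n_items), dtype=np.int64)
    for i in range(n_permutations):
        perms[i] = rng.permutation(n_items)
    return PermutationPlan(mode, n_permutations, int(seed), perms)


# ---------------------------------------------------------------------------
# NAS normalization
# ---------------------------------------------------------------------------


def nas(as_observed: float, as_null: np.ndarray, signed: bool = False) -> float:
    """Normalized association score of a single set: AS over its null mean.

    For the signed KS statistic the observed AS is divided by the mean of
    the same-signed null values, preserving sign. An empty or zero-mean sign
    group yields NAS 0 with a warning.
    """
    obs, null = normalize_scores(
        np.asarray([as_observed], dtype=float),
        np.asarray(as_null, dtype=float)[np.newaxis, :],
        signed=signed,
    )
    return float(obs[0])


def normalize_scores(
    as_observed: np.ndarray, as_null: np.ndarray, signed: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """NAS for the observed ASs and for every null AS, set by set.

    Returns ``(nas_observed, nas_null)`` of shapes (m,) and (m, N).
    """
    as_observed = np.asarray(as_observed, dtype=float)
    as_null = np.asarray(as_null, dtype=float)
    if not signed:
        means = as_null.mean(axis=1)
        bad = means == 0.0
        if np.any(bad):
            warnings.warn(
                f"{int(bad.sum())} set(s) have a zero null mean; NAS reported as 0",
                stacklevel=2,
            )
        safe = np.where(bad, 1.0, means)
        nas_obs = np.where(bad, 0.0, as_observed / safe)
        nas_null = np.where(bad[:, np.newaxis], 0.0, as_null / safe[:, np.newaxis])
        return nas_obs, nas_null

    pos = as_null >= 0.0
    neg = ~pos
    n_pos = pos.sum(axis=1)
    n_neg = neg.sum(axis=1)
    with np.errstate(invalid="ignore"):
        pos_mean = np.where(n_pos > 0, (as_null * pos).sum(axis=1), 0.0) / np.maximum(
            n_pos, 1
        )
        neg_mean_abs = np.abs(
            np.where(n_neg > 0, (as_null * neg).sum(axis=1), 0.0)
        ) / np.maximum(n_neg, 1)
    bad_pos = pos_mean <= 0.0
    bad_neg = neg_mean_abs <= 0.0
    if np.any(bad_pos & (as_observed >= 0)) or np.any(bad_neg & (as_observed < 0)):
        warnings.warn(
            "empty or zero-mean sign group in the KS null; NAS reported as 0",
            stacklevel=2,
        )

    def _norm(values: np.ndarray) -> np.ndarray:
        vpos = values >= 0.0
        out = np.where(
            vpos,
            np.where(bad_pos[:, None], 0.0, values / np.where(bad_pos, 1.0, pos_mean)[:, None]),
            np.where(bad_neg[:, None], 0.0, values / np.where(bad_neg, 1.0, neg_mean_abs)[:, None]),
        )
        return out

    nas_obs = _norm(as_observed[:, np.newaxis])[:, 0]
    nas_null = _norm(as_null)
    return nas_obs, nas_null


# ---------------------------------------------------------------------------
# empirical significance
# ---------------------------------------------------------------------------


def empirical_p(as_observed, as_null, tail: str = GREATER) -> np.ndarray:
    """One-sided empirical p-value(s): #{pi : AS_pi tail AS_0} / N, ties in tail."""
    obs = np.atleast_1d(np.asarray(as_observed, dtype=float))
    null = np.asarray(as_null, dtype=float)
    if null.ndim == 1:
        null = np.broadcast_to(null, (obs.shape[0], null.shape[0]))
    if null.shape[1] < 1:
        raise ValueError("at least one permutation is required")
    if tail == GREATER:
        return (null >= obs[:, np.newaxis]).mean(axis=1)
    if tail == SMALLER:
        return (null <= obs[:, np.newaxis]).mean(axis=1)
    raise ValueError(f"unknown tail {tail!r}")


def empirical_p_signed(as_observed: np.ndarray, as_null: np.ndarray) -> np.ndarray:
    """Same-sign empirical p for the signed KS: each set against its own
    same-signed null values (p = 1 when the sign group is empty)."""
    obs = np.asarray(as_observed, dtype=float)
    null = np.asarray(as_null, dtype=float)
    out = np.empty(obs.shape[0])
    for i, v in enumerate(obs):
        group = null[i][null[i] >= 0.0] if v >= 0.0 else null[i][null[i] < 0.0]
        if group.size == 0:
            out[i] = 1.0
        elif v >= 0.0:
            out[i] = np.mean(group >= v)
        else:
            out[i] = np.mean(group <= v)
    return out


def fdr(nas_observed: np.ndarray, nas_null: np.ndarray, tail: str = GREATER) -> np.ndarray:
    """Permutation FDR on the NAS scale, pooled over all sets.

    FDR(S_i) = mean over all null NAS of I(null tail NAS_i), divided by the
    mean over observed NAS of I(observed tail NAS_i), clipped to [0, 1].
    """
    obs = np.asarray(nas_observed, dtype=float)
    null = np.asarray(nas_null, dtype=float)
    pooled = np.sort(null.ravel())
    obs_sorted = np.sort(obs)
    if tail == GREATER:
        num = pooled.size - np.searchsorted(pooled, obs, side="left")
        den = obs.size - np.searchsorted(obs_sorted, obs, side="left")
    elif tail == SMALLER:
        num = np.searchsorted(pooled, obs, side="right")
        den = np.searchsorted(obs_sorted, obs, side="right")
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return np.clip((num / pooled.size) / (den / obs.size), 0.0, 1.0)


def fdr_signed(nas_observed: np.ndarray, nas_null: np.ndarray) -> np.ndarray:
    """Same-sign pooled FDR for the signed KS NAS values."""
    obs = np.asarray(nas_observed, dtype=float)
    null = np.asarray(nas_null, dtype=float).ravel()
    out = np.empty(obs.shape[0])
    null_pos = null[null >= 0.0]
    null_neg = null[null < 0.0]
    obs_pos = obs[obs >= 0.0]
    obs_neg = obs[obs < 0.0]
    for i, v in enumerate(obs):
        if v >= 0.0:
            num = np.mean(null_pos >= v) if null_pos.size else 0.0
            den = np.mean(obs_pos >= v)
        else:
            num = np.mean(null_neg <= v) if null_neg.size else 0.0
            den = np.mean(obs_neg <= v)
        out[i] = min(num / den, 1.0) if den > 0 else 1.0
    return out


def fwer(nas_observed: np.ndarray, nas_null: np.ndarray, tail: str = GREATER) -> np.ndarray:
    """Permutation FWER: fraction of permutations whose most extreme NAS
    (max for the larger-is-significant family, min for the other) reaches the
    observed NAS."""
    obs = np.asarray(nas_observed, dtype=float)
    null = np.asarray(nas_null, dtype=float)
    if tail == GREATER:
        extremes = null.max(axis=0)
        return (extremes[np.newaxis, :] >= obs[:, np.newaxis]).mean(axis=1)
    if tail == SMALLER:
        extremes = null.min(axis=0)
        return (extremes[np.newaxis, :] <= obs[:, np.newaxis]).mean(axis=1)
    raise ValueError(f"unknown tail {tail!r}")


def fwer_signed(nas_observed: np.ndarray, nas_null: np.ndarray) -> np.ndarray:
    obs = np.asarray(nas_observed, dtype=float)
    null = np.asarray(nas_null, dtype=float)
    colmax = null.max(axis=0)
    colmin = null.min(axis=0)
    out = np.empty(obs.shape[0])
    for i, v in enumerate(obs):
        out[i] = np.mean(colmax >= v) if v >= 0.0 else np.mean(colmin <= v)
    return out


# ---------------------------------------------------------------------------
# result assembly and full pipeline
# ---------------------------------------------------------------------------


def sort_results(table: pd.DataFrame, spec: SetStatSpec) -> pd.DataFrame:
    """FDR ascending, ties by NAS extremity (more extreme first), then name."""
    if spec.signed:
        nas_key = -table["NAS"].abs()
    elif spec.tail == GREATER:
        nas_key = -table["NAS"]
    else:
        nas_key = table["NAS"]
    order = np.lexsort((table["NAME"].to_numpy(), nas_key.to_numpy(), table["FDR"].to_numpy()))
    return table.iloc[order].reset_index(drop=True)


def run_analysis(
    counts: CountMatrix,
    labels: PhenotypeLabels,
    sets: GeneSetCollection,
    gene_stat: str = "signal2noise",
    set_stat: str = "l2norm",
    n_permutations: int = 2000,
    permutation_mode: str = "sample",
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 100,
    alpha: float = 0.05,
    tau: float = 0.05,
    ks_exponent: float = 1.0,
    filter_sets: bool = True,
) -> pd.DataFrame:
    """Full pipeline: normalize, gene stats, AS, NAS, p/FDR/FWER, sorted table."""
    labels = align(counts, labels)
    spec = get_spec(set_stat, ks_exponent=ks_exponent, alpha=alpha, tau=tau)
    norm = normalize(counts)
    if filter_sets:
        sets = filter_gene_sets(sets, counts.gene_ids, min_size, max_size)
    if len(sets) == 0:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    membership = sets.membership_matrix(counts.gene_ids)
    present = membership.any(axis=1)
    if not present.all():
        raise ValueError("gene set with no measured genes; filter sets first")

    observed = gene_scores(norm, labels, gene_stat)
    n = n_permutations
    p_floor = 1.0 / (10.0 * n)
    if permutation_mode == "sample":
        plan = make_permutations(labels, "sample", n, seed)
        perm_scores = permuted_gene_scores(norm, labels, plan.masks(labels.mask()), gene_stat)
        if needs_pvalues(spec):
            pvals, perm_pvals = gene_pvalues(observed, perm_scores)
            pvalues_mat = np.column_stack([pvals, perm_pvals])
        else:
            pvalues_mat = None
        scores_mat = np.column_stack([observed, perm_scores])
    elif permutation_mode == "gene":
        plan = make_permutations(counts.n_genes, "gene", n, seed)
        scores_mat = np.column_stack([observed, observed[plan.permutations.T]])
        if needs_pvalues(spec):
            pvals = crossgene_pvalues(observed)
            pvalues_mat = np.column_stack([pvals, pvals[plan.permutations.T]])
        else:
            pvalues_mat = None
    else:
        raise ValueError(f"unknown permutation mode {permutation_mode!r}")

    as_all = compute_all_as(spec, scores_mat, pvalues_mat, membership, p_floor=p_floor)
    as_obs, as_null = as_all[:, 0], as_all[:, 1:]
    nas_obs, nas_null = normalize_scores(as_obs, as_null, signed=spec.signed)
    if spec.signed:
        p = empirical_p_signed(as_obs, as_null)
        q = fdr_signed(nas_obs, nas_null)
        w = fwer_signed(nas_obs, nas_null)
    else:
        p = empirical_p(as_obs, as_null, spec.tail)
        q = fdr(nas_obs, nas_null, spec.tail)
        w = fwer(nas_obs, nas_null, spec.tail)

    sizes = membership.sum(axis=1)
    table = pd.DataFrame(
        {
            "NAME": sets.names(),
            "SIZE": sizes.astype(int),
            "AS": as_obs,
            "NAS": nas_obs,
            "P-VALUE": p,
            "FDR": q,
            "FWER": w,
        }
    )
    return sort_results(table, spec)
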