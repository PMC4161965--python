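"""scikit-learn-style front end for the permutation gene set association test.

``GeneSetAssociation`` follows the sklearn estimator contract (``fit``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so it
composes with sklearn model-selection utilities; the functional pipeline it
wraps lives in :mod:`countgsa.significance`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import CountMatrix, GeneSetCollection, PhenotypeLabels
from .significance import run_analysis


class GeneSetAssociation(BaseEstimator):
    """Two-group gene set association test for RNA-seq counts.

    ``fit(X, y)`` takes a samples-by-genes raw count matrix and binary
    phenotype labels, runs the full permutation pipeline (median-of-ratios
    normalization, per-gene differential expression scores, set-level
    association scores on observed and permuted data, NAS normalization,
    empirical p-values, FDR, FWER) and stores the ranked result table.

    Parameters
    ----------
    gene_sets : mapping or GeneSetCollection
        Named gene sets (name -> iterable of gene identifiers).
    gene_stat : {"signal2noise", "log2ratio", "signal2noise_log2ratio"}
    set_stat : one of the ten set statistics, e.g. "l2norm", "weighted_ks".
    n_permutations : int, default=2000
    permutation_mode : {"sample", "gene"}, default="sample"
    min_size, max_size : int
        Retained sets have between min_size and max_size measured genes.
    alpha : float
        Gene-level significance threshold of sig_ratio / weighted_sig_ratio.
    tau : float
        Truncation threshold of the truncated product.
    ks_exponent : float
        Weight exponent of the weighted KS running sum.
    class_order : tuple of two labels or None
        Direction of the signed statistics (first minus second); None means
        order of first appearance in ``y``.
    random_state : int, default=0
        Seed for the permutation stream.

    Attributes
    ----------
    results_ : DataFrame with columns NAME, SIZE, AS, NAS, P-VALUE, FDR, FWER,
        sorted by FDR then NAS extremity.
    gene_ids_ : ndarray of the gene identifiers used.
    classes_ : the two phenotype labels in scoring order.
    n_sets_ : number of sets retained after size filtering.

    Examples
    --------
    >>> import numpy as np, pandas as pd
    >>> rng = np.random.default_rng(0)
    >>> X = pd.DataFrame(rng.poisson(30, (12, 40)),
    ...                  columns=[f"G{i}" for i in range(40)])
    >>> y = ["A"] * 6 + ["B"] * 6
    >>> sets = {"S1": [f"G{i}" for i in range(20)],
    ...         "S2": [f"G{i}" for i in range(20, 40)]}
    >>> gsa = GeneSetAssociation(sets, n_permutations=100).fit(X, y)
    >>> list(gsa.results_.columns)
    ['NAME', 'SIZE', 'AS', 'NAS', 'P-VALUE', 'FDR', 'FWER']
    """

    def __init__(
        self,
        gene_sets=None,
        gene_stat: str = "signal2noise",
        set_stat: str = "l2norm",
        n_permutations: int = 2000,
        permutation_mode: str = "sample",
        min_size: int = 15,
        max_size: int = 100,
        alpha: float = 0.05,
        tau: float = 0.05,
        ks_exponent: float = 1.0,
        class_order=None,
        random_state: int = 0,
    ):
        self.gene_sets = gene_sets
        self.gene_stat = gene_stat
        self.set_stat = set_stat
        self.n_permutations = n_permutations
        self.permutation_mode = permutation_mode
        self.min_size = min_size
        self.max_size = max_size
        self.alpha = alpha
        self.tau = tau
        self.ks_exponent = ks_exponent
        self.class_order = class_order
        self.random_state = random_state

    def fit(self, X, y):
        """Run the association analysis on counts ``X`` (samples x genes)."""
        if self.gene_sets is None:
            raise ValueError("gene_sets must be provided")
        if isinstance(X, pd.DataFrame):
            gene_ids = X.columns.to_numpy(dtype=object)
            sample_ids = np.array([str(s) for s in X.index], dtype=object)
            values = X.to_numpy()
        else:
            values = np.asarray(X)
            gene_ids = np.array([f"G{i}" for i in range(values.shape[1])], dtype=object)
            sample_ids = np.array(
                [f"sample_{i}" for i in range(values.shape[0])], dtype=object
            )
        y = np.asarray(list(y), dtype=object)
        if y.shape[0] != values.shape[0]:
            raise ValueError("X and y disagree on the number of samples")
        order = (
            tuple(self.class_order)
            if self.class_order is not None
            else tuple(dict.fromkeys(y.tolist()))
        )
        counts = CountMatrix(gene_ids, sample_ids, values.T)
        labels = PhenotypeLabels(sample_ids, y, order)  # type: ignore[arg-type]
        sets = (
            self.gene_sets
            if isinstance(self.gene_sets, GeneSetCollection)
            else GeneSetCollection.from_dict(self.gene_sets)
        )
        self.results_ = run_analysis(
            counts,
            labels,
            sets,
            gene_stat=self.gene_stat,
            set_stat=self.set_stat,
            n_permutations=self.n_permutations,
            permutation_mode=self.permutation_mode,
            seed=self.random_state,
            min_size=self.min_size,
            max_size=self.max_size,
            alpha=self.alpha,
            tau=self.tau,
            ks_exponent=self.ks_exponent,
        )
        self.gene_ids_ = gene_ids
        self.classes_ = order
        self.n_sets_ = len(self.results_)
        return self
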