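"""In-memory containers for count matrices, phenotype labels and gene sets.

These are lightweight validated dataclasses around numpy arrays; file
parsing lives in :mod:`countgsa.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file or container violates its format contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Gene-by-sample matrix of nonnegative integer read counts.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique gene identifiers, one per row.
    sample_ids : sequence of str
        Unique sample identifiers, one per column.
    counts : ndarray of shape (n_genes, n_samples)
        Nonnegative, finite counts.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D gene-by-sample array")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.issubdtype(self.counts.dtype, np.number):
            raise FormatError("counts must be numeric")
        if not np.all(np.isfinite(self.counts)):
            raise FormatError("counts must be finite")
        if np.any(self.counts < 0):
            raise FormatError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(
            gene_ids=frame.index.to_numpy(dtype=object),
            sample_ids=frame.columns.to_numpy(dtype=object),
            counts=frame.to_numpy(),
        )


@dataclass
class PhenotypeLabels:
    """Binary phenotype assignment for an ordered list of samples.

    ``class_order`` fixes the direction of every signed statistic: scores are
    computed as (class_order[0] minus class_order[1]).
    """

    sample_ids: np.ndarray
    classes: np.ndarray
    class_order: tuple[str, str]

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.classes = np.asarray(self.classes, dtype=object)
        if len(self.sample_ids) != len(self.classes):
            raise FormatError("sample_ids and classes must have equal length")
        observed = set(self.classes.tolist())
        if len(self.class_order) != 2 or self.class_order[0] == self.class_order[1]:
            raise FormatError("class_order must name exactly two distinct classes")
        if observed != set(self.class_order):
            raise FormatError(
                f"assignments use classes {sorted(map(str, observed))} but "
                f"class_order is {self.class_order}"
            )
        for name in self.class_order:
            n = int(np.sum(self.classes == name))
            if n < 2:
                raise FormatError(
                    f"class {name!r} has {n} sample(s); at least 2 are required"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def mask(self) -> np.ndarray:
        """Boolean mask selecting samples of the reference class (class_order[0])."""
        return np.asarray(self.classes == self.class_order[0])

    def swapped(self) -> "PhenotypeLabels":
        return PhenotypeLabels(
            self.sample_ids, self.classes, (self.class_order[1], self.class_order[0])
        )


@dataclass
class GeneSet:
    description: str
    genes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Ordered mapping of set name -> (description, deduplicated gene list)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            genes = tuple(dict.fromkeys(gs.genes))  # dedup, keep order
            self.sets[name] = GeneSet(gs.description, genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def genes_of(self, name: str) -> tuple[str, ...]:
        return self.sets[name].genes

    @classmethod
    def from_dict(
        cls, mapping: Mapping[str, Iterable[str]], descriptions: Mapping[str, str] | None = None
    ) -> "GeneSetCollection":
        descriptions = descriptions or {}
        return cls(
            {
                name: GeneSet(descriptions.get(name, ""), tuple(genes))
                for name, genes in mapping.items()
            }
        )

    def membership_matrix(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Boolean membership matrix of shape (n_sets, n_genes).

        Membership is by identifier; genes absent from ``gene_ids`` are
        ignored.
        """
        index = {g: i for i, g in enumerate(gene_ids)}
        out = np.zeros((len(self.sets), len(index)), dtype=bool)
        for row, (_, gs) in enumerate(self):
            for g in gs.genes:
                j = index.get(g)
                if j is not None:
                    out[row, j] = True
        return out


def align(counts: CountMatrix, labels: PhenotypeLabels) -> PhenotypeLabels:
    """Check positional alignment of labels with the count matrix columns.

    CLS files carry no sample names, so assignment is positional; the only
    checks possible are the sample count and the per-class minimum.
    """
    if labels.n_samples != counts.n_samples:
        raise FormatError(
            f"label count {labels.n_samples} does not match "
            f"sample count {counts.n_samples}"
        )
    if len(labels.sample_ids) and not np.array_equal(
        labels.sample_ids, counts.sample_ids
    ):
        # Positional alignment: adopt the count matrix's sample names.
        return PhenotypeLabels(counts.sample_ids, labels.classes, labels.class_order)
    return labels
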