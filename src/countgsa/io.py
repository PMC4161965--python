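"""Readers and writers for the tab-delimited formats of the GSEA family.

Supported formats: plain TSV and GCT 1.2 count matrices, GMT gene set
collections, CLS two-class phenotype labels, and the tab-delimited result
table (NAME, SIZE, AS, NAS, P-VALUE, FDR, FWER).
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import (
    CountMatrix,
    FormatError,
    GeneSet,
    GeneSetCollection,
    PhenotypeLabels,
)

RESULT_COLUMNS = ["NAME", "SIZE", "AS", "NAS", "P-VALUE", "FDR", "FWER"]


def read_counts(path: str | os.PathLike, dialect: str = "tsv") -> CountMatrix:
    """Read a gene-by-sample count table.

    ``dialect="tsv"``: header row of sample ids (first column = gene id),
    one row per gene. ``dialect="gct"``: GCT 1.2 with its two header lines
    and a Description column, which is ignored.
    """
    if dialect not in ("tsv", "gct"):
        raise ValueError(f"unknown counts dialect {dialect!r}")
    skiprows = 2 if dialect == "gct" else 0
    frame = pd.read_csv(path, sep="\t", skiprows=skiprows, dtype={0: str})
    if dialect == "gct":
        if frame.shape[1] < 3:
            raise FormatError("GCT file must have NAME, Description and data columns")
        frame = frame.drop(columns=frame.columns[1])
    gene_ids = frame.iloc[:, 0].to_numpy(dtype=object)
    data = frame.iloc[:, 1:]
    values = data.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"non-numeric count value in {path}")
    dup = pd.Index(gene_ids).duplicated()
    if dup.any():
        raise FormatError(f"duplicate gene id: {gene_ids[dup][0]!r}")
    return CountMatrix(
        gene_ids=gene_ids,
        sample_ids=data.columns.to_numpy(dtype=object),
        counts=values,
    )


def write_counts(matrix: CountMatrix, path: str | os.PathLike, dialect: str = "tsv") -> None:
    frame = matrix.to_frame()
    if dialect == "tsv":
        frame.to_csv(path, sep="\t", index_label="NAME")
    elif dialect == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            out = frame.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="NAME")
    else:
        raise ValueError(f"unknown counts dialect {dialect!r}")


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} field(s) found)"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = GeneSet(description, genes)
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, gs in sets:
            fh.write("\t".join([name, gs.description or "na", *gs.genes]) + "\n")


def read_cls(path: str | os.PathLike, sample_ids: Iterable[str] | None = None) -> PhenotypeLabels:
    """Read a two-class CLS file.

    Line 1: ``N 2 1``; line 2: ``# name1 name2``; line 3: N space-separated
    tokens, each a class name or the 0-based index into the name line.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: CLS file needs 3 non-empty lines")
    header = lines[0].split()
    if len(header) != 3:
        raise FormatError(f"{path}: malformed CLS header {lines[0]!r}")
    n_samples, n_classes = int(header[0]), int(header[1])
    if n_classes != 2:
        raise FormatError(f"{path}: exactly 2 classes required, got {n_classes}")
    name_line = lines[1].split()
    if name_line and name_line[0].startswith("#"):
        name_line = [name_line[0].lstrip("#"), *name_line[1:]]
        name_line = [t for t in name_line if t]
    if len(name_line) != 2:
        raise FormatError(f"{path}: class-name line must name exactly 2 classes")
    class_order = (name_line[0], name_line[1])
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise FormatError(
            f"{path}: {len(tokens)} assignment token(s) for {n_samples} samples"
        )
    # Tokens may be the class names themselves or 0/1 indexes (first token
    # maps to the first class name, GSEA convention).
    if set(tokens) <= set(class_order):
        classes = np.array(tokens, dtype=object)
    else:
        distinct = list(dict.fromkeys(tokens))
        if len(distinct) != 2:
            raise FormatError(
                f"{path}: assignment line uses {len(distinct)} distinct token(s), expected 2"
            )
        mapping = {distinct[0]: class_order[0], distinct[1]: class_order[1]}
        classes = np.array([mapping[t] for t in tokens], dtype=object)
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(n_samples)]
    return PhenotypeLabels(
        sample_ids=np.array(list(sample_ids), dtype=object),
        classes=classes,
        class_order=class_order,
    )


def write_cls(labels: PhenotypeLabels, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"{labels.n_samples} 2 1\n")
        fh.write(f"# {labels.class_order[0]} {labels.class_order[1]}\n")
        idx = {labels.class_order[0]: "0", labels.class_order[1]: "1"}
        fh.write(" ".join(idx[c] for c in labels.classes) + "\n")


def write_results(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a result table (already sorted) as TSV with 6-decimal floats."""
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"result table is missing column(s) {missing}")
    table.loc[:, RESULT_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return table
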