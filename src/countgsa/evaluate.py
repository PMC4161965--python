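"""Cross-replicate evaluation metrics and cross-method rank aggregation.

Recognition rate: fraction of simulation replicates in which the known
causal set is ranked first (tables are sorted by FDR, ties by NAS). Power:
fraction of replicates with causal p-value below a threshold. The rank
aggregation reproduces the case-study procedure: take each method's top-K
sets, keep sets reaching the top K in at least ``min_methods`` methods, and
order them by their average rank over the methods in which they appear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


def _causal_row(table: pd.DataFrame, causal_name: str) -> pd.Series:
    rows = table.loc[table["NAME"] == causal_name]
    if rows.empty:
        raise ValueError(f"causal set {causal_name!r} not found in result table")
    return rows.iloc[0]


def recognition_rate(replicate_tables: Iterable[pd.DataFrame], causal_name: str) -> float:
    """Fraction of replicates whose top-ranked set (row 1) is the causal set."""
    hits, n = 0, 0
    for table in replicate_tables:
        _causal_row(table, causal_name)  # presence check
        hits += int(table.iloc[0]["NAME"] == causal_name)
        n += 1
    if n == 0:
        raise ValueError("no replicate tables given")
    return hits / n


def power(
    replicate_tables: Iterable[pd.DataFrame],
    causal_name: str,
    threshold: float = 0.05,
) -> float:
    """Fraction of replicates with causal p-value strictly below ``threshold``."""
    hits, n = 0, 0
    for table in replicate_tables:
        hits += int(_causal_row(table, causal_name)["P-VALUE"] < threshold)
        n += 1
    if n == 0:
        raise ValueError("no replicate tables given")
    return hits / n


@dataclass
class EvaluationSummary:
    recognition_rate: float
    power: float
    mean_p: float
    mean_fdr: float
    mean_fwer: float
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def evaluate_replicates(
    replicate_tables: Iterable[pd.DataFrame],
    causal_name: str,
    threshold: float = 0.05,
) -> EvaluationSummary:
    """Recognition rate, power and mean causal p/FDR/FWER over replicates."""
    tables = list(replicate_tables)
    rows = [_causal_row(t, causal_name) for t in tables]
    return EvaluationSummary(
        recognition_rate=recognition_rate(tables, causal_name),
        power=power(tables, causal_name, threshold),
        mean_p=float(np.mean([r["P-VALUE"] for r in rows])),
        mean_fdr=float(np.mean([r["FDR"] for r in rows])),
        mean_fwer=float(np.mean([r["FWER"] for r in rows])),
        n_replicates=len(tables),
    )


def summarize_rank_matrix(
    ranks: pd.DataFrame, min_methods: int = 4
) -> pd.DataFrame:
    """NOC and average rank from a pathway-by-method rank matrix.

    ``ranks`` holds positive ranks, with 0 meaning "not in the top K for that
    method". NOC counts the nonzero entries per pathway; Avg is the mean of
    the nonzero ranks. Pathways with NOC >= ``min_methods`` are kept and
    sorted by Avg ascending (ties by NOC descending, then name).
    """
    values = ranks.to_numpy(dtype=float)
    noc = (values > 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        avg = np.where(noc > 0, values.sum(axis=1) / np.maximum(noc, 1), np.nan)
    out = ranks.copy()
    out.insert(0, "NOC", noc.astype(int))
    out["Avg"] = avg
    out = out[out["NOC"] >= min_methods]
    order = np.lexsort(
        (out.index.to_numpy(), -out["NOC"].to_numpy(), out["Avg"].to_numpy())
    )
    return out.iloc[order]


def aggregate_ranks(
    tables_by_method: Mapping[str, pd.DataFrame],
    top_k: int = 30,
    min_methods: int = 4,
) -> pd.DataFrame:
    """Cross-method occurrence/average-rank table from per-method results.

    A pathway's rank under a method is its 1-based row index in that method's
    sorted result table, or 0 if it falls outside the top ``top_k``.
    """
    if top_k < 1 or min_methods < 1:
        raise ValueError("top_k and min_methods must be at least 1")
    methods = list(tables_by_method)
    pathways: list[str] = []
    seen: set[str] = set()
    rank_of: dict[str, dict[str, int]] = {}
    for method in methods:
        table = tables_by_method[method]
        top = table["NAME"].head(top_k).tolist()
        rank_of[method] = {name: i + 1 for i, name in enumerate(top)}
        for name in top:
            if name not in seen:
                seen.add(name)
                pathways.append(name)
    ranks = pd.DataFrame(
        {m: [rank_of[m].get(p, 0) for p in pathways] for m in methods},
        index=pd.Index(pathways, name="Pathway"),
    )
    return summarize_rank_matrix(ranks, min_methods=min_methods)
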