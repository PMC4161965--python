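"""Negative-binomial simulator with a known causal gene set.

Each dataset has 1000 genes and 400 samples (200 per phenotype class) with
100 gene sets; the first set is the causal set of 16 genes, of which 8 or 12
are differentially expressed with |log2 fold change| drawn uniformly from a
scenario-specific range and a random sign per gene. The remaining 99 sets
are drawn from the 984 non-causal genes (a gene may belong to several sets).

Counts are negative binomial with gene-specific baseline means (log2 mean
uniform on [3, 10]) and a common dispersion (variance = mu + phi * mu^2,
phi = 0.15 by default) — typical bulk RNA-seq ranges. Six scenarios S1–S6
cross {8, 12} differentially expressed causal genes with effect-size ranges
U[0.8, 1], U[1, 3] and U[2, 4].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .containers import CountMatrix, GeneSet, GeneSetCollection, PhenotypeLabels

SCENARIOS: dict[str, tuple[int, tuple[float, float]]] = {
    "S1": (8, (0.8, 1.0)),
    "S2": (8, (1.0, 3.0)),
    "S3": (8, (2.0, 4.0)),
    "S4": (12, (0.8, 1.0)),
    "S5": (12, (1.0, 3.0)),
    "S6": (12, (2.0, 4.0)),
}


@dataclass
class ScenarioConfig:
    """Parameters of one simulated dataset."""

    n_genes: int = 1000
    n_samples_per_class: int = 200
    n_sets: int = 100
    causal_set_size: int = 16
    n_causal_de: int = 8
    effect_range: tuple[float, float] = (0.8, 1.0)
    nb_dispersion: float = 0.15
    baseline_log2_mean_range: tuple[float, float] = (3.0, 10.0)
    noncausal_set_size_range: tuple[int, int] = (15, 100)
    coherent_de_direction: bool = True
    depth_variation: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal_de > self.causal_set_size:
            raise ValueError("n_causal_de cannot exceed causal_set_size")
        lo, hi = self.effect_range
        if not (0 < lo < hi):
            raise ValueError("effect_range must satisfy 0 < low < high")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.causal_set_size >= self.n_genes:
            raise ValueError("causal set must be smaller than the gene universe")
        if self.n_sets > 1 and (
            self.noncausal_set_size_range[1] > self.n_genes - self.causal_set_size
        ):
            raise ValueError(
                "noncausal_set_size_range exceeds the non-causal gene pool"
            )


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    labels: PhenotypeLabels
    sets: GeneSetCollection
    causal_set_name: str
    de_genes: dict[str, float] = field(default_factory=dict)


def scenario(tag: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Config for one of the six named scenarios S1..S6."""
    try:
        n_de, rng = SCENARIOS[tag]
    except KeyError:
        raise ValueError(
            f"unknown scenario {tag!r}; choose from {sorted(SCENARIOS)}"
        ) from None
    return ScenarioConfig(n_causal_de=n_de, effect_range=rng, seed=seed, **overrides)


def generate_dataset(config: ScenarioConfig) -> SimulatedDataset:
    """Draw one dataset: counts, labels, sets, and the causal-gene truth.

    Differential expression is a class-mean shift: a DE gene keeps its
    baseline mean mu in the reference class and has mean mu * 2^(eps * beta)
    in the comparison class, with beta ~ U(effect_range) and eps a random
    sign. Bit-reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    g, npc = config.n_genes, config.n_samples_per_class
    gene_ids = np.array([f"G{i + 1:04d}" for i in range(g)], dtype=object)
    sample_ids = np.array(
        [f"ctrl_{i + 1}" for i in range(npc)] + [f"case_{i + 1}" for i in range(npc)],
        dtype=object,
    )
    classes = np.array(["control"] * npc + ["case"] * npc, dtype=object)
    labels = PhenotypeLabels(sample_ids, classes, ("control", "case"))

    lo, hi = config.baseline_log2_mean_range
    baseline = 2.0 ** rng.uniform(lo, hi, size=g)

    causal_idx = np.arange(config.causal_set_size)
    de_idx = rng.choice(causal_idx, size=config.n_causal_de, replace=False)
    betas = rng.uniform(*config.effect_range, size=config.n_causal_de)
    if config.coherent_de_direction:
        # One direction per dataset: differential activity of a pathway moves
        # its genes together, and the directional (signed KS) statistic can
        # only see a set whose members shift coherently.
        signs = np.full(config.n_causal_de, float(rng.choice([-1.0, 1.0])))
    else:
        signs = rng.choice([-1.0, 1.0], size=config.n_causal_de)
    fold = np.ones(g)
    fold[de_idx] = 2.0 ** (signs * betas)

    mean_ref = np.repeat(baseline[:, np.newaxis], npc, axis=1)
    mean_cmp = np.repeat((baseline * fold)[:, np.newaxis], npc, axis=1)
    mu = np.hstack([mean_ref, mean_cmp])
    if config.depth_variation is not None:
        depth = rng.uniform(*config.depth_variation, size=2 * npc)
        mu = mu * depth[np.newaxis, :]
    phi = config.nb_dispersion
    r = 1.0 / phi
    counts = rng.negative_binomial(r, r / (r + mu))

    causal_name = "SET001"
    sets: dict[str, GeneSet] = {
        causal_name: GeneSet("causal set", tuple(gene_ids[causal_idx]))
    }
    noncausal_pool = np.arange(config.causal_set_size, g)
    size_lo, size_hi = config.noncausal_set_size_range
    for i in range(1, config.n_sets):
        size = int(rng.integers(size_lo, size_hi + 1))
        members = rng.choice(noncausal_pool, size=size, replace=False)
        sets[f"SET{i + 1:03d}"] = GeneSet("null set", tuple(gene_ids[np.sort(members)]))

    de_genes = {
        str(gene_ids[j]): float(signs[k] * betas[k]) for k, j in enumerate(de_idx)
    }
    return SimulatedDataset(
        counts=CountMatrix(gene_ids, sample_ids, counts),
        labels=labels,
        sets=GeneSetCollection(sets),
        causal_set_name=causal_name,
        de_genes=de_genes,
    )


def generate_replicates(
    tag: str, n_replicates: int, seed: int = 0, **overrides
) -> Iterator[SimulatedDataset]:
    """Independent replicate datasets with per-replicate seeds spawned from
    the master seed (reproducible; seeds stay below 2**31)."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    for s in child_seeds:
        yield generate_dataset(scenario(tag, seed=int(s), **overrides))
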