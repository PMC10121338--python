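"""Synthetic two-population expression data with planted differential co-expression.

Each population is sampled from a multivariate normal whose correlation matrix
is block structured: a planted module is a gene subset given one within-module
correlation in population 1 and another in population 2, on top of a
background correlation (0 by default) among all remaining pairs.  Per-gene
means and standard deviations are drawn once (shared by both populations, so
the signal is purely co-expressional, not differential expression).

The generator emulates a case/control transcriptomics study at desk scale and
provides the recovery score used to judge end-to-end mining: the fraction of
planted population-1-specific within-module pairs that surface as an edge of
at least one mined top-k pattern.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionDataset

__all__ = [
    "PlantedModule",
    "SyntheticConfig",
    "generate_dataset",
    "planted_recovery_score",
    "standard_scenario",
]


@dataclasses.dataclass(frozen=True)
class PlantedModule:
    """A gene subset with population-specific within-module correlation."""

    genes: tuple[str, ...]
    rho1: float
    rho2: float

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes) or len(self.genes) < 2:
            raise ValueError("a module needs >= 2 distinct genes")
        for r in (self.rho1, self.rho2):
            if not -1.0 < r < 1.0:
                raise ValueError(f"planted correlation must be in (-1, 1): {r}")

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        gs = sorted(self.genes)
        return tuple(
            (gs[i], gs[j]) for i in range(len(gs)) for j in range(i + 1, len(gs))
        )


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Study design of a synthetic two-population dataset.

    Defaults describe the standard scenario: 30 genes, one 4-gene module
    correlated at 0.9 in population 1 and uncorrelated in population 2,
    40 + 40 samples, independent background.
    """

    n_genes: int = 30
    m1: int = 40
    m2: int = 40
    modules: tuple[PlantedModule, ...] = ()
    background_rho: float = 0.0
    mean_range: tuple[float, float] = (6.0, 10.0)
    sd_range: tuple[float, float] = (0.8, 1.6)
    seed: int = 0
    label1: str = "case"
    label2: str = "control"

    def gene_names(self) -> tuple[str, ...]:
        width = max(2, len(str(self.n_genes)))
        return tuple(f"G{i + 1:0{width}d}" for i in range(self.n_genes))

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.m1 < 2 or self.m2 < 2:
            raise ValueError("need >= 2 genes and >= 2 samples per population")
        if not -1.0 < self.background_rho < 1.0:
            raise ValueError("background correlation must be in (-1, 1)")
        names = set(self.gene_names())
        for mod in self.modules:
            extra = set(mod.genes) - names
            if extra:
                raise ValueError(f"module genes outside the gene list: {sorted(extra)}")
        seen: set[str] = set()
        for mod in self.modules:
            if seen & set(mod.genes):
                raise ValueError("planted modules must not overlap")
            seen |= set(mod.genes)


def _correlation_matrix(config: SyntheticConfig, population: int) -> np.ndarray:
    genes = config.gene_names()
    idx = {g: i for i, g in enumerate(genes)}
    c = np.full((config.n_genes, config.n_genes), config.background_rho)
    np.fill_diagonal(c, 1.0)
    for mod in config.modules:
        rho = mod.rho1 if population == 1 else mod.rho2
        for a, b in mod.pairs:
            c[idx[a], idx[b]] = rho
            c[idx[b], idx[a]] = rho
    return c


def _validated_cholesky(c: np.ndarray, config: SyntheticConfig, population: int) -> np.ndarray:
    eig = np.linalg.eigvalsh(c)
    if eig.min() <= 1e-10:
        offender = ""
        for mod in config.modules:
            sub = _correlation_matrix(
                dataclasses.replace(config, modules=(mod,)), population
            )
            if np.linalg.eigvalsh(sub).min() <= 1e-10:
                offender = f"; offending module: {mod.genes}"
                break
        raise ValueError(
            f"population-{population} correlation matrix not positive definite"
            f" (min eigenvalue {eig.min():.3g}){offender}"
        )
    return np.linalg.cholesky(c)


def generate_dataset(config: SyntheticConfig) -> ExpressionDataset:
    """Draw both populations; deterministic for a fixed master seed.

    The master seed spawns independent substreams for the gene-level
    parameters and for each population, so resizing one population leaves the
    other population's draws unchanged.
    """
    ss = np.random.SeedSequence(config.seed)
    ss_params, ss_pop1, ss_pop2 = ss.spawn(3)
    rng_params = np.random.default_rng(ss_params)
    genes = config.gene_names()
    means = rng_params.uniform(*config.mean_range, size=config.n_genes)
    sds = rng_params.uniform(*config.sd_range, size=config.n_genes)

    blocks = []
    sample_ids = []
    labels = []
    for population, (m, ss_pop, label) in enumerate(
        [(config.m1, ss_pop1, config.label1), (config.m2, ss_pop2, config.label2)], start=1
    ):
        chol = _validated_cholesky(_correlation_matrix(config, population), config, population)
        rng = np.random.default_rng(ss_pop)
        z = rng.standard_normal((m, config.n_genes)) @ chol.T
        x = means + sds * z
        blocks.append(x.T)
        sample_ids += [f"S{population}_{i + 1:03d}" for i in range(m)]
        labels += [label] * m
    values = pd.DataFrame(np.hstack(blocks), index=list(genes), columns=sample_ids)
    return ExpressionDataset(values=values, labels=pd.Series(labels, index=sample_ids))


def planted_recovery_score(results: Sequence, config: SyntheticConfig) -> float:
    """Fraction of population-1-specific planted pairs covered by result edges.

    Population-1-specific modules are those with |rho1| > |rho2|; their
    within-module pairs are the planted signal the guiding direction should
    recover.
    """
    planted = [
        pair
        for mod in config.modules
        if abs(mod.rho1) > abs(mod.rho2)
        for pair in mod.pairs
    ]
    if not planted:
        raise ValueError("no population-1-specific planted module in the configuration")
    covered = set()
    for sp in results:
        pat = sp.pattern if hasattr(sp, "pattern") else sp
        covered |= set(pat.edges)
    return sum(1 for pair in planted if pair in covered) / len(planted)


def standard_scenario(seed: int = 0) -> SyntheticConfig:
    """The standard recovery scenario: 30 genes, one 4-gene module at 0.9 vs 0.0."""
    return SyntheticConfig(
        n_genes=30, m1=40, m2=40,
        modules=(PlantedModule(genes=("G01", "G02", "G03", "G04"), rho1=0.9, rho2=0.0),),
        seed=seed,
    )
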