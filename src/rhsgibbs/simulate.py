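"""Synthetic genotype/phenotype data with known truth.

Genotypes are unlinked biallelic loci in Hardy-Weinberg proportions:
per locus an allele frequency is drawn uniformly from the MAF range and
allele counts are Binomial(2, p) i.i.d. across individuals.  A subset of
loci act as additive QTL with standard-normal effects; the residual
variance is set so that the realized heritability (var(TBV)/var(y))
matches the requested h2 by construction.  Everything is deterministic
given the seed (numpy PCG64 streams, one per stage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coding import RawGenotypes

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes", "simulate_phenotypes", "simulate_dataset"]


@dataclass
class SimConfig:
    m: int
    n: int
    n_qtl: int = 20
    h2: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("m and n must be positive")
        if not 0 < self.n_qtl <= self.n:
            raise ValueError("n_qtl must be in 1..n")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie strictly in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf bounds must satisfy 0 < lo <= hi <= 0.5")


@dataclass
class SimTruth:
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_breeding_values: np.ndarray
    sigma_e2_true: float


def simulate_genotypes(config: SimConfig) -> RawGenotypes:
    """Draw the m x n allele-count matrix (unlinked loci, HWE)."""
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=config.n)
    matrix = rng.binomial(2, p[None, :], size=(config.m, config.n)).astype(np.int8)
    return RawGenotypes(matrix)


def simulate_phenotypes(
    raw: RawGenotypes, config: SimConfig
) -> tuple[np.ndarray, SimTruth]:
    """Additive phenotypes y = TBV + N(0, sigma_e^2) with realized-h2 scaling."""
    rng = np.random.default_rng([config.seed, 1])
    qtl = np.sort(rng.choice(raw.n, size=config.n_qtl, replace=False))
    effects = rng.standard_normal(config.n_qtl)
    g = raw.matrix[:, qtl].astype(np.float64)
    tbv = (g - g.mean(axis=0)) @ effects
    var_g = float(tbv.var())
    if var_g == 0.0:
        raise ValueError("all QTL are monomorphic: zero genetic variance")
    sigma_e2 = var_g * (1.0 - config.h2) / config.h2
    y = tbv + rng.normal(0.0, np.sqrt(sigma_e2), size=raw.m)
    return y, SimTruth(qtl, effects, tbv, sigma_e2)


def simulate_dataset(config: SimConfig) -> tuple[RawGenotypes, np.ndarray, SimTruth]:
    """Convenience wrapper: genotypes plus phenotypes in one call."""
    raw = simulate_genotypes(config)
    y, truth = simulate_phenotypes(raw, config)
    return raw, y, truth
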