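"""Bayes SSVS Gibbs sampler for SNP allele-substitution effects.

Model: y = 1 mu + X alpha + e with e ~ N(0, sigma_e^2 I).  Each effect
alpha_j is, a priori, N(0, sigma_alpha^2) with prior probability 1 - pi
(QTL indicator I_j = 1) and N(0, sigma_alpha^2 / 100) with probability pi
(I_j = 0): excluded effects are shrunk a hundredfold rather than zeroed.
sigma_alpha^2 carries a scaled-inverse-chi-square prior whose scale is
derived from an assumed total additive-genetic variance, and sigma_e^2 a
flat prior.  All conditionals are standard, so the chain is a plain
single-site Gibbs sampler; the per-locus conditional mean can be formed
by any of the three kernels in :mod:`rhsgibbs.kernels`, which are
mathematically equivalent and consume identical random-number streams
(per iteration: one normal for mu, one uniform plus one normal per locus,
two chi-squares for the variances), so equal-seed chains are directly
comparable across algorithms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kernels
from .coding import BlockIndex, LocusCoding, RawGenotypes, assign_blocks, encode_group_codes

__all__ = [
    "Priors",
    "ChainConfig",
    "ModelState",
    "IndicatorStats",
    "PosteriorSummary",
    "derive_effect_variance_prior",
    "sample_mu",
    "indicator_stats",
    "sample_indicator",
    "sample_effect",
    "sample_var_alpha",
    "sample_var_e",
    "run_chain",
    "predict_gebv",
]

ALGORITHMS = ("original", "improved", "rhs")


@dataclass
class Priors:
    """Hyperparameters of the SSVS prior.

    pi: prior exclusion probability of each locus (default 0.999).
    nu_alpha: degrees of freedom of the effect-variance prior (default 4.2).
    sigma_a2: assumed total additive-genetic variance; when None it is set
        to half the phenotypic variance at chain start.
    c: shrinkage divisor for excluded loci, fixed at 100.
    """

    pi: float = 0.999
    nu_alpha: float = 4.2
    sigma_a2: float | None = None
    c: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must be in (0, 1)")
        if not self.nu_alpha > 2.0:
            raise ValueError("nu_alpha must exceed 2")


def derive_effect_variance_prior(priors: Priors, n: int) -> tuple[float, float]:
    """Per-locus effect variance and inverse-chi-square scale from sigma_a^2.

    Partitioning the additive variance over n loci of which a fraction
    1 - pi carry weight 1 and a fraction pi carry weight 1/100 gives
    ``sigma_a^2 = n * sigma_tilde^2 * ((1 - pi) + pi/100)``, hence
    ``sigma_tilde^2 = 100 sigma_a^2 / (n (100 - 99 pi))``.  The prior
    scale is ``S_alpha^2 = sigma_tilde^2 (nu - 2)/nu`` so that the prior
    mean of sigma_alpha^2 equals sigma_tilde^2.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if priors.sigma_a2 is None:
        raise ValueError("sigma_a2 must be set before deriving the prior scale")
    denom = 100.0 - 99.0 * priors.pi
    assert denom > 0.0  # guaranteed for pi < 1
    sigma_tilde2 = 100.0 * priors.sigma_a2 / (n * denom)
    s_alpha2 = sigma_tilde2 * (priors.nu_alpha - 2.0) / priors.nu_alpha
    return sigma_tilde2, s_alpha2


@dataclass
class ModelState:
    """Current Gibbs state (exposed mainly for testing and diagnostics)."""

    mu: float
    alpha: np.ndarray
    indicators: np.ndarray
    omega: np.ndarray
    sigma_e2: float
    sigma_alpha2: float
    residuals: kernels.ResidualState


@dataclass
class IndicatorStats:
    r: float
    v0: float
    v1: float
    p_incl: float


@dataclass
class ChainConfig:
    iterations: int = 2000
    burn_in: int = 500
    thin: int = 10
    seed: int = 0
    algorithm: str = "rhs"
    block_size: int | str = "auto"
    block_ordering: str = "consecutive"
    permute_block_order: bool = False
    #: recompute e = y - mu - X alpha from scratch after every iteration and
    #: fail if the incrementally maintained residuals drift (debug/testing)
    check_residuals: bool = False

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if not self.burn_in < self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSummary:
    """Posterior means, inclusion probabilities, GEBVs and thinned traces."""

    effect_means: np.ndarray
    inclusion_probs: np.ndarray
    var_components: dict[str, float]
    gebv: np.ndarray
    traces: pd.DataFrame
    effect_trace: np.ndarray
    locus_ids: list[str] = field(default_factory=list)
    individual_ids: list[str] = field(default_factory=list)
    config: ChainConfig | None = None


def sample_mu(
    e: np.ndarray, mu_old: float, sigma_e2: float, rng: np.random.Generator
) -> float:
    """Draw mu from its conditional normal, keeping residuals consistent.

    The current mu is added back into the residuals, the new mu is drawn
    from N(mean of corrected phenotypes, sigma_e^2 / m), and subtracted
    again.  Consumes exactly one standard-normal variate.
    """
    m = len(e)
    e += mu_old
    mean = float(e.mean())
    mu_new = mean + rng.standard_normal() * math.sqrt(sigma_e2 / m)
    e -= mu_new
    return mu_new


def indicator_stats(
    r: float,
    xtx: float,
    sigma_alpha2: float,
    sigma_e2: float,
    pi: float,
    c: float = 100.0,
) -> IndicatorStats:
    """Posterior inclusion probability of one locus, computed in log space.

    The locus statistic r = x'y* (= x'e + x'x alpha_current) is normal
    with variance v_delta = (x'x)^2 sigma_alpha^2 / omega_delta
    + x'x sigma_e^2 under I = delta, with omega_1 = 1 and omega_0 = c.
    Log densities are compared directly so that simultaneous underflow of
    both likelihoods cannot corrupt the probability.
    """
    v1 = xtx * xtx * sigma_alpha2 + xtx * sigma_e2
    v0 = xtx * xtx * sigma_alpha2 / c + xtx * sigma_e2
    r2 = r * r
    logf1 = -0.5 * math.log(v1) - r2 / (2.0 * v1)
    logf0 = -0.5 * math.log(v0) - r2 / (2.0 * v0)
    # Pr(I=1) = f1 (1-pi) / (f0 pi + f1 (1-pi))
    t = logf0 - logf1 + math.log(pi) - math.log1p(-pi)
    if t > 700.0:
        p1 = 0.0
    elif t < -700.0:
        p1 = 1.0
    else:
        p1 = 1.0 / (1.0 + math.exp(t))
    return IndicatorStats(r=r, v0=v0, v1=v1, p_incl=p1)


def sample_indicator(
    r: float,
    xtx: float,
    sigma_alpha2: float,
    sigma_e2: float,
    pi: float,
    rng: np.random.Generator,
    c: float = 100.0,
) -> tuple[int, float]:
    """Draw the QTL indicator I_j and return (I_j, omega_j)."""
    if not xtx > 0.0:
        raise ValueError("x'x must be positive")
    stats = indicator_stats(r, xtx, sigma_alpha2, sigma_e2, pi, c)
    ind = 1 if rng.random() < stats.p_incl else 0
    return ind, (1.0 if ind == 1 else c)


def sample_effect(
    mean: float, denominator: float, sigma_e2: float, rng: np.random.Generator
) -> float:
    """Draw alpha_j ~ N(mean, sigma_e^2 / (x'x + lambda)); one normal variate."""
    if not denominator > 0.0:
        raise ValueError("denominator must be positive")
    return mean + rng.standard_normal() * math.sqrt(sigma_e2 / denominator)


def sample_var_alpha(
    alpha: np.ndarray,
    omega: np.ndarray,
    s_alpha2: float,
    nu_alpha: float,
    rng: np.random.Generator,
) -> float:
    """sigma_alpha^2 ~ (S_alpha^2 + sum_j omega_j alpha_j^2) / chi2_{nu+n}."""
    n = len(alpha)
    scale = s_alpha2 + float(omega @ (alpha * alpha))
    return scale / rng.chisquare(nu_alpha + n)


def sample_var_e(e: np.ndarray, m: int, rng: np.random.Generator) -> float:
    """sigma_e^2 ~ e'e / chi2_{m-2} (flat prior on the residual variance)."""
    if m <= 4:
        raise ValueError("m must exceed 4 for the residual-variance posterior")
    return float(e @ e) / rng.chisquare(m - 2)


def _resolve_block_size(block_size: int | str, m: int) -> int:
    if block_size == "auto":
        from .bench import optimal_block_size

        return optimal_block_size(m)
    return int(block_size)


def run_chain(
    y: np.ndarray,
    genotypes: RawGenotypes,
    coding: LocusCoding,
    priors: Priors | None = None,
    config: ChainConfig | None = None,
    block_index: BlockIndex | None = None,
    counters: kernels.OpCounters | None = None,
) -> PosteriorSummary:
    """Run the full SSVS Gibbs chain and summarize the posterior.

    ``coding`` must have been built from ``genotypes`` (its ``kept`` index
    selects the loci actually modelled).  For ``algorithm='rhs'`` a
    :class:`BlockIndex` is built from the config unless one is supplied.
    Posterior means are accumulated over all post-burn-in iterations;
    traces keep every ``thin``-th iteration from the start of the chain.
    """
    priors = priors or Priors()
    config = config or ChainConfig()
    y = np.asarray(y, dtype=np.float64)
    raw = genotypes.subset_loci(coding.kept)
    m, n = raw.m, raw.n
    if len(y) != m:
        raise ValueError("phenotype length does not match genotype rows")
    codes = np.asfortranarray(raw.matrix.astype(np.int64))
    gamma_rows = [tuple(row) for row in coding.gamma]
    xtx = coding.xtx.tolist()
    algorithm = config.algorithm

    if algorithm == "rhs":
        if block_index is None:
            s = _resolve_block_size(config.block_size, m)
            partition = assign_blocks(n, s, config.block_ordering, config.seed)
            block_index = encode_group_codes(raw, partition)
        blocks = block_index.blocks
    coded = None
    if algorithm == "original" or config.check_residuals:
        coded = coding.code_matrix(genotypes)
    if algorithm == "original":
        cols = [np.ascontiguousarray(coded[:, j]) for j in range(n)]

    rng = np.random.default_rng(config.seed)
    if priors.sigma_a2 is None:
        priors = Priors(priors.pi, priors.nu_alpha, float(np.var(y)) / 2.0, priors.c)
    sigma_tilde2, s_alpha2 = derive_effect_variance_prior(priors, n)

    mu = float(y.mean())
    alpha = np.zeros(n)
    indicators = np.zeros(n, dtype=np.int8)
    omega = np.full(n, priors.c)
    sigma_e2 = float(np.var(y)) / 2.0
    sigma_alpha2 = sigma_tilde2
    e = y - mu

    pi, c = priors.pi, priors.c
    xtx_arr = coding.xtx
    sum_alpha = np.zeros(n)
    sum_incl = np.zeros(n)
    sums = {"sigma_e2": 0.0, "sigma_alpha2": 0.0, "genvar": 0.0}
    sums_sq = {"sigma_e2": 0.0, "sigma_alpha2": 0.0}
    n_post = 0
    trace_rows = []
    effect_trace = []
    trace_iters = []

    for it in range(1, config.iterations + 1):
        mu = sample_mu(e, mu, sigma_e2, rng)

        def locus_draw(j: int, num: float) -> tuple[float, float]:
            """Shared indicator/effect sampling; returns (a_old, a_new)."""
            a_old = alpha[j]
            stats = indicator_stats(num, xtx[j], sigma_alpha2, sigma_e2, pi, c)
            ind = 1 if rng.random() < stats.p_incl else 0
            w = 1.0 if ind == 1 else c
            indicators[j] = ind
            omega[j] = w
            lam = w * sigma_e2 / sigma_alpha2
            den = xtx[j] + lam
            a_new = (num / den) + rng.standard_normal() * math.sqrt(sigma_e2 / den)
            alpha[j] = a_new
            return a_old, a_new

        if algorithm == "original":
            for j in range(n):
                num = kernels.numerator_original(e, cols[j], xtx[j], alpha[j], counters)
                a_old, a_new = locus_draw(j, num)
                delta = a_new - a_old
                if delta != 0.0:
                    e -= cols[j] * delta
                if counters is not None:
                    counters.additions_subtractions += m + 1
                    counters.multiplications += m
        elif algorithm == "improved":
            for j in range(n):
                cj = codes[:, j]
                num = kernels.numerator_improved(
                    e, cj, gamma_rows[j], xtx[j], alpha[j], counters
                )
                a_old, a_new = locus_draw(j, num)
                kernels.residual_update(e, cj, gamma_rows[j], a_old, a_new, counters)
        else:  # rhs
            block_order = range(len(blocks))
            if config.permute_block_order:
                block_order = rng.permutation(len(blocks))
            for b in block_order:
                state = kernels.block_initialize(e, block_index, b, counters)
                for t, j in enumerate(blocks[b]):
                    num = kernels.block_locus_numerator(
                        state, block_index, t, gamma_rows[j], xtx[j], alpha[j], counters
                    )
                    a_old, a_new = locus_draw(j, num)
                    kernels.update_block_state(
                        state, block_index, t, gamma_rows[j], a_old, a_new, counters
                    )
                kernels.block_finalize(state, block_index, e, counters)

        sigma_alpha2 = sample_var_alpha(alpha, omega, s_alpha2, priors.nu_alpha, rng)
        sigma_e2 = sample_var_e(e, m, rng)
        if not (math.isfinite(mu) and math.isfinite(sigma_e2) and math.isfinite(sigma_alpha2)):
            raise FloatingPointError(f"chain diverged at iteration {it}")
        if config.check_residuals:
            scratch = kernels.recompute_residuals(y, mu, coded, alpha)
            tol = 1e-8 * (1.0 + float(np.max(np.abs(y))))
            drift = float(np.max(np.abs(e - scratch)))
            if drift > tol:
                raise FloatingPointError(
                    f"residual drift {drift:.3e} > {tol:.3e} at iteration {it}"
                )

        genvar = float(xtx_arr @ (alpha * alpha)) / m
        if it > config.burn_in:
            n_post += 1
            sum_alpha += alpha
            sum_incl += indicators
            sums["sigma_e2"] += sigma_e2
            sums["sigma_alpha2"] += sigma_alpha2
            sums["genvar"] += genvar
            sums_sq["sigma_e2"] += sigma_e2 * sigma_e2
            sums_sq["sigma_alpha2"] += sigma_alpha2 * sigma_alpha2
        if it % config.thin == 0:
            trace_iters.append(it)
            trace_rows.append((mu, sigma_e2, sigma_alpha2, genvar))
            effect_trace.append(alpha.copy())

    effect_means = sum_alpha / n_post
    inclusion_probs = sum_incl / n_post
    var_components = {
        "sigma_e2_mean": sums["sigma_e2"] / n_post,
        "sigma_alpha2_mean": sums["sigma_alpha2"] / n_post,
        "genetic_variance_mean": sums["genvar"] / n_post,
        "sigma_e2_sd": math.sqrt(
            max(sums_sq["sigma_e2"] / n_post - (sums["sigma_e2"] / n_post) ** 2, 0.0)
        ),
        "sigma_alpha2_sd": math.sqrt(
            max(
                sums_sq["sigma_alpha2"] / n_post
                - (sums["sigma_alpha2"] / n_post) ** 2,
                0.0,
            )
        ),
    }
    gebv = coding.code_matrix(genotypes) @ effect_means
    traces = pd.DataFrame(
        trace_rows, columns=["mu", "sigma_e2", "sigma_alpha2", "genetic_variance"]
    )
    traces.insert(0, "iteration", trace_iters)
    return PosteriorSummary(
        effect_means=effect_means,
        inclusion_probs=inclusion_probs,
        var_components=var_components,
        gebv=gebv,
        traces=traces,
        effect_trace=np.asarray(effect_trace),
        locus_ids=list(coding.locus_ids),
        individual_ids=list(genotypes.individual_ids),
        config=config,
    )


def predict_gebv(
    effect_means: np.ndarray,
    genotypes,
    coding: LocusCoding,
    locus_ids: list[str] | None = None,
) -> np.ndarray:
    """Breeding values of candidates from posterior-mean effects.

    Candidates may carry real-valued gene contents (dosages); values are
    transformed with the *training* coding parameters (training allele
    frequencies and scale), so no rounding is required here.  When
    ``genotypes`` is a :class:`RawGenotypes` its loci are matched to the
    training loci by ID; a plain array is assumed already aligned to the
    coding's retained loci (``locus_ids`` may be passed to check).
    """
    if isinstance(genotypes, RawGenotypes):
        values = genotypes.matrix.astype(np.float64)
        locus_ids = genotypes.locus_ids
    else:
        values = np.atleast_2d(np.asarray(genotypes, dtype=np.float64))
    if locus_ids is not None:
        pos = {lid: j for j, lid in enumerate(locus_ids)}
        missing = [lid for lid in coding.locus_ids if lid not in pos]
        if missing:
            raise ValueError(f"candidate loci missing training loci: {missing}")
        values = values[:, [pos[lid] for lid in coding.locus_ids]]
    if values.shape[1] != coding.n:
        raise ValueError(
            f"candidate matrix has {values.shape[1]} loci, coding has {coding.n}"
        )
    return coding.code_values(values) @ np.asarray(effect_means)
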