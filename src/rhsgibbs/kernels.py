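"""SNP-effect update kernels: residual updating and RHS-block updating.

Three mathematically equivalent ways to form the conditional mean of an
allele-substitution effect during a Gibbs (or Gauss-Seidel) sweep:

* **original** — dot the full coded genotype column with the residuals:
  ``mean = (x'e + x'x a_old) / (x'x + lambda)``; m+1 multiplications.
* **improved** — first sum residuals within the three genotype classes
  (one additive pass), then combine the 3 sums with the 3 predictor
  values: the numerator needs exactly 4 multiplications however large m is.
* **rhs** — extend the idea across a block of s loci: at block start the
  residual sums of all 3**s genotype-combination groups are formed once
  (one additive pass); every locus inside the block is then updated from
  those group sums in O(3**s) work, with the pending residual changes
  accumulated per group and applied to the residual vector only when the
  block is finalized.

All kernels optionally instrument an :class:`OpCounters`.  Counting
convention: the division by the denominator and the formation of the
effect change ``delta = a_new - a_old`` are not counted as
multiplications, so the original numerator costs m+1 multiplications and
the improved numerator exactly 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coding import BlockIndex, LocusCoding

__all__ = [
    "OpCounters",
    "ResidualState",
    "BlockState",
    "numerator_original",
    "numerator_improved",
    "conditional_mean_original",
    "conditional_mean_improved",
    "residual_update",
    "block_initialize",
    "block_locus_numerator",
    "block_locus_update",
    "update_block_state",
    "block_finalize",
    "recompute_residuals",
]


@dataclass
class OpCounters:
    """Tally of scalar arithmetic performed by the kernels."""

    multiplications: int = 0
    additions_subtractions: int = 0
    divisions: int = 0

    def reset(self) -> None:
        self.multiplications = 0
        self.additions_subtractions = 0
        self.divisions = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "multiplications": self.multiplications,
            "additions_subtractions": self.additions_subtractions,
            "divisions": self.divisions,
        }


@dataclass
class ResidualState:
    """Residual vector e = y - mu - X alpha, maintained incrementally."""

    e: np.ndarray
    consistent_with: object | None = None


@dataclass
class BlockState:
    """Per-group bookkeeping for the active RHS-block.

    ``F[g]`` is the sum of residuals of group g at block initialization;
    ``dE[g]`` the residual change accumulated for every individual of
    group g since then (all members of a group share the same genotypes
    at every block locus, hence the same pending change).
    """

    F: np.ndarray
    dE: np.ndarray
    active_block: int
    initialized: bool = field(default=True)


def _check_denominator(den: float) -> None:
    if not den > 0.0:
        raise ValueError(
            f"conditional-mean denominator {den} <= 0: invalid lambda or coding"
        )


def numerator_original(
    e: np.ndarray,
    x_col: np.ndarray,
    xtx: float,
    a_old: float,
    counters: OpCounters | None = None,
) -> float:
    """x'e + x'x a_old from the full coded column (m+1 multiplications)."""
    if counters is not None:
        m = len(e)
        counters.multiplications += m + 1
        counters.additions_subtractions += m  # m-1 for the dot, 1 to add x'x a_old
    return float(x_col @ e) + xtx * a_old


def numerator_improved(
    e: np.ndarray,
    codes: np.ndarray,
    gamma: tuple[float, float, float],
    xtx: float,
    a_old: float,
    counters: OpCounters | None = None,
) -> float:
    """gamma'f + n'gamma^2 a_old via per-genotype residual sums.

    One additive O(m) pass builds f (residual sum per genotype class in
    ascending individual order); the numerator then uses exactly 4 scalar
    multiplications: 3 for gamma'f and 1 for x'x a_old (n'gamma^2 = x'x
    is precomputed in the coding).
    """
    f = np.bincount(codes, weights=e, minlength=3)
    f0, f1, f2 = f.tolist()
    if counters is not None:
        counters.multiplications += 4
        counters.additions_subtractions += len(e) + 3
    return gamma[0] * f0 + gamma[1] * f1 + gamma[2] * f2 + xtx * a_old


def _mean_from_numerator(
    num: float, xtx: float, lam: float, counters: OpCounters | None
) -> tuple[float, float, float]:
    den = xtx + lam
    _check_denominator(den)
    if counters is not None:
        counters.additions_subtractions += 1
        counters.divisions += 1
    return num, den, num / den


def conditional_mean_original(
    e: np.ndarray,
    x_col: np.ndarray,
    xtx: float,
    a_old: float,
    lam: float,
    counters: OpCounters | None = None,
) -> tuple[float, float, float]:
    """(numerator, denominator, mean) by original residual updating."""
    num = numerator_original(e, x_col, xtx, a_old, counters)
    return _mean_from_numerator(num, xtx, lam, counters)


def conditional_mean_improved(
    e: np.ndarray,
    codes: np.ndarray,
    gamma: tuple[float, float, float],
    xtx: float,
    a_old: float,
    lam: float,
    counters: OpCounters | None = None,
) -> tuple[float, float, float]:
    """(numerator, denominator, mean) by improved residual updating."""
    num = numerator_improved(e, codes, gamma, xtx, a_old, counters)
    return _mean_from_numerator(num, xtx, lam, counters)


def residual_update(
    e: np.ndarray,
    codes: np.ndarray,
    gamma: tuple[float, float, float],
    a_old: float,
    a_new: float,
    counters: OpCounters | None = None,
) -> np.ndarray:
    """e_i <- e_i - gamma(code_i) * (a_new - a_old), in place.

    Only the 3 distinct products gamma_k * delta are formed; the per-
    individual work is a table-lookup subtraction.
    """
    delta = a_new - a_old
    if delta != 0.0:
        table = np.array([gamma[0] * delta, gamma[1] * delta, gamma[2] * delta])
        e -= table[codes]
    if counters is not None:
        counters.multiplications += 3
        counters.additions_subtractions += len(e) + 1
    return e


def block_initialize(
    e: np.ndarray,
    index: BlockIndex,
    b: int,
    counters: OpCounters | None = None,
) -> BlockState:
    """Sum residuals within every genotype-combination group of block ``b``.

    One O(m) additive pass forms the 3**s group sums F_g (for s=2 these
    are the 9 sums of the two-locus scheme); the accumulated changes dE
    start at zero.
    """
    codes0 = index.codes0(b)
    ng = index.n_groups(b)
    F = np.bincount(codes0, weights=e, minlength=ng)
    if counters is not None:
        counters.additions_subtractions += len(e)
    return BlockState(F=F, dE=np.zeros(ng), active_block=b)


def block_locus_numerator(
    state: BlockState,
    index: BlockIndex,
    t: int,
    gamma: tuple[float, float, float],
    xtx: float,
    a_old: float,
    counters: OpCounters | None = None,
) -> float:
    """Numerator for the within-block locus at position ``t``, O(3**s) work.

    The current residual sum of genotype class k at this locus is
    ``h_k = sum_{g: geno(g,t)=k} (F_g - n_g dE_g)``; no pass over the m
    individuals is needed, so the cost is independent of m.  For t=0 the
    dE correction is identically zero and this coincides with improved
    residual updating on the freshly initialized block.
    """
    if not state.initialized:
        raise RuntimeError("block_initialize must be called before locus updates")
    b = state.active_block
    ng = index.group_counts[b]
    geno_t = index.geno_of_group[b][:, t]
    adj = state.F - ng * state.dE
    h = np.bincount(geno_t, weights=adj, minlength=3)
    h0, h1, h2 = h.tolist()
    if counters is not None:
        g = len(ng)
        counters.multiplications += g + 4
        counters.additions_subtractions += 2 * g + 3
    return gamma[0] * h0 + gamma[1] * h1 + gamma[2] * h2 + xtx * a_old


def block_locus_update(
    state: BlockState,
    index: BlockIndex,
    t: int,
    gamma: tuple[float, float, float],
    xtx: float,
    a_old: float,
    lam: float,
    counters: OpCounters | None = None,
) -> tuple[float, float, float]:
    """(numerator, denominator, mean) for block locus ``t`` by RHS-updating."""
    num = block_locus_numerator(state, index, t, gamma, xtx, a_old, counters)
    return _mean_from_numerator(num, xtx, lam, counters)


def update_block_state(
    state: BlockState,
    index: BlockIndex,
    t: int,
    gamma: tuple[float, float, float],
    a_old: float,
    a_new: float,
    counters: OpCounters | None = None,
) -> BlockState:
    """Record the residual change of locus ``t`` per group: dE_g += gamma_t(g) delta.

    Only the 3 distinct products gamma_k * delta are formed; dE is a
    running sum, so successive locus updates commute additively.
    """
    delta = a_new - a_old
    geno_t = index.geno_of_group[state.active_block][:, t]
    if delta != 0.0:
        table = np.array([gamma[0] * delta, gamma[1] * delta, gamma[2] * delta])
        state.dE += table[geno_t]
    if counters is not None:
        counters.multiplications += 3
        counters.additions_subtractions += len(geno_t) + 1
    return state


def block_finalize(
    state: BlockState,
    index: BlockIndex,
    e: np.ndarray,
    counters: OpCounters | None = None,
) -> np.ndarray:
    """Apply the accumulated per-group changes to the residuals, in place."""
    codes0 = index.codes0(state.active_block)
    e -= state.dE[codes0]
    if counters is not None:
        counters.additions_subtractions += len(e)
    state.initialized = False
    return e


def recompute_residuals(
    y: np.ndarray, mu: float, coded_matrix: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """Residuals from scratch: e = y - mu - X alpha (consistency oracle)."""
    return y - mu - coded_matrix @ alpha
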