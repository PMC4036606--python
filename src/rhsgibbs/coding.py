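"""Genotype coding and RHS-block group coding.

Biallelic SNP genotypes (allele counts 0/1/2) are turned into per-locus
3-valued predictor codings (raw, centered, or centered-and-scaled), and
loci are partitioned into RHS-blocks of ``s`` SNPs.  Within a block the
``3**s`` possible genotype combinations define *groups*; each individual
carries one group code per block, which stores the genotypes at all block
loci implicitly.  Group codes fit in 2 bytes, which caps ``s`` at 9
(``3**9 = 19683``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawGenotypes",
    "LocusCoding",
    "BlockIndex",
    "allele_frequencies",
    "make_locus_coding",
    "round_dosages",
    "assign_blocks",
    "encode_group_codes",
    "cross_counts",
    "MAX_BLOCK_SIZE",
]

#: largest admissible RHS-block size: group codes are stored in at most
#: 2 bytes, and 3**9 = 19683 is the last power of three that fits.
MAX_BLOCK_SIZE = 9

_GENOTYPES = np.array([0, 1, 2])


@dataclass
class RawGenotypes:
    """An m x n matrix of allele counts with row/column labels.

    Every entry must be 0, 1 or 2; missing genotypes are rejected here
    (externally imputed dosages go through :func:`round_dosages` first).
    """

    matrix: np.ndarray
    individual_ids: list[str] = field(default_factory=list)
    locus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.size == 0:
            raise ValueError("genotype matrix must be 2-D and non-empty")
        if not np.issubdtype(self.matrix.dtype, np.integer):
            if not np.all(np.isin(self.matrix, _GENOTYPES)):
                raise ValueError("genotype entries must be integers in {0, 1, 2}")
            self.matrix = self.matrix.astype(np.int8)
        if self.matrix.min() < 0 or self.matrix.max() > 2:
            bad = np.argwhere((self.matrix < 0) | (self.matrix > 2))[0]
            raise ValueError(
                f"genotype entry at (row {bad[0]}, col {bad[1]}) is outside {{0,1,2}}"
            )
        self.matrix = self.matrix.astype(np.int8, copy=False)
        if not self.individual_ids:
            self.individual_ids = [f"ind{i+1}" for i in range(self.matrix.shape[0])]
        if not self.locus_ids:
            self.locus_ids = [f"snp{j+1}" for j in range(self.matrix.shape[1])]
        if len(self.individual_ids) != self.matrix.shape[0]:
            raise ValueError("individual_ids length does not match matrix rows")
        if len(self.locus_ids) != self.matrix.shape[1]:
            raise ValueError("locus_ids length does not match matrix columns")

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        return self.matrix.shape[1]

    def subset_loci(self, idx: np.ndarray) -> "RawGenotypes":
        idx = np.asarray(idx)
        return RawGenotypes(
            self.matrix[:, idx],
            list(self.individual_ids),
            [self.locus_ids[j] for j in idx],
        )


def allele_frequencies(raw: RawGenotypes) -> np.ndarray:
    """Frequency of the allele coded toward genotype 2, per locus.

    With allele counts 0/1/2 over m individuals this is simply the column
    mean divided by 2.
    """
    return raw.matrix.mean(axis=0) / 2.0


@dataclass
class LocusCoding:
    """Per-locus predictor values for genotypes 0/1/2 and their moments.

    ``gamma[j]`` holds the 3 predictor values at locus j; ``counts[j]``
    the genotype counts; ``xtx[j] = sum_k counts[j,k] * gamma[j,k]**2``
    is the precomputed x'x used in every conditional-mean denominator.
    ``kept`` indexes the retained loci in the original matrix (monomorphic
    loci are dropped for the centered schemes).  The coding is linear in
    the allele count, ``coded = (g - offset)/scale``, which is what
    :meth:`code_values` applies (also to real-valued dosages of selection
    candidates).
    """

    gamma: np.ndarray
    gamma_sq: np.ndarray
    counts: np.ndarray
    xtx: np.ndarray
    allele_freq: np.ndarray
    scheme: str
    kept: np.ndarray
    locus_ids: list[str]
    offset: np.ndarray
    scale: np.ndarray

    @property
    def n(self) -> int:
        return self.gamma.shape[0]

    def code_values(self, values: np.ndarray) -> np.ndarray:
        """Apply the (training-derived) linear coding to allele counts or dosages."""
        values = np.asarray(values, dtype=np.float64)
        return (values - self.offset) / self.scale

    def code_matrix(self, raw: RawGenotypes) -> np.ndarray:
        """Coded m x n predictor matrix for the retained loci of ``raw``."""
        return self.code_values(raw.matrix[:, self.kept])


def _genotype_counts(matrix: np.ndarray) -> np.ndarray:
    counts = np.empty((matrix.shape[1], 3), dtype=np.int64)
    for k in range(3):
        counts[:, k] = (matrix == k).sum(axis=0)
    return counts


def make_locus_coding(raw: RawGenotypes, scheme: str = "centered_scaled") -> LocusCoding:
    """Build the 3-valued predictor coding for every locus.

    Schemes: ``raw`` keeps 0/1/2; ``centered`` subtracts twice the allele
    frequency (``g - 2p``); ``centered_scaled`` additionally divides by
    ``sqrt(2p(1-p))`` so each predictor has unit variance under
    Hardy-Weinberg.  The scaled coding is undefined at monomorphic loci;
    those are dropped with a warning under both centered schemes (kept
    under ``raw``).
    """
    if scheme not in ("raw", "centered", "centered_scaled"):
        raise ValueError(f"unknown coding scheme {scheme!r}")
    p = allele_frequencies(raw)
    if scheme == "raw":
        kept = np.arange(raw.n)
    else:
        poly = (p > 0.0) & (p < 1.0)
        kept = np.flatnonzero(poly)
        if kept.size == 0:
            raise ValueError(
                f"all loci are monomorphic: the {scheme!r} coding is undefined"
            )
        if kept.size < raw.n:
            dropped = [raw.locus_ids[j] for j in np.flatnonzero(~poly)]
            warnings.warn(
                f"dropping {len(dropped)} monomorphic locus/loci under "
                f"scheme {scheme!r}: {dropped[:10]}{'...' if len(dropped) > 10 else ''}",
                stacklevel=2,
            )
    p = p[kept]
    if scheme == "raw":
        offset = np.zeros(kept.size)
        scale = np.ones(kept.size)
    elif scheme == "centered":
        offset = 2.0 * p
        scale = np.ones(kept.size)
    else:
        offset = 2.0 * p
        scale = np.sqrt(2.0 * p * (1.0 - p))
    gamma = (_GENOTYPES[None, :] - offset[:, None]) / scale[:, None]
    gamma_sq = gamma**2
    counts = _genotype_counts(raw.matrix[:, kept])
    xtx = (counts * gamma_sq).sum(axis=1)
    return LocusCoding(
        gamma=gamma,
        gamma_sq=gamma_sq,
        counts=counts,
        xtx=xtx,
        allele_freq=p,
        scheme=scheme,
        kept=kept,
        locus_ids=[raw.locus_ids[j] for j in kept],
        offset=offset,
        scale=scale,
    )


def round_dosages(
    dosages: np.ndarray,
    individual_ids: list[str] | None = None,
    locus_ids: list[str] | None = None,
) -> RawGenotypes:
    """Round real-valued gene contents to the most likely genotype.

    Dosages <= 0.5 become 0, dosages >= 1.5 become 2, everything between
    becomes 1 (boundaries inclusive).  Training individuals need integer
    genotypes for the 3-group bookkeeping; selection candidates may keep
    real dosages (see :func:`rhsgibbs.sampler.predict_gebv`).
    """
    d = np.atleast_2d(np.asarray(dosages, dtype=np.float64))
    bad = np.argwhere((d < 0.0) | (d > 2.0) | ~np.isfinite(d))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"dosage {d[i, j]!r} at (row {i}, col {j}) is outside [0, 2]"
        )
    g = np.ones(d.shape, dtype=np.int8)
    g[d <= 0.5] = 0
    g[d >= 1.5] = 2
    return RawGenotypes(g, individual_ids or [], locus_ids or [])


def assign_blocks(
    n: int,
    s: int,
    ordering: str = "consecutive",
    seed: int | None = None,
) -> list[np.ndarray]:
    """Partition ``n`` locus indices into RHS-blocks of ``s`` loci.

    ``consecutive`` chunks the natural order; ``random`` chunks a
    seed-determined permutation (so that neighbouring SNPs are not always
    evaluated together).  The last block holds ``n % s`` loci when the
    division is not exact.
    """
    if not 1 <= s <= MAX_BLOCK_SIZE:
        raise ValueError(
            f"block size s={s} violates the 2-byte group-code width contract "
            f"(1 <= s <= {MAX_BLOCK_SIZE}, since 3**{MAX_BLOCK_SIZE} = "
            f"{3**MAX_BLOCK_SIZE} is the largest group count that fits)"
        )
    if ordering == "consecutive":
        order = np.arange(n)
    elif ordering == "random":
        order = np.random.default_rng(seed).permutation(n)
    else:
        raise ValueError(f"unknown block ordering {ordering!r}")
    return [order[i : i + s] for i in range(0, n, s)]


@dataclass
class BlockIndex:
    """RHS-block partition with per-individual group codes.

    For a block of size ``s_b`` the group code of an individual with
    within-block genotypes ``g_1..g_{s_b}`` is ``1 + sum_t g_t * 3**(t-1)``
    (positional base-3; reproduces the published s=2 layout where at the
    second locus groups 1-3 carry genotype 0, 4-6 genotype 1, 7-9
    genotype 2).  ``geno_of_group[b][g-1, t]`` decodes group ``g`` back to
    the genotype at within-block position ``t``; zero-count groups are kept.
    """

    s: int
    blocks: list[np.ndarray]
    group_code: np.ndarray  # m x n_blocks, 1-based, uint16
    group_counts: list[np.ndarray]
    geno_of_group: list[np.ndarray]
    _codes0: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def m(self) -> int:
        return self.group_code.shape[0]

    def codes0(self, b: int) -> np.ndarray:
        """Zero-based int64 group codes for block ``b`` (cached)."""
        if not self._codes0:
            self._codes0 = [
                (self.group_code[:, j].astype(np.int64) - 1)
                for j in range(self.n_blocks)
            ]
        return self._codes0[b]

    def n_groups(self, b: int) -> int:
        return 3 ** len(self.blocks[b])

    def decode(self) -> np.ndarray:
        """Reconstruct the raw genotype matrix from the group codes."""
        n = sum(len(bl) for bl in self.blocks)
        out = np.empty((self.m, n), dtype=np.int8)
        for b, loci in enumerate(self.blocks):
            out[:, loci] = self.geno_of_group[b][self.codes0(b)]
        return out


def encode_group_codes(raw: RawGenotypes, partition: list[np.ndarray]) -> BlockIndex:
    """Encode each individual's within-block genotypes as a single group code."""
    seen = np.concatenate(partition) if partition else np.array([], dtype=int)
    if len(seen) != raw.n or len(np.unique(seen)) != raw.n:
        raise ValueError("partition must cover every locus exactly once")
    s = max(len(bl) for bl in partition)
    if not 1 <= s <= MAX_BLOCK_SIZE:
        raise ValueError(f"block size {s} exceeds the group-code width contract")
    m = raw.m
    group_code = np.empty((m, len(partition)), dtype=np.uint16)
    group_counts: list[np.ndarray] = []
    geno_of_group: list[np.ndarray] = []
    for b, loci in enumerate(partition):
        sb = len(loci)
        powers = 3 ** np.arange(sb, dtype=np.int64)
        codes0 = raw.matrix[:, loci].astype(np.int64) @ powers
        group_code[:, b] = codes0 + 1
        ng = 3**sb
        group_counts.append(np.bincount(codes0, minlength=ng))
        geno = ((np.arange(ng)[:, None] // powers[None, :]) % 3).astype(np.int8)
        geno_of_group.append(geno)
    return BlockIndex(
        s=s,
        blocks=[np.asarray(bl) for bl in partition],
        group_code=group_code,
        group_counts=group_counts,
        geno_of_group=geno_of_group,
    )


def cross_counts(index: BlockIndex, b: int, t1: int, t2: int) -> np.ndarray:
    """3x3 tally of individuals by (genotype at position t1, at t2) in block b.

    This is the cross-count matrix N between two block loci, reconstructed
    from the per-group counts alone.
    """
    geno = index.geno_of_group[b]
    counts = index.group_counts[b]
    out = np.zeros((3, 3), dtype=np.int64)
    np.add.at(out, (geno[:, t1], geno[:, t2]), counts)
    return out
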