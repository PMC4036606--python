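"""Resource model and operation-count sweeps.

The dominant array of the residual-updating algorithms is the m x n
1-byte genotype store; RHS-updating replaces it with an m x (n/s) 2-byte
group-code store.  That yields the closed-form RAM predictions
``n m 1e-9`` Gb (original/improved) and ``2 n m 1e-9 / s`` Gb (rhs).
The empirically derived rule for the block size that minimizes CPU time
is a step function of the training-set size m.  Wall time and resident
memory are reported as diagnostics only; operation counts are the
portable proxy for the CPU-time comparisons.
"""

from __future__ import annotations

import json
import sys
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import OpCounters
from .sampler import ChainConfig, PosteriorSummary, Priors, run_chain
from .simulate import SimConfig, simulate_dataset
from .coding import make_locus_coding

__all__ = [
    "RamModel",
    "SweepResult",
    "predict_ram_gb",
    "optimal_block_size",
    "sweep",
    "write_results",
    "peak_rss_gb",
]


@dataclass
class RamModel:
    algorithm: str
    m: int
    n: int
    s: int | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ("original", "improved", "rhs"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.m < 1 or self.n < 1:
            raise ValueError("m and n must be positive")


def predict_ram_gb(model: RamModel) -> float:
    """Predicted RAM (Gb) of the dominant genotype/group-code array."""
    if model.algorithm in ("original", "improved"):
        return model.n * model.m * 1e-9
    if model.s is None or model.s < 1:
        raise ValueError("rhs RAM prediction requires the block size s")
    return 2.0 * model.n * model.m * 1e-9 / model.s


# (upper-exclusive m bound, optimal s); the last band is open-ended
_OPT_S_BANDS = [(1000, 2), (2500, 3), (11000, 4), (50000, 5), (100001, 6)]


def optimal_block_size(m: int) -> int:
    """Block size minimizing CPU time as a step function of m.

    2 below 1000 individuals, 3 up to 2500, 4 up to 11000, 5 up to
    50000, 6 up to 100000; beyond the calibrated range 6 is extrapolated
    with a warning.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    for bound, s in _OPT_S_BANDS:
        if m < bound:
            return s
    warnings.warn(
        f"m={m} exceeds the calibrated range (<= 100000); extrapolating s=6",
        stacklevel=2,
    )
    return 6


@dataclass
class SweepResult:
    """Tidy (m, s, algorithm) grid of op counts, wall time and predicted RAM."""

    table: pd.DataFrame
    iterations: int
    seed: int


def peak_rss_gb() -> float:
    """Peak resident set size of this process in Gb (portable diagnostic)."""
    try:
        import resource

        rss_kb = resource.getrusage(resource.RUSAGE_SELF).ru_maxrss
        if sys.platform == "darwin":  # ru_maxrss is bytes on macOS
            return rss_kb / 1e9
        return rss_kb * 1024 / 1e9
    except ImportError:  # pragma: no cover
        return float("nan")


def sweep(
    m_list: list[int],
    s_list: list[int],
    algorithms: list[str],
    iterations: int = 5,
    seed: int = 0,
    n_snps: int = 420,
    n_qtl: int = 20,
    h2: float = 0.5,
) -> SweepResult:
    """Run short chains over a grid and record op counts, time and RAM.

    ``s_list`` applies to the rhs algorithm only; original/improved get a
    single row per m.  Op counts cover the kernel arithmetic of the whole
    chain (all iterations), so per-iteration figures divide by
    ``iterations``.
    """
    if not m_list or not algorithms or ("rhs" in algorithms and not s_list):
        raise ValueError("sweep grid must be non-empty")
    rows = []
    n_qtl = min(n_qtl, n_snps)
    for m in m_list:
        raw, y, _ = simulate_dataset(SimConfig(m=m, n=n_snps, n_qtl=n_qtl, h2=h2, seed=seed))
        coding = make_locus_coding(raw, "centered_scaled")
        for algorithm in algorithms:
            s_values = s_list if algorithm == "rhs" else [None]
            for s in s_values:
                counters = OpCounters()
                config = ChainConfig(
                    iterations=iterations,
                    burn_in=max(iterations - 1, 0) if iterations > 1 else 0,
                    thin=max(iterations, 1),
                    seed=seed,
                    algorithm=algorithm,
                    block_size=s if s is not None else "auto",
                )
                t0 = time.perf_counter()
                run_chain(y, raw, coding, Priors(), config, counters=counters)
                wall = time.perf_counter() - t0
                rows.append(
                    {
                        "m": m,
                        "n": coding.n,
                        "algorithm": algorithm,
                        "s": s if s is not None else np.nan,
                        "iterations": iterations,
                        "multiplications": counters.multiplications,
                        "additions_subtractions": counters.additions_subtractions,
                        "divisions": counters.divisions,
                        "total_ops": counters.multiplications
                        + counters.additions_subtractions
                        + counters.divisions,
                        "wall_time_s": wall,
                        "predicted_ram_gb": predict_ram_gb(
                            RamModel(algorithm, m, coding.n, s)
                        ),
                        "peak_rss_gb": peak_rss_gb(),
                    }
                )
    return SweepResult(table=pd.DataFrame(rows), iterations=iterations, seed=seed)


def _manifest(extra: dict) -> dict:
    from . import __version__

    return {"package": "rhsgibbs", "version": __version__, **extra}


def write_results(summary, prefix: str | Path) -> list[Path]:
    """Write delimited tables plus a JSON manifest for a run or a sweep."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _csv(df: pd.DataFrame, suffix: str) -> None:
        path = Path(f"{prefix}_{suffix}.csv")
        df.to_csv(path, index=False, float_format="%.12g")
        written.append(path)

    if isinstance(summary, PosteriorSummary):
        _csv(
            pd.DataFrame(
                {
                    "locus": summary.locus_ids,
                    "effect_mean": summary.effect_means,
                    "inclusion_prob": summary.inclusion_probs,
                }
            ),
            "effects",
        )
        _csv(
            pd.DataFrame({"individual": summary.individual_ids, "gebv": summary.gebv}),
            "gebv",
        )
        _csv(
            pd.DataFrame(
                [{"component": k, "value": v} for k, v in summary.var_components.items()]
            ),
            "varcomp",
        )
        _csv(summary.traces, "trace")
        manifest = _manifest(
            {"config": vars(summary.config) if summary.config else None}
        )
    elif isinstance(summary, SweepResult):
        keys = ["m", "n", "algorithm", "s", "iterations"]
        for metric in [
            "multiplications",
            "additions_subtractions",
            "divisions",
            "total_ops",
            "wall_time_s",
            "predicted_ram_gb",
            "peak_rss_gb",
        ]:
            _csv(summary.table[keys + [metric]], metric)
        manifest = _manifest({"iterations": summary.iterations, "seed": summary.seed})
    else:
        raise TypeError(f"cannot write results of type {type(summary).__name__}")

    manifest_path = Path(f"{prefix}_manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    written.append(manifest_path)
    return written
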