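"""Readers for genotype matrices and phenotype files.

Two genotype dialects are supported: a plain delimited matrix (header row
of locus IDs, first column the individual ID, entries 0/1/2) and the
PLINK ``.raw`` additive coding (FID IID PAT MAT SEX PHENOTYPE followed by
one allele-count column per SNP).  Phenotypes are a two-column delimited
file (individual ID, value) joined on ID; unmatched IDs are an error, as
is any missing genotype.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .coding import RawGenotypes

__all__ = ["read_genotype_matrix", "read_plink_raw", "read_phenotypes", "read_dataset"]

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _to_raw(df: pd.DataFrame, ids: list[str], source: str) -> RawGenotypes:
    if df.isna().any().any():
        bad = df.columns[df.isna().any()][0]
        raise ValueError(f"missing genotypes in {source} (e.g. column {bad!r})")
    values = df.to_numpy()
    if not np.all(np.isin(values, [0, 1, 2])):
        raise ValueError(f"{source} contains genotype codes outside {{0,1,2}}")
    return RawGenotypes(values.astype(np.int8), ids, [str(c) for c in df.columns])


def read_genotype_matrix(path: str | Path) -> RawGenotypes:
    """Whitespace/tab-delimited matrix: locus-ID header, ID column, 0/1/2 entries."""
    df = pd.read_csv(path, sep=r"\s+")
    ids = df.iloc[:, 0].astype(str).tolist()
    return _to_raw(df.iloc[:, 1:], ids, str(path))


def read_plink_raw(path: str | Path) -> RawGenotypes:
    """PLINK .raw dialect: skip the six metadata columns, keep allele counts."""
    df = pd.read_csv(path, sep=r"\s+")
    meta = [c for c in _PLINK_META if c in df.columns]
    if "IID" not in meta:
        raise ValueError(f"{path} does not look like a PLINK .raw file (no IID column)")
    ids = df["IID"].astype(str).tolist()
    return _to_raw(df.drop(columns=meta), ids, str(path))


def read_phenotypes(path: str | Path, raw: RawGenotypes) -> np.ndarray:
    """Two-column (ID, value) file joined against the genotype individuals."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    # tolerate an optional header line
    try:
        float(df.iloc[0, 1])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    df = df.iloc[:, :2]
    df.columns = ["id", "value"]
    lookup = dict(zip(df["id"].astype(str), pd.to_numeric(df["value"])))
    missing = [i for i in raw.individual_ids if i not in lookup]
    if missing:
        raise ValueError(f"phenotypes missing for individuals: {missing[:10]}")
    return np.array([lookup[i] for i in raw.individual_ids], dtype=np.float64)


def read_dataset(geno_path: str | Path, pheno_path: str | Path) -> tuple[RawGenotypes, np.ndarray]:
    """Load genotypes (auto-detecting the PLINK .raw dialect) and phenotypes."""
    with open(geno_path) as fh:
        header = fh.readline().split()
    if header[:2] == ["FID", "IID"]:
        raw = read_plink_raw(geno_path)
    else:
        raw = read_genotype_matrix(geno_path)
    return raw, read_phenotypes(pheno_path, raw)
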