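"""Readers and writers for the pipeline's file dialects.

TSV with header rows everywhere; genes as rows in expression matrices;
UTF-8; "NA" as the missing-value token; standard GMT (name, description,
then tab-separated genes) for gene sets, modules and regulons.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression", "write_expression",
    "read_metadata", "write_metadata",
    "read_gmt", "write_gmt",
    "read_signature", "read_drug_table",
]

_NA = "NA"


def read_expression(path) -> pd.DataFrame:
    """Genes x samples log2 expression TSV (header row of sample ids)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dups = sorted({s for s in header if header.count(s) > 1})
    if dups:
        raise ValueError(f"duplicated sample id(s) in {path}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA])
    if df.index.duplicated().any():
        warnings.warn(f"duplicated gene ids in {path}; keeping first occurrence")
        df = df[~df.index.duplicated()]
    bad = df.apply(lambda c: ~pd.to_numeric(c, errors="coerce").notna()
                   & c.notna())
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r} in {path}")
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", na_rep=_NA)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA])
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicated sample id(s) in {path}: {dups}")
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", na_rep=_NA)


def read_gmt(path) -> dict:
    """GMT collection as an ordered mapping name -> gene list."""
    sets = {}
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
            raise ValueError(f"malformed GMT line {ln} in {path}: "
                             "need name, description and at least one gene")
        name = parts[0]
        if name in sets:
            raise ValueError(f"duplicated set name {name!r} in {path}")
        sets[name] = [g for g in parts[2:] if g.strip()]
    return sets


def write_gmt(sets: dict, path, description: str = ".") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_signature(path) -> pd.DataFrame:
    """Marker genes x cell types, linear scale, non-negative."""
    sig = pd.read_csv(path, sep="\t", index_col=0)
    if (sig.to_numpy() < 0).any():
        raise ValueError(f"negative signature entries in {path}")
    if (sig.to_numpy().sum(axis=0) == 0).any():
        raise ValueError(f"all-zero cell-type column in {path}")
    return sig.astype(float)


def read_drug_table(path) -> pd.DataFrame:
    """Drug table with columns drug, gene, action in {inhibits, stimulates}."""
    df = pd.read_csv(path, sep="\t")
    required = {"drug", "gene", "action"}
    if not required <= set(df.columns):
        raise ValueError(f"drug table {path} must have columns {sorted(required)}")
    bad = set(df["action"]) - {"inhibits", "stimulates"}
    if bad:
        raise ValueError(f"unknown drug actions in {path}: {sorted(bad)}")
    return df
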