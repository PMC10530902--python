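"""Readers and writers for the pipeline's plain-text formats.

All tables are UTF-8 TSV. Expression matrices are genes x samples with a
header row of sample ids and the gene id in the first column; labels,
survival tables and edge lists are narrow TSVs; gene-set collections use
the GMT convention (one named set per line: name, description, members).
Missing values are errors, never sentinels. Every writer's output is
parseable by its reader with value equality.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression", "write_expression",
    "read_labels", "write_labels",
    "read_survival", "write_survival",
    "read_gmt", "write_gmt",
    "read_edges", "write_edges",
    "read_gene_list", "read_id_map",
    "read_score_table", "write_score_table",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file violated its expected schema."""


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV.

    Duplicate gene ids are accepted (they are the collapse step's job) but
    logged; NaNs are a schema error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    if df.isna().to_numpy().any():
        raise FormatError(f"{path}: expression matrix contains missing values")
    n_dup = int(df.index.duplicated().sum())
    if n_dup:
        logger.info("%s: %d duplicate gene ids (collapse before scoring)", path, n_dup)
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: labels file needs sample_id and status columns")
    df = df.iloc[:, :2]
    df.columns = ["sample_id", "status"]
    bad = df[~df["status"].isin(["M0", "M1"])]
    if len(bad):
        raise FormatError(
            f"{path}: invalid status {bad['status'].iloc[0]!r} "
            f"for sample {bad['sample_id'].iloc[0]!r}"
        )
    return pd.Series(df["status"].to_numpy(), index=df["sample_id"], name="status")


def write_labels(labels: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": labels.index, "status": labels.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_days", "event"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: survival file needs columns {sorted(required)}")
    if (df["time_days"] <= 0).any():
        raise FormatError(f"{path}: nonpositive survival time")
    if not df["event"].isin([0, 1]).all():
        raise FormatError(f"{path}: event indicator must be 0/1")
    return df[["sample_id", "time_days", "event"]]


def write_survival(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict:
    """Read a GMT gene-set collection: name <tab> description <tab> genes..."""
    collection = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene set {name!r}")
            collection[name] = set(genes)
    return collection


def write_gmt(collection: dict, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, description] + sorted(genes)) + "\n")


def read_edges(path) -> pd.DataFrame:
    """Read a two-column undirected edge TSV; self-loops and duplicate
    (undirected) edges are dropped with a warning."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: edge list needs two columns")
    df = df.iloc[:, :2]
    df.columns = ["gene_a", "gene_b"]
    loops = df["gene_a"] == df["gene_b"]
    if loops.any():
        logger.warning("%s: dropped %d self-loop(s)", path, int(loops.sum()))
        df = df[~loops]
    key = df.apply(lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1)
    dup = key.duplicated()
    if dup.any():
        logger.warning("%s: dropped %d duplicate edge(s)", path, int(dup.sum()))
        df = df[~dup]
    return df.reset_index(drop=True)


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list:
    """One-column gene list (e.g. a gene-universe filter)."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def read_id_map(path) -> dict:
    """Two-column old_id -> group_id TSV (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: id map needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_score_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene")
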