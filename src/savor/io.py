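"""Table readers and writers for the pipeline's plain-text formats.

All inputs are UTF-8 CSV/TSV with a mandatory header and "." decimals.
Readers validate schemas up front and raise with the missing column names;
writers emit machine-precision CSV so a written table re-parses to the same
values.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "read_records",
    "read_reference",
    "read_deg_table",
    "read_expression_matrix",
    "read_annotation",
    "write_table",
    "write_edge_list",
    "write_graphml",
]


class SchemaError(ValueError):
    """An input table does not have the required columns."""


def _require(df: pd.DataFrame, columns: set[str], what: str, path) -> None:
    missing = columns - set(df.columns)
    if missing:
        raise SchemaError(f"{what} at {path} missing columns: {sorted(missing)}")


def read_records(path) -> pd.DataFrame:
    """Long concentration table: ``compound, group, replicate?, concentration``."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty input file: {path}") from exc
    _require(df, {"compound", "group", "concentration"}, "concentration table", path)
    return df


def read_reference(path) -> pd.DataFrame:
    """Taste reference CSV; delegates to :func:`savor.taste.load_reference`."""
    from .taste import load_reference

    return load_reference(path)


def read_deg_table(path) -> pd.DataFrame:
    """DEG table CSV/TSV with ``gene_id, log2fc`` and ``fdr`` or ``pvalue``."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty input file: {path}") from exc
    _require(df, {"gene_id", "log2fc"}, "DEG table", path)
    if "fdr" not in df.columns and "pvalue" not in df.columns:
        raise SchemaError(f"DEG table at {path} needs an 'fdr' or 'pvalue' column")
    return df


def read_expression_matrix(path) -> pd.DataFrame:
    """Genes x samples TSV: first column gene ids, header row sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise SchemaError(f"expression matrix at {path} has no sample columns")
    return df


def read_annotation(path) -> dict[str, set]:
    """Two-column TSV ``gene_id<TAB>function`` -> gene -> set of functions."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "function"])
    out: dict[str, set] = {}
    for row in df.itertuples():
        out.setdefault(str(row.gene_id), set()).add(str(row.function))
    return out


def write_table(df: pd.DataFrame, path, decimals: int | None = None) -> None:
    """Write a tidy CSV; ``decimals`` fixes display precision for report tables."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fmt = f"%.{decimals}f" if decimals is not None else None
    df.to_csv(path, index=False, float_format=fmt)


def write_edge_list(graph: nx.Graph, path) -> None:
    """Edge list CSV ``gene_a, gene_b, r, q``."""
    rows = [
        {"gene_a": u, "gene_b": v, "r": d.get("r"), "q": d.get("q")}
        for u, v, d in graph.edges(data=True)
    ]
    write_table(pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "q"]), path)


def write_graphml(graph: nx.Graph, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(graph, path)
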