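"""Delimited-text readers and writers.

The default file layout follows the common expression-table convention:
samples in rows, genes in columns, with one column holding the class
label.  ``transposed=True`` accepts the other dialect (genes in rows,
samples in columns, the label held in a row of the same name).  The
in-memory orientation is always genes x samples.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    GeneScoreRecord,
    LabeledExpressionData,
    SelectionResult,
    ValidationError,
)

__all__ = ["read_expression", "write_expression", "write_selection", "read_selection"]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_expression(path, label_column: str, transposed: bool = False) -> LabeledExpressionData:
    """Read a labeled expression table from CSV/TSV.

    Labels are mapped onto {0, 1} by the sorted order of the two
    observed label values.  Missing or non-numeric expression cells are
    rejected with an error naming the offending gene and sample.
    """
    df = _read_table(path)
    if transposed:
        df = df.T
    if label_column not in df.columns:
        raise ValidationError(
            f"label column {label_column!r} not found in {path}"
        )
    raw_labels = df[label_column].tolist()
    expr = df.drop(columns=[label_column])
    numeric = expr.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        cell = expr.iat[i, j]
        kind = "missing" if pd.isna(cell) else f"non-numeric ({cell!r})"
        raise ValidationError(
            f"{kind} expression value for gene {expr.columns[j]!r}, "
            f"sample {expr.index[i]!r}"
        )
    return LabeledExpressionData.from_raw_labels(
        numeric.to_numpy(dtype=float).T,
        gene_ids=[str(g) for g in expr.columns],
        sample_ids=[str(s) for s in expr.index],
        raw_labels=raw_labels,
    )


def write_expression(data: LabeledExpressionData, path, label_column: str = "class") -> None:
    """Write in the default dialect: samples in rows, genes in columns,
    plus the label column (original class names)."""
    df = pd.DataFrame(
        data.values.T, index=data.sample_ids, columns=data.gene_ids
    )
    df[label_column] = [data.class_names[c] for c in data.labels]
    sep = "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep)


def write_selection(result: SelectionResult, scores: list[GeneScoreRecord], path) -> None:
    """Write the selected set as a TSV report: rank, gene_id, rpos, rdc,
    source (1-based ranks, final order)."""
    by_id = {rec.gene_id: rec for rec in scores}
    rows = []
    for rank, gene in enumerate(result.final, start=1):
        if gene not in by_id:
            raise ValueError(f"gene {gene!r} in selection but not in scores")
        rec = by_id[gene]
        rows.append(
            {
                "rank": rank,
                "gene_id": gene,
                "rpos": rec.rpos,
                "rdc": rec.rdc,
                "source": result.provenance.get(gene, ""),
            }
        )
    pd.DataFrame(rows, columns=["rank", "gene_id", "rpos", "rdc", "source"]).to_csv(
        path, sep="\t", index=False
    )


def read_selection(path) -> pd.DataFrame:
    """Read back a selection report written by :func:`write_selection`."""
    return pd.read_csv(path, sep="\t")
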