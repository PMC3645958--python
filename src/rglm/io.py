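"""Tabular dataset reading/writing and model persistence.

Feature matrices and outcomes travel as delimited text (TSV or CSV, inferred
from the file extension) with a header row and the sample ID in the first
column.  The outcome file is aligned to the feature matrix by sample ID, so
row order is irrelevant.  Trained ensembles round-trip through a JSON
document that preserves predictions bit-exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import RGLMModel

__all__ = [
    "read_dataset",
    "read_table",
    "write_table",
    "write_predictions",
    "write_model",
    "read_model",
]

log = logging.getLogger("rglm")


def _sep(path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","


def read_table(path) -> pd.DataFrame:
    """Read a delimited table with sample IDs in the first column; every data
    cell must be numeric and present."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    bad = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(bad):
        for col in bad:
            rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, "
                f"row(s) {list(rows[:5])}"
            )
    if df.isna().any().any():
        cells = [
            f"(row {df.index[int(r)]}, column {df.columns[int(c)]})"
            for r, c in zip(*np.where(df.isna().to_numpy()))
        ][:5]
        raise ValueError(f"{path}: missing values at {', '.join(cells)}")
    return df


def read_dataset(features_path, outcome_path, outcome_column: "str | None" = None):
    """Read features and outcome and align them by sample ID.

    Returns ``(X, y, sample_ids, feature_names)`` with rows in the feature
    file's order.  Raises listing the offending IDs when the two files do not
    cover the same samples.
    """
    feats = read_table(features_path)
    out = read_table(outcome_path)
    missing = feats.index.difference(out.index)
    extra = out.index.difference(feats.index)
    if len(missing) or len(extra):
        raise ValueError(
            f"sample IDs disagree between {features_path} and {outcome_path}: "
            f"missing from outcome {list(missing[:5])}, "
            f"unknown in outcome {list(extra[:5])}"
        )
    col = outcome_column or out.columns[0]
    if col not in out.columns:
        raise ValueError(f"{outcome_path}: no column named {col!r}")
    y = out.loc[feats.index, col]
    return (
        feats.to_numpy(dtype=float),
        y.to_numpy(dtype=float),
        list(feats.index.astype(str)),
        list(feats.columns.astype(str)),
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep(path), index=True)


def write_predictions(path, sample_ids, values, column: str = "prediction") -> None:
    pd.DataFrame({column: values}, index=pd.Index(sample_ids, name="sample")).to_csv(
        path, sep=_sep(path)
    )


def write_model(model: RGLMModel, path) -> None:
    Path(path).write_text(model.to_json())
    log.info("model written to %s", path)


def read_model(path) -> RGLMModel:
    return RGLMModel.from_json(Path(path).read_text())
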