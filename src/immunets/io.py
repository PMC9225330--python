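"""Reading and writing the pipeline's tabular formats.

Expression matrices are plain TSV with genes in rows and a header of
sample ids (or the transpose, selected by ``orientation``); annotations
and survival tables are TSV with one row per sample/patient. Duplicate
gene ids are resolved by a configurable policy.
"""

from __future__ import annotations

import json
import hashlib

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


def read_expression(
    path,
    orientation: str = "genes_in_rows",
    duplicate_policy: str = "error",
    annotations: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression matrix.

    Parameters
    ----------
    orientation : 'genes_in_rows' or 'samples_in_rows'.
    duplicate_policy : 'error' rejects duplicate gene ids;
        'keep-max-variance' keeps, per duplicated id, the row with the
        largest variance.
    """
    try:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(header) != len(set(header)):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise ValueError(f"duplicate sample ids in {path}: {dupes[:5]}")
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed expression TSV {path}: {exc}") from exc
    if orientation == "samples_in_rows":
        df = df.T
    elif orientation != "genes_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ]
    if len(non_numeric):
        for col in non_numeric:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                # +2: header line and 1-based numbering
                line = df.index.get_loc(bad.index[0]) + 2
                raise ValueError(
                    f"non-numeric cell in column {col!r} near line {line} of {path}"
                )
        df = df.astype(float)

    if df.index.duplicated().any():
        if duplicate_policy == "error":
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in {path}: {dupes[:5]}")
        elif duplicate_policy == "keep-max-variance":
            variances = df.var(axis=1)
            order = np.argsort(-variances.to_numpy(), kind="mergesort")
            df = df.iloc[order]
            df = df[~df.index.duplicated(keep="first")]
        else:
            raise ValueError(f"unknown duplicate policy {duplicate_policy!r}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dupes[:5]}")
    return ExpressionMatrix(df, annotations)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t")


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t")


def read_edge_list(path) -> list:
    """2/3-column TSV edge list -> list of (a, b) pairs (weight ignored)."""
    edges = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or parts[0].lower() in {"gene_a", "source"}:
                continue
            edges.append((parts[0], parts[1]))
    return edges


def read_annotation_map(path) -> dict:
    """2-column TSV (gene, term) -> gene -> set of terms."""
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or parts[0].lower() == "gene":
                continue
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def read_survival_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"survival table {path} lacks required column {col!r}")
    df["event"] = df["event"].astype(bool)
    return df


def file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
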