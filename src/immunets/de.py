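"""Treatment-response differential expression and cross-cohort validation.

RECIST codes map to analysis classes (CR/PR -> response, PD ->
non-response, SD excluded). After low-expression filtering, each gene is
tested with a two-sided Mann-Whitney U between the response classes
(exact for small groups without ties, tie-corrected normal approximation
otherwise), BH-corrected across genes, and flagged as passing when
q < 0.05 and the linear-scale fold change is at least 2 in either
direction. Passing genes are Blom-transformed for Euclidean-distance
hierarchical clustering, and a biomarker panel is the intersection of
genes passing in a discovery and a validation cohort, with direction
concordance recorded per gene (discordant genes are kept but flagged).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage

from .matrix import ExpressionMatrix
from .stats import bh_adjust, blom_transform

RECIST_CLASS = {"CR": "response", "PR": "response", "PD": "non-response", "SD": "excluded"}

FOLD_PSEUDOCOUNT = 0.01  # FPKM/TPM inputs contain zeros


def classify_response(recist_codes) -> pd.Series:
    """Map RECIST codes to response / non-response / excluded classes."""
    codes = pd.Series(recist_codes)
    if codes.empty:
        raise ValueError("empty RECIST input")
    unknown = codes[~codes.isin(RECIST_CLASS)]
    if len(unknown):
        offender = unknown.index[0]
        raise ValueError(
            f"unknown RECIST code {unknown.iloc[0]!r} for sample {offender!r}"
        )
    classes = codes.map(RECIST_CLASS)
    if (classes == "response").sum() == 0 and (classes == "non-response").sum() == 0:
        raise ValueError("both response groups are empty")
    return classes


def filter_low_expression(
    matrix: ExpressionMatrix, min_count: float = 1.0, min_proportion: float = 0.25
) -> ExpressionMatrix:
    """Drop genes not exceeding `min_count` in >= ceil(min_proportion * n) samples.

    The proportion boundary is inclusive: a gene above the count
    threshold in exactly ``ceil(min_proportion * n)`` samples is kept.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("expression values must be non-negative for filtering")
    n = matrix.n_samples
    need = math.ceil(min_proportion * n)
    keep = (vals > min_count).sum(axis=1) >= need
    if not keep.any():
        raise ValueError("no genes pass the low-expression filter")
    return ExpressionMatrix(matrix.values.loc[keep], matrix.annotations)


def _mann_whitney(x: np.ndarray, y: np.ndarray, exact_max_n: int = 8):
    """Two-sided Mann-Whitney U: exact for small tie-free groups, else normal."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if min(x.size, y.size) <= exact_max_n and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def mann_whitney_de(
    matrix: ExpressionMatrix,
    classes: pd.Series,
    q_max: float = 0.05,
    fc_min: float = 2.0,
) -> pd.DataFrame:
    """Per-gene Mann-Whitney DE table between response classes.

    Fold change is the ratio of linear-scale group means with a small
    pseudocount; direction records which class has the larger mean. A
    gene passes when q < ``q_max`` and the fold change is >= ``fc_min``
    or <= 1/``fc_min``. Genes constant across all tested samples get
    p = 1 (and fold change 1).
    """
    classes = classes.reindex(matrix.values.columns)
    resp_ids = classes.index[classes == "response"]
    nonresp_ids = classes.index[classes == "non-response"]
    if len(resp_ids) < 2 or len(nonresp_ids) < 2:
        raise ValueError("both groups need at least 2 samples")
    xr = matrix.values[resp_ids].to_numpy(dtype=float)
    xn = matrix.values[nonresp_ids].to_numpy(dtype=float)

    n_genes = matrix.n_genes
    u = np.empty(n_genes)
    p = np.empty(n_genes)
    for i in range(n_genes):
        xi, yi = xr[i], xn[i]
        if np.all(xi == xi[0]) and np.all(yi == xi[0]):
            u[i], p[i] = xi.size * yi.size / 2.0, 1.0
            continue
        u[i], p[i] = _mann_whitney(xi, yi)

    mean_r = xr.mean(axis=1)
    mean_n = xn.mean(axis=1)
    fc = (mean_r + FOLD_PSEUDOCOUNT) / (mean_n + FOLD_PSEUDOCOUNT)
    q = bh_adjust(p)
    direction = np.where(fc >= 1.0, "up_in_response", "up_in_nonresponse")
    passes = (q < q_max) & ((fc >= fc_min) | (fc <= 1.0 / fc_min))
    return pd.DataFrame(
        {
            "U": u,
            "p": p,
            "q": q,
            "fold_change": fc,
            "direction": direction,
            "passes": passes,
        },
        index=matrix.values.index,
    )


def de_pipeline(
    matrix: ExpressionMatrix,
    recist_key: str = "recist",
    min_count: float = 1.0,
    min_proportion: float = 0.25,
    q_max: float = 0.05,
    fc_min: float = 2.0,
    candidate_genes=None,
) -> pd.DataFrame:
    """Filter -> classify -> Mann-Whitney DE on one cohort.

    SD patients are excluded before the filter statistics are computed,
    matching an analysis restricted to assessable response classes.
    ``candidate_genes`` optionally restricts testing (e.g. to the
    specificity-filtered network genes measured in the cohort).
    """
    classes = classify_response(matrix.annotations[recist_key])
    tested_ids = classes.index[classes != "excluded"]
    sub = matrix.subset_samples(tested_ids)
    if candidate_genes is not None:
        sub = sub.subset_genes([g for g in candidate_genes if g in sub.values.index])
    sub = filter_low_expression(sub, min_count=min_count, min_proportion=min_proportion)
    return mann_whitney_de(sub, classes.loc[tested_ids], q_max=q_max, fc_min=fc_min)


def blom_matrix(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Blom-transform each gene (row) across samples."""
    vals = matrix.values.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = np.vstack([blom_transform(row) for row in vals])
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.annotations,
    )


@dataclass
class ClusterOrder:
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def cluster_order(matrix: ExpressionMatrix, method: str = "complete") -> ClusterOrder:
    """Hierarchical clustering (Euclidean distance) leaf orders for both axes."""
    vals = matrix.values.to_numpy(dtype=float)
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    row_link = linkage(vals, method=method, metric="euclidean")
    col_link = linkage(vals.T, method=method, metric="euclidean")
    rows = [matrix.values.index[i] for i in leaves_list(row_link)]
    cols = [matrix.values.columns[i] for i in leaves_list(col_link)]
    return ClusterOrder(rows, cols, row_link, col_link)


def validate_panel(discovery: pd.DataFrame, validation: pd.DataFrame) -> pd.DataFrame:
    """Biomarker panel: genes passing in both cohorts, with concordance flags.

    Genes that validate with the opposite direction of effect are
    retained but flagged ``concordant = False`` — a discordant validated
    gene is still informative (e.g. splice-variant effects can flip the
    apparent direction between platforms).
    """
    shared = discovery.index.intersection(validation.index)
    rows = []
    for g in shared:
        d, v = discovery.loc[g], validation.loc[g]
        if bool(d["passes"]) and bool(v["passes"]):
            rows.append(
                {
                    "gene": g,
                    "direction_discovery": d["direction"],
                    "direction_validation": v["direction"],
                    "concordant": d["direction"] == v["direction"],
                    "q_discovery": d["q"],
                    "q_validation": v["q"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "direction_discovery",
            "direction_validation",
            "concordant",
            "q_discovery",
            "q_validation",
        ],
    ).set_index("gene") if rows else pd.DataFrame(
        columns=[
            "direction_discovery",
            "direction_validation",
            "concordant",
            "q_discovery",
            "q_validation",
        ],
        index=pd.Index([], name="gene"),
    )
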