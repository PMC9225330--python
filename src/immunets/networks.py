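"""Per-cell-type co-expression network construction.

The protocol: a genome-wide one-way ANOVA screen across the cell-type x
state design strata (BH-corrected, q < 0.01 by default) selects genes
whose expression is regulated anywhere in the compendium; then, within
each cell type separately, all pairs of retained genes are tested for
Pearson correlation across that cell type's samples, BH correction is
applied over the tested pairs within the cell type, and an edge is kept
only when both the effect-size and significance thresholds hold
(r > 0.9 and q < 0.01 by default). The retained edges define one
undirected co-regulation network per cell type; a gene belongs to a
network only through at least one retained edge, and cell types whose
edge set is empty produce no network at all.

The correlation threshold is signed: strong negative correlation is not
an edge.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import ExpressionMatrix
from .stats import bh_adjust


@dataclass
class CoexpressionNetwork:
    """One cell type's undirected, correlation-weighted gene graph."""

    cell_type: str
    # edge -> (r, q); keys are sorted unordered pairs
    edges: dict = field(default_factory=dict)

    @property
    def nodes(self) -> set:
        out: set = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "r": r, "q": q}
            for (a, b), (r, q) in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "q"])


def anova_screen(
    matrix: ExpressionMatrix, group_key: str = "cell_type", q_threshold: float = 0.01
):
    """Genome-wide one-way fixed-effects ANOVA across annotation groups.

    Returns ``(screen, retained)`` where ``screen`` is a DataFrame
    indexed by gene with columns F, p, q and ``retained`` is the list of
    genes with q < ``q_threshold``. Groups are the distinct values of the
    ``group_key`` annotation column; the default grouping is the finest
    design stratum available (see :func:`design_groups`).

    Genes with zero variance everywhere (F undefined, 0/0) are assigned
    p = 1 with a warning; genes with between-group signal but zero
    within-group variance get p = 0 (infinite F).
    """
    if not 0 < q_threshold < 1:
        raise ValueError("q_threshold must be in (0, 1)")
    groups = matrix.annotations[group_key].to_numpy()
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 samples")

    x = matrix.values.to_numpy(dtype=float)
    n = x.shape[1]
    k = len(labels)
    grand = x.mean(axis=1)
    ss_between = np.zeros(x.shape[0])
    ss_within = np.zeros(x.shape[0])
    for lab, cnt in zip(labels, counts):
        cols = groups == lab
        gm = x[:, cols].mean(axis=1)
        ss_between += cnt * (gm - grand) ** 2
        ss_within += ((x[:, cols] - gm[:, None]) ** 2).sum(axis=1)

    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    p = sps.f.sf(f, df_b, df_w)
    # zero everywhere: 0/0 -> no evidence against the null
    degenerate = (ss_within <= 0) & np.isclose(ss_between, 0.0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) constant across all samples; p set to 1"
        )
        f = np.where(degenerate, 0.0, f)
        p = np.where(degenerate, 1.0, p)
    # signal with zero residual variance: infinitely significant
    separated = (ss_within <= 0) & ~degenerate
    p = np.where(separated, 0.0, p)

    q = bh_adjust(p)
    screen = pd.DataFrame({"F": f, "p": p, "q": q}, index=matrix.values.index)
    retained = screen.index[screen["q"] < q_threshold].tolist()
    return screen, retained


def design_groups(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Add a combined cell_type x state grouping column named 'group'."""
    ann = matrix.annotations.copy()
    if "state" in ann.columns:
        ann["group"] = ann["cell_type"].astype(str) + "/" + ann["state"].astype(str)
    else:
        ann["group"] = ann["cell_type"].astype(str)
    return ExpressionMatrix(matrix.values, ann)


def pearson_edge_test(x, y):
    """Pearson r with two-sided p from the t transform on n-2 df.

    ``t = r * sqrt((n - 2) / (1 - r^2))``; at |r| = 1 the p-value is 0.
    Raises on zero variance (callers exclude such pairs from the BH
    family).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("correlation test needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return r, float(p)


def _pairwise_r_p(values: np.ndarray):
    """All-pairs Pearson r and two-sided p across rows of `values`."""
    n = values.shape[1]
    sd = values.std(axis=1)
    # relative tolerance: an all-equal row carries rounding-level jitter
    ok = sd > 1e-10 * np.maximum(1.0, np.abs(values).max(axis=1))
    r = np.corrcoef(values[ok])
    if r.ndim == 0:  # single row
        r = np.array([[1.0]])
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    return r, p, np.flatnonzero(ok)


def build_cell_network(
    matrix: ExpressionMatrix,
    cell_type: str,
    candidate_genes,
    r_min: float = 0.9,
    q_max: float = 0.01,
) -> CoexpressionNetwork:
    """Correlation network for one cell type over the candidate gene set.

    All candidate pairs are tested on the cell type's samples only; BH is
    applied over the tested pairs within this cell type; an edge is kept
    iff r > r_min and q < q_max. Zero-variance genes are skipped (their
    pairs never enter the BH family), with a warning.
    """
    sub = matrix.samples_where("cell_type", cell_type)
    if sub.n_samples < 3:
        raise ValueError(
            f"cell type {cell_type!r} has {sub.n_samples} samples; need >= 3"
        )
    candidates = [g for g in candidate_genes if g in sub.values.index]
    if len(candidates) < 2:
        return CoexpressionNetwork(cell_type)
    vals = sub.values.loc[candidates].to_numpy(dtype=float)
    r_mat, p_mat, ok_idx = _pairwise_r_p(vals)
    n_dropped = len(candidates) - ok_idx.size
    if n_dropped:
        warnings.warn(
            f"{n_dropped} zero-variance gene(s) skipped in {cell_type}"
        )
    kept_genes = [candidates[i] for i in ok_idx]
    m = len(kept_genes)
    iu = np.triu_indices(m, k=1)
    rs = r_mat[iu]
    ps = p_mat[iu]
    if ps.size == 0:
        return CoexpressionNetwork(cell_type)
    qs = bh_adjust(ps)
    keep = (rs > r_min) & (qs < q_max)
    edges = {}
    ii, jj = iu
    for idx in np.flatnonzero(keep):
        a, b = kept_genes[ii[idx]], kept_genes[jj[idx]]
        key = (a, b) if a <= b else (b, a)
        edges[key] = (float(rs[idx]), float(qs[idx]))
    return CoexpressionNetwork(cell_type, edges)


def build_immunets(
    matrix: ExpressionMatrix,
    cell_type_key: str = "cell_type",
    anova_q: float = 0.01,
    r_min: float = 0.9,
    q_max: float = 0.01,
    group_key: str | None = None,
) -> dict:
    """Full protocol: ANOVA screen then one correlation network per cell type.

    Returns a mapping cell type -> CoexpressionNetwork containing only
    cell types that yielded at least one retained edge (a cell type whose
    candidate genes never pass both thresholds is absent from the map).
    """
    if group_key is None:
        with_groups = design_groups(matrix)
        group_key = "group"
    else:
        with_groups = matrix
    _, retained = anova_screen(with_groups, group_key=group_key, q_threshold=anova_q)
    networks = {}
    for ct in pd.unique(matrix.annotations[cell_type_key]):
        net = build_cell_network(matrix, ct, retained, r_min=r_min, q_max=q_max)
        if net.n_edges > 0:
            networks[ct] = net
        else:
            warnings.warn(f"protocol produced no network for cell type {ct!r}")
    return networks


def write_network_tsv(network: CoexpressionNetwork, path) -> None:
    network.edge_table().to_csv(path, sep="\t", index=False)


def write_network_sif(network: CoexpressionNetwork, path) -> None:
    with open(path, "w") as fh:
        for (a, b) in sorted(network.edges):
            fh.write(f"{a}\tpp\t{b}\n")
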