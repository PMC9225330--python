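"""Focus networks: functional coherence filtering on a reference network.

Given a candidate gene list (the specificity-filtered genes of one cell
type) and a reference functional network (HumanNet-style edge list), a
focus network keeps the candidates that are more densely interconnected
in the reference than expected by chance. Coherence is assessed by a
degree-preserving permutation null: candidate labels are reassigned
uniformly within degree strata (quintiles) of the reference node set,
which controls for hub bias; a node's empirical p-value is the chance of
seeing its observed within-candidate degree or more among null draws
from its own stratum. BH correction is applied across candidate nodes
and nodes with q below the threshold are retained, along with the
induced edges among them. Clusters are the connected components of the
retained subgraph, and each cluster is annotated by hypergeometric
term enrichment against a caller-supplied background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust


@dataclass
class FocusNetwork:
    nodes: set
    edges: set  # sorted unordered pairs
    node_table: pd.DataFrame  # per-candidate: observed degree, p, q, retained
    clusters: list = field(default_factory=list)  # list of gene sets


def load_reference_network(edges) -> nx.Graph:
    """Reference network from an iterable of (a, b) or (a, b, weight)."""
    g = nx.Graph()
    for e in edges:
        a, b = e[0], e[1]
        if a == b:
            continue
        g.add_edge(a, b)
    return g


def induced_subgraph(genes, ref: nx.Graph) -> set:
    """Edges of the reference with both endpoints in `genes`."""
    gene_set = set(genes)
    out = set()
    for a, b in ref.edges():
        if a in gene_set and b in gene_set:
            out.add((a, b) if a <= b else (b, a))
    return out


def _degree_strata(ref: nx.Graph, n_strata: int = 5) -> dict:
    """node -> stratum index, by degree quintile over reference nodes."""
    nodes = list(ref.nodes())
    degrees = np.array([ref.degree(v) for v in nodes], dtype=float)
    # quantile bin edges; duplicate edges collapse for very uniform graphs
    qs = np.quantile(degrees, np.linspace(0, 1, n_strata + 1)[1:-1])
    strata = np.searchsorted(np.unique(qs), degrees, side="right")
    return dict(zip(nodes, strata.tolist()))


def coherence_filter(
    genes,
    ref: nx.Graph,
    n_permutations: int = 1000,
    q_max: float = 0.05,
    seed: int = 0,
) -> FocusNetwork:
    """Retain candidates whose induced degree beats a degree-preserving null.

    For each permutation, the candidate set is re-drawn uniformly within
    degree strata of the reference (same per-stratum counts as the
    observed candidates). A candidate's null distribution pools the
    induced degrees of permuted-set members from its own stratum; its
    empirical p-value is ``(1 + #{null >= observed}) / (1 + #null)``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = np.random.default_rng(seed)
    candidates = sorted(set(genes) & set(ref.nodes()))
    obs_edges = induced_subgraph(candidates, ref)
    obs_graph = nx.Graph(list(obs_edges))
    connected = (
        [g for g in candidates if g in obs_graph and obs_graph.degree(g) > 0]
        if obs_edges
        else []
    )
    if len(connected) < 3:
        warnings.warn(
            "fewer than 3 connected candidate genes; focus network is empty"
        )
        table = pd.DataFrame(
            {"degree": 0, "p": 1.0, "q": 1.0, "retained": False},
            index=pd.Index(candidates, name="gene"),
        )
        return FocusNetwork(set(), set(), table, [])

    strata = _degree_strata(ref)
    cand_strata = np.array([strata[g] for g in candidates])
    obs_degree = np.array([obs_graph.degree(g) if g in obs_graph else 0 for g in candidates])

    # pools of reference nodes per stratum
    stratum_pool = {}
    for v, s in strata.items():
        stratum_pool.setdefault(s, []).append(v)
    per_stratum_counts = {
        s: int((cand_strata == s).sum()) for s in np.unique(cand_strata)
    }

    null_degrees: dict = {s: [] for s in per_stratum_counts}
    for _ in range(n_permutations):
        perm_set = []
        perm_strata = []
        for s, cnt in per_stratum_counts.items():
            pool = stratum_pool[s]
            take = rng.choice(len(pool), size=min(cnt, len(pool)), replace=False)
            for i in take:
                perm_set.append(pool[i])
                perm_strata.append(s)
        pset = set(perm_set)
        for v, s in zip(perm_set, perm_strata):
            d = sum(1 for u in ref.neighbors(v) if u in pset)
            null_degrees[s].append(d)

    pvals = np.empty(len(candidates))
    for i, (g, s, d) in enumerate(zip(candidates, cand_strata, obs_degree)):
        null = np.asarray(null_degrees[s])
        pvals[i] = (1.0 + np.sum(null >= d)) / (1.0 + null.size)
    qvals = bh_adjust(pvals)
    retained_mask = qvals < q_max
    retained = {g for g, keep in zip(candidates, retained_mask) if keep}
    retained_edges = {e for e in obs_edges if e[0] in retained and e[1] in retained}

    table = pd.DataFrame(
        {
            "degree": obs_degree,
            "p": pvals,
            "q": qvals,
            "retained": retained_mask,
        },
        index=pd.Index(candidates, name="gene"),
    )
    clusters = cluster_focus(retained_edges)
    return FocusNetwork(retained, retained_edges, table, clusters)


def cluster_focus(edges) -> list:
    """Connected components of the retained subgraph (singletons dropped)."""
    g = nx.Graph(list(edges))
    comps = [set(c) for c in nx.connected_components(g) if len(c) >= 2]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)[0]))


def enrich_cluster(
    cluster, annotation: dict, background, q_max: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric term enrichment of a cluster against a background.

    ``annotation`` maps gene -> set of terms. For each term with at least
    one background gene, the upper-tail p-value is
    ``P(X >= k)`` for X hypergeometric(M=|background|, n=|term genes in
    background|, N=|cluster|), k = observed overlap. BH across terms.
    Returns all terms with their p/q; callers filter on ``q < q_max``
    via the ``significant`` column.
    """
    background = set(background)
    cluster = set(cluster)
    if not cluster <= background:
        raise ValueError("cluster must be a subset of the background")
    term_genes: dict = {}
    all_terms: set = set()
    for g, terms in annotation.items():
        terms = [terms] if isinstance(terms, str) else list(terms)
        all_terms.update(terms)
        if g not in background:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(g)
    absent = all_terms - set(term_genes)
    if absent:
        warnings.warn(
            f"{len(absent)} term(s) have no background genes and were skipped"
        )
    rows = []
    m_total = len(background)
    for term, genes_in_term in sorted(term_genes.items()):
        k = len(cluster & genes_in_term)
        p = float(sps.hypergeom.sf(k - 1, m_total, len(genes_in_term), len(cluster)))
        rows.append(
            {
                "term": term,
                "overlap": k,
                "term_size": len(genes_in_term),
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] < q_max
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def write_focus_sif(focus: FocusNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(focus.edges):
            fh.write(f"{a}\tpp\t{b}\n")


def write_focus_nodes(focus: FocusNetwork, path) -> None:
    focus.node_table.to_csv(path, sep="\t")
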