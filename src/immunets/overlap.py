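"""Membership accounting across the per-cell-type networks.

A gene can appear in several of the cell-type networks; this module
tabulates exact membership (which networks contain each gene), derives
the pairwise-unique overlap matrix (diagonal = genes in exactly one
network, off-diagonal = genes in exactly that pair and no other), and
applies the specificity filter that keeps genes present in at most two
networks — the gene list passed on to focus-network derivation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MembershipTable:
    """gene -> set of network labels containing it."""

    memberships: dict
    labels: list

    def __post_init__(self):
        known = set(self.labels)
        for g, s in self.memberships.items():
            if not s:
                raise ValueError(f"gene {g!r} has empty membership")
            unknown = set(s) - known
            if unknown:
                raise ValueError(f"gene {g!r} references unknown networks {unknown}")

    @property
    def union_size(self) -> int:
        return len(self.memberships)

    def count_by_multiplicity(self) -> dict:
        out: dict = {}
        for s in self.memberships.values():
            out[len(s)] = out.get(len(s), 0) + 1
        return out


def membership(networks: dict) -> MembershipTable:
    """Exact network membership from a label -> CoexpressionNetwork map.

    Membership is defined by network node sets, i.e. genes with at least
    one retained edge; candidate genes that never acquired an edge do not
    count.
    """
    if not networks:
        raise ValueError("need at least one network")
    labels = list(networks)
    table: dict = {}
    for label, net in networks.items():
        for g in net.nodes:
            table.setdefault(g, set()).add(label)
    return MembershipTable(table, labels)


def membership_from_node_sets(node_sets: dict) -> MembershipTable:
    """Membership directly from a label -> iterable-of-genes map."""
    labels = list(node_sets)
    table: dict = {}
    for label, genes in node_sets.items():
        for g in genes:
            table.setdefault(g, set()).add(label)
    return MembershipTable(table, labels)


def unique_overlap_matrix(table: MembershipTable) -> pd.DataFrame:
    """Pairwise-unique overlap counts over the network labels.

    ``M[k, k]`` counts genes found in network k and nowhere else;
    ``M[j, k]`` (j != k) counts genes found in exactly {j, k}. Genes in
    three or more networks contribute to no cell. The matrix is
    symmetric.
    """
    labels = table.labels
    idx = {lab: i for i, lab in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)), dtype=int)
    for gene, nets in table.memberships.items():
        if len(nets) == 1:
            (a,) = nets
            mat[idx[a], idx[a]] += 1
        elif len(nets) == 2:
            a, b = sorted(nets, key=idx.get)
            mat[idx[a], idx[b]] += 1
            mat[idx[b], idx[a]] += 1
    return pd.DataFrame(mat, index=labels, columns=labels)


def specificity_filter(table: MembershipTable, max_networks: int = 2) -> set:
    """Genes present in at most `max_networks` of the networks."""
    if max_networks < 1:
        raise ValueError("max_networks must be >= 1")
    return {g for g, s in table.memberships.items() if len(s) <= max_networks}


def network_summary(networks: dict) -> pd.DataFrame:
    """Per-network node count, edge count and mean degree (2E/V).

    Empty networks are excluded with a warning. The returned frame also
    carries the union gene count as ``df.attrs['union_genes']``.
    """
    rows = []
    union: set = set()
    for label, net in networks.items():
        nodes = net.nodes
        if not nodes:
            warnings.warn(f"network {label!r} is empty; excluded from summary")
            continue
        union |= nodes
        rows.append(
            {
                "network": label,
                "n_nodes": len(nodes),
                "n_edges": net.n_edges,
                "mean_degree": 2.0 * net.n_edges / len(nodes),
            }
        )
    df = pd.DataFrame(rows, columns=["network", "n_nodes", "n_edges", "mean_degree"])
    df.attrs["union_genes"] = len(union)
    return df


def write_membership_tsv(table: MembershipTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tnetworks\n")
        for g in sorted(table.memberships):
            fh.write(f"{g}\t{','.join(sorted(table.memberships[g]))}\n")


def write_overlap_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")
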