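"""Differentiation driver gene (DDG) calling from module networks.

For each gene in a module's Bayesian network, the three-step (radius-3)
neighborhood is extracted after pruning weakly connected nodes; only
unusually large neighborhoods (size > mean + 1 SD within the network) are
kept, and each is tested for enrichment of the boundary's dynamic genes
with an upper-tail hypergeometric test.  A focal gene whose neighborhood is
enriched (BH-adjusted p < 0.05) is a DDG for that boundary.

The hypergeometric population is configurable: the printed recipe counts
"identified neighborhoods" (mode ``"literal"``), which can yield an
infeasible population; the default ``"union"`` counts the genes in the
retained neighborhoods instead, and ``"network"`` counts all network genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import hypergeom

from .datatypes import GeneDAG

log = logging.getLogger(__name__)


def prune_network(dag: GeneDAG, iterate: bool = False) -> GeneDAG:
    """Remove nodes with total degree (in + out) <= 1.

    ``iterate=False`` (default) applies one pass; ``iterate=True`` repeats
    to a fixed point.
    """
    nodes = list(dag.nodes)
    edges = list(dag.edges)
    while True:
        deg: dict[str, int] = {g: 0 for g in nodes}
        for p, c in edges:
            deg[p] += 1
            deg[c] += 1
        drop = {g for g in nodes if deg[g] <= 1}
        if not drop:
            break
        nodes = [g for g in nodes if g not in drop]
        edges = [(p, c) for p, c in edges if p not in drop and c not in drop]
        if not iterate:
            break
    return GeneDAG(dag.cluster_label, dag.module_id, nodes, edges, dag.score)


def three_step_neighborhood(dag: GeneDAG, focal: str, mode: str = "all") -> set[str]:
    """Nodes reachable from ``focal`` within 3 edges (focal included).

    ``mode`` selects edge traversal: ``"all"`` (undirected), ``"out"`` or
    ``"in"``.
    """
    if focal not in dag.nodes:
        raise KeyError(f"focal gene {focal!r} not in network")
    G = nx.DiGraph()
    G.add_nodes_from(dag.nodes)
    G.add_edges_from(dag.edges)
    if mode == "all":
        G = G.to_undirected()
    elif mode == "in":
        G = G.reverse()
    elif mode != "out":
        raise ValueError(f"unknown mode {mode!r}")
    return set(nx.ego_graph(G, focal, radius=3).nodes)


def extract_neighborhoods(dag: GeneDAG, mode: str = "all") -> dict[str, set[str]]:
    """Three-step neighborhood for every node of a (pruned) network."""
    return {g: three_step_neighborhood(dag, g, mode=mode) for g in dag.nodes}


def filter_neighborhoods(neighborhoods: dict[str, set[str]]) -> dict[str, set[str]]:
    """Keep neighborhoods larger than mean + 1 sample SD of sizes.

    Requires at least two neighborhoods; when all sizes are equal nothing
    exceeds the threshold and an empty dict is returned with a warning.
    """
    if len(neighborhoods) < 2:
        raise ValueError("need at least 2 neighborhoods to size-filter")
    sizes = np.array([len(v) for v in neighborhoods.values()], dtype=float)
    thresh = sizes.mean() + sizes.std(ddof=1)
    kept = {g: v for g, v in neighborhoods.items() if len(v) > thresh}
    if not kept:
        log.warning("filter_neighborhoods: no neighborhood exceeds mean + 1 SD")
    return kept


def hypergeom_upper_tail(overlap: int, m: int, n: int, k: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(m successes, n failures, k draws).

    Evaluated as the upper tail at ``q = overlap - 1`` so an overlap of 0
    gives p = 1 exactly.
    """
    if overlap <= 0:
        return 1.0
    return float(hypergeom.sf(overlap - 1, m + n, m, k))


def hypergeom_enrichment(
    focal: str,
    members: set[str],
    dynamic_set: set[str],
    n_neighborhoods: int | None = None,
    union_genes: set[str] | None = None,
    network_genes: set[str] | None = None,
    population_mode: str = "network",
    boundary_label: str = "",
    cluster_label: str = "",
    module_id: str = "",
) -> dict:
    """Enrichment of one neighborhood for a boundary's dynamic genes.

    For the gene-based population modes ("union": genes in retained
    neighborhoods; "network": all network genes) the success count ``m`` is
    the number of dynamic genes *inside* the population, so draws and
    successes refer to the same urn.  Mode "literal" keeps the printed
    parameterization verbatim: ``m`` = all dynamic genes for the boundary
    and ``n`` = number of retained neighborhoods - m.  ``n`` is floored at
    ``k - overlap`` with a logged adjustment when the mode yields an
    infeasible population.
    """
    k = len(members)
    if k < 1:
        raise ValueError("neighborhood must contain at least the focal gene")
    overlap = len(members & dynamic_set)
    if population_mode == "literal":
        if n_neighborhoods is None:
            raise ValueError("literal mode requires n_neighborhoods")
        m = len(dynamic_set)
        n = n_neighborhoods - m
    elif population_mode == "union":
        if union_genes is None:
            raise ValueError("union mode requires union_genes")
        m = len(dynamic_set & union_genes)
        n = len(union_genes) - m
    elif population_mode == "network":
        if network_genes is None:
            raise ValueError("network mode requires network_genes")
        m = len(dynamic_set & network_genes)
        n = len(network_genes) - m
    else:
        raise ValueError(f"unknown population_mode {population_mode!r}")
    floor = max(0, k - overlap)
    if n < floor:
        log.info(
            "hypergeom_enrichment: mode %s gave infeasible n=%d; floored to %d",
            population_mode, n, floor,
        )
        n = floor
    if k > m + n:
        raise ValueError(
            f"population_mode {population_mode!r} yields k={k} > m+n={m + n}"
        )
    p = hypergeom_upper_tail(overlap, m, n, k)
    return {
        "focal_gene": focal, "cluster_label": cluster_label, "module_id": module_id,
        "boundary_label": boundary_label, "k": k, "overlap": overlap,
        "m": m, "n": n, "p": p, "population_mode": population_mode,
    }


def test_network_boundaries(
    dag: GeneDAG,
    dynamic_sets: dict[str, set[str]],
    mode: str = "all",
    population_mode: str = "network",
    prune_iterate: bool = False,
) -> list[dict]:
    """All (retained neighborhood) x (boundary) enrichment records for one network."""
    pruned = prune_network(dag, iterate=prune_iterate)
    if len(pruned.nodes) < 2:
        return []
    hoods = extract_neighborhoods(pruned, mode=mode)
    kept = filter_neighborhoods(hoods)
    if not kept:
        return []
    union_genes = set().union(*kept.values())
    records = []
    for boundary, dyn in dynamic_sets.items():
        for focal, members in kept.items():
            records.append(hypergeom_enrichment(
                focal, members, dyn,
                n_neighborhoods=len(kept), union_genes=union_genes,
                network_genes=set(pruned.nodes),
                population_mode=population_mode,
                boundary_label=boundary,
                cluster_label=dag.cluster_label, module_id=dag.module_id,
            ))
    return records


def call_ddgs(enrichments: list[dict] | pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust within each (cluster, boundary) family and flag DDGs."""
    from statsmodels.stats.multitest import multipletests

    df = pd.DataFrame(enrichments) if not isinstance(enrichments, pd.DataFrame) else enrichments.copy()
    if df.empty:
        return pd.DataFrame(columns=[
            "focal_gene", "cluster_label", "module_id", "boundary_label",
            "k", "overlap", "m", "n", "p", "population_mode", "p_adj", "is_ddg",
        ])
    df["p_adj"] = np.nan
    for _, idx in df.groupby(["cluster_label", "boundary_label"]).groups.items():
        p = df.loc[idx, "p"].to_numpy(dtype=float)
        df.loc[idx, "p_adj"] = multipletests(p, method="fdr_bh")[1]
    df["is_ddg"] = df["p_adj"] < alpha
    return df
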