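"""Guilt-by-association filtering via greedy maximum-weight independent sets.

Network-influence measures can inflate a gene's weight merely because its
interaction partners score high.  To compress a ranking into a set of genes
that do not explain each other, the node-weighted interactome is filtered with
the GWMIN2 greedy heuristic for the (NP-complete) maximum weight independent
set problem: repeatedly pick the node maximizing its weight divided by the
total weight of its closed neighborhood, then delete that closed neighborhood.
The heuristic guarantees a total output weight of at least
``sum_u W(u)^2 / sum_{v in N+(u)} W(v)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .centrality_measures import MeasureResult
from .network_io import SampleInstance

__all__ = ["ConflictGraph", "gwmin2", "gwmin2_bound", "filter_ranking", "FilterReport"]


@dataclass
class ConflictGraph:
    """A graph whose edges are conflicts plus non-negative node importances."""

    graph: nx.Graph
    weights: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(self.graph.nodes) - set(self.weights)
        if missing:
            raise ValueError(f"{len(missing)} conflict-graph nodes lack weights")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("conflict-graph weights must be non-negative")


def gwmin2(cg: ConflictGraph) -> tuple[set[str], float]:
    """GWMIN2 greedy independent set on a node-weighted graph.

    Ratios are recomputed on the residual graph each round (greedy with
    deletion).  Ties break by larger weight, then lexicographic id.  Nodes
    whose closed-neighborhood weight sum is 0 carry no evidence: they are
    skipped during the main loop and appended afterwards only if isolated in
    the residual graph, so they never block weighted neighbors.
    """
    residual = cg.graph.copy()
    w = cg.weights
    chosen: set[str] = set()
    while True:
        best_u = None
        best_key: tuple[float, float] | None = None
        for u in residual.nodes:
            denom = w[u] + sum(w[v] for v in residual[u])
            if denom <= 0.0:
                continue  # 0/0: no evidence here
            key = (w[u] / denom, w[u])
            if (
                best_key is None
                or key > best_key
                or (key == best_key and u < best_u)  # type: ignore[operator]
            ):
                best_u, best_key = u, key
        if best_u is None:
            break
        chosen.add(best_u)
        residual.remove_nodes_from([best_u, *residual[best_u]])
    # zero-evidence leftovers: only isolated ones may join
    for u in sorted(residual.nodes):
        if residual.degree(u) == 0:
            chosen.add(u)
    return chosen, sum(w[u] for u in chosen)


def gwmin2_bound(cg: ConflictGraph) -> float:
    """GWMIN2's provable lower bound on the output weight:
    ``sum_u W(u)^2 / sum_{v in N+(u)} W(v)`` (zero-denominator terms drop)."""
    total = 0.0
    w = cg.weights
    for u in cg.graph.nodes:
        denom = w[u] + sum(w[v] for v in cg.graph[u])
        if denom > 0.0:
            total += w[u] ** 2 / denom
    return total


@dataclass
class FilterReport:
    """MWIS filtration of a ranking: the surviving head of the list plus a
    per-gene report over the unfiltered head."""

    survivors: list[str]
    table: pd.DataFrame
    mwis: set[str]
    total_weight: float


def importance_weights(measure: MeasureResult) -> dict[str, float]:
    """Non-negative 'importance' weights for MWIS.

    Descending measures are already importances; ascending measures (where low
    means interesting) are flipped as w' = max_weight - w.
    """
    if measure.direction == "descending":
        return dict(measure.weights)
    top = max(measure.weights.values(), default=0.0)
    return {g: top - w for g, w in measure.weights.items()}


def filter_ranking(
    measure: MeasureResult,
    H: nx.Graph,
    top_n: int,
    instances: list[SampleInstance] | None = None,
    gold_standards: dict[str, set[str]] | None = None,
) -> FilterReport:
    """Run GWMIN2 on the interactome induced over the measure's universe and
    report the head of the ranking.

    The report table covers the first ``top_n`` genes of the *unfiltered*
    ranking, flagging MWIS membership and, for each filtered-out gene, listing
    its interactome neighbors from the head that made it into the MWIS.  When
    instance data / gold standards are supplied the usual bookkeeping columns
    (normal/tumor expression counts, mutation counts, membership flags) are
    added.  ``survivors`` is the top_n surviving genes in measure order.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    universe = set(measure.weights)
    sub = H.subgraph(universe & set(H.nodes)).copy()
    sub.add_nodes_from(universe - set(H.nodes))
    cg = ConflictGraph(graph=sub, weights=importance_weights(measure))
    mwis, total = gwmin2(cg)

    ranking = measure.ranking()
    head = ranking[:top_n]
    head_mwis = [g for g in head if g in mwis]
    rows = []
    for rank, gene in enumerate(head, start=1):
        neighbors = set(sub[gene]) if gene in sub else set()
        row: dict[str, object] = {
            "rank": rank,
            "gene": gene,
            "weight": measure.weights[gene],
            "in_mwis": gene in mwis,
            "mwis_neighbors": ",".join(g for g in head_mwis if g in neighbors),
        }
        if instances is not None:
            row["n_normal"] = sum(gene in i.normal_expressed for i in instances)
            row["n_tumor"] = sum(gene in i.tumor_expressed for i in instances)
            row["n_mutated"] = sum(gene in i.tumor_mutated for i in instances)
        for name, genes in (gold_standards or {}).items():
            row[f"in_{name}"] = gene in genes
        rows.append(row)

    survivors = [g for g in ranking if g in mwis][:top_n]
    return FilterReport(
        survivors=survivors, table=pd.DataFrame(rows), mwis=mwis, total_weight=total
    )
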