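"""Unlabeled differential centrality measures and the two control measures.

Each unlabeled measure scores every node of the universe by summing, over all
instance pairs, the absolute difference of a per-graph centrality between the
normal and tumor graph (a node absent from a graph scores 0 there):

* ``m_bw``   — normalized betweenness centrality
* ``m_cc``   — clustering coefficient
* ``m_deg1`` — first-order degree |Ne(v)|
* ``m_deg2`` — second-order neighborhood size |Ne2(v)|

Large weights indicate genes whose topological role changes between normal and
tumor networks, so these measures rank descending.  The two controls are the
expression difference (ED) and the per-instance mutation frequency (MF), both
also descending.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import networkx as nx

from .graph_pairs import InstanceSet
from .network_io import SampleInstance

__all__ = [
    "MeasureResult",
    "betweenness",
    "clustering_coefficient",
    "degree_order1",
    "degree_order2",
    "differential_sum",
    "expression_difference",
    "mutation_frequency",
    "UNLABELED_SCORES",
]

#: per-graph node score functions the differential measures plug in
ScoreFunction = Callable[[nx.Graph], dict[str, float]]


@dataclass
class MeasureResult:
    """A per-gene weight map plus the sort direction that turns it into a
    ranking over the universe.

    Unlabeled and control measures rank descending (big change first);
    labeled measures rank ascending (low similarity first).  Ties break
    lexicographically on the gene id, so rankings are reproducible.
    """

    measure_name: str
    weights: dict[str, float]
    direction: str  # "descending" | "ascending"

    def __post_init__(self) -> None:
        if self.direction not in ("descending", "ascending"):
            raise ValueError(f"bad direction {self.direction!r}")

    def ranking(self) -> list[str]:
        """Genes sorted by weight in the measure's direction, ties broken by id."""
        sign = -1.0 if self.direction == "descending" else 1.0
        return sorted(self.weights, key=lambda g: (sign * self.weights[g], g))

    def to_frame(self):
        import pandas as pd

        genes = self.ranking()
        return pd.DataFrame(
            {
                "gene": genes,
                "weight": [self.weights[g] for g in genes],
                "rank": range(1, len(genes) + 1),
            }
        )


# ---------------------------------------------------------------------------
# per-graph node scores


def betweenness(G: nx.Graph) -> dict[str, float]:
    """Normalized betweenness: the shortest-path pair fraction through each
    node, scaled by 2/((|V|-1)(|V|-2)) so values lie in [0, 1].

    Disconnected source/target pairs contribute nothing; graphs with fewer
    than 3 nodes score 0 everywhere (the normalization is undefined).
    """
    n = G.number_of_nodes()
    if n < 3:
        return dict.fromkeys(G.nodes, 0.0)
    return nx.betweenness_centrality(G, normalized=True)


def clustering_coefficient(G: nx.Graph) -> dict[str, float]:
    """Fraction of realized edges among each node's neighbors (0 for degree <= 1)."""
    return nx.clustering(G)


def degree_order1(G: nx.Graph) -> dict[str, int]:
    """|Ne(v)|: the plain degree."""
    return dict(G.degree())


def degree_order2(G: nx.Graph, include_self: bool = True) -> dict[str, int]:
    """|Ne2(v)|: v's neighbors together with all of their neighbors.

    Under the literal definition a non-isolated v is itself in Ne2(v), being a
    neighbor of each of its neighbors; ``include_self=False`` switches that off.
    """
    out: dict[str, int] = {}
    for v in G.nodes:
        second: set[str] = set(G[v])
        for u in list(second):
            second.update(G[u])
        if not include_self:
            second.discard(v)
        out[v] = len(second)
    return out


UNLABELED_SCORES: dict[str, ScoreFunction] = {
    "m_bw": betweenness,
    "m_cc": clustering_coefficient,
    "m_deg1": degree_order1,
    "m_deg2": degree_order2,
}


# ---------------------------------------------------------------------------
# differential measures


def differential_sum(pairs: InstanceSet, score: ScoreFunction, name: str = "differential") -> MeasureResult:
    """W(v) = sum over pairs of |score_N(v) - score_T(v)|, absent nodes scoring 0."""
    weights = dict.fromkeys(pairs.universe, 0.0)
    for pair in pairs.pairs:
        sn = score(pair.normal_graph)
        st = score(pair.tumor_graph)
        for v in set(sn) | set(st):
            weights[v] += abs(sn.get(v, 0.0) - st.get(v, 0.0))
    return MeasureResult(measure_name=name, weights=weights, direction="descending")


def expression_difference(
    instances: Iterable[SampleInstance], universe: set[str] | None = None
) -> MeasureResult:
    """ED(v): |#normal samples expressing v - #tumor samples expressing v|.

    A mutated-but-expressed tumor gene still counts as expressed here; the
    control looks at expression calls only, not at tumor-graph membership.
    """
    instances = list(instances)
    genes = universe if universe is not None else set().union(
        *(i.normal_expressed | i.tumor_expressed for i in instances)
    )
    weights = {}
    for v in genes:
        n = sum(v in i.normal_expressed for i in instances)
        t = sum(v in i.tumor_expressed for i in instances)
        weights[v] = float(abs(n - t))
    return MeasureResult("ed", weights, "descending")


def mutation_frequency(
    instances: Iterable[SampleInstance], universe: set[str] | None = None
) -> MeasureResult:
    """MF(v): number of tumor samples in which v is non-silently mutated
    (instances, not records: several mutations in one sample count once)."""
    instances = list(instances)
    genes = universe if universe is not None else set().union(
        *(i.normal_expressed | i.tumor_expressed | i.tumor_mutated for i in instances)
    )
    weights = {v: float(sum(v in i.tumor_mutated for i in instances)) for v in genes}
    return MeasureResult("mf", weights, "descending")
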