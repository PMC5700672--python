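"""Per-instance normal/tumor induced subgraph pairs.

For each patient instance ``i`` the normal graph ``N_i`` is the interactome
induced on the genes expressed in the normal sample, and the tumor graph
``T_i`` is the interactome induced on the genes expressed and *not* non-silently
mutated in the matched tumor sample.  All measures are defined over the node
universe: the union of the node sets of every graph in the pair list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .network_io import SampleInstance

logger = logging.getLogger(__name__)

__all__ = ["GraphPair", "InstanceSet", "build_pair", "build_instance_set"]


@dataclass
class GraphPair:
    instance_id: str
    normal_graph: nx.Graph
    tumor_graph: nx.Graph


@dataclass
class InstanceSet:
    """The ordered list of graph pairs plus the node universe they span."""

    pairs: list[GraphPair]
    universe: set[str]

    @property
    def pair_count(self) -> int:
        return len(self.pairs)


def build_pair(H: nx.Graph, inst: SampleInstance) -> GraphPair:
    """Induce the normal and tumor subgraphs of ``H`` for one instance.

    Genes absent from the interactome fall outside both graphs.  Mutation data
    only affects the tumor side: a non-silently mutated gene is excluded from
    the tumor graph even when expressed.
    """
    normal_nodes = inst.normal_expressed & set(H.nodes)
    tumor_nodes = (inst.tumor_expressed - inst.tumor_mutated) & set(H.nodes)
    return GraphPair(
        instance_id=inst.instance_id,
        normal_graph=H.subgraph(normal_nodes).copy(),
        tumor_graph=H.subgraph(tumor_nodes).copy(),
    )


def build_instance_set(H: nx.Graph, instances: list[SampleInstance]) -> InstanceSet:
    """Build all pairs (input order) and the node universe.

    Genes present in the expression/mutation data but absent from the
    interactome are excluded from the universe; their count is logged so that
    coverage can be audited.
    """
    if not instances:
        raise ValueError("need at least one sample instance")
    h_nodes = set(H.nodes)
    pairs = [build_pair(H, inst) for inst in instances]
    universe: set[str] = set()
    for p in pairs:
        universe |= set(p.normal_graph.nodes)
        universe |= set(p.tumor_graph.nodes)
    uncovered = set()
    for inst in instances:
        uncovered |= (inst.normal_expressed | inst.tumor_expressed) - h_nodes
    if uncovered:
        logger.info("%d expressed genes absent from the interactome were excluded", len(uncovered))
    return InstanceSet(pairs=pairs, universe=universe)
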