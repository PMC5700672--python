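"""Ranking evaluation: top-k% ROC/PR sweeps, GO-consistency, network rewiring.

Rankings are judged against gold-standard gene lists with a top-k% sweep: the
ranked list is thresholded at every integer percentile k = 1..100, each prefix
is scored as a classifier over the node universe, and AUROC/AUPR are obtained
by trapezoidal integration over the sweep points.  GO consistency (GOC)
measures the functional agreement between a candidate list and a reference
list through Jaccard overlaps of level-restricted GO annotations.  The
rewiring experiment probes robustness to interactome noise by randomly
replacing a fraction of edges and re-running the whole pipeline.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .centrality_measures import MeasureResult
from .graph_pairs import InstanceSet, build_instance_set
from .network_io import GOAnnotationMap, SampleInstance

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationCurve",
    "RewireConfig",
    "RewireResult",
    "top_fraction",
    "roc_pr_sweep",
    "term_levels",
    "restrict_go_level",
    "goc_score",
    "goc_sweep",
    "rewire",
    "rewiring_experiment",
]


@dataclass
class EvaluationCurve:
    points: pd.DataFrame  # columns: k, tpr, fpr, precision, recall
    auroc: float
    aupr: float


def top_fraction(ranking: Sequence[str], k: float) -> list[str]:
    """The first ceil(k% of the list) genes; ceil keeps tiny prefixes non-empty."""
    if not 0 < k <= 100:
        raise ValueError("k must be in (0, 100]")
    return list(ranking[: math.ceil(k * len(ranking) / 100)])


def roc_pr_sweep(
    ranking: Sequence[str],
    gold: Iterable[str],
    universe: Iterable[str] | None = None,
    full_resolution: bool = False,
) -> EvaluationCurve:
    """Top-k% sweep of a ranking against a gold standard.

    The gold standard is intersected with the universe (default: the ranked
    genes) before scoring.  ``full_resolution`` thresholds at every rank
    instead of at integer percentiles.
    """
    universe = set(universe) if universe is not None else set(ranking)
    gold = set(gold) & universe
    if not gold:
        raise ValueError("gold standard is empty after intersection with the universe")
    n = len(ranking)
    n_pos = len(gold)
    n_neg = len(universe) - n_pos

    if full_resolution:
        sizes = list(range(1, n + 1))
        ks = [100 * s / n for s in sizes]
    else:
        ks = list(range(1, 101))
        sizes = [math.ceil(k * n / 100) for k in ks]

    is_gold = np.fromiter((g in gold for g in ranking), dtype=bool, count=n)
    tp_cum = np.cumsum(is_gold)
    rows = []
    for k, size in zip(ks, sizes):
        tp = int(tp_cum[size - 1])
        fp = size - tp
        rows.append(
            {
                "k": k,
                "tpr": tp / n_pos,
                "fpr": fp / n_neg if n_neg else 0.0,
                "precision": tp / size,
                "recall": tp / n_pos,
            }
        )
    points = pd.DataFrame(rows)
    fpr = np.concatenate([[0.0], points["fpr"].to_numpy(), [1.0]])
    tpr = np.concatenate([[0.0], points["tpr"].to_numpy(), [1.0]])
    auroc = float(np.trapezoid(tpr, fpr))
    rec = np.concatenate([[0.0], points["recall"].to_numpy()])
    prec = np.concatenate([[points["precision"].iloc[0]], points["precision"].to_numpy()])
    aupr = float(np.trapezoid(prec, rec))
    return EvaluationCurve(points=points, auroc=auroc, aupr=aupr)


# ---------------------------------------------------------------------------
# gene ontology


def term_levels(ontology: nx.DiGraph) -> dict[str, int]:
    """Level of every term: length (in edges) of the shortest directed path to
    an ontology root (root level = 0; multiple roots take the nearest)."""
    roots = [t for t in ontology.nodes if ontology.out_degree(t) == 0]
    down = ontology.reverse(copy=False)  # parent -> child
    levels: dict[str, int] = {}
    for root in roots:
        for term, depth in nx.single_source_shortest_path_length(down, root).items():
            if term not in levels or depth < levels[term]:
                levels[term] = depth
    return levels


def restrict_go_level(ann: GOAnnotationMap, level: int = 5) -> GOAnnotationMap:
    """Standardize annotations to one DAG level.

    Annotations above the target level (closer to the root) are dropped as too
    generic; deeper annotations are replaced by all of their ancestors sitting
    exactly at the target level; annotations already at the level are kept.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    levels = term_levels(ann.ontology)
    at_level_cache: dict[str, set[str]] = {}

    def level_ancestors(term: str) -> set[str]:
        if term not in at_level_cache:
            ancestors = nx.descendants(ann.ontology, term)  # child->parent reachability
            at_level_cache[term] = {a for a in ancestors if levels.get(a) == level}
        return at_level_cache[term]

    restricted: dict[str, set[str]] = {}
    for gene, terms in ann.annotations.items():
        out: set[str] = set()
        for t in terms:
            lv = levels.get(t)
            if lv is None:
                continue
            if lv == level:
                out.add(t)
            elif lv > level:
                out |= level_ancestors(t)
        restricted[gene] = out
    return GOAnnotationMap(annotations=restricted, ontology=ann.ontology)


def goc_score(test: Sequence[str], reference: Sequence[str], ann: GOAnnotationMap) -> float:
    """GO consistency of a test list against a reference list.

    The sum over all (test, reference) gene pairs of the Jaccard index of
    their annotation sets, divided by the reference size; pairs where both
    sets are empty contribute 0.  Annotations should already be
    level-restricted (see :func:`restrict_go_level`).
    """
    if not reference:
        raise ValueError("reference list is empty")
    go = ann.annotations
    total = 0.0
    for t in test:
        gt = go.get(t, set())
        if not gt:
            continue
        for r in reference:
            gr = go.get(r, set())
            union = gt | gr
            if union:
                total += len(gt & gr) / len(union)
    return total / len(reference)


def goc_sweep(
    ranking: Sequence[str],
    reference: Sequence[str],
    ann: GOAnnotationMap,
    ks: Iterable[int] = range(1, 26),
) -> pd.DataFrame:
    """GOC of the top-k% prefixes of a ranking (small k is the regime of
    interest: candidate lists are meant for further inspection)."""
    rows = [
        {"k": k, "goc": goc_score(top_fraction(ranking, k), reference, ann)} for k in ks
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rewiring


def rewire(H: nx.Graph, ratio: float, seed: int | random.Random) -> nx.Graph:
    """Perturb a network: remove ratio% of edges at random and insert the same
    number of new edges between node pairs non-adjacent in the *original*
    network (so removed edges are never reinserted); the node set and the
    edge count are preserved.
    """
    if not 0 <= ratio <= 100:
        raise ValueError("ratio must be in [0, 100]")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    m = round(ratio / 100 * H.number_of_edges())
    result = H.copy()
    if m == 0:
        return result
    edges = sorted(tuple(sorted(e)) for e in H.edges())
    result.remove_edges_from(rng.sample(edges, m))
    nodes = sorted(H.nodes)
    inserted = 0
    attempts = 0
    max_attempts = 200 * m + 10_000
    while inserted < m:
        if attempts >= max_attempts:
            _insert_exhaustive(H, result, m - inserted, rng)
            break
        attempts += 1
        u, v = rng.sample(nodes, 2)
        if H.has_edge(u, v) or result.has_edge(u, v):
            continue
        result.add_edge(u, v)
        inserted += 1
    return result


def _insert_exhaustive(H: nx.Graph, result: nx.Graph, needed: int, rng: random.Random) -> None:
    """Fallback for dense graphs: enumerate the remaining candidate non-edges."""
    candidates = [
        (u, v)
        for u, v in nx.non_edges(H)
        if not result.has_edge(u, v)
    ]
    if len(candidates) < needed:
        raise ValueError("not enough non-adjacent node pairs to complete the rewiring")
    result.add_edges_from(rng.sample(sorted(candidates), needed))


@dataclass
class RewireConfig:
    ratios: tuple[float, ...] = (5, 10, 15, 20)
    replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= r <= 100 for r in self.ratios) or self.replicates < 1:
            raise ValueError("invalid rewiring configuration")


@dataclass
class RewireResult:
    runs: pd.DataFrame  # measure, ratio, replicate, auroc, aupr
    graphs_built: int

    def summary(self) -> pd.DataFrame:
        """Per-(measure, ratio) means and standard deviations."""
        return (
            self.runs.groupby(["measure", "ratio"])[["auroc", "aupr"]]
            .agg(["mean", "std"])
            .reset_index()
        )


def rewiring_experiment(
    H: nx.Graph,
    instances: list[SampleInstance],
    measures: dict[str, Callable[[InstanceSet], MeasureResult]],
    gold: Iterable[str],
    cfg: RewireConfig | None = None,
) -> RewireResult:
    """Robustness of measures to interactome noise.

    For every rewiring ratio and replicate the interactome is rewired, all
    normal/tumor pairs are rebuilt on it, each measure is recomputed, and its
    ranking is scored against the gold standard; replicate AUROC/AUPR are then
    averaged per ratio.  The total number of induced graphs constructed
    (2 x instances x ratios x replicates) is logged and returned.
    """
    cfg = cfg or RewireConfig()
    gold = set(gold)
    master_rng = random.Random(cfg.seed)
    rows = []
    graphs_built = 0
    for ratio in cfg.ratios:
        for rep in range(cfg.replicates):
            rep_seed = master_rng.randrange(2**31)
            Hr = rewire(H, ratio, rep_seed)
            iset = build_instance_set(Hr, instances)
            graphs_built += 2 * iset.pair_count
            for name, fn in measures.items():
                result = fn(iset)
                curve = roc_pr_sweep(result.ranking(), gold, iset.universe)
                rows.append(
                    {
                        "measure": name,
                        "ratio": ratio,
                        "replicate": rep,
                        "auroc": curve.auroc,
                        "aupr": curve.aupr,
                    }
                )
    logger.info("rewiring experiment built %d induced graphs", graphs_built)
    return RewireResult(runs=pd.DataFrame(rows), graphs_built=graphs_built)
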