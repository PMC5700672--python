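"""Seeded synthetic inputs: interactome, paired samples, gold standard, toy GO.

The generator emulates the shape of a paired tumor/normal network study
without any downloads: a scale-free interactome (preferential attachment), a
set of planted driver genes, and per-patient expression/mutation calls.
Drivers are planted *topologically* — they are the highest-degree hubs and, in
each tumor sample, with some probability their neighborhood is perturbed
(a random subset of their interaction partners, or the driver itself, drops
out of the tumor-expressed set).  Differential centrality measures respond to
exactly this kind of induced-subgraph change, while the expression-difference
control sees only the uniform background flip noise, so the planted signal
separates method from control by construction.

Everything is deterministic under the config seed, and the dataset can be
emitted in the same external file formats the readers consume, so the full
file-based pipeline is exercisable end to end.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .network_io import GOAnnotationMap, SampleInstance, write_edge_list, write_gene_list

__all__ = [
    "SyntheticConfig",
    "generate_network",
    "generate_instances",
    "generate_go",
    "write_dataset",
]


@dataclass
class SyntheticConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults describe a desk-scale cohort: a 500-gene scale-free interactome,
    40 paired samples, 15 planted drivers whose tumor-side neighborhoods are
    perturbed in 60% of samples, 2% background expression flips and a 1%
    per-gene somatic mutation rate per tumor sample.
    """

    n_genes: int = 500
    attachment_degree: int = 2
    n_instances: int = 40
    n_drivers: int = 15
    driver_dropout: float = 0.6
    background_flip: float = 0.02
    mutation_rate: float = 0.01
    seed: int = 7
    #: what the dropout removes from the tumor-expressed set: a random subset
    #: of the driver's neighbors ("neighbors"), the driver itself ("driver"),
    #: or a fair coin between the two ("mixed")
    driver_removal: str = "neighbors"
    #: probability that each individual neighbor drops in a neighbor removal
    neighbor_fraction: float = 0.5

    def __post_init__(self) -> None:
        probs = (self.driver_dropout, self.background_flip, self.mutation_rate,
                 self.neighbor_fraction)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 < self.n_drivers < self.n_genes:
            raise ValueError("need 0 < n_drivers < n_genes")
        if self.n_instances < 1:
            raise ValueError("need at least one instance")
        if self.driver_removal not in ("driver", "neighbors", "mixed"):
            raise ValueError(f"unknown driver_removal {self.driver_removal!r}")


def _gene_id(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def generate_network(cfg: SyntheticConfig) -> nx.Graph:
    """Connected scale-free-like interactome via preferential attachment.

    Gene ids are assigned by a seeded permutation so that identifier order
    carries no information about degree (preferential attachment otherwise
    grows its hubs at the earliest indices).
    """
    if cfg.n_genes < cfg.attachment_degree + 1:
        raise ValueError("n_genes must exceed attachment_degree")
    g = nx.barabasi_albert_graph(cfg.n_genes, cfg.attachment_degree, seed=cfg.seed)
    width = len(str(cfg.n_genes - 1))
    perm = np.random.default_rng(cfg.seed + 3).permutation(cfg.n_genes)
    return nx.relabel_nodes(g, {i: _gene_id(int(perm[i]), width) for i in g.nodes})


def _flip(genes: set[str], all_genes: list[str], p: float, rng: np.random.Generator) -> set[str]:
    """Toggle each gene's membership independently with probability p."""
    if p == 0.0:
        return set(genes)
    toggled = set(np.asarray(all_genes)[rng.random(len(all_genes)) < p])
    return genes ^ toggled


def generate_instances(
    cfg: SyntheticConfig, H: nx.Graph
) -> tuple[list[SampleInstance], list[str]]:
    """Paired samples with planted drivers; returns (instances, gold standard).

    Drivers are the ``n_drivers`` highest-degree hubs (degree ties broken by
    id).  Per instance: the normal-expressed set is all genes minus background
    flips; the tumor-expressed set applies independent background flips on top
    of the normal set and then, per driver with probability ``driver_dropout``,
    the configured removal; tumor mutations are sampled per gene at
    ``mutation_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    all_genes = sorted(H.nodes)
    drivers = sorted(all_genes, key=lambda g: (-H.degree(g), g))[: cfg.n_drivers]
    instances = []
    for i in range(cfg.n_instances):
        normal = _flip(set(all_genes), all_genes, cfg.background_flip, rng)
        tumor = _flip(normal, all_genes, cfg.background_flip, rng)
        for d in drivers:
            if rng.random() >= cfg.driver_dropout:
                continue
            mode = cfg.driver_removal
            if mode == "mixed":
                mode = "driver" if rng.random() < 0.5 else "neighbors"
            if mode == "driver":
                tumor.discard(d)
            else:
                neighbors = sorted(H[d])
                drop = rng.random(len(neighbors)) < cfg.neighbor_fraction
                tumor -= set(np.asarray(neighbors)[drop])
        mutated = set(np.asarray(all_genes)[rng.random(len(all_genes)) < cfg.mutation_rate])
        instances.append(
            SampleInstance(
                instance_id=f"I{i:03d}",
                normal_expressed=normal,
                tumor_expressed=tumor,
                tumor_mutated=mutated,
            )
        )
    return instances, drivers


# ---------------------------------------------------------------------------
# toy gene ontology

_GO_DEPTH = 8
_LEVEL_SIZES = {1: 3, 2: 6, 3: 10, 4: 14, 6: 24, 7: 20, 8: 12}
_GOLD_BLOCK = 5  # level-5 terms reserved for gold genes
_BACKGROUND_POOL = 20  # disjoint level-5 terms for background genes
_CROSS_ANNOTATION = 0.05  # chance a background gene picks up one gold-block term


def generate_go(
    cfg: SyntheticConfig, gold: list[str], genes: list[str] | None = None
) -> GOAnnotationMap:
    """Toy GO DAG of depth 8 with a fully known level structure.

    Levels are exact by construction: every term's parents all sit one level
    up, so the shortest path to the root equals the planted level.  Gold genes
    draw their annotations from a dedicated block of level-5 terms (sometimes
    through a deeper descendant, which level restriction must resolve back);
    background genes draw from a disjoint level-5 pool with a small chance of
    one cross-annotation.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if genes is None:
        width = len(str(cfg.n_genes - 1))
        genes = [_gene_id(i, width) for i in range(cfg.n_genes)]
    gold_set = set(gold)

    counter = 0

    def new_term() -> str:
        nonlocal counter
        counter += 1
        return f"GO:{counter:07d}"

    root = new_term()
    dag = nx.DiGraph()
    dag.add_node(root)
    levels: dict[int, list[str]] = {0: [root]}
    sizes = dict(_LEVEL_SIZES)
    sizes[5] = _GOLD_BLOCK + _BACKGROUND_POOL
    for level in range(1, _GO_DEPTH + 1):
        terms = [new_term() for _ in range(sizes[level])]
        parents = levels[level - 1]
        for j, t in enumerate(terms):
            dag.add_edge(t, parents[j % len(parents)])
            if len(parents) > 1 and rng.random() < 0.3:  # occasional second parent
                dag.add_edge(t, parents[(j + 1) % len(parents)])
        levels[level] = terms
    gold_block = levels[5][:_GOLD_BLOCK]
    background_pool = levels[5][_GOLD_BLOCK:]
    # deep terms descending only from the gold block, for restriction tests
    deep_gold = [t for t in levels[7] if _reaches(dag, t, set(gold_block))]

    annotations: dict[str, set[str]] = {}
    for g in genes:
        if g in gold_set:
            terms = set(rng.choice(gold_block, size=3, replace=False))
            if deep_gold:
                terms.add(str(rng.choice(deep_gold)))
        else:
            terms = set(rng.choice(background_pool, size=3, replace=False))
            if rng.random() < _CROSS_ANNOTATION:
                terms.add(str(rng.choice(gold_block)))
        annotations[g] = {str(t) for t in terms}
    return GOAnnotationMap(annotations=annotations, ontology=dag)


def _reaches(dag: nx.DiGraph, term: str, targets: set[str]) -> bool:
    return bool(nx.descendants(dag, term) & targets)


# ---------------------------------------------------------------------------
# file emission


def _write_obo(ontology: nx.DiGraph, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: toy\n")
        for term in sorted(ontology.nodes):
            fh.write(f"\n[Term]\nid: {term}\nname: synthetic term {term}\n")
            for parent in sorted(ontology[term]):
                fh.write(f"is_a: {parent} ! synthetic term {parent}\n")


def _write_gaf(annotations: dict[str, set[str]], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                cols = ["SYN", gene, gene, "", term, "SYN:0000001", "IEA", "",
                        "P", "", "", "protein", "taxon:0000", "20260101", "SYN", "", ""]
                fh.write("\t".join(cols) + "\n")


def write_dataset(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a full dataset and emit it in the external file formats.

    Writes network.tsv, expression.tsv, mutations.tsv, gold.txt, toy.obo,
    toy.gaf and config.json; the expression matrix encodes the expression
    calls as RPKM values >= 1 (expressed) or in [0, 1) (not expressed), so
    the standard threshold-1 reader reproduces the generated sets exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    H = generate_network(cfg)
    instances, gold = generate_instances(cfg, H)
    go = generate_go(cfg, gold)
    rng = np.random.default_rng(cfg.seed + 2)

    paths = {name: outdir / fname for name, fname in [
        ("network", "network.tsv"), ("expression", "expression.tsv"),
        ("mutations", "mutations.tsv"), ("gold", "gold.txt"),
        ("obo", "toy.obo"), ("gaf", "toy.gaf"), ("config", "config.json"),
    ]}
    write_edge_list(H, paths["network"])
    write_gene_list(gold, paths["gold"])
    _write_obo(go.ontology, paths["obo"])
    _write_gaf(go.annotations, paths["gaf"])

    genes = sorted(H.nodes)
    with open(paths["expression"], "w") as fh:
        cols = [f"{i.instance_id}_{t}" for i in instances for t in ("normal", "tumor")]
        fh.write("gene\t" + "\t".join(cols) + "\n")
        for g in genes:
            vals = []
            for inst in instances:
                for expressed in (g in inst.normal_expressed, g in inst.tumor_expressed):
                    base = rng.random()
                    vals.append(f"{1.0 + 9.0 * base:.3f}" if expressed else f"{0.99 * base:.3f}")
            fh.write(g + "\t" + "\t".join(vals) + "\n")

    with open(paths["mutations"], "w") as fh:
        fh.write("gene\tinstance\tvariant_classification\n")
        for inst in instances:
            for g in sorted(inst.tumor_mutated):
                fh.write(f"{g}\t{inst.instance_id}\tMissense_Mutation\n")

    with open(paths["config"], "w") as fh:
        json.dump(asdict(cfg), fh, indent=2)
    return paths
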