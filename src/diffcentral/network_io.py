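"""Readers and writers for interactomes, expression, mutations, gene lists and GO data.

The master protein-protein interaction network (the interactome ``H``) is held
as a plain :class:`networkx.Graph` over string gene identifiers: undirected,
simple, no self-loops.  All other inputs (expression matrix, mutation calls,
gold-standard lists, GO annotations) are joined against the interactome on a
single caller-chosen identifier space; no identifier-mapping service is built
in, and unmapped rows are simply dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SampleInstance",
    "GOAnnotationMap",
    "read_edge_list",
    "write_edge_list",
    "read_mitab",
    "read_expression",
    "call_expressed",
    "read_mutations",
    "call_mutated",
    "read_gene_list",
    "write_gene_list",
    "read_obo",
    "read_gaf",
    "read_go",
    "instances_from_tables",
]

#: default MI vocabulary filter: keep rows whose interaction-type field
#: mentions one of these substrings (case-insensitive)
PHYSICAL_INTERACTION_KEYWORDS = ("physical", "direct interaction")

#: MAF variant classifications treated as silent (configurable everywhere)
DEFAULT_SILENT_LABELS = frozenset({"Silent"})


@dataclass
class SampleInstance:
    """One patient: expressed genes in the paired normal and tumor samples,
    plus the genes carrying a non-silent somatic mutation in the tumor."""

    instance_id: str
    normal_expressed: set[str]
    tumor_expressed: set[str]
    tumor_mutated: set[str] = field(default_factory=set)


@dataclass
class GOAnnotationMap:
    """Gene -> GO term annotations together with the term DAG.

    ``ontology`` is a directed acyclic :class:`networkx.DiGraph` with edges
    pointing child -> parent, so the root(s) are the sink nodes.
    """

    annotations: dict[str, set[str]]
    ontology: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.ontology):
            raise ValueError("GO ontology graph contains a cycle")
        known = set(self.ontology.nodes)
        dropped = 0
        for gene, terms in self.annotations.items():
            missing = terms - known
            if missing:
                dropped += len(missing)
                self.annotations[gene] = terms - missing
        if dropped:
            logger.warning("dropped %d annotations to terms absent from the ontology", dropped)


# ---------------------------------------------------------------------------
# interactome


def _add_edge_clean(g: nx.Graph, u: str, v: str) -> bool:
    """Add an undirected edge, rejecting self-loops. Returns True if a loop
    was skipped."""
    g.add_node(u)
    g.add_node(v)
    if u == v:
        return True
    g.add_edge(u, v)
    return False


def read_edge_list(path: str | Path, delimiter: str = "\t", header: bool = False) -> nx.Graph:
    """Read a two-column edge list into a simple undirected graph.

    Duplicate lines and reversed duplicates collapse to a single edge;
    self-loops are dropped (their count is logged).
    """
    g = nx.Graph()
    loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: malformed edge line {lineno}: {line!r}")
            loops += _add_edge_clean(g, parts[0].strip(), parts[1].strip())
    if loops:
        logger.info("read_edge_list(%s): dropped %d self-loops", path, loops)
    return g


def write_edge_list(g: nx.Graph, path: str | Path, delimiter: str = "\t") -> None:
    """Write a graph as a two-column edge list; isolated nodes are written as
    commented ``#node`` lines so the node set round-trips."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u}{delimiter}{v}\n")
        for n in sorted(g.nodes()):
            if g.degree(n) == 0:
                fh.write(f"#node{delimiter}{n}\n")


def _read_edge_list_nodes(path: str | Path, delimiter: str = "\t") -> nx.Graph:
    """Internal: read an edge list written by :func:`write_edge_list`,
    restoring isolated nodes from ``#node`` lines."""
    g = read_edge_list(path, delimiter)
    with open(path) as fh:
        for line in fh:
            if line.startswith(f"#node{delimiter}"):
                g.add_node(line.rstrip("\n").split(delimiter)[1])
    return g


# PSI-MITAB 2.5 column indices (0-based)
_MITAB_ID_A, _MITAB_ID_B = 0, 1
_MITAB_ALIAS_A, _MITAB_ALIAS_B = 4, 5
_MITAB_TYPE = 11
_MITAB_MIN_COLUMNS = 15


def _mitab_identifier(field_value: str) -> str | None:
    """First identifier value from a MITAB xref field like 'uniprotkb:P04637'."""
    for token in field_value.split("|"):
        token = token.strip()
        if not token or token == "-":
            continue
        ident = token.split(":", 1)[-1]
        # strip trailing '(description)' decoration used in alias columns
        return ident.split("(")[0]
    return None


def read_mitab(
    path: str | Path,
    physical_keywords: Iterable[str] = PHYSICAL_INTERACTION_KEYWORDS,
    use_alias_column: bool = False,
    protein_prefixes: Iterable[str] = ("uniprotkb",),
) -> nx.Graph:
    """Read a PSI-MITAB 2.5 style file into a simple undirected graph.

    Rows are kept when the interaction-type field matches ``physical_keywords``
    (substring, case-insensitive) and both interactor identifier fields carry a
    database prefix listed in ``protein_prefixes``.  Identifiers come from the
    primary ID columns, or the alias columns when ``use_alias_column`` is set
    (useful for joining on gene symbols).
    """
    keywords = tuple(k.lower() for k in physical_keywords)
    prefixes = tuple(protein_prefixes)
    g = nx.Graph()
    loops = skipped = 0
    id_a, id_b = (
        (_MITAB_ALIAS_A, _MITAB_ALIAS_B) if use_alias_column else (_MITAB_ID_A, _MITAB_ID_B)
    )
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < _MITAB_MIN_COLUMNS:
                raise ValueError(f"{path}: line {lineno} has {len(cols)} columns, "
                                 f"expected >= {_MITAB_MIN_COLUMNS} (PSI-MITAB 2.5)")
            itype = cols[_MITAB_TYPE].lower()
            if keywords and not any(k in itype for k in keywords):
                skipped += 1
                continue
            if not all(
                cols[c].split(":")[0].strip().lower() in prefixes
                for c in (_MITAB_ID_A, _MITAB_ID_B)
            ):
                skipped += 1
                continue
            a = _mitab_identifier(cols[id_a])
            b = _mitab_identifier(cols[id_b])
            if a is None or b is None:
                skipped += 1
                continue
            loops += _add_edge_clean(g, a, b)
    logger.info("read_mitab(%s): %d nodes, %d edges; %d rows filtered, %d self-loops dropped",
                path, g.number_of_nodes(), g.number_of_edges(), skipped, loops)
    return g


# ---------------------------------------------------------------------------
# expression & mutations


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample RPKM matrix (TSV; first column = gene id; sample
    columns named ``<instance>_normal`` / ``<instance>_tumor``)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    bad = [c for c in table.columns if not (c.endswith("_normal") or c.endswith("_tumor"))]
    if bad:
        raise ValueError(f"{path}: sample columns must end in _normal/_tumor, got {bad}")
    if (table.values < 0).any():
        raise ValueError(f"{path}: negative RPKM values")
    return table


def call_expressed(table: pd.DataFrame, threshold: float = 1.0) -> dict[tuple[str, str], set[str]]:
    """Expression calls per sample: a gene is expressed iff RPKM >= threshold.

    Returns a map ``(instance_id, tissue) -> set of gene ids`` with tissue in
    ``{"normal", "tumor"}``.  The boundary is inclusive: a gene sitting exactly
    at the threshold is called expressed.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    calls: dict[tuple[str, str], set[str]] = {}
    for col in table.columns:
        instance, _, tissue = col.rpartition("_")
        calls[(instance, tissue)] = set(table.index[table[col] >= threshold])
    return calls


def read_mutations(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a MAF-like mutation table (TSV) with columns gene, instance,
    variant_classification.  ``column_map`` renames MAF-style headers, e.g.
    ``{"Hugo_Symbol": "gene", "Tumor_Sample_Barcode": "instance"}``."""
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if column_map:
        table = table.rename(columns=dict(column_map))
    required = {"gene", "instance", "variant_classification"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing mutation columns {sorted(missing)}")
    return table[sorted(required)]


def call_mutated(
    table: pd.DataFrame,
    silent_labels: Iterable[str] = DEFAULT_SILENT_LABELS,
) -> dict[str, set[str]]:
    """Non-silent mutation calls: ``instance_id -> set of mutated genes``.

    A gene counts as mutated in an instance iff it has at least one record
    whose variant classification is not in ``silent_labels``.  Instances that
    appear in the table always get an entry, possibly empty.
    """
    silent = set(silent_labels)
    calls: dict[str, set[str]] = {inst: set() for inst in table["instance"].unique()}
    hits = table[~table["variant_classification"].isin(silent)]
    for inst, genes in hits.groupby("instance")["gene"]:
        calls[inst] = set(genes)
    return calls


def instances_from_tables(
    expression: pd.DataFrame,
    mutations: pd.DataFrame,
    threshold: float = 1.0,
    silent_labels: Iterable[str] = DEFAULT_SILENT_LABELS,
) -> list[SampleInstance]:
    """Assemble per-patient instances from an expression matrix and a mutation
    table, in the column order of the expression matrix."""
    expressed = call_expressed(expression, threshold)
    mutated = call_mutated(mutations, silent_labels)
    ids: list[str] = []
    for col in expression.columns:
        inst = col.rpartition("_")[0]
        if inst not in ids:
            ids.append(inst)
    out = []
    for inst in ids:
        out.append(
            SampleInstance(
                instance_id=inst,
                normal_expressed=expressed.get((inst, "normal"), set()),
                tumor_expressed=expressed.get((inst, "tumor"), set()),
                tumor_mutated=mutated.get(inst, set()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# gene lists


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; '#' comments and blank lines skipped; duplicates
    collapse keeping first occurrence."""
    genes: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            gene = line.split("#", 1)[0].strip()
            if gene and gene not in seen:
                genes.append(gene)
                seen.add(gene)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# gene ontology


def read_obo(path: str | Path, relationships: Iterable[str] = ("is_a", "part_of")) -> nx.DiGraph:
    """Read an OBO 1.2 ontology into a child->parent DAG.

    Only the given relationship types become edges; obsolete terms are dropped
    (obonet's default).  Raises on a cyclic ontology.
    """
    multi = obonet.read_obo(str(path))
    wanted = set(relationships)
    dag = nx.DiGraph()
    dag.add_nodes_from(multi.nodes(data=True))
    for child, parent, key in multi.edges(keys=True):
        if key in wanted:
            dag.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError(f"{path}: ontology graph is cyclic")
    return dag


#: GAF 2.x column indices
_GAF_SYMBOL, _GAF_QUALIFIER, _GAF_TERM = 2, 3, 4
_GAF_OBJECT_ID = 1


def read_gaf(path: str | Path, gene_column: int = _GAF_SYMBOL) -> dict[str, set[str]]:
    """Read GAF 2.x annotations: gene id (from ``gene_column``) -> GO term set.

    Rows with a NOT qualifier are skipped.  The default identifier column is
    DB Object Symbol (column 3); pass ``gene_column=1`` to key on the DB
    object id (e.g. UniProt accession) instead.
    """
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) <= max(gene_column, _GAF_TERM):
                raise ValueError(f"{path}: short GAF row at line {lineno}")
            if "NOT" in cols[_GAF_QUALIFIER].split("|"):
                continue
            gene, term = cols[gene_column], cols[_GAF_TERM]
            if gene and term:
                annotations.setdefault(gene, set()).add(term)
    return annotations


def read_go(
    obo_path: str | Path,
    gaf_path: str | Path,
    relationships: Iterable[str] = ("is_a", "part_of"),
    gene_column: int = _GAF_SYMBOL,
) -> GOAnnotationMap:
    """Read ontology + annotations into a validated :class:`GOAnnotationMap`
    (annotations to unknown terms are dropped with a warning)."""
    return GOAnnotationMap(
        annotations=read_gaf(gaf_path, gene_column=gene_column),
        ontology=read_obo(obo_path, relationships=relationships),
    )
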