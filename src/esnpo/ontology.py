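"""Gene Ontology graph and gene->term annotations.

The ontology is a DAG over terms in three namespaces — biological_process
(BP), cellular_component (CC) and molecular_function (MF).  Only ``is_a``
and ``part_of`` edges are retained by default; ``regulates``-family edges
are excluded, as is standard for enrichment analysis.

Annotations follow the true-path rule: a gene annotated to a term is
implicitly annotated to every ancestor of that term.  Propagation is an
explicit, idempotent operation so that both direct and propagated
annotation sets are first-class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
from Bio.UniProt import GOA

from .formats import FormatError, RowIssue

__all__ = [
    "NAMESPACE_CODES",
    "OntologyError",
    "UnknownTermError",
    "OntologyGraph",
    "AnnotationSet",
    "read_obo",
    "read_gaf",
    "ancestors",
    "propagate",
]

NAMESPACE_CODES = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}

DEFAULT_EDGE_TYPES = ("is_a", "part_of")


class OntologyError(ValueError):
    """Structural problem in the ontology graph."""


class UnknownTermError(KeyError):
    """A term id that is neither a primary id nor a known alt_id."""


class OntologyGraph:
    """The GO DAG restricted to non-obsolete terms and a chosen edge set.

    Parameters
    ----------
    graph
        Directed graph with edges pointing child -> parent.
    namespaces
        term id -> namespace code in {BP, CC, MF}.
    names
        term id -> human-readable name.
    alt_ids
        secondary id -> canonical id map.
    """

    def __init__(
        self,
        graph: nx.DiGraph,
        namespaces: Mapping[str, str],
        names: Mapping[str, str],
        alt_ids: Mapping[str, str] | None = None,
    ):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyError(f"ontology graph contains a cycle: {cycle}")
        self._graph = graph
        self._namespaces = dict(namespaces)
        self._names = dict(names)
        self._alt_ids = dict(alt_ids or {})
        for term, ns in self._namespaces.items():
            if ns not in ("BP", "CC", "MF"):
                raise OntologyError(f"term {term} has unknown namespace {ns!r}")

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self._graph or term in self._alt_ids

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def resolve(self, term: str) -> str:
        """Map an id (primary or alt_id) to its canonical term id."""
        if term in self._graph:
            return term
        if term in self._alt_ids:
            return self._alt_ids[term]
        raise UnknownTermError(term)

    def name(self, term: str) -> str:
        return self._names.get(self.resolve(term), "")

    def namespace(self, term: str) -> str:
        return self._namespaces[self.resolve(term)]

    def parents(self, term: str) -> frozenset[str]:
        return frozenset(self._graph.successors(self.resolve(term)))

    def children(self, term: str) -> frozenset[str]:
        return frozenset(self._graph.predecessors(self.resolve(term)))

    def ancestors(self, term: str) -> frozenset[str]:
        """Transitive closure of parents, excluding the term itself."""
        return frozenset(nx.descendants(self._graph, self.resolve(term)))

    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self._graph if self._graph.out_degree(t) == 0)


def read_obo(
    path: str | Path,
    edge_types: Iterable[str] = DEFAULT_EDGE_TYPES,
) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Obsolete terms are excluded (and cannot be annotation targets);
    ``alt_id`` secondary ids are mapped to their canonical term.  Only the
    requested edge types are retained (default: is_a and part_of).
    """
    edge_types = tuple(edge_types)
    multi = obonet.read_obo(path)  # child -> parent MultiDiGraph, obsolete dropped
    graph = nx.DiGraph()
    namespaces: dict[str, str] = {}
    names: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for term, data in multi.nodes(data=True):
        if "namespace" not in data:
            raise OntologyError(
                f"term {term} is referenced as a parent but never defined"
            )
        ns = data["namespace"]
        if ns not in NAMESPACE_CODES:
            raise OntologyError(f"term {term}: unknown namespace {ns!r}")
        graph.add_node(term)
        namespaces[term] = NAMESPACE_CODES[ns]
        names[term] = data.get("name", "")
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
    for child, parent, rel in multi.edges(keys=True):
        if rel in edge_types:
            graph.add_edge(child, parent)
    return OntologyGraph(graph, namespaces, names, alt_ids)


@dataclass
class AnnotationSet:
    """A set of (gene symbol, GO term id) annotation pairs.

    ``propagated`` records whether the set is closed under the ancestor
    relation (the true-path rule).
    """

    pairs: frozenset[tuple[str, str]]
    propagated: bool = False
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)
    issues: list[RowIssue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.pairs)

    def term_to_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, term in self.pairs:
            out.setdefault(term, set()).add(gene)
        return out

    def gene_to_terms(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, term in self.pairs:
            out.setdefault(gene, set()).add(term)
        return out


def read_gaf(
    path: str | Path,
    graph: OntologyGraph | None = None,
    evidence_filter: set[str] | None = None,
    *,
    strict: bool = True,
) -> AnnotationSet:
    """Read gene->GO annotations from a GAF 2.x file.

    Gene identity is the DB_Object_Symbol column (column 3).  Rows with a
    ``NOT`` qualifier are excluded, as are ND ("no data") evidence rows,
    which annotate roots merely to say the function is unknown.  If an
    ``evidence_filter`` is given, only rows whose evidence code is in the
    set are kept.  When a graph is supplied, alt_ids are resolved and
    annotations to terms missing from the graph are row errors.
    """
    pairs: set[tuple[str, str]] = set()
    evidence: dict[tuple[str, str], str] = {}
    issues: list[RowIssue] = []
    with open(path) as fh:
        # GOA.gafiterator consumes header lines itself, so track line
        # numbers by counting non-comment records.
        lineno = sum(1 for line in open(path) if line.startswith("!"))
        for rec in GOA.gafiterator(fh):
            lineno += 1
            gene = rec.get("DB_Object_Symbol", "").strip()
            term = rec.get("GO_ID", "").strip()
            code = rec.get("Evidence", "").strip()
            if not gene or not term:
                msg = "missing gene symbol or GO id"
                if strict:
                    raise FormatError(f"{path}: line {lineno}: {msg}")
                issues.append(RowIssue(lineno, msg))
                continue
            if "NOT" in rec.get("Qualifier", []):
                continue
            if code == "ND":
                continue
            if evidence_filter is not None and code not in evidence_filter:
                continue
            if graph is not None:
                try:
                    term = graph.resolve(term)
                except UnknownTermError:
                    msg = f"annotation to unknown term {term}"
                    if strict:
                        raise FormatError(f"{path}: line {lineno}: {msg}")
                    issues.append(RowIssue(lineno, msg))
                    continue
            pairs.add((gene, term))
            evidence.setdefault((gene, term), code)
    return AnnotationSet(frozenset(pairs), propagated=False, evidence=evidence, issues=issues)


def ancestors(graph: OntologyGraph, term: str) -> frozenset[str]:
    """All ancestors of ``term`` over the retained edge types (term excluded)."""
    return graph.ancestors(term)


def propagate(annotations: AnnotationSet, graph: OntologyGraph) -> AnnotationSet:
    """Close an annotation set upward under the true-path rule.

    Every (gene, term) pair gains (gene, ancestor) for each ancestor of
    the term.  Idempotent; annotation to a term absent from the graph
    raises :class:`UnknownTermError`.
    """
    closed: set[tuple[str, str]] = set()
    for gene, term in annotations.pairs:
        canonical = graph.resolve(term)  # raises UnknownTermError
        closed.add((gene, canonical))
        for anc in graph.ancestors(canonical):
            closed.add((gene, anc))
    return AnnotationSet(frozenset(closed), propagated=True, evidence=dict(annotations.evidence))
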