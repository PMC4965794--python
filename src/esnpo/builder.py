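"""Construction of the SNP -> GO-term association map (the eSNPO build).

A SNP is linked to a GO term when at least one gene is both (a)
eQTL-associated with the SNP at FDR below the inclusion threshold and
(b) annotated to the term.  Duplicate (SNP, term) pairs arising through
different genes or tissues are merged, unioning the mediating-gene and
tissue provenance.  Builds are tissue-stratified by default; merging
across tissues is an explicit operation because it changes the
enrichment universe.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .formats import RSID_PATTERN, EqtlAssociation, EqtlTable
from .ontology import AnnotationSet, OntologyGraph

__all__ = [
    "SnpTermAssociation",
    "Esnpo",
    "EsnpoSummary",
    "filter_eqtl",
    "build_associations",
    "merge_tissues",
    "summarize",
]


@dataclass(frozen=True)
class SnpTermAssociation:
    """One SNP -> GO-term link with its mediating genes and tissues."""

    snp_id: str
    term: str
    namespace: str
    genes: frozenset[str]
    tissues: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(
                f"association ({self.snp_id}, {self.term}) has no mediating gene"
            )


class Esnpo:
    """A set of SNP-term associations with its SNP universe and term index.

    The universe (all SNPs carrying at least one association) is the
    background N of the enrichment test; the term index maps each term to
    the universe SNPs annotated to it.
    """

    def __init__(
        self,
        associations: Iterable[SnpTermAssociation],
        scope: str = "",
        unannotated_genes: frozenset[str] = frozenset(),
    ):
        index: dict[tuple[str, str], SnpTermAssociation] = {}
        for a in associations:
            key = (a.snp_id, a.term)
            if key in index:
                prev = index[key]
                a = SnpTermAssociation(
                    a.snp_id,
                    a.term,
                    a.namespace,
                    prev.genes | a.genes,
                    prev.tissues | a.tissues,
                )
            index[key] = a
        self._assoc = index
        self.scope = scope
        #: eQTL genes that carried no annotation and so contributed nothing.
        self.unannotated_genes = unannotated_genes

    def __len__(self) -> int:
        return len(self._assoc)

    def __iter__(self):
        return iter(sorted(self._assoc.values(), key=lambda a: (a.snp_id, a.term)))

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._assoc

    def get(self, snp_id: str, term: str) -> SnpTermAssociation | None:
        return self._assoc.get((snp_id, term))

    @property
    def associations(self) -> frozenset[SnpTermAssociation]:
        return frozenset(self._assoc.values())

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(a.snp_id for a in self._assoc.values())

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(a.term for a in self._assoc.values())

    @property
    def term_index(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for snp, term in self._assoc:
            out.setdefault(term, set()).add(snp)
        return {t: frozenset(s) for t, s in out.items()}

    def namespace_of(self, term: str) -> str:
        for a in self._assoc.values():
            if a.term == term:
                return a.namespace
        raise KeyError(term)


@dataclass(frozen=True)
class EsnpoSummary:
    """Build-level counts: associations, SNPs, terms, terms per namespace."""

    n_assoc: int
    n_snps: int
    n_terms: int
    by_namespace: tuple[tuple[str, int], ...]  # (("BP", k), ("CC", k), ("MF", k))

    def as_dict(self) -> dict:
        return {
            "n_assoc": self.n_assoc,
            "n_snps": self.n_snps,
            "n_terms": self.n_terms,
            "by_namespace": dict(self.by_namespace),
        }


def filter_eqtl(
    table: EqtlTable,
    fdr_threshold: float = 0.05,
    snp_pattern: str = RSID_PATTERN,
) -> EqtlTable:
    """Apply the eQTL inclusion filter: FDR strictly below the threshold.

    Also drops records whose SNP id is not a reference SNP name (default
    pattern ``rs\\d+``) or whose gene symbol is empty.  The inequality is
    strict — an FDR exactly at the threshold is excluded.
    """
    if not 0.0 < fdr_threshold <= 1.0:
        raise ValueError(f"fdr_threshold must be in (0, 1], got {fdr_threshold}")
    pattern = re.compile(snp_pattern)
    kept = [
        r
        for r in table.records
        if r.fdr < fdr_threshold and pattern.fullmatch(r.snp_id) and r.gene
    ]
    return EqtlTable(
        kept,
        tissue_label=table.tissue_label,
        source_label=table.source_label,
        issues=list(table.issues),
    )


def _join(
    triples: Iterable[tuple[str, str, str]],
    annotations: AnnotationSet,
    graph: OntologyGraph,
    scope: str,
) -> Esnpo:
    """Join (snp, gene, tissue) triples against gene->term annotations.

    Single code path shared by the eQTL-based and position-based builds:
    for every triple (s, g, l) and every annotation (g, t), emit (s, t)
    carrying gene g and label l; duplicates merge by provenance union.
    """
    gene_terms = annotations.gene_to_terms()
    merged: dict[tuple[str, str], tuple[set[str], set[str]]] = {}
    unannotated: set[str] = set()
    for snp, gene, label in triples:
        terms = gene_terms.get(gene)
        if not terms:
            unannotated.add(gene)
            continue
        for term in terms:
            genes, labels = merged.setdefault((snp, term), (set(), set()))
            genes.add(gene)
            labels.add(label)
    assocs = [
        SnpTermAssociation(
            snp_id=snp,
            term=term,
            namespace=graph.namespace(term),
            genes=frozenset(genes),
            tissues=frozenset(labels),
        )
        for (snp, term), (genes, labels) in merged.items()
    ]
    return Esnpo(assocs, scope=scope, unannotated_genes=frozenset(unannotated))


def build_associations(
    eqtl_tables: Sequence[EqtlTable] | EqtlTable,
    annotations: AnnotationSet,
    graph: OntologyGraph,
    scope: str = "",
) -> Esnpo:
    """Build an eSNPO from filtered eQTL tables and annotations.

    Every annotation term must exist in ``graph``.  Genes present in the
    eQTL data but absent from the annotations contribute nothing and are
    recorded in ``Esnpo.unannotated_genes``.
    """
    if isinstance(eqtl_tables, EqtlTable):
        eqtl_tables = [eqtl_tables]
    triples = (
        (r.snp_id, r.gene, r.tissue or t.tissue_label)
        for t in eqtl_tables
        for r in t.records
    )
    if not scope:
        scope = "+".join(sorted({t.tissue_label for t in eqtl_tables})) or "all"
    return _join(triples, annotations, graph, scope)


def merge_tissues(esnpos: Sequence[Esnpo]) -> Esnpo:
    """Union several builds into one, merging provenance per (SNP, term)."""
    if not esnpos:
        raise ValueError("merge_tissues requires at least one build")
    merged = Esnpo(
        (a for e in esnpos for a in e.associations),
        scope="+".join(sorted({e.scope for e in esnpos if e.scope})),
        unannotated_genes=frozenset().union(*(e.unannotated_genes for e in esnpos)),
    )
    return merged


def summarize(esnpo: Esnpo) -> EsnpoSummary:
    """Count associations, SNPs, and terms (total and per namespace)."""
    term_ns: dict[str, str] = {}
    for a in esnpo.associations:
        term_ns[a.term] = a.namespace
    counts = {"BP": 0, "CC": 0, "MF": 0}
    for ns in term_ns.values():
        counts[ns] += 1
    return EsnpoSummary(
        n_assoc=len(esnpo),
        n_snps=len(esnpo.universe),
        n_terms=len(term_ns),
        by_namespace=tuple(sorted(counts.items())),
    )
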