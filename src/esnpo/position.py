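"""Position-based SNP-to-gene assignment — the comparison baseline.

Instead of eQTL evidence, a SNP is assigned to every gene whose interval
(optionally widened by a symmetric flank) contains its position.  The
resulting (SNP, gene) pairs feed the exact same join and enrichment code
path as the eQTL-based build, so the two methods differ only in how SNPs
reach genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .builder import Esnpo, _join
from .formats import GeneInterval, SnpLocus
from .ontology import AnnotationSet, OntologyGraph

__all__ = ["PositionMap", "map_snps_to_genes", "build_position_associations"]

#: Tissue/provenance label attached to every position-derived association.
POSITION_LABEL = "position"


@dataclass(frozen=True)
class PositionMap:
    """SNP->gene pairs from interval overlap under a given flank window."""

    pairs: frozenset[tuple[str, str]]
    window: int
    unmapped_snps: frozenset[str]

    def __len__(self) -> int:
        return len(self.pairs)


def map_snps_to_genes(
    snps: Sequence[SnpLocus],
    genes: Sequence[GeneInterval],
    window: int = 0,
) -> PositionMap:
    """Assign each SNP to the genes it overlaps, gene body +/- window bp.

    A SNP at position p maps to gene g iff they share a chromosome and
    g.start - window <= p < g.end + window (0-based half-open).  Strand
    is ignored; a SNP may map to several overlapping genes.  SNPs mapping
    to no gene are reported in ``unmapped_snps``.
    """
    if window < 0:
        raise ValueError(f"window must be non-negative, got {window}")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start - window, g.end + window, g.gene
        )
    pairs: set[tuple[str, str]] = set()
    unmapped: set[str] = set()
    for s in snps:
        tree = trees.get(s.chrom)
        hits = tree[s.pos] if tree is not None else ()
        if hits:
            for iv in hits:
                pairs.add((s.snp_id, iv.data))
        else:
            unmapped.add(s.snp_id)
    return PositionMap(frozenset(pairs), window=window, unmapped_snps=frozenset(unmapped))


def build_position_associations(
    pmap: PositionMap,
    annotations: AnnotationSet,
    graph: OntologyGraph,
) -> Esnpo:
    """Join positional SNP-gene pairs against annotations.

    Identical join semantics to the eQTL build (same code path); the
    provenance label is fixed to "position".
    """
    triples = ((snp, gene, POSITION_LABEL) for snp, gene in sorted(pmap.pairs))
    return _join(triples, annotations, graph, scope=POSITION_LABEL)
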