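"""Synthetic eQTL / ontology / annotation fixtures with planted structure.

Generates, from a single integer seed, the complete input bundle the
toolkit consumes — an eQTL association table, an OBO ontology, a GAF
annotation file, a BED gene model and a SNP locus table — plus query SNP
sets with a controllable enrichment signal.

The generator emulates the statistical structure the enrichment model
assumes: a small GO-like DAG with the three namespace roots, genes
annotated to non-root terms, SNPs linked to genes with eQTL FDR values
drawn below the 0.05 inclusion threshold for true links and above it for
decoys (so the filter is exercised), and gene bodies on three
chromosomes so the position baseline has something to map.  One BP leaf
term (child of the BP root, never a parent) is the designated "planted"
term: queries drawn with odds ratio rho > 1 over-sample its SNPs, and
rho = 1 reduces to uniform sampling from the universe.

It makes no attempt to mimic LD structure, allele frequencies, or the
tissue-sharing patterns of real eQTL data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "generate_query"]

#: Namespace roots of the synthetic ontology.
ROOTS = {"GO:0000001": "BP", "GO:0000002": "CC", "GO:0000003": "MF"}
#: The designated planted BP leaf term.
PLANTED_TERM = "GO:0000004"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic bundle.  A fixed seed gives byte-identical files."""

    n_snps: int = 200
    n_genes: int = 60
    n_terms: int = 25
    genes_per_term: tuple[int, int] = (3, 8)  # uniform inclusive range
    planted_term_genes: int = 8
    eqtl_density: float = 2.0  # expected genes per SNP
    decoy_fraction: float = 0.2  # links drawn with FDR >= 0.05
    n_unannotated_genes: int = 5
    n_bad_snp_rows: int = 5  # extra rows with positional (non-rsID) SNP names
    seed: int = 0

    def validate(self) -> None:
        annotatable = self.n_genes - self.n_unannotated_genes
        if self.n_terms < 4:
            raise ValueError("need at least the 3 roots plus one term")
        if annotatable <= 0:
            raise ValueError("no annotatable genes left")
        if self.genes_per_term[1] > annotatable or self.planted_term_genes > annotatable:
            raise ValueError("genes_per_term exceeds the annotatable gene pool")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise ValueError("decoy_fraction must be in [0, 1]")
        if self.eqtl_density < 1.0:
            raise ValueError("eqtl_density must be >= 1")


@dataclass
class Fixture:
    """A generated bundle: file paths plus the generator's ground truth.

    The ground-truth maps (term ancestry, annotation closure, true
    SNP-gene links, SNP universe) are computed inside the generator with
    a plain DFS, independently of the ontology/builder modules, so tests
    can use them as an oracle.
    """

    spec: FixtureSpec
    paths: dict[str, Path]
    term_namespace: dict[str, str]
    term_parents: dict[str, set[str]]
    term_genes_direct: dict[str, set[str]]
    snp_gene_true: set[tuple[str, str]]  # links passing FDR < 0.05, rsID names only
    planted_term: str = PLANTED_TERM

    # -- ground-truth derivations (independent closure implementation) -----
    def term_ancestors(self, term: str) -> set[str]:
        out: set[str] = set()
        stack = list(self.term_parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.term_parents.get(t, ()))
        return out

    def gene_terms_closed(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for term, genes in self.term_genes_direct.items():
            closure = {term} | self.term_ancestors(term)
            for g in genes:
                out.setdefault(g, set()).update(closure)
        return out

    @property
    def universe(self) -> set[str]:
        annotated = set(self.gene_terms_closed())
        return {s for s, g in self.snp_gene_true if g in annotated}

    def term_snps(self, term: str) -> set[str]:
        gene_terms = self.gene_terms_closed()
        return {
            s
            for s, g in self.snp_gene_true
            if term in gene_terms.get(g, ())
        }


def _make_dag(spec: FixtureSpec, rng: np.random.Generator):
    """Random DAG: 3 roots, a planted BP leaf, remaining terms with 1-2 parents."""
    term_ns: dict[str, str] = dict(ROOTS)
    term_parents: dict[str, set[str]] = {r: set() for r in ROOTS}
    term_ns[PLANTED_TERM] = "BP"
    term_parents[PLANTED_TERM] = {"GO:0000001"}
    ns_pool = {"BP": ["GO:0000001"], "CC": ["GO:0000002"], "MF": ["GO:0000003"]}
    # planted term deliberately left out of ns_pool so it stays a leaf
    for i in range(5, spec.n_terms + 1):
        term = f"GO:{i:07d}"
        ns = ("BP", "BP", "CC", "MF")[rng.integers(0, 4)]  # BP-heavy, like real GO
        parents_avail = ns_pool[ns]
        k = int(rng.integers(1, min(2, len(parents_avail)) + 1))
        chosen = rng.choice(len(parents_avail), size=k, replace=False)
        term_ns[term] = ns
        term_parents[term] = {parents_avail[j] for j in chosen}
        ns_pool[ns].append(term)
    return term_ns, term_parents


def _annotate(spec: FixtureSpec, rng: np.random.Generator, term_ns, term_parents):
    genes = [f"G{i:03d}" for i in range(1, spec.n_genes + 1)]
    annotatable = genes[: spec.n_genes - spec.n_unannotated_genes]
    term_genes: dict[str, set[str]] = {}
    lo, hi = spec.genes_per_term
    for term in sorted(term_ns):
        if term in ROOTS:
            continue
        size = spec.planted_term_genes if term == PLANTED_TERM else int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(annotatable), size=size, replace=False)
        term_genes[term] = {annotatable[j] for j in chosen}
    # every annotatable gene must reach >= 1 term, else it is silently inert
    assigned = set().union(*term_genes.values())
    leaf_terms = sorted(set(term_genes) - {PLANTED_TERM})
    for g in annotatable:
        if g not in assigned:
            term_genes[leaf_terms[rng.integers(0, len(leaf_terms))]].add(g)
    return genes, term_genes


def _sample_eqtl(spec: FixtureSpec, rng: np.random.Generator, genes):
    """(snp, gene, fdr) rows; true links FDR < 0.05, decoys >= 0.05."""
    rows: list[tuple[str, str, float]] = []
    true_links: set[tuple[str, str]] = set()
    snp_genes: dict[str, list[str]] = {}
    snps = [f"rs{1000 + i}" for i in range(spec.n_snps)]
    for snp in snps:
        k = max(1, int(rng.poisson(spec.eqtl_density)))
        k = min(k, len(genes))
        chosen = rng.choice(len(genes), size=k, replace=False)
        snp_genes[snp] = [genes[j] for j in chosen]
        for g in snp_genes[snp]:
            if rng.random() < spec.decoy_fraction:
                fdr = float(rng.uniform(0.05, 1.0))
            else:
                fdr = float(rng.uniform(0.0, 0.05))
                true_links.add((snp, g))
            rows.append((snp, g, fdr))
    for i in range(spec.n_bad_snp_rows):
        g = genes[int(rng.integers(0, len(genes)))]
        rows.append((f"chr1:{100000 + i}", g, float(rng.uniform(0.0, 0.05))))
    return snps, rows, true_links, snp_genes


def _place_genes(spec: FixtureSpec, rng: np.random.Generator, genes):
    """Non-overlapping gene bodies in 30 kb slots on chr1-chr3."""
    intervals: dict[str, tuple[str, int, int]] = {}
    slot_of_chrom: dict[str, int] = {"chr1": 0, "chr2": 0, "chr3": 0}
    for i, g in enumerate(genes):
        chrom = f"chr{(i % 3) + 1}"
        slot = slot_of_chrom[chrom]
        slot_of_chrom[chrom] += 1
        start = 10_000 + slot * 30_000
        length = int(rng.integers(5_000, 20_001))
        intervals[g] = (chrom, start, start + length)
    return intervals


def _place_snps(spec: FixtureSpec, rng: np.random.Generator, snps, snp_genes, gene_pos):
    """SNP loci: mostly inside an eQTL-linked gene (cis), some random, some intergenic."""
    loci: list[tuple[str, str, int]] = []
    for snp in snps:
        u = rng.random()
        if u < 0.6:
            gene = snp_genes[snp][int(rng.integers(0, len(snp_genes[snp])))]
            chrom, start, end = gene_pos[gene]
            pos = int(rng.integers(start, end))
        elif u < 0.8:
            gene = list(gene_pos)[int(rng.integers(0, len(gene_pos)))]
            chrom, start, end = gene_pos[gene]
            pos = int(rng.integers(start, end))
        else:
            chrom = f"chr{int(rng.integers(1, 4))}"
            pos = int(rng.integers(0, 10_000))  # all genes start at >= 10 kb
        loci.append((snp, chrom, pos))
    return loci


def _write_obo(path: Path, seed: int, term_ns, term_parents) -> None:
    ns_long = {"BP": "biological_process", "CC": "cellular_component", "MF": "molecular_function"}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"remark: synthetic fixture, seed={seed}\n")
        fh.write("ontology: synthetic-go\n")
        for term in sorted(term_ns):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: synthetic term {term[-4:]}\n")
            fh.write(f"namespace: {ns_long[term_ns[term]]}\n")
            for parent in sorted(term_parents.get(term, ())):
                fh.write(f"is_a: {parent}\n")


def _write_gaf(path: Path, seed: int, term_genes, term_ns) -> None:
    aspect = {"BP": "P", "CC": "C", "MF": "F"}
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        fh.write(f"!synthetic fixture, seed={seed}\n")
        for term in sorted(term_genes):
            for gene in sorted(term_genes[term]):
                fields = [
                    "SYNTH", gene, gene, "", term, "SYNTH:0001", "EXP", "",
                    aspect[term_ns[term]], "", "", "protein", "taxon:9606",
                    "20160101", "SYNTH", "", "",
                ]
                fh.write("\t".join(fields) + "\n")


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> Fixture:
    """Write a complete synthetic input bundle into ``outdir``.

    Files: eqtl.tsv, ontology.obo, annotations.gaf, genes.bed,
    snp_loci.tsv.  All sampling flows from ``spec.seed``; every file
    embeds the seed in a comment header.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    term_ns, term_parents = _make_dag(spec, rng)
    genes, term_genes = _annotate(spec, rng, term_ns, term_parents)
    snps, eqtl_rows, true_links, snp_genes = _sample_eqtl(spec, rng, genes)
    gene_pos = _place_genes(spec, rng, genes)
    loci = _place_snps(spec, rng, snps, snp_genes, gene_pos)

    paths = {
        "eqtl": outdir / "eqtl.tsv",
        "obo": outdir / "ontology.obo",
        "gaf": outdir / "annotations.gaf",
        "bed": outdir / "genes.bed",
        "loci": outdir / "snp_loci.tsv",
    }
    with open(paths["eqtl"], "w") as fh:
        fh.write(f"# synthetic fixture, seed={spec.seed}\n")
        fh.write("SNP\tGENE\tFDR\n")
        for snp, gene, fdr in eqtl_rows:
            fh.write(f"{snp}\t{gene}\t{fdr:.6g}\n")
    _write_obo(paths["obo"], spec.seed, term_ns, term_parents)
    _write_gaf(paths["gaf"], spec.seed, term_genes, term_ns)
    with open(paths["bed"], "w") as fh:
        fh.write(f"# synthetic fixture, seed={spec.seed}\n")
        for gene in sorted(gene_pos, key=lambda g: (gene_pos[g][0], gene_pos[g][1])):
            chrom, start, end = gene_pos[gene]
            fh.write(f"{chrom}\t{start}\t{end}\t{gene}\t0\t+\n")
    with open(paths["loci"], "w") as fh:
        fh.write(f"# synthetic fixture, seed={spec.seed}\n")
        fh.write("snp\tchrom\tpos\n")
        for snp, chrom, pos in loci:
            fh.write(f"{snp}\t{chrom}\t{pos}\n")

    return Fixture(
        spec=spec,
        paths=paths,
        term_namespace=term_ns,
        term_parents=term_parents,
        term_genes_direct=term_genes,
        snp_gene_true=true_links,
    )


def generate_query(
    fixture: Fixture,
    planted_term: str | None = None,
    rho: float = 20.0,
    size: int = 30,
    seed: int = 0,
) -> list[str]:
    """Draw a query SNP set with planted enrichment for one term.

    SNPs annotated (through the true-link ground truth, with ancestor
    closure) to ``planted_term`` enter the query with ``rho`` times the
    background inclusion odds; ``rho = 1`` is a uniform draw from the
    universe.  Sampling is without replacement.
    """
    if rho < 1.0:
        raise ValueError(f"rho must be >= 1, got {rho}")
    planted_term = planted_term or fixture.planted_term
    if planted_term not in fixture.term_namespace:
        raise ValueError(f"planted term {planted_term} not in fixture ontology")
    universe = sorted(fixture.universe)
    if size > len(universe):
        raise ValueError(f"query size {size} exceeds universe size {len(universe)}")
    planted = fixture.term_snps(planted_term)
    weights = np.array([rho if s in planted else 1.0 for s in universe])
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(universe), size=size, replace=False, p=weights)
    return sorted(universe[j] for j in chosen)
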