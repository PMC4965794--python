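"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (literal enumeration, exact
rational arithmetic, all-pairs scans) and shares no code with the
package modules it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def hypergeom_pvalue_enum(N: int, M: int, n: int, m: int) -> Fraction:
    """Upper-tail p by literally enumerating all C(N, n) draws.

    The universe is {0..N-1} with query set {0..M-1}; count the draws of
    size n whose overlap with the query is >= m.
    """
    hits = sum(
        1
        for draw in itertools.combinations(range(N), n)
        if sum(1 for x in draw if x < M) >= m
    )
    return Fraction(hits, comb(N, n))


def hypergeom_pvalue_exact(N: int, M: int, n: int, m: int) -> Fraction:
    """Upper-tail p as an exact rational from closed-form binomials."""
    total = comb(N, n)
    return sum(
        (Fraction(comb(M, k) * comb(N - M, n - k), total) for k in range(m, min(M, n) + 1)),
        Fraction(0),
    )


def hypergeom_pmf_exact(N: int, M: int, n: int, k: int) -> Fraction:
    return Fraction(comb(M, k) * comb(N - M, n - k), comb(N, n))


def hommel_closed_testing(ps: list[float]) -> list[float]:
    """Hommel adjusted p-values by brute-force closed testing.

    The adjusted p of hypothesis i is the max, over every subset S
    containing i, of the Simes p-value of S.  Exponential in k; only for
    small vectors.
    """
    k = len(ps)
    adj = [0.0] * k
    for r in range(1, k + 1):
        for subset in itertools.combinations(range(k), r):
            sub = sorted(ps[i] for i in subset)
            simes = min(len(sub) * p / (j + 1) for j, p in enumerate(sub))
            for i in subset:
                if simes > adj[i]:
                    adj[i] = simes
    return [min(1.0, a) for a in adj]


def join_bruteforce(
    snp_gene: set[tuple[str, str]],
    gene_term: set[tuple[str, str]],
) -> dict[tuple[str, str], set[str]]:
    """All (snp, term) pairs sharing >= 1 gene, with the exact gene intersection."""
    out: dict[tuple[str, str], set[str]] = {}
    snps = {s for s, _ in snp_gene}
    terms = {t for _, t in gene_term}
    for s in snps:
        s_genes = {g for s2, g in snp_gene if s2 == s}
        for t in terms:
            t_genes = {g for g, t2 in gene_term if t2 == t}
            shared = s_genes & t_genes
            if shared:
                out[(s, t)] = shared
    return out


def ancestors_by_path_enumeration(
    parents: dict[str, set[str]], term: str
) -> set[str]:
    """Every node reachable from ``term`` by enumerating all upward paths."""
    found: set[str] = set()

    def walk(path: list[str]) -> None:
        for p in parents.get(path[-1], ()):
            if p in path:
                raise ValueError("cycle")
            found.add(p)
            walk(path + [p])

    walk([term])
    return found


def overlap_bruteforce(loci, intervals, window: int) -> set[tuple[str, str]]:
    """All-pairs SNP x gene overlap scan under a symmetric flank."""
    return {
        (s.snp_id, g.gene)
        for s in loci
        for g in intervals
        if s.chrom == g.chrom and g.start - window <= s.pos < g.end + window
    }
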