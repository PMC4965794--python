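"""SNP-set over-representation testing on an eSNPO build.

For a build with N universe SNPs, M in-universe query SNPs, and a term
annotated to n universe SNPs of which m are query SNPs, the one-sided
(upper tail) hypergeometric p-value is

    p = sum_{k=m}^{min(M, n)} C(M, k) C(N-M, n-k) / C(N, n),

i.e. the Fisher exact test for over-representation.  The tail is summed
in log space (log-gamma binomials + logsumexp) so that counts in the
hundreds of thousands do not overflow.

Seven multiple-testing adjustments are implemented from first principles
with the same semantics as R's p.adjust: bonferroni, holm, hochberg,
hommel, BH (alias "fdr"), BY, and none.  The tested family is the set of
terms the query actually touches (m >= 1) unless ``test_all_terms`` is
requested, which widens the adjustment denominator to every term in the
build.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .builder import Esnpo

__all__ = [
    "ADJUSTMENT_METHODS",
    "ContingencyCounts",
    "EnrichmentResult",
    "EnrichmentRun",
    "make_contingency",
    "hypergeom_pvalue",
    "adjust_pvalues",
    "run_enrichment",
]

ADJUSTMENT_METHODS = ("bonferroni", "holm", "hochberg", "hommel", "BH", "BY", "none")
_ALIASES = {"fdr": "BH", "by": "BY", "bh": "BH"}


@dataclass(frozen=True)
class ContingencyCounts:
    """The (N, M, n, m) quadruple for one term's test.

    N: universe SNPs; M: in-universe query SNPs; n: universe SNPs
    annotated to the term; m: query SNPs annotated to the term.
    """

    N: int
    M: int
    n: int
    m: int

    def __post_init__(self) -> None:
        N, M, n, m = self.N, self.M, self.n, self.m
        if min(N, M, n, m) < 0:
            raise ValueError(f"negative count in {self}")
        if M > N or n > N:
            raise ValueError(f"M and n must not exceed N: {self}")
        if m > min(M, n) or m < max(0, n + M - N):
            raise ValueError(f"m outside hypergeometric support: {self}")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term test outcome: counts, raw and adjusted p, significance."""

    term: str
    namespace: str
    counts: ContingencyCounts
    p: float
    p_adj: float
    significant: bool
    name: str = ""
    query_genes: frozenset[str] = frozenset()


@dataclass
class EnrichmentRun:
    """A full enrichment run: sorted results plus run-level metadata."""

    results: list[EnrichmentResult]
    method: str
    alpha: float
    universe_size: int
    n_query: int
    n_query_in_universe: int
    n_query_dropped: int
    n_tested: int
    n_significant: int
    dropped_snps: frozenset[str] = frozenset()

    @property
    def pct_significant(self) -> float:
        """Share of tested terms that are significant, one-decimal percent."""
        if self.n_tested == 0:
            return 0.0
        return round(100.0 * self.n_significant / self.n_tested, 1)

    def significant_terms(self) -> frozenset[str]:
        return frozenset(r.term for r in self.results if r.significant)

    def metadata(self) -> dict:
        return {
            "method": self.method,
            "alpha": self.alpha,
            "universe_size": self.universe_size,
            "n_query": self.n_query,
            "n_query_in_universe": self.n_query_in_universe,
            "n_query_dropped": self.n_query_dropped,
            "n_tested": self.n_tested,
            "n_significant": self.n_significant,
            "pct_significant": self.pct_significant,
        }


def make_contingency(esnpo: Esnpo, query: Iterable[str], term: str) -> ContingencyCounts:
    """Count the (N, M, n, m) quadruple for one term.

    Query SNPs outside the build's universe are excluded from M (they
    carry no annotation and cannot contribute to any term).
    """
    index = esnpo.term_index
    if term not in index:
        raise KeyError(f"term {term} has no SNP associations in this build")
    universe = esnpo.universe
    query_in = frozenset(query) & universe
    term_snps = index[term]
    return ContingencyCounts(
        N=len(universe),
        M=len(query_in),
        n=len(term_snps),
        m=len(query_in & term_snps),
    )


def _log_binom(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_pvalue(c: ContingencyCounts) -> float:
    """Upper-tail hypergeometric probability P(X >= m), in log space.

    Returns exactly 1.0 when m is at the lower edge of the support
    (in particular whenever m = 0).
    """
    N, M, n, m = c.N, c.M, c.n, c.m
    if m <= max(0, n + M - N):
        return 1.0
    k = np.arange(m, min(M, n) + 1, dtype=float)
    log_terms = _log_binom(M, k) + _log_binom(N - M, n - k) - _log_binom(N, np.array(n, dtype=float))
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def _canon_method(method: str) -> str:
    method = _ALIASES.get(method, _ALIASES.get(method.lower(), method))
    if method not in ADJUSTMENT_METHODS:
        raise ValueError(
            f"unknown adjustment method {method!r}; expected one of {ADJUSTMENT_METHODS}"
        )
    return method


def adjust_pvalues(ps: Sequence[float], method: str = "BH") -> np.ndarray:
    """Adjust a vector of p-values for multiple testing.

    Output is aligned with the input order and clipped to [p, 1].  The
    step procedures follow the standard definitions: holm is step-down
    with factors (k-i+1); hochberg is the step-up mirror; hommel is the
    closed-testing procedure with Simes local tests (computed with the
    usual O(k^2) recursion); BH is step-up with factors k/i; BY is BH
    inflated by the harmonic sum; "none" is the identity.
    """
    method = _canon_method(method)
    p = np.asarray(ps, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-D vector of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    if method == "none" or k == 1:
        return np.minimum(p.copy(), 1.0)

    order = np.argsort(p, kind="stable")
    ranked = p[order]
    inverse = np.empty(k, dtype=int)
    inverse[order] = np.arange(k)

    if method == "bonferroni":
        return np.minimum(k * p, 1.0)
    if method == "holm":
        adj = np.maximum.accumulate(np.arange(k, 0, -1) * ranked)
    elif method == "hochberg":
        adj = np.minimum.accumulate((np.arange(k, 0, -1) * ranked)[::-1])[::-1]
    elif method == "BH":
        factors = k / np.arange(1, k + 1)
        adj = np.minimum.accumulate((factors * ranked)[::-1])[::-1]
    elif method == "BY":
        c_k = np.sum(1.0 / np.arange(1, k + 1))
        factors = c_k * k / np.arange(1, k + 1)
        adj = np.minimum.accumulate((factors * ranked)[::-1])[::-1]
    elif method == "hommel":
        adj = _hommel(ranked)
    else:  # pragma: no cover - exhausted above
        raise AssertionError(method)
    adj = np.minimum(adj, 1.0)
    adj = np.maximum(adj, ranked)
    return adj[inverse]


def _hommel(ranked: np.ndarray) -> np.ndarray:
    """Hommel adjustment on an ascending-sorted vector (R p.adjust recursion)."""
    n = ranked.size
    i = np.arange(1, n + 1)
    q = np.full(n, np.min(n * ranked / i))
    pa = q.copy()
    for m in range(n - 1, 1, -1):
        i1 = np.arange(n - m + 1)          # 0-based indices 0 .. n-m
        i2 = np.arange(n - m + 1, n)       # 0-based indices n-m+1 .. n-1
        q1 = np.min(m * ranked[i2] / np.arange(2, m + 1))
        q[i1] = np.minimum(m * ranked[i1], q1)
        q[i2] = q[n - m]
        pa = np.maximum(pa, q)
    return np.maximum(pa, ranked)


def run_enrichment(
    esnpo: Esnpo,
    query: Iterable[str],
    method: str = "BH",
    alpha: float = 0.01,
    *,
    test_all_terms: bool = False,
    graph=None,
) -> EnrichmentRun:
    """Test the query SNP set against every touched term of a build.

    The tested family is the set of terms with at least one query SNP
    (m >= 1); set ``test_all_terms`` to widen it to every term in the
    build.  The adjustment is applied over that family; results are
    sorted by ascending p with the term id as a deterministic tie-break.
    ``graph`` (optional OntologyGraph) only supplies human-readable term
    names for the report.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    method = _canon_method(method)
    if len(esnpo) == 0:
        raise ValueError("cannot run enrichment on an empty build")
    query = list(dict.fromkeys(query))
    universe = esnpo.universe
    query_in = frozenset(query) & universe
    if not query_in:
        raise ValueError("query disjoint from eSNPO universe")
    dropped = frozenset(query) - universe

    index = esnpo.term_index
    M = len(query_in)
    N = len(universe)
    tested_terms = sorted(
        t for t, snps in index.items() if test_all_terms or (query_in & snps)
    )
    counts = []
    for term in tested_terms:
        snps = index[term]
        counts.append(ContingencyCounts(N=N, M=M, n=len(snps), m=len(query_in & snps)))
    raw = [hypergeom_pvalue(c) for c in counts]
    adjusted = adjust_pvalues(raw, method) if raw else np.array([])

    term_ns = {a.term: a.namespace for a in esnpo.associations}
    results = []
    for term, c, p, p_adj in zip(tested_terms, counts, raw, adjusted):
        query_genes: set[str] = set()
        for snp in query_in & index[term]:
            assoc = esnpo.get(snp, term)
            if assoc is not None:
                query_genes |= assoc.genes
        results.append(
            EnrichmentResult(
                term=term,
                namespace=term_ns[term],
                counts=c,
                p=float(p),
                p_adj=float(p_adj),
                significant=bool(p_adj < alpha),
                name=graph.name(term) if graph is not None else "",
                query_genes=frozenset(query_genes),
            )
        )
    results.sort(key=lambda r: (r.p, r.term))
    return EnrichmentRun(
        results=results,
        method=method,
        alpha=alpha,
        universe_size=N,
        n_query=len(query),
        n_query_in_universe=M,
        n_query_dropped=len(dropped),
        n_tested=len(results),
        n_significant=sum(r.significant for r in results),
        dropped_snps=dropped,
    )
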