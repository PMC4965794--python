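"""Comparison of significant term sets between two enrichment runs.

Used to contrast the eQTL-based and position-based analyses: how many
terms each flags at a given adjusted-p threshold, how many are shared,
and how the shared/exclusive sets break down by GO namespace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

from .enrichment import EnrichmentResult

__all__ = ["ComparisonReport", "compare_runs"]


def _ns_counts(terms: set[str], namespaces: dict[str, str]) -> dict[str, int]:
    counts = {"BP": 0, "CC": 0, "MF": 0}
    for t in terms:
        counts[namespaces[t]] += 1
    return counts


@dataclass(frozen=True)
class ComparisonReport:
    """Shared and exclusive significant terms of two runs, by namespace."""

    n_sig_a: int
    n_sig_b: int
    common: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]
    ns_common: tuple[tuple[str, int], ...]
    ns_only_a: tuple[tuple[str, int], ...]
    ns_only_b: tuple[tuple[str, int], ...]
    n_tested_a: int
    n_tested_b: int
    pct_sig_a: float
    pct_sig_b: float
    alpha: float

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_tested_a": self.n_tested_a,
            "n_tested_b": self.n_tested_b,
            "n_sig_a": self.n_sig_a,
            "n_sig_b": self.n_sig_b,
            "pct_sig_a": self.pct_sig_a,
            "pct_sig_b": self.pct_sig_b,
            "n_common": len(self.common),
            "common": sorted(self.common),
            "only_a": sorted(self.only_a),
            "only_b": sorted(self.only_b),
            "ns_common": dict(self.ns_common),
            "ns_only_a": dict(self.ns_only_a),
            "ns_only_b": dict(self.ns_only_b),
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2, sort_keys=True) + "\n"

    def to_markdown(self) -> str:
        d = self.as_dict()
        lines = [
            "# Enrichment run comparison",
            "",
            f"Significance threshold: adjusted p < {self.alpha}",
            "",
            "| run | terms tested | significant | % significant |",
            "|-----|-------------:|------------:|--------------:|",
            f"| A | {self.n_tested_a} | {self.n_sig_a} | {self.pct_sig_a} |",
            f"| B | {self.n_tested_b} | {self.n_sig_b} | {self.pct_sig_b} |",
            "",
            f"Terms in common: {len(self.common)} "
            f"(BP {d['ns_common']['BP']}, CC {d['ns_common']['CC']}, MF {d['ns_common']['MF']})",
            f"Only in A: {len(self.only_a)} "
            f"(BP {d['ns_only_a']['BP']}, CC {d['ns_only_a']['CC']}, MF {d['ns_only_a']['MF']})",
            f"Only in B: {len(self.only_b)} "
            f"(BP {d['ns_only_b']['BP']}, CC {d['ns_only_b']['CC']}, MF {d['ns_only_b']['MF']})",
            "",
        ]
        return "\n".join(lines)


def compare_runs(
    a: Sequence[EnrichmentResult],
    b: Sequence[EnrichmentResult],
    alpha: float = 0.01,
) -> ComparisonReport:
    """Intersect the significant term sets of two runs at threshold alpha.

    Significance is recomputed as adjusted p < alpha on each run, so a
    report written at one threshold can be compared at another.
    Comparison is by term identity; namespace labels must be present on
    both runs.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    namespaces = {r.term: r.namespace for r in list(a) + list(b)}
    sig_a = {r.term for r in a if r.p_adj < alpha}
    sig_b = {r.term for r in b if r.p_adj < alpha}
    common = sig_a & sig_b
    only_a = sig_a - sig_b
    only_b = sig_b - sig_a

    def pct(n_sig: int, n_tested: int) -> float:
        return round(100.0 * n_sig / n_tested, 1) if n_tested else 0.0

    return ComparisonReport(
        n_sig_a=len(sig_a),
        n_sig_b=len(sig_b),
        common=frozenset(common),
        only_a=frozenset(only_a),
        only_b=frozenset(only_b),
        ns_common=tuple(sorted(_ns_counts(common, namespaces).items())),
        ns_only_a=tuple(sorted(_ns_counts(only_a, namespaces).items())),
        ns_only_b=tuple(sorted(_ns_counts(only_b, namespaces).items())),
        n_tested_a=len(a),
        n_tested_b=len(b),
        pct_sig_a=pct(len(sig_a), len(a)),
        pct_sig_b=pct(len(sig_b), len(b)),
        alpha=alpha,
    )
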