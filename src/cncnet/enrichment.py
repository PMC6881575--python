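"""Term (GO/KEGG-style) over-representation of DE gene sets.

Flat-set testing: for a term with K members in a universe of N genes, of
which n are differentially expressed and k of those fall in the term, the
p-value is the hypergeometric upper tail P(X >= k) (equivalently one-sided
Fisher), or the conservative EASE variant that discounts one overlapping
gene.  The display rule keeps the 10 smallest p-values among terms with
p < p_max (all of them if fewer than 10 qualify).  DAG-aware decorrelation
(topGO elim/weight) is deliberately not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .errors import DomainError

METHODS = ("hypergeom", "fisher", "ease")


def _check_counts(k: int, K: int, n: int, N: int):
    if N <= 0:
        raise DomainError("empty universe")
    if not (0 <= K <= N and 0 <= n <= N):
        raise DomainError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise DomainError(f"inconsistent counts: k={k}, K={K}, n={n}")


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    _check_counts(k, K, n, N)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_pvalue(k: int, K: int, n: int, N: int) -> float:
    """One-sided (greater) Fisher exact p of the 2x2 table; identical to the
    hypergeometric upper tail."""
    _check_counts(k, K, n, N)
    table = [[k, n - k], [K - k, N - K - n + k]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def ease_pvalue(k: int, K: int, n: int, N: int) -> float:
    """EASE score: hypergeometric upper tail after removing one overlap gene."""
    _check_counts(k, K, n, N)
    return hypergeom_pvalue(max(k - 1, 0), K, n, N)


_PVALUE = {"hypergeom": hypergeom_pvalue, "fisher": fisher_pvalue,
           "ease": ease_pvalue}


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float
    fold_enrichment: float
    genes: tuple[str, ...]  # DE genes in the term


def enrich_terms(de_genes: Iterable[str], term_table: Mapping[str, Sequence[str]],
                 universe: Iterable[str], method: str = "hypergeom",
                 p_max: float = 0.05, top: int = 10,
                 term_names: Mapping[str, str] | None = None
                 ) -> list[EnrichmentResult]:
    """Over-representation of ``de_genes`` in each term.

    ``term_table`` maps term_id -> gene ids.  BH q is computed across all
    tested terms; the returned ranking filters on raw p (< p_max), sorts by
    ascending p with term_id as tie-break, and truncates to ``top``.
    """
    if method not in METHODS:
        raise DomainError(f"unknown method {method!r}")
    universe = set(universe)
    if not universe:
        raise DomainError("empty universe")
    de = set(de_genes)
    outside = de - universe
    if outside:
        warnings.warn(f"{len(outside)} DE genes outside universe dropped",
                      stacklevel=2)
        de &= universe
    N = len(universe)
    n = len(de)
    names = term_names or {}

    rows = []
    for term_id in sorted(term_table):
        members = set(term_table[term_id]) & universe
        K = len(members)
        if K == 0:
            continue
        overlap = sorted(de & members)
        k = len(overlap)
        p = _PVALUE[method](k, K, n, N)
        fe = (k / n) / (K / N) if n else 0.0
        rows.append((term_id, k, K, p, fe, tuple(overlap)))
    if not rows:
        return []
    qs = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(term_id, names.get(term_id, term_id), k, K, n, N,
                         float(p), float(q), float(fe), genes)
        for (term_id, k, K, p, fe, genes), q in zip(rows, qs)
    ]
    results = [r for r in results if r.p < p_max]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results[:top]


def pathway_gene_network(results: Sequence[EnrichmentResult],
                         de_genes: Iterable[str]) -> list[tuple[str, str]]:
    """Bipartite (term, gene) edges: one edge per DE gene in each significant
    term, sorted lexicographically."""
    de = set(de_genes)
    edges = sorted(
        (r.term_id, g) for r in results for g in r.genes if g in de
    )
    return edges
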