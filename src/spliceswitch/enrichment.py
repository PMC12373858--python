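"""Hypergeometric over-representation machinery shared by pathway enrichment,
domain-centric GO-style analysis and cancer-gene-set crossover."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ValidationError


@dataclass
class EnrichmentResult:
    term: str
    k: int  # hits in query
    K: int  # term size in universe
    n: int  # query size
    N: int  # universe size
    p: float
    q: float | None = None


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, K marked,
    n drawn). Delegated to scipy's survival function (stable log-space
    internals)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValidationError(f"invalid hypergeometric parameters k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min over j >= i of p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_fdr expects a 1-D p-value vector")
    if len(p) == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values outside [0,1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def ora(
    query: set[str],
    gene_sets: list[tuple[str, set[str]]],
    universe: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation analysis: one hypergeometric test per gene set with
    at least one hit; BH across tested sets. Sets are intersected with the
    universe first and the query must be contained in the universe."""
    if not query <= universe:
        raise ValidationError("query genes missing from universe")
    N, n = len(universe), len(query)
    results: list[EnrichmentResult] = []
    for name, members in gene_sets:
        inter = members & universe
        k = len(query & inter)
        if k == 0 or not inter:
            continue
        p = hypergeom_upper(k, len(inter), n, N)
        results.append(EnrichmentResult(name, k, len(inter), n, N, p))
    if results:
        qvals = bh_fdr([r.p for r in results])
        for r, q in zip(results, qvals):
            r.q = float(q)
    results.sort(key=lambda r: (r.p, r.term))
    return results


def dcgo_style_enrich(
    impacted_domains: set[str],
    domain_to_terms: dict[str, set[str]],
    domain_universe: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Domain-centric enrichment: identical statistics to :func:`ora` with
    protein domains as the sampling unit and GO-style terms as the sets."""
    term_sets: dict[str, set[str]] = {}
    for dom, terms in domain_to_terms.items():
        for t in terms:
            term_sets.setdefault(t, set()).add(dom)
    return ora(
        impacted_domains & domain_universe,
        sorted((name, doms) for name, doms in term_sets.items()),
        domain_universe,
        alpha,
    )


def crossover(
    dei_genes: set[str],
    curated_sets: list[tuple[str, set[str]]],
    universe: set[str],
) -> list[dict]:
    """Overlap of isoform-level altered genes with curated cancer gene sets:
    per set, the overlap count, the fraction of the set covered, and a
    hypergeometric p-value against the expression universe."""
    rows = []
    N, n = len(universe), len(dei_genes & universe)
    for name, members in curated_sets:
        inter = members & universe
        k = len(dei_genes & inter)
        frac = k / len(members) if members else 0.0
        p = hypergeom_upper(k, len(inter), n, N) if inter else 1.0
        rows.append(
            {"set": name, "set_size": len(members), "overlap": k,
             "overlap_fraction": frac, "p": p}
        )
    return rows
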