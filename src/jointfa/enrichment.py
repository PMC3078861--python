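"""Hypergeometric over-representation of genomic miRNA clusters and generic
term sets, with Bonferroni or Benjamini–Hochberg correction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .io import GenomicCluster, TermMap

BONFERRONI = "bonferroni"
BENJAMINI_HOCHBERG = "benjamini_hochberg"
METHODS = (BONFERRONI, BENJAMINI_HOCHBERG)


@dataclass
class EnrichmentResult:
    unit: str
    N: int          # background size
    K: int          # background members of the unit
    n: int          # number selected
    k: int          # selected members of the unit
    p_raw: float
    p_adj: float
    method: str


def _check_bounds(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"invalid hypergeometric parameters N={N}, K={K}, n={n}, k={k}"
        )


def _log_binom(n: int, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(N: int, K: int, n: int, k: int, tail: str = "upper") -> float:
    """Exact hypergeometric tail probability by log-space summation.

    ``upper`` gives P(X ≥ k), ``lower`` gives P(X < k), for k successes
    among n draws without replacement from N items of which K are successes.
    """
    _check_bounds(N, K, n, k)
    if tail not in ("upper", "lower"):
        raise ValueError(f"unknown tail {tail!r}")
    lo = max(0, n - (N - K))
    hi = min(K, n)
    if tail == "upper":
        if k <= lo:
            return 1.0  # tail covers the entire support
        support = np.arange(k, hi + 1)
    else:
        support = np.arange(lo, k)
        if support.size == 0:
            return 0.0
    logp = (
        _log_binom(K, support)
        + _log_binom(N - K, n - support)
        - _log_binom(N, n)
    )
    return float(min(1.0, np.exp(logsumexp(logp))))


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X ≥ k): probability a random selection does at least as well."""
    return hypergeom_tail(N, K, n, k, tail="upper")


def bonferroni(p: float, hypothesis_count: int) -> float:
    if hypothesis_count < 1:
        raise ValueError("hypothesis count must be at least 1")
    return min(1.0, p * hypothesis_count)


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """Step-up BH adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return np.minimum(adj, 1.0).tolist()


def _adjust(results: list[EnrichmentResult], method: str) -> list[EnrichmentResult]:
    if method == BONFERRONI:
        m = len(results)
        for r in results:
            r.p_adj = bonferroni(r.p_raw, m)
            r.method = BONFERRONI
    elif method == BENJAMINI_HOCHBERG:
        for r, adj in zip(results, benjamini_hochberg([r.p_raw for r in results])):
            r.p_adj = adj
            r.method = BENJAMINI_HOCHBERG
    else:
        raise ValueError(f"unknown correction method {method!r}")
    return results


def cluster_enrichment(
    selected: set[str],
    clusters: list[GenomicCluster],
    background: set[str],
    method: str = BONFERRONI,
) -> list[EnrichmentResult]:
    """Upper-tail enrichment of each genomic cluster among the selected
    miRNAs, plus one result for the union of all clusters.

    The background is the set of detected miRNAs; cluster membership is
    intersected with it.  The correction count equals the number of results
    emitted.
    """
    selected, background = set(selected), set(background)
    offenders = sorted(selected - background)
    if offenders:
        raise ValueError(f"selected ids not in background: {offenders}")
    N, n = len(background), len(selected)
    units: list[tuple[str, set[str]]] = [
        (c.cluster_name, set(c.member_ids)) for c in clusters
    ]
    if clusters:
        union = set().union(*(set(c.member_ids) for c in clusters))
        units.append(("all_clusters", union))
    results = []
    for name, members in units:
        members_bg = members & background
        K = len(members_bg)
        k = len(selected & members_bg)
        results.append(
            EnrichmentResult(
                unit=name, N=N, K=K, n=n, k=k,
                p_raw=hypergeom_upper_tail(N, K, n, k),
                p_adj=np.nan, method=method,
            )
        )
    return _adjust(results, method)


def term_overrepresentation(
    selected: set[str],
    terms: TermMap,
    background: set[str],
    method: str = BENJAMINI_HOCHBERG,
) -> list[EnrichmentResult]:
    """Generic gene-set over-representation, sorted by adjusted p."""
    selected, background = set(selected), set(background)
    offenders = sorted(selected - background)
    if offenders:
        raise ValueError(f"selected ids not in background: {offenders}")
    N, n = len(background), len(selected)
    results = []
    for term, genes in terms.terms.items():
        genes_bg = genes & background
        K = len(genes_bg)
        k = len(selected & genes_bg)
        results.append(
            EnrichmentResult(
                unit=term, N=N, K=K, n=n, k=k,
                p_raw=hypergeom_upper_tail(N, K, n, k),
                p_adj=np.nan, method=method,
            )
        )
    return sorted(_adjust(results, method), key=lambda r: (r.p_adj, r.p_raw, r.unit))


def indirect_annotation(
    selected_mirnas: list[str],
    target_map: dict[str, set[str]],
    terms: TermMap,
) -> list[tuple[str, str, tuple[str, ...]]]:
    """Relational join miRNA → validated target gene → terms (no statistics).

    miRNAs without any mapped target appear once with an empty target field.
    """
    rows: list[tuple[str, str, tuple[str, ...]]] = []
    for mir in selected_mirnas:
        targets = sorted(target_map.get(mir, ()))
        if not targets:
            rows.append((mir, "", ()))
            continue
        for gene in targets:
            rows.append((mir, gene, tuple(terms.terms_for_gene(gene))))
    return rows
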