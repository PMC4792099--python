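"""Hypergeometric phenotype enrichment of patient cliques.

Each clique is a sample of size n drawn from the N annotated patients of the
cohort; a term carried by K cohort patients and k clique members is scored by
the upper hypergeometric tail P(X >= k).  Per clique, p-values are Bonferroni
corrected over the m terms actually carried by at least one member, and a
result is kept only if it passes the three selection thresholds (significant
adjusted p, k >= 3 annotated members, and >= 50% of the clique annotated).
Surviving terms are pruned of ontological redundancy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import hypergeom

from .clique_analysis import CliqueLocus
from .hpo_ontology import PhenotypeOntology, prune_redundant


@dataclass(frozen=True)
class EnrichmentResult:
    """One clique x term enrichment outcome (k of n vs K of N)."""

    clique_ref: int
    term_id: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_adj: float
    n_tests: int


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    k successes in a sample of n, drawn without replacement from a population
    of N containing K successes.
    """
    if not 0 <= k <= min(n, K):
        raise ValueError(f"require 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"require n <= N and K <= N; got n={n}, K={K}, N={N}")
    if N == 0:
        raise ValueError("empty population")
    return float(min(1.0, max(0.0, hypergeom.sf(k - 1, N, K, n))))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value min(1, p*m)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of [0, 1]: {p}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return min(1.0, p * m)


def cohort_term_counts(
    annotations: Mapping[str, frozenset[str]]
) -> Counter[str]:
    """K per term: number of cohort patients whose (closed) set carries it."""
    counts: Counter[str] = Counter()
    for terms in annotations.values():
        counts.update(terms)
    return counts


def clique_enrichment(
    clique: CliqueLocus,
    annotations: Mapping[str, frozenset[str]],
    term_counts: Mapping[str, int],
    N: int,
    ontology: PhenotypeOntology,
    clique_ref: int = 0,
    alpha: float = 0.05,
    min_annotated: int = 3,
    min_fraction: float = 0.5,
    threshold_adjusted: bool = True,
    m_override: int | None = None,
) -> list[EnrichmentResult]:
    """Score every term carried by >=1 member; keep gated, pruned survivors.

    ``m_override`` replaces the per-clique Bonferroni family size with a
    global one (family = all tests of the run).  ``threshold_adjusted``
    selects whether the significance gate uses the adjusted (default,
    conservative) or the raw p-value.
    """
    member_sets = {}
    for member in sorted(clique.members):
        if member not in annotations:
            raise KeyError(f"clique member {member!r} missing from annotations")
        member_sets[member] = annotations[member]
    n = clique.size
    tested = sorted(set().union(*member_sets.values()))
    m = m_override if m_override is not None else len(tested)

    gated: list[EnrichmentResult] = []
    for term in tested:
        k = sum(1 for terms in member_sets.values() if term in terms)
        K = term_counts[term]
        p_raw = hypergeom_tail(k, n, K, N)
        p_adj = bonferroni(p_raw, m)
        p_gate = p_adj if threshold_adjusted else p_raw
        if p_gate < alpha and k >= min_annotated and k / n >= min_fraction:
            gated.append(
                EnrichmentResult(
                    clique_ref=clique_ref,
                    term_id=term,
                    k=k,
                    n=n,
                    K=K,
                    N=N,
                    p_raw=p_raw,
                    p_adj=p_adj,
                    n_tests=m,
                )
            )

    kept_terms = {
        term
        for term, _ in prune_redundant(
            ontology, [(r.term_id, r.p_raw) for r in gated]
        )
    }
    return [r for r in gated if r.term_id in kept_terms]
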