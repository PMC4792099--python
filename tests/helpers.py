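"""Independent oracles and small builders shared across the test suite.

Everything here is deliberately naive (enumeration, brute force, rational
arithmetic) and independent of the library code paths it checks.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

from pelnet.cohort_io import CnvRecord, GenomicInterval, PatientRecord


def hypergeom_tail_enum(k: int, n: int, K: int, N: int) -> Fraction:
    """Exact upper tail P(X >= k) by summing the rational pmf."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(n, K) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc


def bh_adjust_stepup(ps):
    """Step-up BH by the textbook recipe, independent of statsmodels."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adjusted = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, ps[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def brute_force_edges(patients):
    """All-pairs, all-CNV-pairs overlap check (the quadratic oracle)."""
    edges = set()
    for a, b in combinations(patients, 2):
        for ca in a.cnvs:
            for cb in b.cnvs:
                if (
                    ca.cnv_class == cb.cnv_class
                    and ca.interval.chrom == cb.interval.chrom
                    and ca.interval.start < cb.interval.end
                    and cb.interval.start < ca.interval.end
                ):
                    edges.add(frozenset({a.patient_id, b.patient_id}))
    return edges


def brute_force_maximal_cliques(nodes, edges, min_size):
    """Maximal cliques by enumerating all 2^n node subsets."""
    nodes = list(nodes)
    edge_set = {frozenset(e) for e in edges}

    def is_clique(subset):
        return all(
            frozenset({a, b}) in edge_set for a, b in combinations(subset, 2)
        )

    cliques = [
        frozenset(subset)
        for r in range(2, len(nodes) + 1)
        for subset in combinations(nodes, r)
        if is_clique(subset)
    ]
    maximal = {
        c
        for c in cliques
        if not any(c < other for other in cliques)
    }
    return {c for c in maximal if len(c) >= min_size}


def patient(patient_id, *cnv_specs, phenotypes=("HP:0000001",)):
    """Build a PatientRecord from (chrom, start, end, class) tuples."""
    cnvs = tuple(
        CnvRecord(
            patient_id,
            GenomicInterval(chrom, start, end),
            cls,
            inheritance,
        )
        for chrom, start, end, cls, *rest in cnv_specs
        for inheritance in [rest[0] if rest else "unknown"]
    )
    return PatientRecord(patient_id, cnvs, frozenset(phenotypes))
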