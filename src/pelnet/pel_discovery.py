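"""From enriched cliques to phenotypically enriched loci (PELs).

Each enriched clique term becomes a candidate locus-phenotype association.
The locus is tested against the healthy-population control set with a
one-sided Fisher exact test (cases enriched) on the 2x2 table

    [[k_case, K_case - k_case], [m_ctrl, N_ctrl - m_ctrl]]

whose one-sided p equals the hypergeometric upper tail of k_case given the
margins.  Benjamini-Hochberg is applied jointly across all candidate
associations of a run, and penetrance is estimated with a Cooper-style
frequency-ratio estimator scaled by a baseline prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import fisher_exact as _scipy_fisher
from statsmodels.stats.multitest import multipletests

from .clique_analysis import CliqueLocus
from .cohort_io import ControlVariant, GenomicInterval, SyndromeRecord, \
    control_population_size
from .phenotype_enrichment import EnrichmentResult, hypergeom_tail

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PelAssociation:
    """A locus x phenotype association with its case-control statistics."""

    pel_id: str
    locus: GenomicInterval
    cnv_class: str
    term_id: str
    term_name: str
    k_case: int
    n_clique: int
    K_case: int
    N_case: int
    m_ctrl: int
    N_ctrl: int
    p_enrich: float
    p_fisher_raw: float
    p_fisher_bh: float
    penetrance_pct: float
    significant: bool


def count_control_carriers(
    locus: GenomicInterval,
    cnv_class: str,
    controls: Sequence[ControlVariant],
) -> int:
    """Distinct control samples with >=1 same-class variant overlapping locus.

    Records without a sample id each count as their own sample.
    """
    carriers: set = set()
    for idx, variant in enumerate(controls):
        if variant.cnv_class != cnv_class:
            continue
        if variant.interval.overlaps(locus):
            carriers.add(variant.sample_id if variant.sample_id is not None else idx)
    return len(carriers)


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (cases-enriched) Fisher exact p for [[a, b], [c, d]].

    Computed as the hypergeometric upper tail of ``a`` given the table
    margins -- the exact identity underlying the one-sided Fisher test.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    total = a + b + c + d
    if total == 0:
        raise ValueError("empty contingency table")
    return hypergeom_tail(a, a + b, a + c, total)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided alternative, for configurations that request it."""
    return float(_scipy_fisher([[a, b], [c, d]], alternative="two-sided")[1])


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    if len(p_values) == 0:
        return []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {p}")
    return list(multipletests(p_values, method="fdr_bh")[1])


def penetrance(
    k_case: int,
    N_case: int,
    m_ctrl: int,
    N_ctrl: int,
    prevalence: float = 0.05,
) -> float:
    """Cooper-style penetrance estimate, in percent.

    With case carrier frequency f_case = k_case/N_case, control frequency
    f_ctrl = m_ctrl/N_ctrl and baseline prevalence pi:

        100 * f_case*pi / (f_case*pi + f_ctrl*(1 - pi))

    When no control carries the locus the estimate is complete (100%); when
    neither population carries it, 0 by convention.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    if N_case <= 0 or N_ctrl <= 0:
        raise ValueError("population sizes must be positive")
    f_case = k_case / N_case
    f_ctrl = m_ctrl / N_ctrl
    if f_case == 0.0 and f_ctrl == 0.0:
        return 0.0
    if f_case == 0.0:
        return 0.0
    return 100.0 * (f_case * prevalence) / (
        f_case * prevalence + f_ctrl * (1.0 - prevalence)
    )


def associate_pels(
    cliques: Sequence[CliqueLocus],
    enrichments: Sequence[EnrichmentResult],
    controls: Sequence[ControlVariant],
    *,
    n_ctrl: int | None = None,
    prevalence: float = 0.05,
    alpha: float = 0.05,
    two_sided: bool = False,
    term_names: Mapping[str, str] | None = None,
) -> list[PelAssociation]:
    """Case-control test and penetrance for every enriched clique term.

    BH is applied jointly across all candidate associations; associations
    with adjusted p below ``alpha`` are flagged significant (pathogenic).
    PEL ids are assigned by ascending adjusted p, then genomic order.
    """
    N_ctrl = control_population_size(controls, override=n_ctrl)
    term_names = term_names or {}

    candidates = []
    raw_ps = []
    for enr in enrichments:
        clique = cliques[enr.clique_ref]
        m_ctrl = count_control_carriers(clique.locus, clique.cnv_class, controls)
        a, b = enr.k, enr.K - enr.k
        c, d = m_ctrl, N_ctrl - m_ctrl
        if d < 0:
            raise ValueError(
                f"control carriers ({m_ctrl}) exceed control population "
                f"({N_ctrl}); pass an explicit n_ctrl"
            )
        p_raw = (
            fisher_exact_two_sided(a, b, c, d)
            if two_sided
            else fisher_exact_greater(a, b, c, d)
        )
        candidates.append((enr, clique, m_ctrl, p_raw))
        raw_ps.append(p_raw)

    adjusted = bh_adjust(raw_ps)
    ordered = sorted(
        zip(candidates, adjusted),
        key=lambda item: (
            item[1],
            item[0][1].locus.chrom,
            item[0][1].locus.start,
            item[0][1].locus.end,
            item[0][1].cnv_class,
            item[0][0].term_id,
        ),
    )
    associations = []
    for rank, ((enr, clique, m_ctrl, p_raw), p_bh) in enumerate(ordered, start=1):
        associations.append(
            PelAssociation(
                pel_id=f"PEL_{rank}",
                locus=clique.locus,
                cnv_class=clique.cnv_class,
                term_id=enr.term_id,
                term_name=term_names.get(enr.term_id, enr.term_id),
                k_case=enr.k,
                n_clique=enr.n,
                K_case=enr.K,
                N_case=enr.N,
                m_ctrl=m_ctrl,
                N_ctrl=N_ctrl,
                p_enrich=enr.p_adj,
                p_fisher_raw=p_raw,
                p_fisher_bh=float(p_bh),
                penetrance_pct=penetrance(
                    enr.k, enr.N, m_ctrl, N_ctrl, prevalence
                ),
                significant=bool(p_bh < alpha),
            )
        )
    n_sig = sum(a.significant for a in associations)
    log.info(
        "%d candidate associations, %d significant after BH (alpha=%g)",
        len(associations), n_sig, alpha,
    )
    return associations


def syndrome_overlap(
    associations: Sequence[PelAssociation],
    syndromes: Sequence[SyndromeRecord],
) -> dict[str, list[str]]:
    """Match each PEL to known syndromes (>=1 bp overlap, same mutation type).

    PELs mapping to an empty list are candidate novel loci.
    """
    matches: dict[str, list[str]] = {}
    for assoc in associations:
        hits = [
            s.name
            for s in syndromes
            if s.mutation_type == assoc.cnv_class
            and s.locus.overlaps(assoc.locus)
        ]
        matches[assoc.pel_id] = sorted(set(hits))
    return matches
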