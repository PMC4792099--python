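"""End-to-end discovery pipeline and its configuration.

``run_discovery`` chains annotation propagation, network construction,
clique mining with the common-locus filter, per-clique phenotype enrichment
and the case-control association step.  It is shared by the command-line
front end and the randomization harness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

from .clique_analysis import CliqueLocus, find_clique_loci
from .cohort_io import ControlVariant, PatientRecord
from .hpo_ontology import PhenotypeOntology, propagate_annotations
from .patient_network import PatientGraph, build_patient_graph
from .pel_discovery import PelAssociation, associate_pels
from .phenotype_enrichment import (
    EnrichmentResult,
    clique_enrichment,
    cohort_term_counts,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and correction choices of one discovery run.

    Defaults follow the method's stated selection rules: enrichment gate at
    adjusted p < 0.05 with at least three annotated members covering at
    least half the clique; association gate at BH-adjusted one-sided Fisher
    p < 0.05.
    """

    alpha_enrich: float = 0.05
    min_annotated: int = 3
    min_fraction: float = 0.5
    alpha_assoc: float = 0.05
    min_clique_size: int = 3
    propagate: bool = True
    enrich_threshold_adjusted: bool = True
    bonferroni_global: bool = False
    fisher_two_sided: bool = False
    prevalence: float = 0.05
    n_ctrl_override: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_enrich", "alpha_assoc", "min_fraction"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class DiscoveryResult:
    """Everything a discovery run produced, with its stage counts."""

    patients: list[PatientRecord]
    annotations: dict[str, frozenset[str]]
    graph: PatientGraph | None
    clique_loci: list[CliqueLocus]
    n_maximal_cliques: int
    n_rejected_cliques: int
    enrichments: list[EnrichmentResult]
    associations: list[PelAssociation]

    @property
    def significant(self) -> list[PelAssociation]:
        return [a for a in self.associations if a.significant]

    @property
    def significant_pel_loci(self) -> set:
        return {
            (a.locus.chrom, a.locus.start, a.locus.end, a.cnv_class)
            for a in self.significant
        }

    def counts(self) -> dict[str, int]:
        return {
            "n_patients": len(self.patients),
            "n_network_nodes": (
                self.graph.graph.number_of_nodes() if self.graph else 0
            ),
            "n_network_edges": (
                self.graph.graph.number_of_edges() if self.graph else 0
            ),
            "n_isolated_patients": (
                len(self.graph.isolated) if self.graph else len(self.patients)
            ),
            "n_maximal_cliques": self.n_maximal_cliques,
            "n_rejected_cliques": self.n_rejected_cliques,
            "n_clique_loci": len(self.clique_loci),
            "n_enriched_terms": len(self.enrichments),
            "n_candidate_associations": len(self.associations),
            "n_significant_associations": len(self.significant),
            "n_significant_pels": len(self.significant_pel_loci),
        }


def run_discovery(
    patients: Sequence[PatientRecord],
    controls: Sequence[ControlVariant],
    ontology: PhenotypeOntology,
    config: RunConfig = RunConfig(),
) -> DiscoveryResult:
    """Run the full network -> cliques -> enrichment -> association chain.

    A cohort whose CNVs never overlap yields an empty (association-free)
    result rather than an error; topology statistics, which do require a
    non-empty network, are computed separately by the callers that need
    them.
    """
    patients = list(patients)
    if config.propagate:
        annotations = propagate_annotations(ontology, patients)
    else:
        # raw annotation sets, still validated against the ontology
        propagate_annotations(ontology, patients)
        annotations = {p.patient_id: frozenset(p.phenotypes) for p in patients}
    term_counts = cohort_term_counts(annotations)
    N = len(patients)

    empty = DiscoveryResult(
        patients=patients,
        annotations=annotations,
        graph=None,
        clique_loci=[],
        n_maximal_cliques=0,
        n_rejected_cliques=0,
        enrichments=[],
        associations=[],
    )
    if len(patients) < 2:
        return empty
    graph = build_patient_graph(patients)
    empty.graph = graph
    if graph.graph.number_of_edges() == 0:
        return empty

    clique_loci, n_rejected = find_clique_loci(
        graph, patients, min_size=config.min_clique_size
    )
    from .clique_analysis import maximal_cliques  # count before filtering

    n_maximal = len(maximal_cliques(graph, min_size=config.min_clique_size))

    m_override = None
    if config.bonferroni_global:
        m_override = sum(
            len(set().union(*(annotations[m] for m in locus.members)))
            for locus in clique_loci
        ) or None
    enrichments: list[EnrichmentResult] = []
    for ref, locus in enumerate(clique_loci):
        enrichments.extend(
            clique_enrichment(
                locus,
                annotations,
                term_counts,
                N,
                ontology,
                clique_ref=ref,
                alpha=config.alpha_enrich,
                min_annotated=config.min_annotated,
                min_fraction=config.min_fraction,
                threshold_adjusted=config.enrich_threshold_adjusted,
                m_override=m_override,
            )
        )

    associations = associate_pels(
        clique_loci,
        enrichments,
        controls,
        n_ctrl=config.n_ctrl_override,
        prevalence=config.prevalence,
        alpha=config.alpha_assoc,
        two_sided=config.fisher_two_sided,
        term_names={t: ontology.name_of(t) for t in ontology.terms},
    )
    result = DiscoveryResult(
        patients=patients,
        annotations=annotations,
        graph=graph,
        clique_loci=clique_loci,
        n_maximal_cliques=n_maximal,
        n_rejected_cliques=n_rejected,
        enrichments=enrichments,
        associations=associations,
    )
    log.info("discovery funnel: %s", result.counts())
    return result
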