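"""Phenotype ontology handling: loading, annotation propagation, redundancy pruning.

The ontology is a DAG of terms linked by is_a (parent-child) relations, as in
the Human Phenotype Ontology.  Patients annotated with a specific term
implicitly carry every ancestor of that term, so annotation sets are closed
under the ancestor relation before any counting; this is what lets broad terms
accumulate patient counts at the ontological level where cliques agree.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

from .cohort_io import PatientRecord


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or unknown terms."""


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str
    parent_ids: frozenset[str]


class PhenotypeOntology:
    """A validated is_a DAG with memoized ancestor closure and term depths.

    Depth is the shortest distance to a root following is_a links upward;
    roots have depth 0.  Multiple parents (DAG, not tree) are supported.
    """

    def __init__(self, terms: Mapping[str, OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = dict(terms)
        for term in self.terms.values():
            for parent in term.parent_ids:
                if parent not in self.terms:
                    raise OntologyError(
                        f"term {term.term_id!r}: is_a target {parent!r} is not defined"
                    )
        graph = nx.DiGraph()  # edges child -> parent
        graph.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parent_ids:
                graph.add_edge(term.term_id, parent)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyError(
                f"is_a relation contains a cycle through {cycle[0][0]!r}"
            )
        self.roots: frozenset[str] = frozenset(
            t for t, term in self.terms.items() if not term.parent_ids
        )
        if self.terms and not self.roots:
            raise OntologyError("ontology has terms but no root")
        self._children: dict[str, set[str]] = {t: set() for t in self.terms}
        for term in self.terms.values():
            for parent in term.parent_ids:
                self._children[parent].add(term.term_id)
        # multi-source BFS downward from the roots
        self.depth: dict[str, int] = {r: 0 for r in self.roots}
        queue = deque(self.roots)
        while queue:
            node = queue.popleft()
            for child in self._children[node]:
                if child not in self.depth:
                    self.depth[child] = self.depth[node] + 1
                    queue.append(child)
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    @classmethod
    def from_parent_map(
        cls,
        parent_map: Mapping[str, Iterable[str]],
        names: Mapping[str, str] | None = None,
    ) -> "PhenotypeOntology":
        names = names or {}
        terms = {
            term_id: OntologyTerm(term_id, names.get(term_id, term_id),
                                  frozenset(parents))
            for term_id, parents in parent_map.items()
        }
        return cls(terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def name_of(self, term_id: str) -> str:
        return self.terms[term_id].name

    def depth_of(self, term_id: str) -> int:
        self._require(term_id)
        return self.depth[term_id]

    @property
    def leaves(self) -> frozenset[str]:
        return frozenset(t for t, ch in self._children.items() if not ch)

    def children(self, term_id: str) -> frozenset[str]:
        self._require(term_id)
        return frozenset(self._children[term_id])

    def _require(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise OntologyError(f"unknown term: {term_id!r}")

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All strict ancestors of ``term_id`` (the term itself excluded)."""
        self._require(term_id)
        cached = self._ancestor_cache.get(term_id)
        if cached is not None:
            return cached
        result: set[str] = set()
        for parent in self.terms[term_id].parent_ids:
            result.add(parent)
            result.update(self.ancestors(parent))
        frozen = frozenset(result)
        self._ancestor_cache[term_id] = frozen
        return frozen

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        return ancestor in self.ancestors(descendant)

    def closure(self, term_ids: Iterable[str]) -> frozenset[str]:
        """Terms plus all their ancestors."""
        result: set[str] = set()
        for term in term_ids:
            self._require(term)
            result.add(term)
            result.update(self.ancestors(term))
        return frozenset(result)


def read_obo(path) -> PhenotypeOntology:
    """Load an OBO flat file (id/name/is_a stanzas; obsolete terms skipped)."""
    graph = obonet.read_obo(path)
    # obonet materializes is_a targets that have no stanza as bare nodes
    undefined = [n for n, data in graph.nodes(data=True) if "name" not in data]
    if undefined:
        raise OntologyError(
            f"is_a target(s) not defined in {path}: {sorted(undefined)}"
        )
    terms = {}
    for node, data in graph.nodes(data=True):
        parents = frozenset(
            v for _, v, key in graph.out_edges(node, keys=True) if key == "is_a"
        )
        terms[node] = OntologyTerm(node, data["name"], parents)
    return PhenotypeOntology(terms)


def write_obo(ontology: PhenotypeOntology, path) -> None:
    """Serialize to OBO (round-trips through :func:`read_obo`)."""
    with open(path, "w") as handle:
        handle.write("format-version: 1.2\n")
        for term_id in sorted(ontology.terms):
            term = ontology.terms[term_id]
            handle.write(f"\n[Term]\nid: {term.term_id}\nname: {term.name}\n")
            for parent in sorted(term.parent_ids):
                handle.write(f"is_a: {parent} ! {ontology.name_of(parent)}\n")


def propagate_annotations(
    ontology: PhenotypeOntology, patients: Sequence[PatientRecord]
) -> dict[str, frozenset[str]]:
    """Close each patient's annotation set under the ancestor relation."""
    propagated: dict[str, frozenset[str]] = {}
    for patient in patients:
        for term in patient.phenotypes:
            if term not in ontology:
                raise OntologyError(
                    f"patient {patient.patient_id!r} annotated with unknown "
                    f"term {term!r}"
                )
        propagated[patient.patient_id] = ontology.closure(patient.phenotypes)
    return propagated


def prune_redundant(
    ontology: PhenotypeOntology,
    enriched: Sequence[tuple[str, float]],
) -> list[tuple[str, float]]:
    """Drop ontologically redundant enriched terms.

    For every ancestor-descendant pair among the input terms only the more
    significant (lower p) member survives; on ties the deeper (more specific)
    term wins, then the lexicographically smaller id.  Terms unrelated to all
    other input terms always survive.
    """
    for term, p in enriched:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of [0, 1] for {term!r}: {p}")
    key = {
        term: (p, -ontology.depth_of(term), term) for term, p in enriched
    }
    survivors: list[tuple[str, float]] = []
    for term, p in enriched:
        related = [
            other
            for other, _ in enriched
            if other != term
            and (
                ontology.is_ancestor(other, term)
                or ontology.is_ancestor(term, other)
            )
        ]
        if all(key[term] < key[other] for other in related):
            survivors.append((term, p))
    return survivors
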