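"""Genotype-based patient network: CNV-overlap edges and topology statistics.

Two patients are connected iff they each carry a CNV of the same class (gain
or loss) on the same chromosome sharing at least one base pair.  Every edge
records the supporting CNV pairs.  Patients whose CNVs overlap nobody else's
are not network nodes (they can never join a clique), but are reported.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .cohort_io import CnvRecord, PatientRecord

log = logging.getLogger(__name__)


def cnvs_overlap(a: CnvRecord, b: CnvRecord) -> bool:
    """True iff the two CNVs share >=1 bp and belong to the same class."""
    return a.cnv_class == b.cnv_class and a.interval.overlaps(b.interval)


@dataclass
class PatientGraph:
    """Patients as nodes; class-specific CNV-overlap edges with support.

    ``graph`` is an undirected networkx graph whose edge attribute
    ``support`` holds a frozenset of ``(cnv_u, cnv_v, cnv_class)`` triples,
    with ``cnv_u`` owned by the lexicographically smaller patient id.
    ``isolated`` lists input patients that ended up with no edge.
    """

    graph: nx.Graph
    isolated: tuple[str, ...] = ()

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.graph.edges)

    def edge_support(self, p: str, q: str):
        """Support triples for edge (p, q), oriented so cnv_a belongs to p."""
        triples = self.graph.edges[p, q]["support"]
        if p <= q:
            return frozenset(triples)
        return frozenset((b, a, cls) for a, b, cls in triples)


def build_patient_graph(patients: Sequence[PatientRecord]) -> PatientGraph:
    """Build the overlap network via a per-(class, chromosome) sweep.

    Equivalent to the brute-force all-pairs, all-CNV-pairs check but only
    touches CNV pairs that actually overlap.
    """
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to build a network")
    by_key: dict[tuple[str, str], list[CnvRecord]] = {}
    for patient in patients:
        for cnv in patient.cnvs:
            by_key.setdefault((cnv.cnv_class, cnv.interval.chrom), []).append(cnv)

    graph = nx.Graph()
    for (cls, _chrom), cnvs in by_key.items():
        cnvs.sort(key=lambda c: (c.interval.start, c.interval.end, c.patient_id))
        active: list[CnvRecord] = []
        for cnv in cnvs:
            active = [a for a in active if a.interval.end > cnv.interval.start]
            for other in active:
                if other.patient_id == cnv.patient_id:
                    continue  # a patient's own CNVs never create a self-edge
                p, q = sorted((other.patient_id, cnv.patient_id))
                first, second = (
                    (other, cnv) if other.patient_id == p else (cnv, other)
                )
                if graph.has_edge(p, q):
                    graph.edges[p, q]["support"].add((first, second, cls))
                else:
                    graph.add_edge(p, q, support={(first, second, cls)})
            active.append(cnv)

    isolated = tuple(
        sorted(p.patient_id for p in patients if p.patient_id not in graph)
    )
    for p, q in graph.edges:
        graph.edges[p, q]["support"] = frozenset(graph.edges[p, q]["support"])
    if isolated:
        log.info(
            "%d of %d patients have no overlapping CNV and are excluded "
            "from the network", len(isolated), len(patients),
        )
    return PatientGraph(graph=graph, isolated=isolated)


def average_degree(n_nodes: int, n_edges: int) -> float:
    return 2 * n_edges / n_nodes


def graph_density(n_nodes: int, n_edges: int) -> float:
    return 2 * n_edges / (n_nodes * (n_nodes - 1))


@dataclass(frozen=True)
class TopologyStats:
    """Summary topology of the patient network.

    Shortest-path quantities are over ordered pairs of distinct nodes within
    the same connected component; the diameter is the largest eccentricity
    within the largest component.
    """

    n_nodes: int
    n_edges: int
    density: float
    avg_degree: float
    avg_clustering: float
    n_components: int
    diameter: int
    n_shortest_paths: int
    avg_shortest_path: float

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "avg_degree": self.avg_degree,
            "avg_clustering": self.avg_clustering,
            "n_components": self.n_components,
            "diameter": self.diameter,
            "n_shortest_paths": self.n_shortest_paths,
            "avg_shortest_path": self.avg_shortest_path,
        }


def topology_stats(patient_graph: PatientGraph) -> TopologyStats:
    graph = patient_graph.graph
    if graph.number_of_edges() == 0:
        raise ValueError("cannot compute topology statistics of an empty graph")
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    components = [graph.subgraph(c) for c in nx.connected_components(graph)]
    largest = max(components, key=len)
    total_dist = 0
    n_pairs = 0
    for source in graph:
        lengths = nx.single_source_shortest_path_length(graph, source)
        total_dist += sum(lengths.values())  # distance to self is 0
        n_pairs += len(lengths) - 1
    return TopologyStats(
        n_nodes=n,
        n_edges=e,
        density=graph_density(n, e),
        avg_degree=average_degree(n, e),
        avg_clustering=nx.average_clustering(graph),
        n_components=len(components),
        diameter=nx.diameter(largest),
        n_shortest_paths=n_pairs,
        avg_shortest_path=total_dist / n_pairs,
    )


def write_edge_list(patient_graph: PatientGraph, path) -> None:
    """Edge-list TSV: patient_a, patient_b, n_supports, classes."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["patient_a", "patient_b", "n_supports", "classes"])
        for p, q in sorted(tuple(sorted(e)) for e in patient_graph.graph.edges):
            support = patient_graph.edge_support(p, q)
            classes = sorted({cls for _, _, cls in support})
            writer.writerow([p, q, len(support), ",".join(classes)])


def read_edge_list(path) -> PatientGraph:
    """Read an edge-list TSV back into a (support-free) patient graph."""
    graph = nx.Graph()
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        for row in reader:
            if not row:
                continue
            graph.add_edge(row[0], row[1], support=frozenset())
    return PatientGraph(graph=graph)
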