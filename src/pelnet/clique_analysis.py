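"""Maximal-clique mining and the common-locus filter.

A clique of mutually overlapping patients does not guarantee one shared
genomic region: a long CNV can connect to different partners at different
places.  Each maximal clique is therefore screened for genomic positions
covered, for some CNV class and chromosome, by at least one CNV of *every*
member; each maximal such region yields a candidate locus -- the minimal
common intersection of one assigned CNV per member.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import reduce
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .cohort_io import CnvRecord, GenomicInterval, PatientRecord
from .patient_network import PatientGraph


@dataclass(frozen=True)
class CliqueLocus:
    """A qualified clique plus its minimal common intersection.

    ``assigned`` maps each member to the single CNV accounting for the locus;
    every assigned CNV covers every base pair of ``locus``.
    """

    members: frozenset[str]
    cnv_class: str
    assigned: tuple[tuple[str, CnvRecord], ...]  # sorted by patient id
    locus: GenomicInterval

    def __post_init__(self) -> None:
        if len(self.members) < 3:
            raise ValueError("a clique locus needs at least 3 members")
        for patient_id, cnv in self.assigned:
            if cnv.cnv_class != self.cnv_class:
                raise ValueError("assigned CNV class mismatch")
            if not cnv.interval.contains(self.locus):
                raise ValueError(
                    f"assigned CNV of {patient_id} does not cover the locus"
                )

    @property
    def assignment(self) -> dict[str, CnvRecord]:
        return dict(self.assigned)

    @property
    def size(self) -> int:
        return len(self.members)


def maximal_cliques(
    graph: PatientGraph, min_size: int = 3
) -> list[frozenset[str]]:
    """All maximal cliques with >= ``min_size`` members, each exactly once.

    Collecting the maximal cliques containing each node and merging identical
    member sets is equivalent to deduplicated maximal-clique enumeration,
    which is what Bron-Kerbosch (networkx ``find_cliques``) returns directly.
    """
    if min_size < 2:
        raise ValueError(f"min_size must be >= 2, got {min_size}")
    cliques = {
        frozenset(c)
        for c in nx.find_cliques(graph.graph)
        if len(c) >= min_size
    }
    return sorted(cliques, key=lambda c: (-len(c), sorted(c)))


def common_intersection(
    intervals: Sequence[GenomicInterval],
) -> GenomicInterval | None:
    """(max start, min end) of the intervals, or None when empty."""
    if not intervals:
        return None
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) != 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    start = max(iv.start for iv in intervals)
    end = min(iv.end for iv in intervals)
    if start >= end:
        return None
    return GenomicInterval(chroms.pop(), start, end)


def _merge_union(intervals: Iterable[GenomicInterval]) -> list[tuple[int, int]]:
    """Disjoint maximal (start, end) runs covered by the intervals."""
    spans = sorted((iv.start, iv.end) for iv in intervals)
    merged: list[tuple[int, int]] = []
    for start, end in spans:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _intersect_spans(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        start = max(a[i][0], b[j][0])
        end = min(a[i][1], b[j][1])
        if start < end:
            out.append((start, end))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def resolve_clique_locus(
    clique: frozenset[str] | Iterable[str],
    patients: Sequence[PatientRecord] | Mapping[str, PatientRecord],
) -> list[CliqueLocus]:
    """Screen one clique for common mutated regions, one locus per region.

    For every (CNV class, chromosome): positions covered by >=1 CNV of every
    member are found by interval-set intersection of the members' coverage
    unions.  For each maximal common region, each member is assigned one CNV
    (preferring full coverage of the region, then the longest, then the
    leftmost) and the locus is the common intersection of the assigned CNVs.
    A clique yielding no region anywhere is rejected (empty list).
    """
    if isinstance(patients, Mapping):
        by_id = patients
    else:
        by_id = {p.patient_id: p for p in patients}
    members = sorted(clique)
    records = [by_id[m] for m in members]

    keys = sorted(
        {(c.cnv_class, c.interval.chrom) for p in records for c in p.cnvs}
    )
    loci: list[CliqueLocus] = []
    seen: set[tuple[frozenset[str], str, GenomicInterval]] = set()
    for cls, chrom in keys:
        per_member: list[list[CnvRecord]] = []
        for record in records:
            cnvs = [
                c
                for c in record.cnvs
                if c.cnv_class == cls and c.interval.chrom == chrom
            ]
            if not cnvs:
                break
            per_member.append(cnvs)
        if len(per_member) != len(records):
            continue
        regions = reduce(
            _intersect_spans,
            (_merge_union(c.interval for c in cnvs) for cnvs in per_member),
        )
        for start, end in regions:
            region = GenomicInterval(chrom, start, end)
            assigned: list[tuple[str, CnvRecord]] = []
            for member, cnvs in zip(members, per_member):
                candidates = [c for c in cnvs if c.interval.overlaps(region)]
                best = max(
                    candidates,
                    key=lambda c: (
                        c.interval.contains(region),
                        c.interval.length,
                        -c.interval.start,
                    ),
                )
                assigned.append((member, best))
            locus = common_intersection([c.interval for _, c in assigned])
            if locus is None:
                continue  # region covered only piecewise by some member
            key = (frozenset(members), cls, locus)
            if key in seen:
                continue
            seen.add(key)
            loci.append(
                CliqueLocus(
                    members=frozenset(members),
                    cnv_class=cls,
                    assigned=tuple(assigned),
                    locus=locus,
                )
            )
    return loci


def find_clique_loci(
    graph: PatientGraph,
    patients: Sequence[PatientRecord],
    min_size: int = 3,
) -> tuple[list[CliqueLocus], int]:
    """Enumerate qualified clique loci; also return the rejected-clique count."""
    by_id = {p.patient_id: p for p in patients}
    loci: list[CliqueLocus] = []
    rejected = 0
    for clique in maximal_cliques(graph, min_size=min_size):
        resolved = resolve_clique_locus(clique, by_id)
        if resolved:
            loci.extend(resolved)
        else:
            rejected += 1
    return loci, rejected


def write_clique_table(loci: Sequence[CliqueLocus], path) -> None:
    """Clique dump TSV: id, size, members, class, chrom, locus span."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["clique_id", "size", "members", "class", "chrom",
             "locus_start", "locus_end"]
        )
        for i, locus in enumerate(loci, start=1):
            writer.writerow(
                [
                    f"CL_{i}",
                    locus.size,
                    "|".join(sorted(locus.members)),
                    locus.cnv_class,
                    locus.locus.chrom,
                    locus.locus.start,
                    locus.locus.end,
                ]
            )
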