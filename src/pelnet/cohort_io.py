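"""Reading and writing of patient cohorts, control variant sets and result tables.

Coordinate convention
---------------------
Internally every interval is 0-based, half-open (``[start, end)``), which makes
overlap and intersection arithmetic off-by-one-proof.  Published tab-separated
files -- DECIPHER-like patient CNV tables and DGV-like control tables -- use
1-based inclusive coordinates and are converted on read/write.  BED output is
0-based half-open, as BED requires; syndrome catalogues are read as BED.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

CNV_CLASSES = frozenset({"gain", "loss"})
INHERITANCE_LABELS = frozenset(
    {"de_novo", "inherited_unaffected", "inherited_affected", "unknown"}
)

#: Default mapping of DGV variant subtypes onto the gain/loss dichotomy.
#: Subtypes not listed here (e.g. inversions) are skipped and counted.
DEFAULT_SUBTYPE_MAP: Mapping[str, str] = {
    "gain": "gain",
    "duplication": "gain",
    "insertion": "gain",
    "loss": "loss",
    "deletion": "loss",
}

PATIENT_CNV_COLUMNS = ("patient_id", "chrom", "start", "end", "class", "inheritance")
ANNOTATION_COLUMNS = ("patient_id", "terms")


class CohortIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored 0-based half-open span."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: start={self.start}, end={self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the spans share at least one base pair."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @classmethod
    def from_one_based(cls, chrom: str, start: int, end: int) -> "GenomicInterval":
        """Convert a 1-based inclusive span (as printed in input tables)."""
        return cls(chrom, start - 1, end)

    def to_one_based(self) -> tuple[int, int]:
        """Inverse of :meth:`from_one_based`."""
        return self.start + 1, self.end


@dataclass(frozen=True)
class CnvRecord:
    """A gain/loss interval owned by one patient."""

    patient_id: str
    interval: GenomicInterval
    cnv_class: str
    inheritance: str = "unknown"

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("empty patient_id")
        if self.cnv_class not in CNV_CLASSES:
            raise ValueError(
                f"unknown CNV class {self.cnv_class!r}; allowed: {sorted(CNV_CLASSES)}"
            )
        if self.inheritance not in INHERITANCE_LABELS:
            raise ValueError(
                f"unknown inheritance {self.inheritance!r}; "
                f"allowed: {sorted(INHERITANCE_LABELS)}"
            )


@dataclass(frozen=True)
class PatientRecord:
    """A patient with at least one CNV and at least one phenotype term."""

    patient_id: str
    cnvs: tuple[CnvRecord, ...]
    phenotypes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.cnvs:
            raise ValueError(f"patient {self.patient_id}: no CNVs")
        if not self.phenotypes:
            raise ValueError(f"patient {self.patient_id}: no phenotype terms")
        for cnv in self.cnvs:
            if cnv.patient_id != self.patient_id:
                raise ValueError(
                    f"CNV owned by {cnv.patient_id!r} inside record of "
                    f"{self.patient_id!r}"
                )


@dataclass(frozen=True)
class ControlVariant:
    """A gain/loss interval from a healthy-population sample."""

    interval: GenomicInterval
    cnv_class: str
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.cnv_class not in CNV_CLASSES:
            raise ValueError(
                f"unknown CNV class {self.cnv_class!r}; allowed: {sorted(CNV_CLASSES)}"
            )


@dataclass(frozen=True)
class SyndromeRecord:
    """A known genomic-disorder interval with its mutation type."""

    name: str
    locus: GenomicInterval
    mutation_type: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.mutation_type not in CNV_CLASSES:
            raise ValueError(
                f"unknown mutation type {self.mutation_type!r}; "
                f"allowed: {sorted(CNV_CLASSES)}"
            )


def _parse_positive_int(token: str, path, line_no: int, column: str) -> int:
    try:
        value = int(token)
    except ValueError:
        raise CohortIOError(
            f"{path}: line {line_no}: column {column!r}: not an integer: {token!r}"
        ) from None
    return value


def read_patient_cnvs(path, annotation_path) -> list[PatientRecord]:
    """Read a patient CNV table plus its phenotype annotation table.

    Only patients with at least one CNV *and* at least one phenotype term are
    returned; the number of genotyped patients dropped for lack of phenotype
    annotation is reported on the module logger.  Coordinates are converted
    from the files' 1-based inclusive convention to internal half-open spans.
    """
    path, annotation_path = Path(path), Path(annotation_path)
    cnvs_by_patient: dict[str, list[CnvRecord]] = {}
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != PATIENT_CNV_COLUMNS:
            raise CohortIOError(
                f"{path}: expected header {list(PATIENT_CNV_COLUMNS)}, got {header}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(PATIENT_CNV_COLUMNS):
                raise CohortIOError(
                    f"{path}: line {line_no}: expected "
                    f"{len(PATIENT_CNV_COLUMNS)} columns, got {len(row)}"
                )
            patient_id, chrom, start_tok, end_tok, cls, inh = row
            if not patient_id:
                raise CohortIOError(f"{path}: line {line_no}: empty patient_id")
            start = _parse_positive_int(start_tok, path, line_no, "start")
            end = _parse_positive_int(end_tok, path, line_no, "end")
            if end < start:
                raise CohortIOError(
                    f"{path}: line {line_no}: end ({end}) < start ({start})"
                )
            if cls not in CNV_CLASSES:
                raise CohortIOError(
                    f"{path}: line {line_no}: unknown class {cls!r}; "
                    f"allowed: {sorted(CNV_CLASSES)}"
                )
            if inh not in INHERITANCE_LABELS:
                raise CohortIOError(
                    f"{path}: line {line_no}: unknown inheritance {inh!r}; "
                    f"allowed: {sorted(INHERITANCE_LABELS)}"
                )
            interval = GenomicInterval.from_one_based(chrom, start, end)
            cnvs_by_patient.setdefault(patient_id, []).append(
                CnvRecord(patient_id, interval, cls, inh)
            )

    terms_by_patient: dict[str, set[str]] = {}
    with open(annotation_path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != ANNOTATION_COLUMNS:
            raise CohortIOError(
                f"{annotation_path}: expected header {list(ANNOTATION_COLUMNS)}, "
                f"got {header}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise CohortIOError(
                    f"{annotation_path}: line {line_no}: expected 2 columns, "
                    f"got {len(row)}"
                )
            patient_id, terms = row
            parsed = {t for t in terms.split("|") if t}
            terms_by_patient.setdefault(patient_id, set()).update(parsed)

    records: list[PatientRecord] = []
    dropped = 0
    for patient_id, cnvs in cnvs_by_patient.items():
        terms = terms_by_patient.get(patient_id, set())
        if terms:
            records.append(
                PatientRecord(patient_id, tuple(cnvs), frozenset(terms))
            )
        else:
            dropped += 1
    log.info(
        "read %d genotyped patients from %s: retained %d annotated, "
        "dropped %d without phenotype terms",
        len(cnvs_by_patient), path, len(records), dropped,
    )
    return records


def write_patient_cnvs(
    patients: Sequence[PatientRecord], path, annotation_path
) -> None:
    """Inverse of :func:`read_patient_cnvs` (round-trip exact)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(PATIENT_CNV_COLUMNS)
        for patient in patients:
            for cnv in patient.cnvs:
                start, end = cnv.interval.to_one_based()
                writer.writerow(
                    [
                        patient.patient_id,
                        cnv.interval.chrom,
                        start,
                        end,
                        cnv.cnv_class,
                        cnv.inheritance,
                    ]
                )
    with open(annotation_path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for patient in patients:
            writer.writerow(
                [patient.patient_id, "|".join(sorted(patient.phenotypes))]
            )


_CONTROL_COLUMN_ALIASES = {
    "chrom": ("chr", "chrom", "chromosome"),
    "start": ("start",),
    "end": ("end",),
    "subtype": ("variantsubtype", "variant_subtype", "subtype"),
    "samples": ("samples", "sample", "sample_id"),
}


def read_control_variants(
    path,
    subtype_map: Mapping[str, str] | None = None,
    row_filter=None,
) -> list[ControlVariant]:
    """Read a DGV-dialect control variant table.

    Variant subtypes are mapped onto gain/loss via ``subtype_map``
    (default :data:`DEFAULT_SUBTYPE_MAP`); unmapped subtypes are skipped and
    counted.  ``row_filter`` is an optional predicate on the raw pandas row
    (e.g. a platform filter); rows failing it are skipped.
    """
    if subtype_map is None:
        subtype_map = DEFAULT_SUBTYPE_MAP
    frame = pd.read_csv(path, sep="\t", dtype=str)
    lower = {c.lower(): c for c in frame.columns}
    resolved: dict[str, str | None] = {}
    for key, aliases in _CONTROL_COLUMN_ALIASES.items():
        resolved[key] = next((lower[a] for a in aliases if a in lower), None)
    for key in ("chrom", "start", "end", "subtype"):
        if resolved[key] is None:
            raise CohortIOError(
                f"{path}: missing required column for {key!r} "
                f"(accepted names: {list(_CONTROL_COLUMN_ALIASES[key])})"
            )

    variants: list[ControlVariant] = []
    skipped = 0
    filtered = 0
    for _, row in frame.iterrows():
        if row_filter is not None and not row_filter(row):
            filtered += 1
            continue
        subtype = str(row[resolved["subtype"]]).strip().lower()
        cls = subtype_map.get(subtype)
        if cls is None:
            skipped += 1
            continue
        interval = GenomicInterval.from_one_based(
            str(row[resolved["chrom"]]),
            int(row[resolved["start"]]),
            int(row[resolved["end"]]),
        )
        sample = None
        if resolved["samples"] is not None:
            raw = row[resolved["samples"]]
            if pd.notna(raw) and str(raw):
                sample = str(raw)
        variants.append(ControlVariant(interval, cls, sample))
    log.info(
        "read %d control variants from %s (%d unmapped subtypes skipped, "
        "%d filtered); %d distinct samples",
        len(variants), path, skipped, filtered,
        control_population_size(variants),
    )
    return variants


def control_population_size(
    controls: Sequence[ControlVariant], override: int | None = None
) -> int:
    """Control population size: distinct sample ids when present, else records.

    The DGV-style sample count is only an upper bound on independent
    individuals, hence the explicit ``override``.
    """
    if override is not None:
        return override
    samples = {v.sample_id for v in controls if v.sample_id is not None}
    return len(samples) if samples else len(controls)


def write_control_variants(controls: Sequence[ControlVariant], path) -> None:
    """Write controls in the DGV-dialect format accepted by the reader."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["chr", "start", "end", "variantsubtype", "samples"])
        for v in controls:
            start, end = v.interval.to_one_based()
            writer.writerow(
                [v.interval.chrom, start, end, v.cnv_class, v.sample_id or ""]
            )


def read_syndrome_catalogue(path) -> list[SyndromeRecord]:
    """Read a BED-like known-syndrome catalogue.

    Columns (no header): chrom, start, end, name, mutation_type, source.
    Coordinates are BED-style 0-based half-open.
    """
    records: list[SyndromeRecord] = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for line_no, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 5:
                raise CohortIOError(
                    f"{path}: line {line_no}: expected >=5 columns "
                    "(chrom, start, end, name, mutation_type[, source])"
                )
            chrom, start_tok, end_tok, name, mutation = row[:5]
            source = row[5] if len(row) > 5 else ""
            start = _parse_positive_int(start_tok, path, line_no, "start")
            end = _parse_positive_int(end_tok, path, line_no, "end")
            records.append(
                SyndromeRecord(name, GenomicInterval(chrom, start, end), mutation, source)
            )
    return records


PEL_TABLE_COLUMNS = (
    "pel_id",
    "class",
    "chrom",
    "start",
    "end",
    "length_kb",
    "phenotype_id",
    "phenotype_name",
    "cases_with_phenotype",
    "clique_size",
    "control_carriers",
    "enrichment_p",
    "fisher_p_raw",
    "fisher_p_bh",
    "penetrance_pct",
)


def write_pel_table(associations, path, bed_path=None) -> None:
    """Write the locus-phenotype association table plus a BED interval file.

    Table coordinates are 1-based inclusive; the BED file is 0-based
    half-open.  Rows are ordered by ascending BH-adjusted Fisher p-value.
    """
    path = Path(path)
    if bed_path is None:
        bed_path = path.with_suffix(".bed")
    ordered = sorted(
        associations,
        key=lambda a: (
            a.p_fisher_bh,
            a.locus.chrom,
            a.locus.start,
            a.locus.end,
            a.term_id,
        ),
    )
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(PEL_TABLE_COLUMNS)
        for a in ordered:
            start, end = a.locus.to_one_based()
            writer.writerow(
                [
                    a.pel_id,
                    a.cnv_class,
                    a.locus.chrom,
                    start,
                    end,
                    f"{a.locus.length / 1000:.3f}",
                    a.term_id,
                    a.term_name,
                    a.k_case,
                    a.n_clique,
                    a.m_ctrl,
                    f"{a.p_enrich:.6g}",
                    f"{a.p_fisher_raw:.6g}",
                    f"{a.p_fisher_bh:.6g}",
                    f"{a.penetrance_pct:.1f}",
                ]
            )
    with open(bed_path, "w", newline="") as handle:
        for a in ordered:
            handle.write(
                f"{a.locus.chrom}\t{a.locus.start}\t{a.locus.end}\t"
                f"{a.pel_id}|{a.term_id}\n"
            )


def write_run_summary(summary: Mapping, path) -> None:
    """Write the machine-readable run manifest (counts, seeds, thresholds)."""
    with open(path, "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")
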