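"""Seeded synthetic cohorts with implanted ground-truth loci.

The generator emulates the structure of a rare-CNV patient repository paired
with a healthy-population control set: heavy-tailed (log-normal) CNV lengths
with case CNVs two orders of magnitude longer than control CNVs, one or two
CNVs per patient, sparse multi-term phenotype profiles over a toy ontology
(about half of patients carry a single term), and implanted loci whose
carriers share a phenotype term at a set penetrance.  Carrier CNVs cover the
whole implanted locus and extend past it by exponentially distributed flanks,
so the minimal common intersection of a carrier clique recovers the locus
while breakpoints stay variable.

Default parameters are the package's study conditions; they are used by the
test-suite benchmarks and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .cohort_io import (
    CnvRecord,
    ControlVariant,
    GenomicInterval,
    PatientRecord,
    write_control_variants,
    write_patient_cnvs,
)
from .hpo_ontology import PhenotypeOntology, write_obo
from .pel_discovery import PelAssociation

#: Autosome lengths (bp), hg19 scale rounded to the nearest Mb.  A
#: genome-sized coordinate space keeps the CNV overlap density of the
#: simulated network comparable to real case/control data.
DEFAULT_GENOME: dict[str, int] = {
    "1": 249_000_000, "2": 243_000_000, "3": 198_000_000, "4": 191_000_000,
    "5": 181_000_000, "6": 171_000_000, "7": 159_000_000, "8": 146_000_000,
    "9": 141_000_000, "10": 136_000_000, "11": 135_000_000, "12": 134_000_000,
    "13": 115_000_000, "14": 107_000_000, "15": 103_000_000, "16": 90_000_000,
    "17": 81_000_000, "18": 78_000_000, "19": 59_000_000, "20": 63_000_000,
    "21": 48_000_000, "22": 51_000_000,
}

_INHERITANCE_CHOICES = (
    "de_novo", "inherited_unaffected", "inherited_affected", "unknown",
)
#: Approximate inheritance-label mix of a clinical case repository.
_INHERITANCE_PROBS = (0.30, 0.23, 0.03, 0.44)

_MIN_CNV_LENGTH = 1_000


@dataclass(frozen=True)
class ImplantSpec:
    """A ground-truth locus: carriers share a covering CNV and, with the
    given penetrance, a phenotype term."""

    locus: GenomicInterval
    cnv_class: str
    term_id: str
    n_carriers: int
    penetrance: float
    flank_scale: int = 200_000

    def __post_init__(self) -> None:
        if self.n_carriers < 1:
            raise ValueError("n_carriers must be >= 1")
        if not 0.0 < self.penetrance <= 1.0:
            raise ValueError("penetrance must be in (0, 1]")


@dataclass(frozen=True)
class ImplantTruth:
    implant_id: str
    locus: GenomicInterval
    cnv_class: str
    term_id: str
    carriers: tuple[str, ...]


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a simulated cohort.

    Case CNV lengths are log-normal with mean ~= 3 Mb
    (``exp(14.3 + 1.0^2/2)``); control lengths log-normal with mean ~= 27 Kb,
    emulating the case/control length contrast of clinical vs population
    repositories.  ``background_cnv_rate`` is the Poisson mean of benign CNVs
    per individual (floored at one per patient).  ``noise_terms_per_patient``
    is the Poisson mean of unrelated phenotype terms, drawn uniformly over
    ontology leaves and floored at one term per patient.
    ``control_leak_rate`` is the probability that a control sample carries a
    CNV covering a random implant locus (0 keeps implants control-free,
    giving 100% estimated penetrance).
    """

    genome: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENOME)
    )
    n_patients: int = 200
    n_controls: int = 500
    implants: tuple[ImplantSpec, ...] = ()
    background_cnv_rate: float = 1.0
    case_length_log_mean: float = 14.3
    case_length_log_sd: float = 1.0
    control_length_log_mean: float = 9.8
    control_length_log_sd: float = 0.9
    noise_terms_per_patient: float = 0.7
    control_leak_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("cohort sizes must be positive")
        for chrom, length in self.genome.items():
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {chrom}")
        for implant in self.implants:
            if implant.locus.chrom not in self.genome:
                raise ValueError(
                    f"implant chromosome {implant.locus.chrom!r} not in genome"
                )
            if implant.locus.end > self.genome[implant.locus.chrom]:
                raise ValueError(
                    f"implant locus {implant.locus} exceeds chromosome length"
                )
            if implant.n_carriers > self.n_patients:
                raise ValueError("more carriers than patients")


def make_toy_ontology(depth: int, branching: int) -> PhenotypeOntology:
    """A rooted tree ontology with ``branching**d`` terms at depth ``d``.

    Term ids are deterministic (``HP:0000001`` is the root, then
    breadth-first).
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    counter = 1
    parent_map: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    root = f"HP:{counter:07d}"
    parent_map[root] = []
    names[root] = "Phenotypic abnormality"
    level = [root]
    for d in range(1, depth + 1):
        next_level = []
        for parent in level:
            for i in range(branching):
                counter += 1
                term = f"HP:{counter:07d}"
                parent_map[term] = [parent]
                names[term] = f"Abnormality L{d}.{counter}"
                next_level.append(term)
        level = next_level
    return PhenotypeOntology.from_parent_map(parent_map, names)


def _draw_length(rng, mu: float, sd: float, chrom_length: int) -> int:
    length = int(rng.lognormal(mu, sd))
    return max(_MIN_CNV_LENGTH, min(length, chrom_length))


def _draw_background_interval(
    rng, genome_chroms, genome_lengths, probs, mu, sd
) -> GenomicInterval:
    chrom = genome_chroms[rng.choice(len(genome_chroms), p=probs)]
    chrom_length = genome_lengths[chrom]
    length = _draw_length(rng, mu, sd, chrom_length)
    start = int(rng.integers(0, chrom_length - length + 1))
    return GenomicInterval(chrom, start, start + length)


def _implant_interval(rng, implant: ImplantSpec, chrom_length: int) -> GenomicInterval:
    left = int(rng.exponential(implant.flank_scale))
    right = int(rng.exponential(implant.flank_scale))
    start = max(0, implant.locus.start - left)
    end = min(chrom_length, implant.locus.end + right)
    return GenomicInterval(implant.locus.chrom, start, end)


def simulate_cohort(
    spec: CohortSpec, ontology: PhenotypeOntology
) -> tuple[list[PatientRecord], list[ControlVariant], list[ImplantTruth]]:
    """Generate (patients, controls, truth) for one seeded cohort."""
    for implant in spec.implants:
        if implant.term_id not in ontology:
            raise ValueError(f"implant term {implant.term_id!r} not in ontology")
    rng = np.random.default_rng(spec.seed)
    genome_chroms = sorted(spec.genome, key=lambda c: (len(c), c))
    genome_lengths = dict(spec.genome)
    total = sum(genome_lengths[c] for c in genome_chroms)
    probs = np.array([genome_lengths[c] / total for c in genome_chroms])
    probs = probs / probs.sum()
    leaves = sorted(ontology.leaves)

    patient_ids = [f"P{i + 1:04d}" for i in range(spec.n_patients)]
    carrier_sets: list[np.ndarray] = [
        rng.choice(spec.n_patients, size=imp.n_carriers, replace=False)
        for imp in spec.implants
    ]
    carriers_of: dict[int, list[int]] = {}
    for imp_idx, rows in enumerate(carrier_sets):
        for row in rows:
            carriers_of.setdefault(int(row), []).append(imp_idx)

    patients: list[PatientRecord] = []
    for row, patient_id in enumerate(patient_ids):
        cnvs: list[CnvRecord] = []
        terms: set[str] = set()
        for imp_idx in carriers_of.get(row, []):
            implant = spec.implants[imp_idx]
            interval = _implant_interval(
                rng, implant, genome_lengths[implant.locus.chrom]
            )
            inheritance = _INHERITANCE_CHOICES[
                rng.choice(len(_INHERITANCE_CHOICES), p=_INHERITANCE_PROBS)
            ]
            cnvs.append(
                CnvRecord(patient_id, interval, implant.cnv_class, inheritance)
            )
            if rng.random() < implant.penetrance:
                terms.add(implant.term_id)
        n_background = int(rng.poisson(spec.background_cnv_rate))
        if not cnvs and n_background == 0:
            n_background = 1  # every patient carries at least one CNV
        for _ in range(n_background):
            interval = _draw_background_interval(
                rng, genome_chroms, genome_lengths, probs,
                spec.case_length_log_mean, spec.case_length_log_sd,
            )
            cls = "loss" if rng.random() < 0.5 else "gain"
            inheritance = _INHERITANCE_CHOICES[
                rng.choice(len(_INHERITANCE_CHOICES), p=_INHERITANCE_PROBS)
            ]
            cnvs.append(CnvRecord(patient_id, interval, cls, inheritance))
        n_noise = int(rng.poisson(spec.noise_terms_per_patient))
        for _ in range(n_noise):
            terms.add(leaves[int(rng.integers(0, len(leaves)))])
        if not terms:  # guarantee >=1 phenotype term
            terms.add(leaves[int(rng.integers(0, len(leaves)))])
        patients.append(
            PatientRecord(patient_id, tuple(cnvs), frozenset(terms))
        )

    controls: list[ControlVariant] = []
    for i in range(spec.n_controls):
        sample_id = f"C{i + 1:04d}"
        n_cnvs = max(1, int(rng.poisson(spec.background_cnv_rate)))
        for _ in range(n_cnvs):
            interval = _draw_background_interval(
                rng, genome_chroms, genome_lengths, probs,
                spec.control_length_log_mean, spec.control_length_log_sd,
            )
            cls = "loss" if rng.random() < 0.5 else "gain"
            controls.append(ControlVariant(interval, cls, sample_id))
        if spec.implants and rng.random() < spec.control_leak_rate:
            implant = spec.implants[int(rng.integers(0, len(spec.implants)))]
            interval = _implant_interval(
                rng, implant, genome_lengths[implant.locus.chrom]
            )
            controls.append(
                ControlVariant(interval, implant.cnv_class, sample_id)
            )

    truth = [
        ImplantTruth(
            implant_id=f"IMP_{idx + 1}",
            locus=imp.locus,
            cnv_class=imp.cnv_class,
            term_id=imp.term_id,
            carriers=tuple(sorted(patient_ids[int(r)] for r in rows)),
        )
        for idx, (imp, rows) in enumerate(zip(spec.implants, carrier_sets))
    ]
    return patients, controls, truth


def default_benchmark_spec(
    seed: int = 0,
    n_implants: int = 3,
    n_carriers: int = 12,
    implant_penetrance: float = 0.9,
    **overrides,
) -> tuple[CohortSpec, PhenotypeOntology]:
    """The package's standard benchmark: 200 patients, 500 controls, three
    implanted loci (two losses, one gain) with distinct leaf phenotypes."""
    ontology = make_toy_ontology(depth=3, branching=3)
    leaves = sorted(ontology.leaves)
    term_picks = [leaves[0], leaves[len(leaves) // 2], leaves[-1]]
    locus_picks = [
        (GenomicInterval("1", 40_000_000, 40_500_000), "loss"),
        (GenomicInterval("2", 60_000_000, 60_400_000), "loss"),
        (GenomicInterval("3", 25_000_000, 25_600_000), "gain"),
    ]
    if not 0 <= n_implants <= len(locus_picks):
        raise ValueError(f"n_implants must be 0..{len(locus_picks)}")
    implants = tuple(
        ImplantSpec(
            locus=locus,
            cnv_class=cls,
            term_id=term,
            n_carriers=n_carriers,
            penetrance=implant_penetrance,
        )
        for (locus, cls), term in list(zip(locus_picks, term_picks))[:n_implants]
    )
    return CohortSpec(implants=implants, seed=seed, **overrides), ontology


def _spec_to_mapping(spec: CohortSpec) -> dict:
    return {
        "genome": dict(spec.genome),
        "n_patients": spec.n_patients,
        "n_controls": spec.n_controls,
        "implants": [
            {
                "chrom": imp.locus.chrom,
                "start": imp.locus.start,
                "end": imp.locus.end,
                "class": imp.cnv_class,
                "term_id": imp.term_id,
                "n_carriers": imp.n_carriers,
                "penetrance": imp.penetrance,
                "flank_scale": imp.flank_scale,
            }
            for imp in spec.implants
        ],
        "background_cnv_rate": spec.background_cnv_rate,
        "case_length_log_mean": spec.case_length_log_mean,
        "case_length_log_sd": spec.case_length_log_sd,
        "control_length_log_mean": spec.control_length_log_mean,
        "control_length_log_sd": spec.control_length_log_sd,
        "noise_terms_per_patient": spec.noise_terms_per_patient,
        "control_leak_rate": spec.control_leak_rate,
        "seed": spec.seed,
    }


def spec_from_mapping(data: Mapping) -> CohortSpec:
    """Build a CohortSpec from a YAML-style mapping (inverse of the echo)."""
    implants = tuple(
        ImplantSpec(
            locus=GenomicInterval(
                str(item["chrom"]), int(item["start"]), int(item["end"])
            ),
            cnv_class=item["class"],
            term_id=item["term_id"],
            n_carriers=int(item["n_carriers"]),
            penetrance=float(item["penetrance"]),
            flank_scale=int(item.get("flank_scale", 200_000)),
        )
        for item in data.get("implants", [])
    )
    kwargs = {
        key: data[key]
        for key in (
            "n_patients", "n_controls", "background_cnv_rate",
            "case_length_log_mean", "case_length_log_sd",
            "control_length_log_mean", "control_length_log_sd",
            "noise_terms_per_patient", "control_leak_rate", "seed",
        )
        if key in data
    }
    genome = {
        str(c): int(l) for c, l in data.get("genome", DEFAULT_GENOME).items()
    }
    return CohortSpec(genome=genome, implants=implants, **kwargs)


def write_cohort(
    patients: Sequence[PatientRecord],
    controls: Sequence[ControlVariant],
    truth: Sequence[ImplantTruth],
    spec: CohortSpec,
    ontology: PhenotypeOntology,
    outdir,
) -> dict[str, Path]:
    """Emit the cohort in the exact file formats the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cnvs": outdir / "patient_cnvs.tsv",
        "annotations": outdir / "patient_phenotypes.tsv",
        "controls": outdir / "controls.tsv",
        "obo": outdir / "ontology.obo",
        "truth": outdir / "truth.tsv",
        "spec": outdir / "spec.yaml",
    }
    write_patient_cnvs(patients, paths["cnvs"], paths["annotations"])
    write_control_variants(controls, paths["controls"])
    write_obo(ontology, paths["obo"])
    with open(paths["truth"], "w") as handle:
        handle.write(
            "implant_id\tchrom\tstart\tend\tclass\tterm_id\tcarriers\n"
        )
        for t in truth:
            handle.write(
                f"{t.implant_id}\t{t.locus.chrom}\t{t.locus.start}\t"
                f"{t.locus.end}\t{t.cnv_class}\t{t.term_id}\t"
                f"{'|'.join(t.carriers)}\n"
            )
    with open(paths["spec"], "w") as handle:
        yaml.safe_dump(_spec_to_mapping(spec), handle, sort_keys=True)
    return paths


def read_truth(path) -> list[ImplantTruth]:
    truth = []
    with open(path) as handle:
        next(handle)
        for line in handle:
            if not line.strip():
                continue
            implant_id, chrom, start, end, cls, term, carriers = (
                line.rstrip("\n").split("\t")
            )
            truth.append(
                ImplantTruth(
                    implant_id,
                    GenomicInterval(chrom, int(start), int(end)),
                    cls,
                    term,
                    tuple(carriers.split("|")) if carriers else (),
                )
            )
    return truth


@dataclass(frozen=True)
class RecoveryReport:
    """Recall/precision of significant associations against implant truth.

    Undefined ratios (zero denominators) are reported as 1.0 and flagged.
    """

    recall: float
    precision: float
    n_recovered: int
    n_matched_associations: int
    n_significant: int
    recovered_ids: tuple[str, ...]
    recall_undefined: bool
    precision_undefined: bool


def evaluate_recovery(
    associations: Sequence[PelAssociation],
    truth: Sequence[ImplantTruth],
    ontology: PhenotypeOntology,
) -> RecoveryReport:
    """Score discovered associations against the implanted ground truth.

    An implant is recovered iff some significant association overlaps its
    locus by >=1 bp with the same CNV class and a term equal to, or an
    ancestor of, the implanted term (enrichment may surface a broader
    ontology level than the implanted leaf).
    """
    significant = [a for a in associations if a.significant]
    recovered: set[str] = set()
    matched_assoc: set[str] = set()
    for t in truth:
        acceptable = {t.term_id} | ontology.ancestors(t.term_id)
        for assoc in significant:
            if (
                assoc.cnv_class == t.cnv_class
                and assoc.locus.overlaps(t.locus)
                and assoc.term_id in acceptable
            ):
                recovered.add(t.implant_id)
                matched_assoc.add(assoc.pel_id)
    recall_undefined = len(truth) == 0
    precision_undefined = len(significant) == 0
    return RecoveryReport(
        recall=1.0 if recall_undefined else len(recovered) / len(truth),
        precision=(
            1.0 if precision_undefined
            else len(matched_assoc) / len(significant)
        ),
        n_recovered=len(recovered),
        n_matched_associations=len(matched_assoc),
        n_significant=len(significant),
        recovered_ids=tuple(sorted(recovered)),
        recall_undefined=recall_undefined,
        precision_undefined=precision_undefined,
    )
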