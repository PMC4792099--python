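"""Five null models and the repeated-experiment harness.

Each null destroys one structure of the data while conserving chosen
marginals exactly:

- ``dgv_cnvs``        -- case CNVs replaced by control variants drawn without
                         replacement (per-patient CNV counts conserved);
- ``case_location``   -- case CNVs relocated uniformly on their own
                         chromosome (length multiset and per-chromosome
                         counts conserved);
- ``control_location``-- same relocation applied to the control set;
- ``rewire_patient_cnv`` -- the CNV multiset permuted across patients
                         (per-patient counts conserved);
- ``shuffle_phenotypes`` -- whole phenotype profiles permuted across patients
                         (per-term patient counts conserved exactly).

The harness reruns the full discovery pipeline on every randomized dataset
and records significant-PEL counts and sub-threshold Fisher p-values.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort_io import CnvRecord, ControlVariant, GenomicInterval, PatientRecord
from .hpo_ontology import PhenotypeOntology
from .pipeline import RunConfig, run_discovery

log = logging.getLogger(__name__)

NULL_KINDS = (
    "dgv_cnvs",
    "case_location",
    "control_location",
    "rewire_patient_cnv",
    "shuffle_phenotypes",
)


@dataclass(frozen=True)
class NullModelSpec:
    kind: str
    n_reps: int = 1000
    seed: int = 0
    genome: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in NULL_KINDS:
            raise ValueError(
                f"unknown null kind {self.kind!r}; allowed: {list(NULL_KINDS)}"
            )
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for chrom, length in self.genome.items():
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {chrom}")


@dataclass
class NullRunResult:
    kind: str
    per_rep_pel_counts: list[int]
    per_rep_fisher_p: list[list[float]]


def null_dgv_cnvs(
    patients: Sequence[PatientRecord],
    controls: Sequence[ControlVariant],
    seed: int,
) -> list[PatientRecord]:
    """Replace every case CNV by a control variant drawn without replacement.

    Patient identities, per-patient CNV counts, inheritance labels and
    phenotype profiles are untouched; interval and class come from the
    control draw.
    """
    total = sum(len(p.cnvs) for p in patients)
    if len(controls) < total:
        raise ValueError(
            f"need >= {total} control variants to replace all case CNVs, "
            f"have {len(controls)}"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(controls), size=total, replace=False)
    out: list[PatientRecord] = []
    cursor = 0
    for patient in patients:
        new_cnvs = []
        for cnv in patient.cnvs:
            control = controls[int(picks[cursor])]
            cursor += 1
            new_cnvs.append(
                CnvRecord(
                    patient.patient_id,
                    control.interval,
                    control.cnv_class,
                    cnv.inheritance,
                )
            )
        out.append(dataclasses.replace(patient, cnvs=tuple(new_cnvs)))
    return out


def _relocate(interval: GenomicInterval, genome: Mapping[str, int], rng):
    chrom_length = genome[interval.chrom]
    if interval.length > chrom_length:
        raise ValueError(
            f"CNV of length {interval.length} exceeds chromosome "
            f"{interval.chrom} ({chrom_length} bp)"
        )
    start = int(rng.integers(0, chrom_length - interval.length + 1))
    return GenomicInterval(interval.chrom, start, start + interval.length)


def null_shuffle_locations(records, genome: Mapping[str, int], seed: int):
    """Relocate each record uniformly on its own chromosome, keeping length.

    Works on any sequence of interval-bearing records (case CNVs or control
    variants); classes and ownership are unchanged, so both the length
    multiset and per-chromosome counts are conserved exactly.
    """
    rng = np.random.default_rng(seed)
    return [
        dataclasses.replace(r, interval=_relocate(r.interval, genome, rng))
        for r in records
    ]


def shuffle_patient_locations(
    patients: Sequence[PatientRecord], genome: Mapping[str, int], seed: int
) -> list[PatientRecord]:
    """``null_shuffle_locations`` applied inside patient records."""
    rng = np.random.default_rng(seed)
    out = []
    for patient in patients:
        new_cnvs = tuple(
            dataclasses.replace(c, interval=_relocate(c.interval, genome, rng))
            for c in patient.cnvs
        )
        out.append(dataclasses.replace(patient, cnvs=new_cnvs))
    return out


def null_rewire_patient_cnv(
    patients: Sequence[PatientRecord], seed: int
) -> list[PatientRecord]:
    """Permute the CNV multiset across patients, keeping per-patient counts."""
    if len(patients) < 2:
        raise ValueError("need >= 2 patients to rewire")
    rng = np.random.default_rng(seed)
    pool = [cnv for p in patients for cnv in p.cnvs]
    order = rng.permutation(len(pool))
    out = []
    cursor = 0
    for patient in patients:
        new_cnvs = []
        for _ in patient.cnvs:
            source = pool[int(order[cursor])]
            cursor += 1
            new_cnvs.append(
                dataclasses.replace(source, patient_id=patient.patient_id)
            )
        out.append(dataclasses.replace(patient, cnvs=tuple(new_cnvs)))
    return out


def null_shuffle_phenotypes(
    patients: Sequence[PatientRecord], seed: int
) -> list[PatientRecord]:
    """Permute whole phenotype profiles across patients.

    Permuting profiles (rather than term-patient pairs) conserves every
    term's patient count and the co-occurrence structure within profiles.
    """
    rng = np.random.default_rng(seed)
    profiles = [p.phenotypes for p in patients]
    order = rng.permutation(len(profiles))
    return [
        dataclasses.replace(patient, phenotypes=profiles[int(order[i])])
        for i, patient in enumerate(patients)
    ]


def _randomize(
    kind: str,
    patients: Sequence[PatientRecord],
    controls: Sequence[ControlVariant],
    genome: Mapping[str, int],
    seed: int,
):
    if kind == "dgv_cnvs":
        return null_dgv_cnvs(patients, controls, seed), controls
    if kind == "case_location":
        return shuffle_patient_locations(patients, genome, seed), controls
    if kind == "control_location":
        return list(patients), null_shuffle_locations(controls, genome, seed)
    if kind == "rewire_patient_cnv":
        return null_rewire_patient_cnv(patients, seed), controls
    if kind == "shuffle_phenotypes":
        return null_shuffle_phenotypes(patients, seed), controls
    raise ValueError(f"unknown null kind {kind!r}")


def genome_from_data(
    patients: Sequence[PatientRecord],
    controls: Sequence[ControlVariant] = (),
) -> dict[str, int]:
    """Fallback genome: per-chromosome maximum observed end position."""
    genome: dict[str, int] = {}
    intervals = [c.interval for p in patients for c in p.cnvs]
    intervals += [v.interval for v in controls]
    for interval in intervals:
        genome[interval.chrom] = max(
            genome.get(interval.chrom, 0), interval.end
        )
    return genome


def run_null_experiments(
    patients: Sequence[PatientRecord],
    controls: Sequence[ControlVariant],
    ontology: PhenotypeOntology,
    spec: NullModelSpec,
    config: RunConfig = RunConfig(),
) -> NullRunResult:
    """Repeat (randomize -> full discovery) ``n_reps`` times.

    Each rep gets an independent child seed derived from ``spec.seed``, so
    the whole result is reproducible bit-for-bit from (spec, config).
    Recorded per rep: the significant-PEL (association) count, and the
    BH-adjusted Fisher p-values below the association threshold.
    """
    genome = dict(spec.genome) or genome_from_data(patients, controls)
    rep_seeds = np.random.default_rng(spec.seed).integers(
        0, 2**31 - 1, size=spec.n_reps
    )
    counts: list[int] = []
    fisher_ps: list[list[float]] = []
    for rep, rep_seed in enumerate(rep_seeds):
        null_patients, null_controls = _randomize(
            spec.kind, patients, controls, genome, int(rep_seed)
        )
        result = run_discovery(null_patients, null_controls, ontology, config)
        significant = result.significant
        counts.append(len(significant))
        fisher_ps.append(sorted(a.p_fisher_bh for a in significant))
    log.info(
        "null %s: %d reps, significant-PEL counts %s",
        spec.kind, spec.n_reps, counts,
    )
    return NullRunResult(
        kind=spec.kind, per_rep_pel_counts=counts, per_rep_fisher_p=fisher_ps
    )


def write_null_summary(results: Sequence[NullRunResult], path) -> None:
    """Null-run summary TSV: kind, rep, n_pels, n_significant."""
    with open(path, "w") as handle:
        handle.write("kind\trep\tn_pels\tn_significant\n")
        for result in results:
            for rep, count in enumerate(result.per_rep_pel_counts):
                handle.write(
                    f"{result.kind}\t{rep}\t{count}\t"
                    f"{len(result.per_rep_fisher_p[rep])}\n"
                )
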