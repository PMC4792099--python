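import statistics

import numpy as np
import pytest

from pelnet.cohort_io import GenomicInterval
from pelnet.pel_discovery import PelAssociation
from pelnet.synthetic_cohort import (
    CohortSpec,
    ImplantSpec,
    default_benchmark_spec,
    evaluate_recovery,
    make_toy_ontology,
    read_truth,
    simulate_cohort,
    write_cohort,
)

SMALL_GENOME = {"1": 50_000_000, "2": 40_000_000}


def _small_spec(**overrides):
    defaults = dict(
        genome=SMALL_GENOME,
        n_patients=30,
        n_controls=20,
        seed=0,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


def _implant(term, n_carriers=10, penetrance=1.0, cls="loss"):
    return ImplantSpec(
        locus=GenomicInterval("1", 10_000_000, 10_500_000),
        cnv_class=cls,
        term_id=term,
        n_carriers=n_carriers,
        penetrance=penetrance,
    )


class TestToyOntology:
    def test_term_counts(self):
        onto = make_toy_ontology(depth=2, branching=3)
        assert len(onto) == 1 + 3 + 9

    def test_depth_one_branching_one_is_a_chain(self):
        onto = make_toy_ontology(depth=1, branching=1)
        assert len(onto) == 2
        (leaf,) = onto.leaves
        assert onto.depth_of(leaf) == 1

    def test_every_leaf_has_depth_many_ancestors(self):
        onto = make_toy_ontology(depth=3, branching=2)
        for leaf in onto.leaves:
            assert len(onto.ancestors(leaf)) == 3


class TestSimulateCohort:
    def test_every_patient_has_a_term_even_without_noise(self, toy_ontology):
        spec = _small_spec(noise_terms_per_patient=0.0)
        patients, _, _ = simulate_cohort(spec, toy_ontology)
        assert len(patients) == 30
        assert all(p.phenotypes for p in patients)
        assert all(p.cnvs for p in patients)

    def test_full_penetrance_implant(self, toy_ontology):
        term = sorted(toy_ontology.leaves)[3]
        spec = _small_spec(
            implants=(_implant(term),), noise_terms_per_patient=0.0
        )
        patients, _, truth = simulate_cohort(spec, toy_ontology)
        (imp,) = truth
        assert len(imp.carriers) == 10
        by_id = {p.patient_id: p for p in patients}
        for carrier in imp.carriers:
            record = by_id[carrier]
            assert term in record.phenotypes
            covering = [
                c for c in record.cnvs
                if c.cnv_class == "loss" and c.interval.contains(imp.locus)
            ]
            assert covering

    def test_truth_row_per_implant(self, toy_ontology):
        terms = sorted(toy_ontology.leaves)[:2]
        spec = _small_spec(
            implants=(_implant(terms[0]), _implant(terms[1], cls="gain"))
        )
        _, _, truth = simulate_cohort(spec, toy_ontology)
        assert [t.implant_id for t in truth] == ["IMP_1", "IMP_2"]

    def test_case_cnvs_longer_than_control_cnvs(self, toy_ontology):
        spec, onto = default_benchmark_spec(seed=5)
        patients, controls, _ = simulate_cohort(spec, onto)
        case_mean = statistics.mean(
            c.interval.length for p in patients for c in p.cnvs
        )
        ctrl_mean = statistics.mean(v.interval.length for v in controls)
        assert case_mean > 10 * ctrl_mean

    def test_unknown_implant_term_errors(self, toy_ontology):
        spec = _small_spec(implants=(_implant("HP:9999999"),))
        with pytest.raises(ValueError, match="HP:9999999"):
            simulate_cohort(spec, toy_ontology)

    def test_locus_must_fit_chromosome(self):
        implant = ImplantSpec(
            locus=GenomicInterval("2", 39_000_000, 41_000_000),
            cnv_class="loss",
            term_id="HP:0000002",
            n_carriers=3,
            penetrance=1.0,
        )
        with pytest.raises(ValueError, match="exceeds chromosome"):
            _small_spec(implants=(implant,))

    def test_term_positive_carriers_are_binomial(self, toy_ontology):
        """Mean count over 200 seeds within 3 SE of n * penetrance."""
        term = sorted(toy_ontology.leaves)[0]
        n, pen = 10, 0.6
        counts = []
        for seed in range(200):
            spec = _small_spec(
                seed=seed,
                noise_terms_per_patient=0.0,
                implants=(_implant(term, n_carriers=n, penetrance=pen),),
            )
            patients, _, truth = simulate_cohort(spec, toy_ontology)
            carriers = set(truth[0].carriers)
            counts.append(
                sum(
                    1 for p in patients
                    if p.patient_id in carriers and term in p.phenotypes
                )
            )
        se = np.sqrt(n * pen * (1 - pen) / len(counts))
        assert abs(statistics.mean(counts) - n * pen) < 3 * se


class TestWriteCohort:
    def test_same_seed_gives_byte_identical_files(self, tmp_path, toy_ontology):
        spec = _small_spec(implants=(_implant(sorted(toy_ontology.leaves)[0]),))
        for sub in ("a", "b"):
            patients, controls, truth = simulate_cohort(spec, toy_ontology)
            write_cohort(
                patients, controls, truth, spec, toy_ontology, tmp_path / sub
            )
        for name in (
            "patient_cnvs.tsv", "patient_phenotypes.tsv", "controls.tsv",
            "ontology.obo", "truth.tsv", "spec.yaml",
        ):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_truth_round_trip(self, tmp_path, toy_ontology):
        spec = _small_spec(implants=(_implant(sorted(toy_ontology.leaves)[0]),))
        patients, controls, truth = simulate_cohort(spec, toy_ontology)
        paths = write_cohort(
            patients, controls, truth, spec, toy_ontology, tmp_path
        )
        assert read_truth(paths["truth"]) == truth


def _assoc(locus, cls, term, significant=True):
    return PelAssociation(
        pel_id="PEL_1", locus=locus, cnv_class=cls, term_id=term,
        term_name=term, k_case=5, n_clique=6, K_case=9, N_case=30,
        m_ctrl=0, N_ctrl=20, p_enrich=1e-6, p_fisher_raw=1e-5,
        p_fisher_bh=1e-4, penetrance_pct=100.0, significant=significant,
    )


class TestEvaluateRecovery:
    def test_empty_associations(self, toy_ontology):
        term = sorted(toy_ontology.leaves)[0]
        spec = _small_spec(implants=(_implant(term),))
        _, _, truth = simulate_cohort(spec, toy_ontology)
        report = evaluate_recovery([], truth, toy_ontology)
        assert report.recall == 0.0
        assert report.precision == 1.0 and report.precision_undefined

    def test_exact_match_recovers(self, toy_ontology):
        term = sorted(toy_ontology.leaves)[0]
        spec = _small_spec(implants=(_implant(term),))
        _, _, truth = simulate_cohort(spec, toy_ontology)
        assoc = _assoc(truth[0].locus, "loss", term)
        report = evaluate_recovery([assoc], truth, toy_ontology)
        assert report.recall == 1.0 and report.precision == 1.0

    def test_ancestor_term_counts_as_recovery(self, toy_ontology):
        term = sorted(toy_ontology.leaves)[0]
        parent = sorted(toy_ontology.ancestors(term))[-1]
        spec = _small_spec(implants=(_implant(term),))
        _, _, truth = simulate_cohort(spec, toy_ontology)
        assoc = _assoc(truth[0].locus, "loss", parent)
        assert evaluate_recovery([assoc], truth, toy_ontology).recall == 1.0

    def test_wrong_class_or_disjoint_locus_does_not_recover(self, toy_ontology):
        term = sorted(toy_ontology.leaves)[0]
        spec = _small_spec(implants=(_implant(term),))
        _, _, truth = simulate_cohort(spec, toy_ontology)
        wrong_class = _assoc(truth[0].locus, "gain", term)
        elsewhere = _assoc(GenomicInterval("2", 0, 100), "loss", term)
        report = evaluate_recovery(
            [wrong_class, elsewhere], truth, toy_ontology
        )
        assert report.recall == 0.0 and report.precision == 0.0

    def test_insignificant_associations_are_ignored(self, toy_ontology):
        term = sorted(toy_ontology.leaves)[0]
        spec = _small_spec(implants=(_implant(term),))
        _, _, truth = simulate_cohort(spec, toy_ontology)
        assoc = _assoc(truth[0].locus, "loss", term, significant=False)
        report = evaluate_recovery([assoc], truth, toy_ontology)
        assert report.recall == 0.0
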