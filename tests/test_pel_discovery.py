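from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from pelnet.cohort_io import CnvRecord, ControlVariant, GenomicInterval, \
    SyndromeRecord
from pelnet.clique_analysis import CliqueLocus
from pelnet.pel_discovery import (
    associate_pels,
    bh_adjust,
    count_control_carriers,
    fisher_exact_greater,
    penetrance,
    syndrome_overlap,
)
from pelnet.phenotype_enrichment import EnrichmentResult, bonferroni, \
    hypergeom_tail

from helpers import bh_adjust_stepup, hypergeom_tail_enum


def _ctrl(chrom, start, end, cls, sample=None):
    return ControlVariant(GenomicInterval(chrom, start, end), cls, sample)


class TestControlCarriers:
    LOCUS = GenomicInterval("1", 250, 300)

    def test_distinct_samples(self):
        controls = [
            _ctrl("1", 100, 260, "loss", "S1"),
            _ctrl("1", 290, 400, "loss", "S2"),
        ]
        assert count_control_carriers(self.LOCUS, "loss", controls) == 2

    def test_same_sample_counts_once(self):
        controls = [
            _ctrl("1", 100, 260, "loss", "S1"),
            _ctrl("1", 290, 400, "loss", "S1"),
        ]
        assert count_control_carriers(self.LOCUS, "loss", controls) == 1

    def test_class_must_match(self):
        controls = [_ctrl("1", 0, 1000, "gain", "S1")]
        assert count_control_carriers(self.LOCUS, "loss", controls) == 0

    def test_records_without_sample_ids_count_individually(self):
        controls = [_ctrl("1", 100, 260, "loss"), _ctrl("1", 290, 400, "loss")]
        assert count_control_carriers(self.LOCUS, "loss", controls) == 2


class TestFisher:
    def test_three_one_one_three(self):
        want = hypergeom_tail_enum(3, 4, 4, 8)
        assert want == Fraction(17, 70)
        assert fisher_exact_greater(3, 1, 1, 3) == pytest.approx(
            float(want), abs=1e-12
        )

    def test_observed_minimum_of_support_gives_one(self):
        assert fisher_exact_greater(0, 5, 5, 0) == 1.0

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            fisher_exact_greater(0, 0, 0, 0)

    @pytest.mark.parametrize("seed", range(4))
    def test_identity_with_hypergeometric_tail(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(0, 8, size=4))
            if a + b + c + d == 0:
                continue
            assert fisher_exact_greater(a, b, c, d) == pytest.approx(
                hypergeom_tail(a, a + b, a + c, a + b + c + d), abs=1e-12
            )

    def test_agrees_with_independent_implementation(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 10, size=4))
            if a + b + c + d == 0:
                continue
            want = scipy_fisher([[a, b], [c, d]], alternative="greater")[1]
            assert fisher_exact_greater(a, b, c, d) == pytest.approx(
                float(want), abs=1e-9
            )


class TestBhAdjust:
    def test_hand_worked_list(self):
        got = bh_adjust([0.005, 0.011, 0.02, 0.04])
        assert got == pytest.approx([0.02, 0.022, 0.0267, 0.04], abs=5e-5)

    def test_monotone_enforcement_collapses_a_linear_ladder(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_is_identity(self):
        assert bh_adjust([0.3]) == [0.3]

    def test_empty_list(self):
        assert bh_adjust([]) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_properties_against_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ps = list(rng.random(12))
        got = bh_adjust(ps)
        assert got == pytest.approx(bh_adjust_stepup(ps), abs=1e-12)
        for p, q in zip(ps, got):
            assert q >= p - 1e-12
            assert q <= bonferroni(p, len(ps)) + 1e-12
        order = np.argsort(ps)
        adjusted_sorted = [got[i] for i in order]
        assert all(
            a <= b + 1e-12 for a, b in zip(adjusted_sorted, adjusted_sorted[1:])
        )


class TestPenetrance:
    @pytest.mark.parametrize("pi", [0.01, 0.05, 0.3])
    def test_no_control_carriers_means_complete_penetrance(self, pi):
        assert penetrance(15, 6564, 0, 5072, pi) == 100.0

    def test_equal_frequencies_reduce_to_prevalence(self):
        assert penetrance(30, 100, 15, 50, 0.3) == pytest.approx(30.0)

    def test_no_case_carriers_is_zero(self):
        assert penetrance(0, 100, 5, 50, 0.05) == 0.0
        assert penetrance(0, 100, 0, 50, 0.05) == 0.0

    def test_prevalence_bounds(self):
        with pytest.raises(ValueError):
            penetrance(1, 10, 1, 10, 0.0)
        with pytest.raises(ValueError):
            penetrance(1, 10, 1, 10, 1.0)

    def test_monotone_in_cases_and_controls(self):
        base = penetrance(5, 100, 5, 100, 0.05)
        assert penetrance(10, 100, 5, 100, 0.05) > base
        assert penetrance(5, 100, 10, 100, 0.05) < base

    def test_published_reduced_penetrance_rows_share_one_prevalence(self):
        """Rows with one control carrier (10/16 -> 30.2, 9/16 -> 28,
        8/13 -> 25.7 at N_case=6564, N_ctrl=5072) are mutually consistent
        with the frequency-ratio estimator under a single prevalence."""

        def solve_pi(k_case, target):
            # invert the estimator: pi/(1-pi) = r*f_ctrl / ((1-r)*f_case)
            r = target / 100.0
            f_case, f_ctrl = k_case / 6564, 1 / 5072
            odds = r * f_ctrl / ((1 - r) * f_case)
            return odds / (1 + odds)

        pis = [solve_pi(10, 30.2), solve_pi(9, 28.0), solve_pi(8, 25.7)]
        assert max(pis) - min(pis) < 0.005
        for k_case, target, pi in zip((10, 9, 8), (30.2, 28.0, 25.7), pis):
            assert penetrance(k_case, 6564, 1, 5072, pi) == pytest.approx(
                target, abs=0.05
            )


def _clique_locus(members, locus, cls="loss"):
    assigned = tuple(
        (
            m,
            CnvRecord(
                m,
                GenomicInterval(locus.chrom, locus.start - 10, locus.end + 10),
                cls,
            ),
        )
        for m in sorted(members)
    )
    return CliqueLocus(frozenset(members), cls, assigned, locus)


def _enrichment(ref, term, k, n, K, N):
    return EnrichmentResult(
        clique_ref=ref, term_id=term, k=k, n=n, K=K, N=N,
        p_raw=1e-6, p_adj=1e-5, n_tests=10,
    )


class TestAssociatePels:
    def test_clean_locus_is_kept_with_full_penetrance(self):
        locus = GenomicInterval("1", 1000, 2000)
        cliques = [_clique_locus(["P1", "P2", "P3", "P4", "P5", "P6"], locus)]
        enrichments = [_enrichment(0, "HP:0000002", 6, 6, 6, 10)]
        controls = [
            _ctrl("2", 0, 10_000, "loss", f"S{i}") for i in range(50)
        ]
        (assoc,) = associate_pels(cliques, enrichments, controls)
        assert assoc.significant
        assert assoc.m_ctrl == 0
        assert assoc.penetrance_pct == 100.0
        assert assoc.pel_id == "PEL_1"

    def test_common_control_locus_is_dropped(self):
        locus = GenomicInterval("1", 1000, 2000)
        cliques = [_clique_locus(["P1", "P2", "P3"], locus)]
        enrichments = [_enrichment(0, "HP:0000002", 3, 3, 5, 10)]
        # 40% of 50 control samples carry the locus
        controls = [
            _ctrl("1", 500, 3000, "loss", f"S{i}") for i in range(20)
        ] + [_ctrl("2", 0, 10, "loss", f"S{i}") for i in range(20, 50)]
        (assoc,) = associate_pels(cliques, enrichments, controls)
        assert not assoc.significant
        assert assoc.m_ctrl == 20
        assert assoc.penetrance_pct < 100.0

    def test_no_enrichments_yield_no_associations(self):
        assert associate_pels([], [], [_ctrl("1", 0, 10, "loss", "S1")]) == []

    def test_ids_follow_significance_then_genomic_order(self):
        l1 = GenomicInterval("1", 1000, 2000)
        l2 = GenomicInterval("2", 1000, 2000)
        cliques = [
            _clique_locus(["P1", "P2", "P3"], l1),
            _clique_locus(["P4", "P5", "P6", "P7"], l2),
        ]
        enrichments = [
            _enrichment(0, "HP:0000002", 3, 3, 6, 20),
            _enrichment(1, "HP:0000003", 4, 4, 6, 20),
        ]
        controls = [_ctrl("3", 0, 10, "loss", f"S{i}") for i in range(30)]
        got = associate_pels(cliques, enrichments, controls)
        # the 4/4 clique has the smaller Fisher p, so it is PEL_1
        by_id = {a.pel_id: a for a in got}
        assert by_id["PEL_1"].term_id == "HP:0000003"
        assert by_id["PEL_2"].term_id == "HP:0000002"


class TestSyndromeOverlap:
    def _assoc(self, pel_id, locus, cls="loss"):
        from pelnet.pel_discovery import PelAssociation

        return PelAssociation(
            pel_id=pel_id, locus=locus, cnv_class=cls, term_id="HP:0000002",
            term_name="t", k_case=3, n_clique=3, K_case=5, N_case=10,
            m_ctrl=0, N_ctrl=50, p_enrich=1e-5, p_fisher_raw=1e-4,
            p_fisher_bh=1e-3, penetrance_pct=100.0, significant=True,
        )

    def test_overlap_and_type_match(self):
        pel = self._assoc("PEL_1", GenomicInterval("1", 100, 300))
        syn = SyndromeRecord("S", GenomicInterval("1", 250, 600), "loss")
        assert syndrome_overlap([pel], [syn]) == {"PEL_1": ["S"]}

    def test_type_mismatch_at_same_coordinates_is_no_match(self):
        pel = self._assoc("PEL_1", GenomicInterval("1", 100, 300))
        syn = SyndromeRecord("S", GenomicInterval("1", 100, 300), "gain")
        assert syndrome_overlap([pel], [syn]) == {"PEL_1": []}

    def test_empty_catalogue_flags_all_novel(self):
        pels = [
            self._assoc("PEL_1", GenomicInterval("1", 100, 300)),
            self._assoc("PEL_2", GenomicInterval("2", 100, 300)),
        ]
        assert syndrome_overlap(pels, []) == {"PEL_1": [], "PEL_2": []}
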