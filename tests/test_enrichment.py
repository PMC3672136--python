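"""Exclusive partitioning and Fisher's-exact reassignment."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from conftest import make_profile
from specsort.enrichment import (
    ContingencyTable,
    classify_exclusive,
    filter_printed_pvalues,
    fisher_exact_two_sided,
    format_pvalue,
    reassign_shared,
    results_to_frame,
    venn_shared_count,
)


def brute_force_fisher(a, b, c, d):
    """Exact-rational enumeration of every table with the observed margins."""
    row, col, total = a + b, a + c, a + b + c + d
    denom = comb(total, row)
    p_obs = Fraction(comb(col, a) * comb(total - col, row - a), denom)
    p = Fraction(0)
    for k in range(max(0, row - (total - col)), min(row, col) + 1):
        pk = Fraction(comb(col, k) * comb(total - col, row - k), denom)
        if pk <= p_obs:
            p += pk
    return float(p)


class TestClassifyExclusive:
    def test_zero_nsc_is_hc_only(self):
        summary, cats = classify_exclusive([make_profile("P", hc=5, nsc=0)])
        assert cats["P"] == "HC_ONLY"
        assert summary.n_HC_only == 1

    def test_both_nonzero_is_shared(self):
        _, cats = classify_exclusive([make_profile("P", hc=3, nsc=11)])
        assert cats["P"] == "SHARED"

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="zero counts"):
            classify_exclusive([make_profile("P")])

    def test_summary_totals(self):
        profiles = [
            make_profile("A", hc=1), make_profile("B", nsc=1),
            make_profile("C", hc=2, nsc=2), make_profile("D", nsc=9),
        ]
        summary, _ = classify_exclusive(profiles)
        assert (summary.n_HC_only, summary.n_NSC_only, summary.n_shared) == (1, 2, 1)
        assert summary.n_total == 4


class TestFisherExact:
    def test_perfect_symmetry_gives_one(self):
        assert fisher_exact_two_sided(ContingencyTable(5, 5, 95, 95)) == 1.0

    def test_three_vs_zero(self):
        # tables with margins (3,3)/(3,3): only a=0 and a=3 are as unlikely
        p = fisher_exact_two_sided(ContingencyTable(3, 0, 0, 3))
        assert p == pytest.approx(0.1, rel=1e-9)

    def test_matches_brute_force_on_example(self):
        p = fisher_exact_two_sided(ContingencyTable(10, 0, 40, 50))
        assert p == pytest.approx(brute_force_fisher(10, 0, 40, 50), rel=1e-7)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            ours = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
            theirs = scipy_fisher([[a, b], [c, d]], alternative="two-sided")[1]
            assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-12)

    def test_small_margin_sweep_matches_enumeration(self):
        for th in range(8):
            for tn in range(8):
                for a in range(th + 1):
                    for b in range(tn + 1):
                        ours = fisher_exact_two_sided(
                            ContingencyTable(a, b, th - a, tn - b))
                        oracle = brute_force_fisher(a, b, th - a, tn - b)
                        assert ours == pytest.approx(oracle, rel=1e-7, abs=1e-12)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
            assert fisher_exact_two_sided(ContingencyTable(a, b, c, d)) == \
                pytest.approx(
                    fisher_exact_two_sided(ContingencyTable(b, a, d, c)),
                    rel=1e-9, abs=1e-12)

    def test_monotone_in_count_asymmetry(self):
        # fixed margins, fixed row total: p never increases as the split
        # moves away from proportionality
        th = tn = 50
        row = 20
        balanced = row // 2
        last = None
        for a in range(balanced, row + 1):
            b = row - a
            p = fisher_exact_two_sided(ContingencyTable(a, b, th - a, tn - b))
            if last is not None:
                assert p <= last + 1e-12
            last = p

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 5, 5)

    def test_double_tail_alternative(self):
        p_min = fisher_exact_two_sided(ContingencyTable(8, 1, 42, 49))
        p_dbl = fisher_exact_two_sided(ContingencyTable(8, 1, 42, 49),
                                       method="double_tail")
        assert 0 < p_min <= 1 and 0 < p_dbl <= 1


class TestReassignShared:
    def test_strongly_enriched_protein_detected(self):
        profiles = [make_profile("HOT", hc=100, nsc=2),
                    make_profile("BG", hc=4900, nsc=4998)]
        results = reassign_shared(profiles, margins=(5000, 5000), alpha=0.05)
        hot = next(r for r in results if r.accession == "HOT")
        assert hot.category == "HC_ENRICHED"
        assert hot.direction == "HC"
        assert hot.p_value < 0.05

    def test_balanced_protein_unresolved(self):
        profiles = [make_profile("EQ", hc=50, nsc=50),
                    make_profile("BG", hc=4950, nsc=4950)]
        (eq, _) = reassign_shared(profiles, margins=(5000, 5000))
        assert eq.category == "SHARED_UNRESOLVED"
        assert eq.direction == "none"

    def test_exclusive_proteins_pass_through_untested(self):
        results = reassign_shared([make_profile("X", hc=9)], margins=(9, 0))
        assert results[0].category == "HC_ONLY"
        assert results[0].table is None

    def test_margins_smaller_than_counts_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            reassign_shared([make_profile("P", hc=10, nsc=1)], margins=(5, 5))

    def test_default_margins_are_totals(self):
        profiles = [make_profile("A", hc=30, nsc=1),
                    make_profile("B", hc=10, nsc=40)]
        explicit = reassign_shared(profiles, margins=(40, 41))
        default = reassign_shared(profiles)
        assert [(r.category, r.p_value) for r in explicit] == [
            (r.category, r.p_value) for r in default
        ]


class TestVenn:
    def test_reported_overlap(self):
        assert venn_shared_count(634, 64, 103) == 467

    def test_zero_shared(self):
        assert venn_shared_count(10, 10, 0) == 0

    def test_generic(self):
        assert venn_shared_count(100, 30, 30) == 40

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            venn_shared_count(10, 8, 8)


class TestPrintedPValues:
    def test_rounded_boundary_value_passes(self):
        assert filter_printed_pvalues([0.05], alpha=0.05).tolist() == [True]

    def test_above_alpha_fails(self):
        assert filter_printed_pvalues([0.051], alpha=0.05).tolist() == [False]

    def test_formatting(self):
        assert format_pvalue(7.912e-26) == "7.9e-26"
        assert format_pvalue(1e-310) == "0"
        assert format_pvalue(0.023) == "0.023"


class TestResultsFrame:
    def test_bh_column_is_informational(self):
        profiles = [make_profile("A", hc=40, nsc=2),
                    make_profile("B", hc=500, nsc=510)]
        frame = results_to_frame(reassign_shared(profiles))
        assert "q_value_bh" in frame.columns
        assert (frame["q_value_bh"] >= frame["p_value"] - 1e-12).all()
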