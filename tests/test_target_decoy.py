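"""Decoy construction, FDR estimation, and the filter cascade."""

import numpy as np
import pytest

from specsort.synthetic_data import generate_database, generate_psms
from specsort.target_decoy import (
    PSM,
    FilterPolicy,
    UnsatisfiableFDR,
    apply_filter_policy,
    build_decoy_database,
    estimate_fdr,
    threshold_for_fdr,
)


def psm(sid, score, proteins, peptide="PEPTIDEK", group="HC", exp=1):
    return PSM(
        spectrum_id=sid, experiment_id=exp, group=group, fraction=1,
        peptide=peptide, mods=(), charge=2, experimental_mz=500.0,
        score=score, proteins=tuple(proteins),
    )


class TestDecoyDatabase:
    def test_reversal(self):
        out = build_decoy_database({"P1": "MKLV"})
        assert out == {"P1": "MKLV", "REV_P1": "VLKM"}

    def test_palindrome_keeps_distinct_accession(self):
        out = build_decoy_database({"P1": "ABA"})
        assert out["REV_P1"] == "ABA"
        assert set(out) == {"P1", "REV_P1"}

    def test_doubles_record_count(self):
        targets = {f"P{i}": "MKLVAG" for i in range(634)}
        assert len(build_decoy_database(targets)) == 1268

    def test_decoy_prefixed_input_rejected(self):
        with pytest.raises(ValueError, match="REV_"):
            build_decoy_database({"REV_P1": "MKLV"})

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_decoy_database({})


class TestEstimateFdr:
    def test_two_decoys_in_hundred(self):
        hits = [(10.0, False)] * 98 + [(10.0, True)] * 2
        assert estimate_fdr(hits, 5.0) == pytest.approx(0.04)

    def test_no_decoys(self):
        assert estimate_fdr([(3.0, False)], 1.0) == 0.0

    def test_all_decoys_capped_at_one(self):
        assert estimate_fdr([(3.0, True), (4.0, True)], 1.0) == 1.0

    def test_nothing_above_threshold(self):
        assert estimate_fdr([(1.0, False)], 5.0) == 0.0

    def test_decoy_ratio_option(self):
        hits = [(10.0, False)] * 50 + [(10.0, True)] * 5
        assert estimate_fdr(hits, 5.0, estimator="decoy_ratio") == pytest.approx(0.1)

    def test_label_swap_symmetry(self):
        # With Bernoulli(1/2) labels, swapping labels leaves the estimator's
        # distribution unchanged; check the paired means agree.
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(200):
            scores = rng.normal(size=40)
            labels = rng.random(40) < 0.5
            hits = list(zip(scores, labels))
            flipped = list(zip(scores, ~labels))
            thr = float(np.median(scores))
            diffs.append(estimate_fdr(hits, thr) - estimate_fdr(flipped, thr))
        assert abs(np.mean(diffs)) < 0.05


class TestThresholdForFdr:
    def test_excludes_both_decoys(self):
        hits = [(1.0, True), (2.0, True)] + [(float(s), False) for s in range(3, 101)]
        thr = threshold_for_fdr(hits, 0.01)
        assert thr > 2.0
        assert estimate_fdr(hits, thr) <= 0.01

    def test_permissive_limit_retains_everything(self):
        hits = [(1.0, True), (2.0, False), (3.0, False)]
        thr = threshold_for_fdr(hits, 1.0)
        assert thr == 1.0

    def test_single_target_retained(self):
        assert threshold_for_fdr([(5.0, False)], 0.01) == 5.0

    def test_unsatisfiable_raises(self):
        with pytest.raises(UnsatisfiableFDR):
            threshold_for_fdr([(5.0, True), (4.0, True)], 0.01)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(5, 60))
            hits = [
                (float(rng.normal(2 if rng.random() > 0.3 else 0, 1)),
                 bool(rng.random() < 0.3))
                for _ in range(n)
            ]
            for fdr_max in (0.0, 0.05, 0.2, 0.5, 1.0):
                qualifying = [
                    s for s in {h[0] for h in hits}
                    if estimate_fdr(hits, s) <= fdr_max
                ]
                if not qualifying:
                    with pytest.raises(UnsatisfiableFDR):
                        threshold_for_fdr(hits, fdr_max)
                else:
                    assert threshold_for_fdr(hits, fdr_max) == min(qualifying)

    def test_retention_monotone_in_fdr_max(self):
        rng = np.random.default_rng(3)
        hits = [
            (float(rng.normal()), bool(rng.random() < 0.4)) for _ in range(200)
        ]
        retained = []
        for fdr_max in (0.05, 0.1, 0.3, 0.6, 1.0):
            try:
                thr = threshold_for_fdr(hits, fdr_max)
                retained.append(sum(1 for s, _ in hits if s >= thr))
            except UnsatisfiableFDR:
                retained.append(0)
        assert retained == sorted(retained)


class TestApplyFilterPolicy:
    def test_single_peptide_protein_excluded(self):
        psms = [
            psm("s1", 9.0, ["A"], peptide="AAAAK"),
            psm("s2", 8.0, ["B"], peptide="CCCCK"),
            psm("s3", 7.0, ["B"], peptide="DDDDK"),
        ]
        out = apply_filter_policy(psms, FilterPolicy(1.0, 1.0, 1.0, 2))
        assert set(out.proteins) == {"B"}

    def test_all_target_input_has_zero_fdr(self):
        psms = [psm(f"s{i}", float(i), ["A"], peptide=f"PEP{i}K") for i in range(1, 6)]
        out = apply_filter_policy(psms, FilterPolicy(0.05, 0.01, 0.03, 2))
        assert out.achieved_psm_fdr == 0.0
        assert out.achieved_peptide_fdr == 0.0
        assert out.achieved_protein_fdr == 0.0
        assert out.n_psms == 5

    def test_empty_input_is_graceful(self):
        out = apply_filter_policy([], FilterPolicy())
        assert out.n_psms == 0
        assert out.diagnostics

    def test_unsatisfiable_policy_is_diagnosed_not_raised(self):
        psms = [psm("s1", 5.0, ["REV_A"], peptide="AAAAK"),
                psm("s2", 4.0, ["REV_A"], peptide="CCCCK")]
        out = apply_filter_policy(psms, FilterPolicy(0.01, 0.01, 0.01, 1))
        assert out.n_psms == 0
        assert any("unsatisfiable" in d for d in out.diagnostics)

    def test_decoys_absent_from_final_report(self, small_config, small_database):
        psms, _ = generate_psms(small_config, small_database)
        out = apply_filter_policy(psms, FilterPolicy())
        assert not any(p.is_decoy for p in out.psms)
        assert not any(acc.startswith("REV_") for acc in out.proteins)

    def test_every_retained_protein_has_min_peptides(self, small_config,
                                                     small_database):
        psms, _ = generate_psms(small_config, small_database)
        out = apply_filter_policy(psms, FilterPolicy(min_peptides_per_protein=2))
        for group in out.proteins.values():
            assert group.n_peptides >= 2

    def test_realized_fdp_bounded_on_labelled_benchmark(self):
        # Clean 5,000-PSM benchmark with known per-PSM labels: the realized
        # false-discovery proportion among retained target PSMs stays within
        # twice the policy maximum.
        from specsort.synthetic_data import SyntheticConfig

        cfg = SyntheticConfig(psms_per_run=2500, n_runs_per_group=1,
                              contamination_epsilon=0.0, seed=5)
        db = generate_database(cfg)
        psms, truth = generate_psms(cfg, db)
        policy = FilterPolicy(psm_fdr_max=0.05)
        out = apply_filter_policy(psms, policy)
        assert out.n_psms > 1000
        wrong = sum(1 for p in out.psms if not truth.psm_correct[p.spectrum_id])
        assert wrong / out.n_psms <= 2 * policy.psm_fdr_max
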