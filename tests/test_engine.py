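"""Anchor detection, geminal/stereo bookkeeping, propagation, coverage."""

import numpy as np
import pytest

from methylassign.engine import (AssignmentState, EvidenceWeights, Peak,
                                 PeakList, coverage_percentage,
                                 coverage_report, detect_anchor, pair_geminal,
                                 propagate_assignments, stereo_assign,
                                 tag_minor_forms)
from methylassign.synthetic import (add_minor_form, generate_constellation,
                                    run_recovery, simulate_dataset,
                                    simulate_mutant, simulate_peaklist)


class TestAssignmentState:
    def test_injectivity_enforced(self):
        state = AssignmentState()
        state.assign("L1-QD1", "pk1", 0.9, ["anchor"])
        with pytest.raises(ValueError):
            state.assign("L1-QD1", "pk2", 0.9, ["anchor"])
        with pytest.raises(ValueError):
            state.assign("L1-QD2", "pk1", 0.9, ["anchor"])

    def test_confidence_bounds(self):
        state = AssignmentState()
        with pytest.raises(ValueError):
            state.assign("L1-QD1", "pk1", 1.5, [])


class TestDetectAnchor:
    def _lists(self, scheme="LV[rac]"):
        wt = PeakList("wt", scheme, [Peak("p1", 0.5, 22.0),
                                     Peak("p2", 0.9, 24.0),
                                     Peak("p3", 0.7, 23.0)])
        mut = PeakList("mut", scheme, [Peak("q1", 0.7, 23.0)])
        return wt, mut

    def test_identical_lists_give_no_candidates(self):
        wt, _ = self._lists()
        result = detect_anchor(wt, wt, "A", 10, "LEU")
        assert result.candidate_peak_ids == []
        assert result.status == "deficit"

    def test_two_deleted_leucine_peaks_found(self):
        wt, mut = self._lists()
        result = detect_anchor(wt, mut, "A", 10, "LEU")
        assert sorted(result.candidate_peak_ids) == ["p1", "p2"]
        assert result.status == "ok"

    def test_surplus_flagged_not_resolved(self):
        wt, mut = self._lists()
        result = detect_anchor(wt, mut, "A", 10, "VAL")  # VAL expects 2 too
        assert result.status == "ok"
        result = detect_anchor(wt, PeakList("m", "LV[rac]", []), "A", 10,
                               "LEU")
        assert result.status == "surplus"
        assert len(result.candidate_peak_ids) == 3

    def test_scheme_incompatible_with_residue(self):
        wt, mut = self._lists("LV[rac]")
        with pytest.raises(ValueError, match="invisible"):
            detect_anchor(wt, mut, "A", 10, "ILE")

    def test_differing_schemes_rejected(self):
        wt, _ = self._lists("LV[rac]")
        mut = PeakList("m", "ILV[rac]", [])
        with pytest.raises(ValueError, match="differ"):
            detect_anchor(wt, mut, "A", 10, "LEU")

    def test_reorder_invariant(self):
        wt, mut = self._lists()
        shuffled = PeakList("wt2", "LV[rac]", list(reversed(wt.peaks)))
        r1 = detect_anchor(wt, mut, "A", 10, "LEU")
        r2 = detect_anchor(shuffled, mut, "A", 10, "LEU")
        assert sorted(r1.candidate_peak_ids) == sorted(r2.candidate_peak_ids)

    def test_monte_carlo_recovery_rate(self):
        # ~100-peak lists, one Leu deleted, jitter 0.005/0.05 ppm,
        # tolerances 0.02/0.2: correct pair found in >= 95% of 100 seeds
        _, truth = generate_constellation(n_ile=10, n_leu=30, n_val=12,
                                          n_met=6, seed=99)
        leu = next(m.residue_number for m in truth.methyls
                   if m.residue_type == "LEU")
        expected = {truth.assignment[m.id] for m in truth.methyls
                    if m.residue_number == leu}
        hits = 0
        for seed in range(100):
            wt = simulate_peaklist(truth, 0.0, 0.0, seed=seed,
                                   scheme="IMLV[rac]")
            mut_clean = simulate_mutant(truth, wt, leu)
            jittered = PeakList(mut_clean.spectrum_id, mut_clean.scheme, [
                Peak(p.id,
                     p.dh + np.random.default_rng(seed * 7 + 1).normal(0, 0.005),
                     p.dc + np.random.default_rng(seed * 7 + 2).normal(0, 0.05),
                     p.intensity) for p in mut_clean.peaks])
            result = detect_anchor(wt, jittered, "A", leu, "LEU",
                                   tol_h=0.02, tol_c=0.2)
            if set(result.candidate_peak_ids) == expected:
                hits += 1
        assert hits >= 95


class TestPairGeminal:
    def test_empty_table(self):
        assert pair_geminal([]) == []

    def test_three_disjoint_pairs(self):
        out = pair_geminal([("p1", "p2"), ("p3", "p4"), ("p5", "p6")])
        assert len(out) == 3

    def test_conflicting_pair_rejected(self):
        with pytest.raises(ValueError, match="two geminal pairs"):
            pair_geminal([("p1", "p2"), ("p2", "p3")])

    def test_degenerate_pair_rejected(self):
        with pytest.raises(ValueError):
            pair_geminal([("p1", "p1")])


class TestStereoAssign:
    def _state_and_peaks(self, swap=False):
        state = AssignmentState()
        peaks = {"p1": Peak("p1", 0.50, 22.0), "p2": Peak("p2", 0.90, 24.0)}
        if swap:  # wrong orientation: pro-S peak on the pro-R methyl id
            state.assign("L1-QD1", "p2", 0.8, ["noe"])
            state.assign("L1-QD2", "p1", 0.8, ["noe"])
        else:
            state.assign("L1-QD1", "p1", 0.8, ["noe"])
            state.assign("L1-QD2", "p2", 0.8, ["noe"])
        return state, peaks

    def _stereo_lists(self, include=True):
        pro_r = PeakList("r", "LV[pro-R]",
                         [Peak("r1", 0.50, 22.0)] if include else [])
        pro_s = PeakList("s", "MV[pro-S]", [])
        return pro_s, pro_r

    def test_pro_r_member_labelled(self):
        state, peaks = self._state_and_peaks()
        pro_s, pro_r = self._stereo_lists()
        report = stereo_assign(state, peaks, [frozenset(("p1", "p2"))],
                               pro_s, pro_r)
        assert report.resolved and not report.conflicts
        assert state.assignments["L1-QD1"] == "p1"

    def test_wrong_orientation_swapped(self):
        state, peaks = self._state_and_peaks(swap=True)
        pro_s, pro_r = self._stereo_lists()
        stereo_assign(state, peaks, [frozenset(("p1", "p2"))], pro_s, pro_r)
        assert state.assignments["L1-QD1"] == "p1"
        assert state.assignments["L1-QD2"] == "p2"
        assert "stereo" in state.evidence["L1-QD1"]

    def test_no_match_stays_ambiguous(self):
        state, peaks = self._state_and_peaks()
        pro_s, pro_r = self._stereo_lists(include=False)
        report = stereo_assign(state, peaks, [frozenset(("p1", "p2"))],
                               pro_s, pro_r)
        assert report.ambiguous
        assert frozenset(("L1-QD1", "L1-QD2")) in state.stereo_ambiguous

    def test_both_matching_same_list_is_conflict(self):
        state, peaks = self._state_and_peaks()
        pro_r = PeakList("r", "LV[pro-R]", [Peak("r1", 0.50, 22.0),
                                            Peak("r2", 0.90, 24.0)])
        report = stereo_assign(state, peaks, [frozenset(("p1", "p2"))],
                               PeakList("s", "MV[pro-S]", []), pro_r)
        assert report.conflicts

    def test_full_synthetic_stereo_resolution(self):
        ds = simulate_dataset(seed=21)
        correct, assigned, total = run_recovery(ds)
        assert correct == assigned == total
        # every Leu/Val methyl ends on the stereochemically correct peak
        for m in ds.truth.methyls:
            if m.residue_type in ("LEU", "VAL"):
                assert ds.truth.assignment[m.id] is not None


class TestPropagation:
    def test_noise_free_full_recovery(self, noise_free_dataset):
        correct, assigned, total = run_recovery(noise_free_dataset)
        assert correct == assigned == total

    def test_no_evidence_leaves_only_anchors(self, noise_free_dataset):
        ds = noise_free_dataset
        state = propagate_assignments(ds.anchors, ds.truth.methyls,
                                      ds.peaklist, [], [], [], [])
        assert state.assignments == ds.anchors

    def test_empty_anchor_set_rejected(self, noise_free_dataset):
        ds = noise_free_dataset
        with pytest.raises(ValueError):
            propagate_assignments({}, ds.truth.methyls, ds.peaklist,
                                  ds.contacts, ds.noe_peaks,
                                  ds.merged_predictions)

    def test_idempotent_on_own_output(self, noise_free_dataset):
        ds = noise_free_dataset
        state = propagate_assignments(
            ds.anchors, ds.truth.methyls, ds.peaklist, ds.contacts,
            ds.noe_peaks, ds.merged_predictions, ds.pre_evidence,
            geminal_constraints=ds.geminal_pairs)
        again = propagate_assignments(
            dict(state.assignments), ds.truth.methyls, ds.peaklist,
            ds.contacts, ds.noe_peaks, ds.merged_predictions,
            ds.pre_evidence, geminal_constraints=ds.geminal_pairs)
        assert again.assignments == state.assignments

    def test_injective_and_evidence_recorded(self, noise_free_dataset):
        ds = noise_free_dataset
        state = propagate_assignments(
            ds.anchors, ds.truth.methyls, ds.peaklist, ds.contacts,
            ds.noe_peaks, ds.merged_predictions, ds.pre_evidence,
            geminal_constraints=ds.geminal_pairs)
        state.check_injective()
        non_anchor = [m for m in state.assignments if m not in ds.anchors]
        assert non_anchor
        for mid in non_anchor:
            assert state.evidence[mid]
            assert 0.0 <= state.confidence[mid] <= 1.0

    def test_weights_influence_scoring(self, noise_free_dataset):
        ds = noise_free_dataset
        only_shift = EvidenceWeights(noe=0.0, shift=1.0, pre=0.0)
        state = propagate_assignments(
            ds.anchors, ds.truth.methyls, ds.peaklist, ds.contacts,
            ds.noe_peaks, ds.merged_predictions, ds.pre_evidence,
            geminal_constraints=ds.geminal_pairs, weights=only_shift)
        correct = sum(1 for m, p in state.assignments.items()
                      if ds.truth.assignment[m] == p)
        assert correct == len(state.assignments)  # exact predictions suffice


class TestMinorForms:
    def test_nothing_unassigned_nothing_flagged(self):
        state = AssignmentState()
        state.assign("M1-QE", "p1", 1.0, ["anchor"])
        pl = PeakList("s", "IMLV[rac]", [Peak("p1", 2.0, 17.0)])
        assert tag_minor_forms(pl, state).links == {}

    def test_carbon_displaced_duplicate_linked(self):
        # an unassigned peak sharing dH with an assigned methyl peak but
        # offset 0.5 ppm in dC is flagged and linked to that methyl
        state = AssignmentState()
        state.assign("M508-QE", "p1", 1.0, ["anchor"])
        pl = PeakList("s", "IMLV[rac]", [Peak("p1", 2.0, 17.0),
                                         Peak("x", 2.0, 17.5)])
        report = tag_minor_forms(pl, state)
        assert report.links == {"x": "M508-QE"}
        assert pl.by_id["x"].form == "minor"

    def test_proton_displaced_peak_not_flagged(self):
        state = AssignmentState()
        state.assign("M1-QE", "p1", 1.0, ["anchor"])
        pl = PeakList("s", "IMLV[rac]", [Peak("p1", 2.0, 17.0),
                                         Peak("x", 2.4, 17.5)])
        assert tag_minor_forms(pl, state).links == {}

    def test_synthetic_minor_duplicates_all_flagged(self):
        _, truth = generate_constellation(seed=5)
        add_minor_form(truth, fraction=0.1, seed=5)
        assert truth.minor_offsets
        peaklist = simulate_peaklist(truth, seed=5)
        state = AssignmentState()
        for mid, pid in truth.assignment.items():
            state.assign(mid, pid, 1.0, ["anchor"])
        report = tag_minor_forms(peaklist, state)
        expected = {f"{truth.assignment[mid]}-minor"
                    for mid in truth.minor_offsets}
        assert set(report.links) == expected
        for pid, mid in report.links.items():
            assert pid == f"{truth.assignment[mid]}-minor"
        majors = {p for p in truth.assignment.values()}
        assert not majors & set(report.links)


class TestCoverage:
    def test_printed_coverage_arithmetic(self):
        assert coverage_percentage(224, 243) == 92

    def test_extremes(self):
        assert coverage_percentage(0, 243) == 0
        assert coverage_percentage(243, 243) == 100

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            coverage_percentage(5, 0)
        with pytest.raises(ValueError):
            coverage_percentage(10, 5)

    def test_per_type_report(self):
        _, truth = generate_constellation(n_ile=3, n_leu=2, n_val=1,
                                          n_met=2, seed=8)
        state = AssignmentState()
        for m in truth.methyls:
            if m.residue_type != "VAL":
                state.assign(m.id, truth.assignment[m.id], 1.0, ["anchor"])
        report = coverage_report(state, truth.methyls)
        assert report.per_type["ILE"] == (3, 3)
        assert report.per_type["LEU"] == (4, 4)
        assert report.per_type["VAL"] == (0, 2)
        assert report.per_type["MET"] == (2, 2)
        assert report.assigned == 9
        assert report.total == 11
        assert report.percentage == coverage_percentage(9, 11)
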