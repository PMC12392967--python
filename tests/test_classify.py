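"""Event-to-guide assignment, excision detection and sample statistics."""

import numpy as np
import pytest

from ampedit.align import IndelEvent
from ampedit.classify import (
    ClassifiedEdit,
    apply_display_threshold,
    assign_events,
    detect_excision,
    excision_frequency_by_type,
    sample_statistics,
)
from ampedit.guides import CutWindow, GuideSite
from ampedit.refdb import Amp, AmpSet, ReferenceAmp


def make_site(guide, cut, lo, hi, ref_id="R"):
    return GuideSite(
        guide_name=guide, ref_id=ref_id, strand="+",
        protospacer_start=max(0, lo - 20), protospacer_end=max(0, lo),
        pam_start=hi, pam_end=hi + 3, mismatches=0, seed_perfect=True,
        cut_window=CutWindow(expected_cut=cut, window_start=lo, window_end=hi),
    )


REF = ReferenceAmp(
    id="R", sequence="ACGT" * 100, baseline_abundance=1.0, alpha_type=7,
    epitope_region=(70, 196),
)
SITE_A = make_site("gA", 67, 61, 72)
SITE_B = make_site("gB", 196, 190, 201)
SITES = [SITE_A, SITE_B]


def make_edit(events, count=1, ref=REF):
    edit = ClassifiedEdit(
        amp=Amp("ACGT", count=count), reference=ref, alignment=None,
        events=list(events),
    )
    edit.guide_assignments = assign_events(edit.events, SITES)
    return detect_excision(edit, SITES)


class TestAssignEvents:
    def test_overlapping_deletion_assigned(self):
        events = [IndelEvent("deletion", 60, 36)]
        assert assign_events(events, SITES) == {0: ["gA"]}

    def test_disjoint_insertion_unassigned(self):
        events = [IndelEvent("insertion", 120, 3, "AAA")]
        assert assign_events(events, SITES) == {}

    def test_brute_force_interval_overlap(self):
        """Assignments equal an exhaustive overlap test on random events."""
        rng = np.random.default_rng(29)
        sites = [
            make_site(f"g{k}", c + 5, c, c + 11)
            for k, c in enumerate(rng.integers(0, 350, size=6))
        ]
        for _ in range(300):
            pos = int(rng.integers(0, 380))
            if rng.random() < 0.5:
                ev = IndelEvent("deletion", pos, int(rng.integers(1, 40)))
            else:
                ev = IndelEvent("insertion", pos, 3, "AAA")
            got = assign_events([ev], sites).get(0, [])
            expected = []
            for s in sites:
                w = s.cut_window
                if ev.kind == "deletion":
                    ok = any(
                        w.window_start <= p < w.window_end
                        for p in range(ev.ref_pos, ev.ref_pos + ev.length)
                    )
                else:
                    ok = w.window_start <= ev.ref_pos <= w.window_end
                if ok:
                    expected.append(s.guide_name)
            assert got == expected


class TestDetectExcision:
    def test_cut_to_cut_deletion_is_in_frame_excision(self):
        edit = make_edit([IndelEvent("deletion", 67, 129)])
        assert edit.category == "multi_guide_excision"
        assert edit.excised_span == (67, 196)
        assert edit.frame_status == "in_frame"  # 129 ≡ 0 (mod 3)

    def test_two_separate_deletions_not_an_excision(self):
        edit = make_edit(
            [IndelEvent("deletion", 65, 4), IndelEvent("deletion", 193, 5)]
        )
        assert edit.category == "single_guide_indel"
        assert edit.excised_span is None
        assert edit.frame_status == "in_frame"  # net -9

    def test_frameshift_from_net_length(self):
        edit = make_edit(
            [IndelEvent("deletion", 67, 129), IndelEvent("insertion", 67, 1, "A")]
        )
        assert edit.category == "multi_guide_excision"
        assert edit.frame_status == "frameshift"  # net -128

    def test_three_cut_cas12a_style_excision(self):
        sites = SITES + [make_site("gC", 130, 125, 136)]
        edit = ClassifiedEdit(
            amp=Amp("ACGT", 1), reference=REF, alignment=None,
            events=[IndelEvent("deletion", 67, 129)],
        )
        edit.guide_assignments = assign_events(edit.events, sites)
        detect_excision(edit, sites)
        assert edit.category == "multi_guide_excision"
        lo, hi = edit.excised_span
        covered = [
            s.guide_name for s in sites
            if lo <= s.cut_window.expected_cut <= hi
        ]
        assert covered == ["gA", "gB", "gC"]

    def test_unassigned_indel_category(self):
        edit = make_edit([IndelEvent("deletion", 120, 3)])
        assert edit.category == "unassigned_indel"
        assert not edit.is_edited


def make_ampset(edits):
    return AmpSet(
        [e.amp for e in edits],
        total_reads=sum(e.amp.count for e in edits),
    )


PERFECT = {"R": ["gA", "gB"]}


class TestSampleStatistics:
    def test_all_wild_type(self):
        edits = [make_edit([], count=10) for _ in range(3)]
        report = sample_statistics(edits, make_ampset(edits), PERFECT)
        assert report.editing_pct == 0
        assert report.indel_spectrum == {}
        assert report.per_guide_efficiency == {"gA": 0.0, "gB": 0.0}

    def test_excision_fixture_arithmetic(self):
        """742 abundance units excised vs 258 wild-type -> 74.2% editing and
        a single -129 spectrum line."""
        excised = make_edit([IndelEvent("deletion", 67, 129)], count=742)
        wt = make_edit([], count=258)
        edits = [excised, wt]
        report = sample_statistics(edits, make_ampset(edits), PERFECT)
        assert report.editing_pct == pytest.approx(74.2)
        assert report.deletions_pct == pytest.approx(74.2)
        assert report.indel_spectrum == {-129: pytest.approx(100.0)}
        # the excision covers both cuts, so both guides are fully efficient
        assert report.per_guide_efficiency == {
            "gA": pytest.approx(74.2), "gB": pytest.approx(74.2)
        }
        by_type = excision_frequency_by_type(edits, None)
        assert by_type == {7: pytest.approx(74.2)}

    def test_deletion_plus_insertion_counts_once_in_editing(self):
        both = make_edit(
            [IndelEvent("deletion", 65, 4), IndelEvent("insertion", 196, 2, "AT")],
            count=50,
        )
        wt = make_edit([], count=50)
        edits = [both, wt]
        report = sample_statistics(edits, make_ampset(edits), PERFECT)
        assert report.editing_pct == pytest.approx(50.0)
        assert report.deletions_pct == pytest.approx(50.0)
        assert report.insertions_pct == pytest.approx(50.0)
        assert report.deletions_pct + report.insertions_pct > report.editing_pct

    def test_editing_bounds_invariant(self):
        rng = np.random.default_rng(5)
        edits = []
        for _ in range(30):
            events = []
            if rng.random() < 0.4:
                events.append(IndelEvent("deletion", 65, int(rng.integers(1, 10))))
            if rng.random() < 0.4:
                events.append(IndelEvent("insertion", 196, 2, "AT"))
            edits.append(make_edit(events, count=int(rng.integers(1, 20))))
        report = sample_statistics(edits, make_ampset(edits), PERFECT)
        assert max(report.deletions_pct, report.insertions_pct) <= report.editing_pct
        assert report.editing_pct <= report.deletions_pct + report.insertions_pct

    def test_spectrum_sums_to_100_and_scales(self):
        edits = [
            make_edit([IndelEvent("deletion", 67, 129)], count=3),
            make_edit([IndelEvent("deletion", 65, 4)], count=5),
            make_edit([IndelEvent("insertion", 196, 2, "AT")], count=2),
        ]
        report = sample_statistics(edits, make_ampset(edits), PERFECT)
        assert sum(report.indel_spectrum.values()) == pytest.approx(100.0, abs=1e-6)
        doubled = [
            make_edit(list(e.events), count=2 * e.amp.count) for e in edits
        ]
        report2 = sample_statistics(doubled, make_ampset(doubled), PERFECT)
        assert report2.indel_spectrum == pytest.approx(report.indel_spectrum)

    def test_zero_family_abundance(self):
        report = sample_statistics([], AmpSet([], total_reads=0), PERFECT)
        assert report.editing_pct is None

    def test_display_threshold_formatting_only(self):
        spectrum = {-36: 99.6, 1: 0.4}
        assert apply_display_threshold(spectrum, 0.5) == {-36: 99.6}


class TestExcisionByType:
    def test_type_separation(self):
        ref5 = ReferenceAmp(
            id="R5", sequence="ACGT" * 100, baseline_abundance=0.5,
            alpha_type=5, epitope_region=(70, 178),
        )
        excised5 = ClassifiedEdit(
            amp=Amp("AC", 4), reference=ref5, alignment=None,
            events=[IndelEvent("deletion", 67, 111)],
        )
        excised5.guide_assignments = {0: ["gA", "gB"]}
        excised5.category = "multi_guide_excision"
        excised5.excised_span = (67, 178)
        wt7 = make_edit([], count=6)
        freqs = excision_frequency_by_type([excised5, wt7], None)
        assert freqs == {5: pytest.approx(100.0), 7: pytest.approx(0.0)}

    def test_partial_span_not_counted(self):
        """A two-cut deletion that misses part of the epitope block does not
        count as removal of the region."""
        edit = make_edit([IndelEvent("deletion", 67, 100)], count=1)
        edit.excised_span = (67, 167)  # ends before epitope_region end (196)
        edit.category = "multi_guide_excision"
        freqs = excision_frequency_by_type([edit], None)
        assert freqs == {7: pytest.approx(0.0)}
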