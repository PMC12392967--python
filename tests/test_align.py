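"""Affine-gap aligners, closest-reference choice, event extraction and
InDel normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampedit.align import (
    DEFAULT_GLOBAL,
    DEFAULT_LOCAL,
    IndelEvent,
    Scoring,
    align_global,
    align_local,
    apply_event,
    choose_reference,
    extract_indels,
    normalize_indel,
)
from ampedit.guides import CutWindow
from ampedit.refdb import Amp, ReferenceAmp, ReferencePanel

from conftest import random_dna
from oracles import enumerate_indel_placements, naive_affine


def reconstruct_query(aln):
    """Rebuild the query from the reference and the alignment ops."""
    out = []
    i, j = aln.ref_start, aln.query_start
    for op, length in aln.ops:
        if op in ("M", "X"):
            out.append(aln.query[j : j + length])
            i += length
            j += length
        elif op == "I":
            out.append(aln.query[j : j + length])
            j += length
        else:
            i += length
    return "".join(out)


class TestAligners:
    def test_identity_local(self, rng):
        seq = random_dna(rng, 60)
        aln = align_local(seq, seq)
        assert aln.ops == [("M", 60)]
        assert aln.score == 60 * DEFAULT_LOCAL.match
        assert aln.query_clipped == 0

    def test_identity_global(self, rng):
        seq = random_dna(rng, 60)
        aln = align_global(seq, seq)
        assert aln.ops == [("M", 60)]
        assert aln.score == 60 * DEFAULT_GLOBAL.match

    def test_interior_deletion_local(self, rng):
        ref = random_dna(rng, 200)
        query = ref[:90] + ref[126:]
        aln = align_local(query, ref)
        assert ("D", 36) in aln.ops

    def test_large_deletion_global(self, rng):
        ref = random_dna(rng, 300)
        query = ref[:100] + ref[229:]
        aln = align_global(query, ref)
        assert aln.ops == [("M", 100), ("D", 129), ("M", 71)]

    def test_insertion_recovered_verbatim(self, rng):
        ref = random_dna(rng, 120)
        ins = "GGATCCGGATCC"
        query = ref[:40] + ins + ref[40:]
        aln = align_global(query, ref)
        (event,) = extract_indels(aln)
        assert event.kind == "insertion" and event.length == 12
        # placement may differ within the repeat-equivalence class,
        # but the edited haplotype is exactly the query
        assert apply_event(ref, event) == query

    def test_local_clips_unrelated_flanks(self, rng):
        ref = random_dna(rng, 150)
        block = ref[60:95]
        query = random_dna(rng, 30) + block + random_dna(rng, 25)
        aln = align_local(query, ref)
        # the alignment covers the shared block (possibly extended by a few
        # chance matches into the random flanks) and clips the rest
        assert aln.ref_start <= 60 and aln.ref_end >= 95
        assert aln.query_clipped >= 40
        assert aln.matches >= 35

    @pytest.mark.parametrize("mode", ["local", "global"])
    def test_full_matrix_oracle_equivalence(self, mode):
        """Scores, paths and endpoints equal the naive DP on random pairs."""
        rng = np.random.default_rng(97)
        sc = DEFAULT_LOCAL if mode == "local" else DEFAULT_GLOBAL
        fn = align_local if mode == "local" else align_global
        for _ in range(60):
            ref = random_dna(rng, int(rng.integers(15, 120)))
            if rng.random() < 0.5:
                q = list(ref)
                for _ in range(int(rng.integers(0, 6))):
                    p = int(rng.integers(0, len(q)))
                    r = rng.random()
                    if r < 0.4:
                        q[p] = "ACGT"[rng.integers(4)]
                    elif r < 0.7:
                        q.insert(p, "ACGT"[rng.integers(4)])
                    elif len(q) > 10:
                        del q[p : p + int(rng.integers(1, 5))]
                query = "".join(q) or "A"
            else:
                query = random_dna(rng, int(rng.integers(15, 120)))
            aln = fn(query, ref, sc)
            score, ops, rs, re_, qs, qe = naive_affine(
                query, ref, sc.match, sc.mismatch, sc.gap_open,
                sc.gap_extend, mode,
            )
            assert aln.score == score
            assert aln.ops == ops
            assert (aln.ref_start, aln.ref_end, aln.query_start, aln.query_end) == (
                rs, re_, qs, qe
            )

    def test_event_sequence_duality(self, rng):
        """Applying extracted ops to the reference reproduces the query."""
        for _ in range(25):
            ref = random_dna(rng, 150)
            q = list(ref)
            for _ in range(int(rng.integers(1, 4))):
                p = int(rng.integers(10, len(q) - 10))
                if rng.random() < 0.5:
                    q.insert(p, "ACGT"[rng.integers(4)])
                else:
                    del q[p : p + int(rng.integers(1, 8))]
            query = "".join(q)
            aln = align_global(query, ref)
            assert reconstruct_query(aln) == query

    def test_scoring_validation(self):
        with pytest.raises(ValueError):
            Scoring(match=0)
        with pytest.raises(ValueError):
            Scoring(gap_open=0)


class TestChooseReference:
    def make_panel(self, rng, n=6, length=240):
        refs = [
            ReferenceAmp(
                id=f"R{i}", sequence=random_dna(rng, length),
                baseline_abundance=1 / n,
            )
            for i in range(n)
        ]
        return ReferencePanel(refs, k=12)

    def test_exact_match(self, rng):
        panel = self.make_panel(rng)
        ref, aln = choose_reference(Amp(panel.amps[3].sequence, 1), panel)
        assert ref.id == "R3"
        assert aln.ops == [("M", len(ref.sequence))]

    def test_large_deletion_escalates_to_global(self, rng):
        panel = self.make_panel(rng)
        target = panel.amps[2]
        query = target.sequence[:60] + target.sequence[189:]
        ref, aln = choose_reference(Amp(query, 1), panel)
        assert ref.id == "R2"
        assert aln.mode == "global"
        assert ("D", 129) in aln.ops

    def test_lexicographic_tie_break(self, rng):
        seq = random_dna(rng, 100)
        refs = [
            ReferenceAmp(id=i, sequence=seq, baseline_abundance=0.5)
            for i in ("B7", "A9")
        ]
        panel = ReferencePanel(refs, k=12)
        ref, _ = choose_reference(Amp(seq, 1), panel)
        assert ref.id == "A9"

    def test_unalignable_returns_none(self, rng):
        panel = self.make_panel(rng)
        stranger = random_dna(np.random.default_rng(12345), 100)
        assert choose_reference(Amp(stranger, 1), panel) is None

    def test_panel_order_invariance(self, rng):
        panel = self.make_panel(rng)
        query = panel.amps[4].sequence[:100] + panel.amps[4].sequence[130:]
        ref1, aln1 = choose_reference(Amp(query, 1), panel)
        reversed_panel = ReferencePanel(list(reversed(panel.amps)), k=12)
        ref2, aln2 = choose_reference(Amp(query, 1), reversed_panel)
        assert ref1.id == ref2.id and aln1.ops == aln2.ops

    def test_exhaustive_flag_matches_preselection(self, rng):
        panel = self.make_panel(rng)
        query = panel.amps[1].sequence[:150] + "ACGT" + panel.amps[1].sequence[150:]
        a = choose_reference(Amp(query, 1), panel, exhaustive=False)
        b = choose_reference(Amp(query, 1), panel, exhaustive=True)
        assert a[0].id == b[0].id and a[1].ops == b[1].ops


class TestExtractIndels:
    def test_all_match_alignment(self, rng):
        seq = random_dna(rng, 80)
        assert extract_indels(align_local(seq, seq)) == []

    def test_direct_mapping_of_ops(self, rng):
        ref = random_dna(rng, 300)
        query = ref[:100] + ref[136:210] + "GGATCC" + ref[210:]
        events = extract_indels(align_global(query, ref))
        assert [(e.kind, e.ref_pos, e.signed_length) for e in events] == [
            ("deletion", 100, -36),
            ("insertion", 210, 6),
        ]

    def test_planted_events_reconstruct_query(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            ref = random_dna(rng, 200)
            pos = int(rng.integers(30, 150))
            if rng.random() < 0.5:
                length = int(rng.integers(1, 30))
                query = ref[:pos] + ref[pos + length :]
            else:
                ins = random_dna(rng, int(rng.integers(1, 20)))
                query = ref[:pos] + ins + ref[pos:]
            aln = align_global(query, ref)
            seq = ref
            for ev in sorted(extract_indels(aln), key=lambda e: -e.ref_pos):
                seq = apply_event(seq, ev)
            assert seq == query


class TestNormalize:
    def test_repeat_deletion_shifts_into_window(self):
        ref = "TTTTTACACACACAGTTTTT"
        # deleting any CA in the run yields the same haplotype
        ev = IndelEvent("deletion", 5, 2)
        window = CutWindow(expected_cut=13, window_start=11, window_end=14)
        norm = normalize_indel(ev, ref, [window])
        assert norm.ref_pos > ev.ref_pos
        assert apply_event(ref, norm) == apply_event(ref, ev)
        assert norm.normalized

    def test_non_repetitive_context_left_aligned(self, rng):
        ref = random_dna(rng, 60)
        ev = IndelEvent("deletion", 20, 5)
        norm = normalize_indel(ev, ref, [])
        assert (norm.ref_pos, norm.length) == (20, 5)
        assert norm.normalized

    def test_idempotent_and_haplotype_preserving(self):
        rng = np.random.default_rng(23)
        windows = [CutWindow(expected_cut=50, window_start=44, window_end=55)]
        for _ in range(200):
            # repeat-rich references maximize shiftable events
            unit = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 4))))
            ref = (unit * 60)[:100] + random_dna(rng, 40)
            pos = int(rng.integers(1, 90))
            if rng.random() < 0.5:
                length = int(rng.integers(1, 8))
                if pos + length >= len(ref):
                    continue
                ev = IndelEvent("deletion", pos, length)
            else:
                ins = (unit * 5)[: int(rng.integers(1, 6))]
                ev = IndelEvent("insertion", pos, len(ins), ins)
            norm = normalize_indel(ev, ref, windows)
            assert apply_event(ref, norm) == apply_event(ref, ev)
            again = normalize_indel(norm, ref, windows)
            assert (again.ref_pos, again.inserted_seq) == (
                norm.ref_pos, norm.inserted_seq
            )

    def test_window_overlap_maximal_over_class(self):
        """The chosen placement has the best window overlap among all
        placements enumerated exhaustively."""
        rng = np.random.default_rng(29)
        window = CutWindow(expected_cut=30, window_start=25, window_end=36)

        def overlap(pos, length, kind):
            if kind == "deletion":
                return max(0, min(pos + length, 36) - max(pos, 25))
            return 1 if 25 <= pos <= 36 else 0

        for _ in range(100):
            unit = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 3))))
            ref = (unit * 40)[:60] + random_dna(rng, 20)
            pos = int(rng.integers(0, 50))
            if rng.random() < 0.5:
                ev = IndelEvent("deletion", pos, int(rng.integers(1, 6)))
                if ev.ref_pos + ev.length >= len(ref):
                    continue
                placements = enumerate_indel_placements(
                    "deletion", ev.ref_pos, ev.length, "", ref
                )
                best = max(overlap(p, ev.length, "deletion") for p in placements)
            else:
                ins = (unit * 4)[: int(rng.integers(1, 5))]
                ev = IndelEvent("insertion", pos, len(ins), ins)
                placements = enumerate_indel_placements(
                    "insertion", ev.ref_pos, ev.length, ins, ref
                )
                best = max(overlap(p, ev.length, "insertion") for p, _ in placements)
            norm = normalize_indel(ev, ref, [window])
            assert overlap(norm.ref_pos, norm.length, ev.kind) == best
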