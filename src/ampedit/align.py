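"""Affine-gap alignment of sample Amps against the reference panel.

Two modes are provided, mirroring the two complementary strategies used to
map edited amplicons:

* ``local`` — optimal Smith-Waterman with affine gaps; unaligned query ends
  are reported as clipping.  Best for point InDels and substitutions.
* ``global`` — Needleman-Wunsch with affine gaps and free end gaps on the
  reference side (the query is consumed in full, reference overhangs cost
  nothing).  The gap-extension penalty is an order of magnitude smaller
  than in local mode (implemented with x10 integer-scaled scores), which is
  what makes a single long deletion preferable to runs of fragmentary
  mismatches — the property that recovers large guide-to-guide excisions.

Tie-breaking during traceback is deterministic: diagonal over deletion over
insertion, and gap closure over gap extension at equal score.  The same rule
is implemented by the naive full-matrix oracle used in the test-suite
cross-check, so alignments are reproducible bit-for-bit across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .refdb import Amp, ReferenceAmp, ReferencePanel

NEG = -(2**28)

__all__ = [
    "Scoring",
    "Alignment",
    "IndelEvent",
    "align_local",
    "align_global",
    "choose_reference",
    "extract_indels",
    "normalize_indel",
    "DEFAULT_LOCAL",
    "DEFAULT_GLOBAL",
]


@dataclass(frozen=True)
class Scoring:
    """Integer alignment scores; penalties are stored as positive numbers."""

    match: int = 2
    mismatch: int = 3
    gap_open: int = 6
    gap_extend: int = 1
    mode: str = "local"

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be >= 0")
        if self.gap_open < 1:
            raise ValueError("gap_open must be >= 1")
        if self.mode not in ("local", "global"):
            raise ValueError("mode must be 'local' or 'global'")


DEFAULT_LOCAL = Scoring(match=2, mismatch=3, gap_open=6, gap_extend=1, mode="local")
# global scores are scaled x10 so the effective gap extension is 0.1/base;
# the stiff gap-open keeps a long deletion (or a deletion+insertion
# replacement) in one piece instead of fragmenting it across the chance
# 1-in-4 matches that any two unrelated DNA segments share
DEFAULT_GLOBAL = Scoring(match=20, mismatch=30, gap_open=250, gap_extend=1, mode="global")


@dataclass
class Alignment:
    """A single-path alignment with M/X/I/D ops on reference coordinates."""

    ref_id: str
    score: int
    mode: str
    ops: list[tuple[str, int]]
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    query_clipped: int
    query: str = ""
    ref: str = ""

    @property
    def matches(self) -> int:
        return sum(n for op, n in self.ops if op == "M")

    @property
    def identity(self) -> float:
        """Matched bases over full query length (clipping counts against)."""
        return self.matches / len(self.query) if self.query else 0.0

    def cigar(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.ops)


@dataclass(frozen=True)
class IndelEvent:
    """One insertion or deletion on reference coordinates.

    ``ref_pos`` is the start of the deleted span for deletions and the
    between-base insertion index for insertions.  ``signed_length`` is
    negative for deletions (a 36-bp deletion is -36).
    """

    kind: str
    ref_pos: int
    length: int
    inserted_seq: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError("kind must be insertion|deletion")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.kind == "insertion" and len(self.inserted_seq) != self.length:
            raise ValueError("inserted_seq length mismatch")
        if self.kind == "deletion" and self.inserted_seq:
            raise ValueError("deletions carry no inserted_seq")

    @property
    def signed_length(self) -> int:
        return self.length if self.kind == "insertion" else -self.length

    @property
    def ref_end(self) -> int:
        return self.ref_pos + (self.length if self.kind == "deletion" else 0)


@njit(cache=False)
def _dp_kernel(q, r, match, mismatch, gap_open, ext, local):  # pragma: no cover
    n = r.shape[0]
    m = q.shape[0]
    open_ext = gap_open + ext
    H = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    hcode = np.full((n + 1, m + 1), 3, dtype=np.uint8)
    fopen = np.zeros((n + 1, m + 1), dtype=np.bool_)
    eopen = np.zeros((n + 1, m + 1), dtype=np.bool_)
    hp_row = np.zeros(m + 1, dtype=np.int64)

    if local:
        for j in range(m + 1):
            H[0, j] = 0
        for i in range(n + 1):
            H[i, 0] = 0
    else:
        H[0, 0] = 0
        for j in range(1, m + 1):
            H[0, j] = -(gap_open + ext * j)  # leading query insertions
            E[0, j] = H[0, j]
        for i in range(1, n + 1):
            H[i, 0] = 0  # free leading reference gap

    for i in range(1, n + 1):
        hp_row[0] = H[i, 0]
        for j in range(1, m + 1):
            sub = match if r[i - 1] == q[j - 1] else -mismatch
            f_ext = F[i - 1, j] - ext
            f_open = H[i - 1, j] - open_ext
            if f_open >= f_ext:
                F[i, j] = f_open
                fopen[i, j] = True
            else:
                F[i, j] = f_ext
            hp = H[i - 1, j - 1] + sub
            hc = np.uint8(0)
            if F[i, j] > hp:
                hp = F[i, j]
                hc = np.uint8(1)
            if local and hp < 0:
                hp = 0
                hc = np.uint8(3)
            hp_row[j] = hp
            e_ext = E[i, j - 1] - ext
            e_open = hp_row[j - 1] - open_ext
            if e_open >= e_ext:
                E[i, j] = e_open
                eopen[i, j] = True
            else:
                E[i, j] = e_ext
            if E[i, j] > hp:
                H[i, j] = E[i, j]
                hcode[i, j] = np.uint8(2)
            else:
                H[i, j] = hp
                hcode[i, j] = hc
    return H, E, F, hcode, fopen, eopen


def _dp_fill(query: str, ref: str, sc: Scoring):
    """Fill Gotoh matrices (rows = reference, cols = query).

    Returns (H, E, F, hcode, fopen, eopen) where hcode records the source of
    each H cell (0 diagonal, 1 vertical/deletion, 2 horizontal/insertion,
    3 floor/boundary) with the priority diagonal > deletion > insertion, and
    fopen/eopen record whether each gap cell opened (vs extended), with
    closure preferred at ties.  Insertion gaps re-open only from
    non-insertion states (never optimal otherwise with gap_open >= 1),
    which keeps the row recurrence single-pass.
    """
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    return _dp_kernel(
        q, r, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend,
        sc.mode == "local",
    )


def _traceback(query, ref, sc, H, E, F, hcode, fopen, eopen, start):
    """Walk the stored choices from ``start`` back to the alignment origin."""
    i, j = start
    ops_rev: list[str] = []
    state = "H"
    while True:
        if state == "H":
            if i == 0 and j == 0:
                break
            if sc.mode == "local" and hcode[i, j] == 3:
                break
            if i == 0:
                if sc.mode == "global" and j > 0:
                    ops_rev.extend("I" * j)
                    j = 0
                break
            if j == 0:
                break  # free/zero column
            code = hcode[i, j]
            if code == 0:
                ops_rev.append("M" if ref[i - 1] == query[j - 1] else "X")
                i, j = i - 1, j - 1
            elif code == 1:
                state = "F"
            elif code == 2:
                state = "E"
            else:
                break
        elif state == "F":
            ops_rev.append("D")
            if fopen[i, j]:
                state = "H"
            i -= 1
        else:  # state E
            ops_rev.append("I")
            closed = eopen[i, j]
            j -= 1
            if closed:
                state = "H"
            elif j == 0:
                break
    return ops_rev[::-1], i, j


def _collapse(ops_seq: list[str]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op in ops_seq:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out


def _align(query: str, ref: str, sc: Scoring, ref_id: str = "") -> Alignment:
    if not query or not ref:
        raise ValueError("sequences must be non-empty")
    n, m = len(ref), len(query)
    H, E, F, hcode, fopen, eopen = _dp_fill(query, ref, sc)
    if sc.mode == "local":
        flat = int(np.argmax(H))
        si, sj = divmod(flat, m + 1)
        score = int(H[si, sj])
        ops_seq, oi, oj = _traceback(query, ref, sc, H, E, F, hcode, fopen, eopen, (si, sj))
        ref_start, ref_end = oi, si
        query_start, query_end = oj, sj
        clipped = m - (query_end - query_start)
    else:
        col = H[:, m]
        si = int(np.argmax(col))
        score = int(col[si])
        ops_seq, oi, oj = _traceback(query, ref, sc, H, E, F, hcode, fopen, eopen, (si, m))
        ref_start, ref_end = oi, si
        query_start, query_end = oj, m
        clipped = 0
    return Alignment(
        ref_id=ref_id,
        score=score,
        mode=sc.mode,
        ops=_collapse(ops_seq),
        ref_start=ref_start,
        ref_end=ref_end,
        query_start=query_start,
        query_end=query_end,
        query_clipped=clipped,
        query=query,
        ref=ref,
    )


def align_local(query: str, ref: str, scoring: Scoring = DEFAULT_LOCAL,
                ref_id: str = "") -> Alignment:
    """Optimal Smith-Waterman affine-gap alignment with deterministic traceback."""
    if scoring.mode != "local":
        scoring = Scoring(scoring.match, scoring.mismatch, scoring.gap_open,
                          scoring.gap_extend, "local")
    return _align(query, ref, scoring, ref_id)


def align_global(query: str, ref: str, scoring: Scoring = DEFAULT_GLOBAL,
                 ref_id: str = "") -> Alignment:
    """Affine-gap global alignment; reference end gaps are free, the query is
    consumed in full (no clipping)."""
    if scoring.mode != "global":
        scoring = Scoring(scoring.match, scoring.mismatch, scoring.gap_open,
                          scoring.gap_extend, "global")
    return _align(query, ref, scoring, ref_id)


# ---------------------------------------------------------------------------
# Closest-reference assignment


def _identity_all_m(amp_seq: str, ref: ReferenceAmp, mode: str) -> Alignment:
    sc = DEFAULT_LOCAL if mode == "local" else DEFAULT_GLOBAL
    return Alignment(
        ref_id=ref.id,
        score=len(amp_seq) * sc.match,
        mode=mode,
        ops=[("M", len(amp_seq))],
        ref_start=0,
        ref_end=len(amp_seq),
        query_start=0,
        query_end=len(amp_seq),
        query_clipped=0,
        query=amp_seq,
        ref=ref.sequence,
    )


def choose_reference(
    amp: Amp,
    panel: ReferencePanel,
    scoring_local: Scoring = DEFAULT_LOCAL,
    scoring_global: Scoring = DEFAULT_GLOBAL,
    top_c: int = 8,
    clip_frac: float = 0.15,
    exhaustive: bool = False,
) -> tuple[ReferenceAmp, Alignment] | None:
    """Assign an Amp to its closest reference.

    Candidates are preselected by shared k-mer count (top ``top_c``), the
    best local alignment is chosen, and when clipping exceeds
    ``clip_frac`` x query length the free-end-gap global alignment is
    computed and used if its identity is higher — the escalation that
    recovers amplicons carrying large deletions, which local alignment
    truncates.  Ties break by higher score, then higher baseline abundance,
    then lexicographically smaller reference id.  Returns ``None`` when the
    Amp shares no k-mer with the panel (unalignable, excluded downstream).
    """
    by_id = {r.id: r for r in panel}
    exact = [r for r in panel if r.sequence == amp.sequence]
    if exact:
        best = min(exact, key=lambda r: (-r.baseline_abundance, r.id))
        return best, _identity_all_m(amp.sequence, best, "local")

    if exhaustive:
        candidates = list(panel)
    else:
        shared = panel.shared_kmer_counts(amp.sequence)
        if not shared:
            return None
        ranked = sorted(
            shared.items(),
            key=lambda kv: (-kv[1], -by_id[kv[0]].baseline_abundance, kv[0]),
        )
        candidates = [by_id[rid] for rid, _ in ranked[:top_c]]

    def best_of(alignments: list[tuple[ReferenceAmp, Alignment]]):
        return min(
            alignments,
            key=lambda ra: (-ra[1].score, -ra[0].baseline_abundance, ra[0].id),
        )

    local = [
        (r, align_local(amp.sequence, r.sequence, scoring_local, ref_id=r.id))
        for r in candidates
    ]
    ref_l, aln_l = best_of(local)
    if aln_l.query_clipped <= clip_frac * len(amp.sequence):
        return ref_l, aln_l
    global_ = [
        (r, align_global(amp.sequence, r.sequence, scoring_global, ref_id=r.id))
        for r in candidates
    ]
    ref_g, aln_g = best_of(global_)
    if aln_g.identity > aln_l.identity:
        return ref_g, aln_g
    return ref_l, aln_l


# ---------------------------------------------------------------------------
# Event extraction and normalization


def _merge_gap_clusters(ops: list[tuple[str, int]], merge_gap: int):
    """Absorb short M/X runs sandwiched between gap ops into the gaps.

    A replacement junction (one fragment deleted, another inserted) rarely
    aligns as one clean D plus one I: any two unrelated DNA segments share
    chance 1-in-4 matches, so the optimal path threads short match "bridges"
    through the replaced region, fragmenting the gaps.  Runs of aligned
    columns of total length <= ``merge_gap`` that lie between two gap ops
    are folded into the surrounding gaps; the resulting cluster is emitted
    as a single deletion spanning all consumed reference and a single
    insertion carrying all consumed query.  The query/reference pair the
    ops describe is unchanged.
    """
    merged: list[tuple[str, int]] = list(ops)
    changed = True
    while changed:
        changed = False
        for i in range(1, len(merged) - 1):
            op, length = merged[i]
            if op in ("M", "X") or length > merge_gap:
                continue
            # total aligned run between the neighbouring ops
            j = i
            run = 0
            while j < len(merged) and merged[j][0] in ("M", "X"):
                run += merged[j][1]
                j += 1
            if run > merge_gap or j >= len(merged):
                continue
            if merged[i - 1][0] in ("I", "D") and merged[j][0] in ("I", "D"):
                # fold the run into a D (consumes ref) and an I (consumes query)
                merged[i:j] = [("D", run), ("I", run)]
                changed = True
                break
    return merged


def extract_indels(aln: Alignment, merge_gap: int = 8) -> list[IndelEvent]:
    """Interior I/D runs as events; substitutions never produce events.

    Gap ops separated only by short aligned runs (<= ``merge_gap`` columns)
    are consolidated first (see :func:`_merge_gap_clusters`), so a
    replacement is reported as one deletion plus one insertion at the same
    locus (deletion first).  Terminal I/D runs are not called: in local mode
    the ends are clipped by construction, and in global mode end gaps are
    free alignment artifacts, not edits.
    """
    ops = _merge_gap_clusters(aln.ops, merge_gap) if merge_gap else list(aln.ops)
    # walk ops, emitting one (deletion, insertion) pair per gap cluster
    events: list[IndelEvent] = []
    ref_pos = aln.ref_start
    q_pos = aln.query_start
    n_ops = len(ops)
    idx = 0
    while idx < n_ops:
        op, length = ops[idx]
        if op in ("M", "X"):
            ref_pos += length
            q_pos += length
            idx += 1
            continue
        # gap cluster: consecutive I/D ops
        j = idx
        del_len = ins_len = 0
        while j < n_ops and ops[j][0] in ("I", "D"):
            if ops[j][0] == "D":
                del_len += ops[j][1]
            else:
                ins_len += ops[j][1]
            j += 1
        terminal = idx == 0 or j == n_ops
        if not terminal:
            if del_len:
                events.append(
                    IndelEvent(kind="deletion", ref_pos=ref_pos, length=del_len)
                )
            if ins_len:
                events.append(
                    IndelEvent(
                        kind="insertion",
                        ref_pos=ref_pos,
                        length=ins_len,
                        inserted_seq=aln.query[q_pos : q_pos + ins_len],
                    )
                )
        ref_pos += del_len
        q_pos += ins_len
        idx = j
    return events


def query_interval(aln: Alignment, c1: int, c2: int) -> tuple[int, int] | None:
    """Query coordinates of the segment aligned opposite reference [c1, c2).

    Returns (q1, q2) such that ``aln.query[q1:q2]`` is everything the
    alignment places between reference positions c1 and c2: insertions
    sitting exactly at c1 or c2 are included in the segment (they belong to
    the junction).  ``None`` when the alignment does not span [c1, c2).
    """
    if aln.ref_start > c1 or aln.ref_end < c2 or c1 > c2:
        return None
    r, q = aln.ref_start, aln.query_start
    q1 = q2 = None
    for op, length in aln.ops:
        if op in ("M", "X"):
            if q1 is None and r <= c1 < r + length:
                q1 = q + (c1 - r)
            if r <= c2 < r + length:
                q2 = q + (c2 - r)
            r += length
            q += length
        elif op == "D":
            if q1 is None and r <= c1 < r + length:
                q1 = q
            if r <= c2 < r + length:
                q2 = q
            r += length
        else:  # I (does not advance r)
            if q1 is None and r == c1:
                q1 = q  # insertion sitting at c1 is inside the segment
            q += length
            if r == c2:
                q2 = q  # insertion sitting at c2 is inside the segment
    if q1 is None:  # c1 == aln.ref_end
        q1 = aln.query_end
    if q2 is None:  # c2 == aln.ref_end
        q2 = aln.query_end
    return (q1, q2) if q1 <= q2 else None


def apply_event(ref: str, ev: IndelEvent) -> str:
    """Reference haplotype after applying one event (used for invariants)."""
    if ev.kind == "deletion":
        return ref[: ev.ref_pos] + ref[ev.ref_pos + ev.length :]
    return ref[: ev.ref_pos] + ev.inserted_seq + ref[ev.ref_pos :]


def _equivalence_class(ev: IndelEvent, ref: str) -> list[IndelEvent]:
    """All placements of ``ev`` on ``ref`` that yield the same haplotype."""
    reps = [ev]
    # shift left
    cur = ev
    while True:
        p = cur.ref_pos
        if p == 0:
            break
        if cur.kind == "deletion":
            if ref[p - 1] != ref[p + cur.length - 1]:
                break
            cur = IndelEvent("deletion", p - 1, cur.length)
        else:
            if cur.inserted_seq[-1] != ref[p - 1]:
                break
            cur = IndelEvent(
                "insertion", p - 1, cur.length,
                ref[p - 1] + cur.inserted_seq[:-1],
            )
        reps.append(cur)
    # shift right
    cur = ev
    while True:
        p = cur.ref_pos
        if cur.kind == "deletion":
            if p + cur.length >= len(ref) or ref[p] != ref[p + cur.length]:
                break
            cur = IndelEvent("deletion", p + 1, cur.length)
        else:
            if p >= len(ref) or cur.inserted_seq[0] != ref[p]:
                break
            cur = IndelEvent(
                "insertion", p + 1, cur.length,
                cur.inserted_seq[1:] + ref[p],
            )
        reps.append(cur)
    reps.sort(key=lambda e: e.ref_pos)
    return reps


def normalize_indel(ev: IndelEvent, ref: str, windows=()) -> IndelEvent:
    """Canonical placement of an InDel within its equivalence class.

    In repetitive sequence an InDel admits several placements that produce
    the same edited haplotype; raw alignments need not pick the one under
    the guide cut site, which creates false-negative edit assignments.  The
    event is re-placed to maximize total overlap with the supplied cut
    windows (insertions score window membership of the insertion point),
    breaking ties leftward; with no windows, or no overlapping placement,
    this is plain left-alignment.  The edited haplotype is unchanged.
    """
    reps = _equivalence_class(ev, ref)

    def overlap(e: IndelEvent) -> int:
        total = 0
        for w in windows:
            if e.kind == "deletion":
                lo = max(e.ref_pos, w.window_start)
                hi = min(e.ref_pos + e.length, w.window_end)
                total += max(0, hi - lo)
            else:
                total += 1 if w.contains_point(e.ref_pos) else 0
        return total

    best = max(reps, key=lambda e: (overlap(e), -e.ref_pos))
    return IndelEvent(
        best.kind, best.ref_pos, best.length, best.inserted_seq, normalized=True
    )
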