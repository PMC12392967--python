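"""Detection of targeted dsODN insertions at guide cut sites.

A dsODN (double-stranded oligodeoxynucleotide) is delivered together with
the nuclease so that NHEJ captures it at the cut.  Two scenarios occur:
(i) *single_cut* — the dsODN inserts at one guide's cut site; (ii)
*replacement* — the fragment between two paired-guide cuts is excised and
the dsODN fills the junction, substituting the immunogenic region.  The
insertion orientation (forward vs reverse) is decided by which strand of
the dsODN matches the inserted sequence; blunt-ended dsODNs insert in
either orientation while overhang designs bias insertion forward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .align import DEFAULT_LOCAL, IndelEvent, Scoring, align_local, query_interval
from .classify import ClassifiedEdit, assign_events, detect_excision
from .guides import GuideSite
from .refdb import Amp, reverse_complement

__all__ = ["DsodnSpec", "DsodnCall", "detect_dsodn", "dsodn_frequency"]


@dataclass(frozen=True)
class DsodnSpec:
    """A dsODN design: top strand, end chemistry and match thresholds."""

    name: str
    top_strand: str
    end_type: str = "blunt"
    min_identity: float = 0.9
    min_covered_frac: float = 0.8

    def __post_init__(self) -> None:
        object.__setattr__(self, "top_strand", self.top_strand.upper())
        if set(self.top_strand) - set("ACGT"):
            raise ValueError("dsODN top strand must be ACGT")
        if self.end_type not in ("blunt", "overhang"):
            raise ValueError("end_type must be blunt|overhang")
        for v in (self.min_identity, self.min_covered_frac):
            if not (0 < v <= 1):
                raise ValueError("thresholds must be in (0, 1]")


@dataclass(frozen=True)
class DsodnCall:
    """One targeted dsODN insertion call on a sample Amp."""

    amp: Amp
    dsodn_name: str
    orientation: str  # forward | reverse
    scenario: str  # single_cut | replacement
    guides_covered: tuple[str, ...]
    identity: float
    event_index: int


def _match_stats(inserted: str, strand: str, scoring: Scoring):
    """Identity over aligned columns and fraction of the dsODN covered."""
    aln = align_local(inserted, strand, scoring)
    columns = sum(n for _, n in aln.ops)
    identity = aln.matches / columns if columns else 0.0
    coverage = (aln.ref_end - aln.ref_start) / len(strand)
    return aln.score, identity, coverage


def detect_dsodn(
    edit: ClassifiedEdit,
    spec: DsodnSpec,
    sites: Sequence[GuideSite],
    scoring: Scoring = DEFAULT_LOCAL,
    tol: int = 5,
) -> DsodnCall | None:
    """Test the Amp's insertions against both strands of a dsODN design.

    A call requires: local identity >= ``min_identity`` over at least
    ``min_covered_frac`` of the dsODN, and an insertion point inside a guide
    cut window (a matching insertion elsewhere stays a plain non-targeted
    insertion).  On a call the Amp's category becomes ``dsodn_targeted``;
    the scenario is ``replacement`` when the Amp also carries a paired-cut
    excision, else ``single_cut``.
    """
    windows = [(s.guide_name, s.cut_window) for s in sites if s.cut_window]
    for i, ev in enumerate(edit.events):
        if ev.kind != "insertion":
            continue
        in_window_guides = [g for g, w in windows if w.contains_point(ev.ref_pos)]
        if not in_window_guides:
            continue
        fwd = _match_stats(ev.inserted_seq, spec.top_strand, scoring)
        rev = _match_stats(
            ev.inserted_seq, reverse_complement(spec.top_strand), scoring
        )
        score, identity, coverage = max(fwd, rev)
        orientation = "forward" if fwd >= rev else "reverse"
        if identity < spec.min_identity or coverage < spec.min_covered_frac:
            continue
        if edit.is_excision:
            scenario = "replacement"
            lo, hi = edit.excised_span
            cut_guides = [
                s.guide_name
                for s in sites
                if s.cut_window
                and lo - tol <= s.cut_window.expected_cut <= hi + tol
            ]
            guides = list(dict.fromkeys(cut_guides + in_window_guides))
        else:
            scenario = "single_cut"
            guides = in_window_guides
        edit.category = "dsodn_targeted"
        return DsodnCall(
            amp=edit.amp,
            dsodn_name=spec.name,
            orientation=orientation,
            scenario=scenario,
            guides_covered=tuple(guides),
            identity=identity,
            event_index=i,
        )
    return _detect_replacement_by_region(edit, spec, sites, scoring, tol)


def _detect_replacement_by_region(
    edit: ClassifiedEdit,
    spec: DsodnSpec,
    sites: Sequence[GuideSite],
    scoring: Scoring,
    tol: int,
) -> DsodnCall | None:
    """Replacement refinement: match the inter-cut query segment directly.

    When a replacement and the replaced fragment have comparable lengths the
    optimal alignment threads the dsODN through the excised block as a
    mosaic of small InDels and chance matches, so no single insertion event
    carries the dsODN.  Here the query segment aligned opposite the
    inter-cut reference span is reconstructed from the alignment and tested
    against the dsODN strands; on a hit the mosaic events inside the span
    are rewritten as the canonical pair — one cut-to-cut deletion plus one
    insertion carrying the segment — which is an exact re-representation of
    the same query sequence.
    """
    if edit.alignment is None or not edit.events:
        return None
    cuts = {
        s.guide_name: s.cut_window.expected_cut
        for s in sites
        if s.cut_window is not None
    }
    if len(cuts) < 2:
        return None
    c1, c2 = min(cuts.values()), max(cuts.values())
    # only worth testing when the span content actually changed
    if not any(
        ev.ref_pos < c2 + tol and ev.ref_end > c1 - tol for ev in edit.events
    ):
        return None
    interval = query_interval(edit.alignment, c1, c2)
    if interval is None:
        return None
    q1, q2 = interval
    segment = edit.alignment.query[q1:q2]
    # a genuine replacement leaves little residual reference sequence in the
    # span: the segment is essentially the dsODN, not the dsODN plus the
    # intact block
    lo_len = spec.min_covered_frac * len(spec.top_strand)
    hi_len = len(spec.top_strand) / spec.min_covered_frac
    if not (lo_len <= len(segment) <= hi_len):
        return None
    fwd = _match_stats(segment, spec.top_strand, scoring)
    rev = _match_stats(segment, reverse_complement(spec.top_strand), scoring)
    score, identity, coverage = max(fwd, rev)
    if identity < spec.min_identity or coverage < spec.min_covered_frac:
        return None
    orientation = "forward" if fwd >= rev else "reverse"
    # only events fully inside [c1, c2] can be folded into the rewritten
    # pair; an event crossing the span boundary would make the rewrite an
    # inexact re-representation, so leave such edits untouched
    contained = [
        ev for ev in edit.events if c1 <= ev.ref_pos and ev.ref_end <= c2
    ]
    crossing = [
        ev
        for ev in edit.events
        if ev not in contained and ev.ref_pos < c2 and ev.ref_end > c1
    ]
    if crossing:
        return None
    kept = [ev for ev in edit.events if ev not in contained]
    rewritten = [IndelEvent("deletion", c1, c2 - c1, normalized=True)]
    if segment:
        rewritten.append(
            IndelEvent("insertion", c1, len(segment), segment, normalized=True)
        )
    edit.events = sorted(kept + rewritten, key=lambda e: e.ref_pos)
    edit.guide_assignments = assign_events(edit.events, sites)
    detect_excision(edit, sites, tol=tol)
    edit.category = "dsodn_targeted"
    ins_index = next(
        i for i, ev in enumerate(edit.events)
        if ev.kind == "insertion" and ev.ref_pos == c1
    )
    covered = [g for g, c in cuts.items() if c1 - tol <= c <= c2 + tol]
    return DsodnCall(
        amp=edit.amp,
        dsodn_name=spec.name,
        orientation=orientation,
        scenario="replacement",
        guides_covered=tuple(covered),
        identity=identity,
        event_index=ins_index,
    )


def dsodn_frequency(
    calls: Sequence[DsodnCall], edits: Sequence[ClassifiedEdit]
) -> dict[str, float | None]:
    """Per-orientation dsODN insertion frequency.

    The denominator is the abundance-weighted count of *all* insertion
    events in the sample, targeted and non-targeted alike; with no
    insertions at all both orientations report ``None``.
    """
    total = 0
    for edit in edits:
        n_ins = sum(1 for ev in edit.events if ev.kind == "insertion")
        total += n_ins * edit.amp.count
    if total == 0:
        return {"forward": None, "reverse": None}
    weights = {"forward": 0, "reverse": 0}
    for call in calls:
        weights[call.orientation] += call.amp.count
    return {o: 100.0 * w / total for o, w in weights.items()}
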