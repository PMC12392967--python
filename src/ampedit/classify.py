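"""Assign InDels to guides, detect paired-guide excisions, and compute
abundance-weighted per-sample editing statistics.

An amplicon family member is "edited" when it carries at least one InDel
attributable to a guide cut window.  A *multi-guide excision* is a single
deletion whose span covers the expected cut positions of two or more
guides — the signature of paired-sgRNA fragment removal.  Frame status is
the net signed length of all events on the Amp modulo 3, since downstream
translation depends on the combined effect, not on the excision alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import Alignment, IndelEvent
from .guides import GuideSite
from .refdb import Amp, AmpSet, ReferenceAmp

CATEGORIES = (
    "wild_type",
    "single_guide_indel",
    "multi_guide_excision",
    "unassigned_indel",
    "dsodn_targeted",
)

__all__ = [
    "ClassifiedEdit",
    "SampleReport",
    "assign_events",
    "detect_excision",
    "sample_statistics",
    "excision_frequency_by_type",
]


@dataclass
class ClassifiedEdit:
    """One sample Amp with its chosen reference and classified events."""

    amp: Amp
    reference: ReferenceAmp
    alignment: Alignment | None
    events: list[IndelEvent] = field(default_factory=list)
    guide_assignments: dict[int, list[str]] = field(default_factory=dict)
    category: str = "wild_type"
    excised_span: tuple[int, int] | None = None
    frame_status: str = "not_applicable"

    @property
    def assigned_events(self) -> list[tuple[int, IndelEvent]]:
        return [
            (i, ev)
            for i, ev in enumerate(self.events)
            if self.guide_assignments.get(i)
        ]

    @property
    def is_edited(self) -> bool:
        return bool(self.guide_assignments) and any(
            g for g in self.guide_assignments.values()
        )

    @property
    def is_excision(self) -> bool:
        return self.excised_span is not None


@dataclass
class SampleReport:
    """Abundance-weighted editing statistics for one sample.

    Percentages are of total family abundance (reads assigned to the gene
    family); ``indel_spectrum`` maps signed InDel length to its share of the
    total abundance-weighted InDel frequency.  ``None`` marks statistics
    whose denominator was empty.
    """

    sample_id: str
    family_abundance: int = 0
    editing_pct: float | None = None
    deletions_pct: float | None = None
    insertions_pct: float | None = None
    per_guide_efficiency: dict[str, float | None] = field(default_factory=dict)
    indel_spectrum: dict[int, float] = field(default_factory=dict)
    excision_freq_by_type: dict[object, float | None] = field(default_factory=dict)
    dsodn_freq: dict[str, float | None] = field(default_factory=dict)
    epitope_loss: dict[str, float | None] = field(default_factory=dict)
    combined_epitope_loss: float | None = None
    alignment_mode_pct: dict[str, float] = field(default_factory=dict)
    unalignable_reads: int = 0


def assign_events(
    events: Sequence[IndelEvent], sites: Sequence[GuideSite]
) -> dict[int, list[str]]:
    """Map each event index to the guides whose cut windows it hits.

    Deletions are assigned by interval overlap with the window; insertions
    by membership of the insertion point (window edges inclusive).  Events
    hitting no window stay unassigned (absent from the result).
    """
    assignments: dict[int, list[str]] = {}
    for i, ev in enumerate(events):
        hits = []
        for site in sites:
            win = site.cut_window
            if win is None:
                continue
            if ev.kind == "deletion":
                ok = win.overlaps(ev.ref_pos, ev.ref_pos + ev.length)
            else:
                ok = win.contains_point(ev.ref_pos)
            if ok and site.guide_name not in hits:
                hits.append(site.guide_name)
        if hits:
            assignments[i] = hits
    return assignments


def _frame_status(events: Sequence[IndelEvent]) -> str:
    if not events:
        return "not_applicable"
    net = sum(ev.signed_length for ev in events)
    return "in_frame" if net % 3 == 0 else "frameshift"


def detect_excision(
    edit: ClassifiedEdit, sites: Sequence[GuideSite], tol: int = 5
) -> ClassifiedEdit:
    """Categorize the Amp, flagging single deletions that span >= 2 cuts.

    A cut position is covered when it lies within the deleted span, edges
    included (a deletion running exactly cut-to-cut is the canonical paired
    excision and must cover both cuts).  ``tol`` bases of slack absorb the
    junction wobble of replacement alignments, where a chance match can
    steal one or two columns from a gap edge.
    """
    cuts = {
        s.guide_name: s.cut_window.expected_cut
        for s in sites
        if s.cut_window is not None
    }
    best_span: tuple[int, int] | None = None
    for ev in edit.events:
        if ev.kind != "deletion":
            continue
        lo, hi = ev.ref_pos, ev.ref_pos + ev.length
        covered = {g for g, c in cuts.items() if lo - tol <= c <= hi + tol}
        if len(covered) >= 2:
            if best_span is None or hi - lo > best_span[1] - best_span[0]:
                best_span = (lo, hi)
    edit.excised_span = best_span
    if best_span is not None:
        edit.category = "multi_guide_excision"
    elif edit.is_edited:
        edit.category = "single_guide_indel"
    elif edit.events:
        edit.category = "unassigned_indel"
    else:
        edit.category = "wild_type"
    edit.frame_status = _frame_status(edit.events)
    return edit


def sample_statistics(
    edits: Sequence[ClassifiedEdit],
    ampset: AmpSet,
    perfect_sites_by_ref: Mapping[str, Iterable[str]] | None = None,
) -> SampleReport:
    """Compute the abundance-weighted editing summary for one sample.

    * ``editing_pct``: abundance share of Amps carrying >= 1 guide-assigned
      event (deletion and insertion carriers counted once).
    * ``deletions_pct`` / ``insertions_pct``: analogous for Amps with >= 1
      assigned deletion / insertion; one Amp may count in both, so their sum
      may exceed ``editing_pct``.
    * ``per_guide_efficiency``: edited abundance at a guide over the
      abundance of Amps whose chosen reference carries a perfect-seed site
      for it (designed targets only; degenerate-site edits contribute to
      ``editing_pct`` but not to per-guide denominators).
    * ``indel_spectrum``: abundance-weighted share of each signed length
      among all assigned events; sums to 100 before any display threshold.
    """
    report = SampleReport(sample_id=ampset.sample_id)
    family = sum(e.amp.count for e in edits)
    report.family_abundance = family
    if family == 0:
        return report

    edited = del_ab = ins_ab = 0
    guide_num: dict[str, int] = {}
    spectrum: dict[int, float] = {}
    for edit in edits:
        w = edit.amp.count
        kinds = set()
        guides_hit = set()
        for i, ev in edit.assigned_events:
            kinds.add(ev.kind)
            guides_hit.update(edit.guide_assignments[i])
            spectrum[ev.signed_length] = spectrum.get(ev.signed_length, 0) + w
        if kinds:
            edited += w
        if "deletion" in kinds:
            del_ab += w
        if "insertion" in kinds:
            ins_ab += w
        for g in guides_hit:
            guide_num[g] = guide_num.get(g, 0) + w

    report.editing_pct = 100.0 * edited / family
    report.deletions_pct = 100.0 * del_ab / family
    report.insertions_pct = 100.0 * ins_ab / family

    total_events = sum(spectrum.values())
    if total_events > 0:
        report.indel_spectrum = {
            length: 100.0 * weight / total_events
            for length, weight in sorted(spectrum.items())
        }

    if perfect_sites_by_ref is not None:
        guide_denom: dict[str, int] = {}
        for edit in edits:
            for g in perfect_sites_by_ref.get(edit.reference.id, ()):
                guide_denom[g] = guide_denom.get(g, 0) + edit.amp.count
        all_guides = set(guide_denom) | set(guide_num)
        report.per_guide_efficiency = {
            g: (100.0 * guide_num.get(g, 0) / guide_denom[g])
            if guide_denom.get(g)
            else None
            for g in sorted(all_guides)
        }
    return report


def excision_frequency_by_type(
    edits: Sequence[ClassifiedEdit], panel=None, tol: int = 5
) -> dict[object, float | None]:
    """Excised abundance share per amplicon archetype.

    For each Alpha type with any assigned abundance: the fraction of that
    type's abundance carried by Amps whose single-deletion excision covers
    the reference's annotated epitope-coding interval (within ``tol`` bases
    of junction slack).  Types with zero denominator report ``None``.
    """
    denom: dict[object, int] = {}
    numer: dict[object, int] = {}
    for edit in edits:
        t = edit.reference.alpha_type
        if t in (None, 0, "pseudogene"):
            continue
        denom[t] = denom.get(t, 0) + edit.amp.count
        if not edit.is_excision:
            continue
        region = edit.reference.epitope_region
        lo, hi = edit.excised_span
        if region is None or (lo - tol <= region[0] and region[1] <= hi + tol):
            numer[t] = numer.get(t, 0) + edit.amp.count
    return {
        t: (100.0 * numer.get(t, 0) / denom[t]) if denom[t] else None
        for t in sorted(denom, key=str)
    }


def apply_display_threshold(
    spectrum: Mapping[int, float], threshold: float = 0.5
) -> dict[int, float]:
    """Drop spectrum entries below the display threshold (presentation only;
    all statistics are computed on the full spectrum)."""
    return {k: v for k, v in spectrum.items() if v >= threshold}
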