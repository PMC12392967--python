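"""Celiac-disease epitope profiling of amplicon translations.

The immunodominant α-gliadin 33-mer carries six overlapping copies of three
HLA-DQ2.5-restricted 9-mer epitopes (one DQ2.5_glia_α1a, two α1b, three α2)
and is followed by one copy of DQ2.5_glia_α3.  Amplicons are classified
into Alpha types by their total DQ2.5 hit count, capped at 7: Alpha0 lacks
epitopes, Alpha7 carries the complete 33-mer plus α3.  The innate-immunity
p31-43 peptide is tracked separately and never enters the type count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Seq import Seq

DQ25_MOTIFS: dict[str, str] = {
    "DQ2.5_glia_a1a": "PFPQPQLPY",
    "DQ2.5_glia_a1b": "PYPQPQLPY",
    "DQ2.5_glia_a2": "PQPQLPYPQ",
    "DQ2.5_glia_a3": "FRPQQPYPQ",
}

#: canonical 33-mer peptide (six overlapping DQ2.5 epitope copies)
THIRTY_THREE_MER = "LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQPF"

__all__ = [
    "DQ25_MOTIFS",
    "THIRTY_THREE_MER",
    "EpitopeProfile",
    "EpitopeLossReport",
    "translate_amp",
    "scan_epitopes",
    "classify_alpha_type",
    "relative_epitope_loss",
]


@dataclass(frozen=True)
class EpitopeProfile:
    """Overlapping motif counts on one translated amplicon."""

    motif_hits: Mapping[str, int]
    total_hits: int
    p31_43_present: bool = False
    has_internal_stop: bool = False


@dataclass
class EpitopeLossReport:
    """Relative epitope loss per motif; the combined loss sums the per-motif
    losses and may exceed 100% by construction."""

    per_epitope_loss: dict[str, float | None] = field(default_factory=dict)
    combined_loss: float | None = None


def translate_amp(sequence: str, frame_offset: int = 0) -> str:
    """Standard-code translation of ``sequence`` in the given frame.

    Stop codons are retained as ``*`` so downstream scans can see truncation;
    trailing bases short of a codon are dropped.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    coding = sequence[frame_offset:]
    coding = coding[: 3 * (len(coding) // 3)]
    if not coding:
        return ""
    return str(Seq(coding).translate())


def count_overlapping(peptide: str, motif: str) -> int:
    n, hits, start = len(motif), 0, 0
    while True:
        idx = peptide.find(motif, start)
        if idx < 0:
            return hits
        hits += 1
        start = idx + 1


def scan_epitopes(
    peptide: str,
    motifs: Mapping[str, str] = DQ25_MOTIFS,
    p31_43: str | None = None,
) -> EpitopeProfile:
    """Count every overlapping occurrence of each motif in ``peptide``.

    ``total_hits`` sums the DQ2.5 motif counts; the optional p31-43 motif is
    flagged separately and excluded from the total.
    """
    if not motifs:
        raise ValueError("motifs must be non-empty")
    hits = {name: count_overlapping(peptide, m) for name, m in motifs.items()}
    return EpitopeProfile(
        motif_hits=hits,
        total_hits=sum(hits.values()),
        p31_43_present=bool(p31_43) and count_overlapping(peptide, p31_43) > 0,
        has_internal_stop="*" in peptide[:-1] if peptide else False,
    )


def classify_alpha_type(profile: EpitopeProfile, pseudogene: bool | None = None):
    """Alpha type = total DQ2.5 hits capped at 7; a pseudogene flag (explicit
    or an internal stop in the scanned translation) overrides the count."""
    if pseudogene or (pseudogene is None and profile.has_internal_stop):
        return "pseudogene"
    return min(profile.total_hits, 7)


def amp_frame_offset(alignment, ref_frame_offset: int) -> int:
    """Translation frame for a query given its alignment to a framed reference.

    The query base at ``query_start`` pairs with reference base ``ref_start``;
    the returned offset starts query translation at the first complete codon
    in the reference's frame.
    """
    phase = (alignment.ref_start - ref_frame_offset) % 3
    return alignment.query_start + ((3 - phase) % 3)


def relative_epitope_loss(
    edits: Sequence,
    panel,
    motifs: Mapping[str, str] = DQ25_MOTIFS,
    p31_43: str | None = None,
) -> EpitopeLossReport:
    """Relative loss of each epitope, weighted by wild-type abundance.

    For motif *e* the loss is::

        100 * sum_r b(r) * lost_frac_e(r) / sum_{r : hits_e(r) >= 1} b(r)

    where b(r) is the baseline abundance of reference r and lost_frac_e(r)
    is the abundance-weighted mean, over sample Amps assigned to r, of the
    fraction of r's *e* occurrences missing from the Amp's re-scanned
    translation.  Re-scanning (rather than coordinate bookkeeping) means
    frameshifts and motif-breaking substitutions count as losses too.  The
    combined loss sums per-motif losses (plus p31-43 when tracked), so it
    can exceed 100%.  Motifs carried by no reference report ``None``.
    """
    all_motifs = dict(motifs)
    if p31_43:
        all_motifs["p31_43"] = p31_43

    ref_profiles: dict[str, dict[str, int]] = {}
    for ref in panel:
        pep = translate_amp(ref.sequence, ref.reading_frame_offset)
        ref_profiles[ref.id] = {
            name: count_overlapping(pep, m) for name, m in all_motifs.items()
        }

    # per-reference abundance and per-motif lost-occurrence weight
    ab_by_ref: dict[str, int] = {}
    lost_by_ref: dict[str, dict[str, float]] = {}
    for edit in edits:
        rid = edit.reference.id
        w = edit.amp.count
        ab_by_ref[rid] = ab_by_ref.get(rid, 0) + w
        start = (
            amp_frame_offset(edit.alignment, edit.reference.reading_frame_offset)
            if edit.alignment is not None
            else edit.reference.reading_frame_offset
        )
        pep = translate_amp(edit.amp.sequence[start:]) if start < len(edit.amp.sequence) else ""
        bucket = lost_by_ref.setdefault(rid, {})
        for name, motif in all_motifs.items():
            ref_hits = ref_profiles[rid][name]
            if ref_hits == 0:
                continue
            amp_hits = count_overlapping(pep, motif)
            lost = max(0, ref_hits - amp_hits) / ref_hits
            bucket[name] = bucket.get(name, 0.0) + w * lost

    report = EpitopeLossReport()
    combined = 0.0
    any_motif = False
    for name in all_motifs:
        denom = sum(
            r.baseline_abundance for r in panel if ref_profiles[r.id][name] >= 1
        )
        if denom == 0:
            report.per_epitope_loss[name] = None
            continue
        numer = 0.0
        for r in panel:
            if ref_profiles[r.id][name] < 1:
                continue
            ab = ab_by_ref.get(r.id, 0)
            if ab == 0:
                continue
            numer += r.baseline_abundance * lost_by_ref.get(r.id, {}).get(name, 0.0) / ab
        loss = 100.0 * numer / denom
        report.per_epitope_loss[name] = loss
        combined += loss
        any_motif = True
    report.combined_loss = combined if any_motif else None
    return report
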