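"""Synthetic reference panels and edited read sets with known truth.

The generator emulates a tandem α-gliadin-like gene family of eight
archetypes (Alpha0-Alpha7) that differ in the epitope content of a central
immunogenic block flanked by two Cas9 guide sites, so that every pipeline
stage — dereplication, family screening, closest-reference assignment,
InDel extraction, excision and dsODN detection, epitope-loss profiling —
can be exercised against a per-read truth table without external data.

Archetype layout (forward strand, frame 0 throughout)::

    [PRE][CCA|GCA][  excised span  ][GTC TGG][POST]
          ^PAM ^      ^cut1    ^cut2  ^PAM
          (upstream guide, minus strand)   (downstream guide, plus strand)

The excised span codes ``LQLQPF + (PQPQLPY)*r + PQPQPF + {F|S}RPQQPYPQ + P``;
with r repeats the DQ2.5 hit count is 2r, plus one when the tail starts
with F (an intact DQ2.5_glia_α3).  Alpha7 (r = 3, F tail) therefore spans
43 codons — 129 bp cut to cut, so the paired-guide excision is in-frame and
removes the complete 33-mer plus α3.  The upstream guide sits on the minus
strand so that both PAMs fall *outside* the excised fragment: with only
3 bp of slack between the 126-bp epitope block and the 129-bp excision
there is no room for a PAM inside.  Guide footprints and PAMs are held
constant across references; all remaining codons are wobble-randomized per
reference so family members are distinguishable everywhere, inside and
outside the excised span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .epitopes import scan_epitopes, translate_amp
from .guides import GuideSpec, GuideSite, sites_with_windows
from .refdb import ReferenceAmp, ReferencePanel, reverse_complement
from .dsodn import DsodnSpec

# fixed codon blocks shared by every reference (guide footprints)
_HEAD_AA = "LQLQPF"
_HEAD_DNA = "CTTCAACTCCAGCCATTC"  # fixed codons for LQLQPF
_TAIL_CONST_AA = "RPQQPYPQ" + "P"  # tail minus its first residue, plus spacer
_TAIL_CONST_DNA = "AGACCTCAACAGCCGTACCCCCAACCT"
_TAIL_F, _TAIL_S = "TTT", "TCT"  # F completes the α3 epitope, S breaks it
_X3 = "GCA"  # codon between upstream PAM and cut1
_PAM_UP = "CCA"  # reads TGG (NGG) on the minus strand
_POST_CUT = "GTCTGG"  # V + W; TGG is the downstream guide's PAM

_CODONS = {
    "A": ["GCT", "GCA", "GCC"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGA"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC"],
    "K": ["AAA", "AAG"],
    "L": ["CTT", "CTC", "CTA", "CTG", "TTA", "TTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCA", "CCC", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["AGA", "CGT"],
    "S": ["TCT", "TCA", "AGC"],
    "T": ["ACT", "ACA"],
    "V": ["GTT", "GTC", "GTA"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}

# flank residues exclude Y and R so no DQ2.5 motif can arise outside the
# designed epitope block (every motif requires a Y or R)
_FLANK_AA = "PQLSTAVIEGF"
_FLANK_WEIGHTS = np.array([4, 4, 2, 1, 1, 1, 1, 1, 1, 1, 1], dtype=float)
_FLANK_WEIGHTS /= _FLANK_WEIGHTS.sum()

#: per-type Dirichlet concentration for baseline abundances (Alpha0-heavy,
#: Alpha7 rare, pseudogenes common — the qualitative wild-type skew)
DEFAULT_TYPE_CONCENTRATION: dict[object, float] = {
    0: 30.0, 1: 12.0, 2: 10.0, 3: 8.0, 4: 6.0, 5: 5.0, 6: 3.0, 7: 2.0,
    "pseudogene": 15.0,
}

DEFAULT_N_PER_TYPE: dict[object, int] = {
    0: 3, 1: 1, 2: 2, 3: 1, 4: 1, 5: 1, 6: 1, 7: 1, "pseudogene": 1,
}

# epitope-free in-frame cassettes (no Y/R, so no DQ2.5 motif can form); the
# codon content is deliberately dissimilar from the P/Q-rich epitope block so
# that a replacement aligns as one deletion plus one insertion rather than a
# mosaic of near-matches
_DSODN_AA_75 = "GDTVKENIAWMHSGTKDVLENQASG"  # 25 codons
_DSODN_AA_51 = "GDTVKENIASGMHKDVL"  # 17 codons


def _fixed_backtranslate(peptide: str) -> str:
    return "".join(_CODONS[aa][0] for aa in peptide)


#: default simulated dsODN designs (in-frame, epitope-free)
DSODN_75 = DsodnSpec(name="dsODN75", top_strand=_fixed_backtranslate(_DSODN_AA_75))
DSODN_51 = DsodnSpec(name="dsODN51", top_strand=_fixed_backtranslate(_DSODN_AA_51))

__all__ = [
    "EditSpec",
    "build_reference_panel",
    "default_guides",
    "simulate_sample",
    "truth_tallies",
    "DSODN_75",
    "DSODN_51",
    "DEFAULT_N_PER_TYPE",
]


def default_guides(seed_length: int = 12) -> list[GuideSpec]:
    """The two Cas9 guides flanking the simulated immunogenic block."""
    g_up = GuideSpec(
        name="gUp",
        protospacer=reverse_complement(_X3 + _HEAD_DNA[:17]),
        nuclease="cas9",
        seed_length=seed_length,
    )
    g_down = GuideSpec(
        name="gDown",
        protospacer=_TAIL_CONST_DNA[-17:] + _POST_CUT[:3],
        nuclease="cas9",
        seed_length=seed_length,
    )
    return [g_up, g_down]


def _repeats_for_type(t: int) -> tuple[int, bool]:
    """(number of PQPQLPY repeats, tail completes α3) for a hit count t."""
    if not 0 <= t <= 7:
        raise ValueError("alpha type must be 0-7")
    return t // 2 if t % 2 == 0 else (t - 1) // 2, t % 2 == 1


def _random_codons(peptide: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in peptide
    )


def _random_flank(n_codons: int, rng: np.random.Generator) -> str:
    aas = rng.choice(list(_FLANK_AA), size=n_codons, p=_FLANK_WEIGHTS)
    return _random_codons("".join(aas), rng)


def _build_reference(
    t: int | str, idx: int, rng: np.random.Generator,
    pre_codons: int, post_codons: int,
) -> ReferenceAmp:
    pseudo = t == "pseudogene"
    hits = 0 if pseudo else int(t)
    r, alpha3 = _repeats_for_type(hits)
    mid_aa = "PQPQLPY" * r + "PQPQPF"
    mid_dna = _random_codons(mid_aa, rng)
    if pseudo:
        mid_dna = mid_dna[:3] + "TAA" + mid_dna[6:]  # premature stop
    tail0 = _TAIL_F if alpha3 else _TAIL_S
    excised = _HEAD_DNA + mid_dna + tail0 + _TAIL_CONST_DNA
    pre = _random_flank(pre_codons, rng)
    post = _random_flank(post_codons, rng)
    sequence = pre + _PAM_UP + _X3 + excised + _POST_CUT + post
    cut1 = len(pre) + 6
    cut2 = cut1 + len(excised)
    name = f"Pseudo.{idx:02d}" if pseudo else f"Alpha{t}.{idx:02d}"
    return ReferenceAmp(
        id=name,
        sequence=sequence,
        alpha_type="pseudogene" if pseudo else hits,
        reading_frame_offset=0,
        epitope_region=(cut1, cut2),
    )


def build_reference_panel(
    n_per_type: Mapping[object, int] | None = None,
    seed: int = 0,
    pre_codons: int = 24,
    post_codons: int = 24,
    concentration: Mapping[object, float] | None = None,
    k: int = 12,
) -> ReferencePanel:
    """Synthesize a reference panel with the requested archetype counts.

    Baseline abundances are drawn from a Dirichlet whose per-reference
    concentration is the type's concentration divided by the number of
    references of that type (so expected type totals follow the skew).
    Every reference is self-checked before return: its translation carries
    exactly the requested DQ2.5 hit count and each guide has exactly one
    perfect-seed site at the designed cut position.
    """
    n_per_type = dict(DEFAULT_N_PER_TYPE if n_per_type is None else n_per_type)
    concentration = dict(
        DEFAULT_TYPE_CONCENTRATION if concentration is None else concentration
    )
    rng = np.random.default_rng(seed)
    refs: list[ReferenceAmp] = []
    alphas: list[float] = []
    for t in sorted(n_per_type, key=str):
        count = n_per_type[t]
        if count < 0:
            raise ValueError("counts must be >= 0")
        for idx in range(1, count + 1):
            for _ in range(100):
                ref = _build_reference(t, idx, rng, pre_codons, post_codons)
                if all(ref.sequence != other.sequence for other in refs):
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not generate a unique reference")
            refs.append(ref)
            alphas.append(concentration.get(t, 1.0) / count)
    if not refs:
        raise ValueError("empty panel requested")
    weights = rng.dirichlet(alphas)
    refs = [
        ReferenceAmp(
            id=r.id, sequence=r.sequence, baseline_abundance=float(w),
            alpha_type=r.alpha_type, reading_frame_offset=0,
            epitope_region=r.epitope_region,
        )
        for r, w in zip(refs, weights)
    ]
    panel = ReferencePanel(amps=refs, k=k)
    _self_check(panel)
    return panel


def _self_check(panel: ReferencePanel) -> None:
    for ref in panel:
        profile = scan_epitopes(translate_amp(ref.sequence, 0))
        lo, hi = ref.epitope_region
        if ref.alpha_type == "pseudogene":
            if not profile.has_internal_stop:
                raise AssertionError(f"{ref.id}: expected internal stop")
        elif profile.total_hits != ref.alpha_type:
            raise AssertionError(
                f"{ref.id}: epitope scan found {profile.total_hits} hits, "
                f"expected {ref.alpha_type}"
            )
        for guide, cut in zip(default_guides(), (lo, hi)):
            sites = sites_with_windows(guide, ref)
            if len(sites) != 1 or sites[0].cut_window.expected_cut != cut:
                raise AssertionError(f"{ref.id}: bad site layout for {guide.name}")


def annotate_panel(panel: ReferencePanel,
                   guides: Sequence[GuideSpec] | None = None) -> ReferencePanel:
    """Recover archetype and epitope-region annotation on a loaded panel.

    A panel round-tripped through FASTA loses its annotations; they are
    reconstructed from the sequences themselves — the epitope region spans
    the two guide cuts, and the type is the epitope scan of the translation
    (an internal stop marks a pseudogene).
    """
    guides = list(default_guides() if guides is None else guides)
    amps = []
    for ref in panel:
        cuts = []
        for guide in guides:
            sites = sites_with_windows(guide, ref)
            if len(sites) == 1:
                cuts.append(sites[0].cut_window.expected_cut)
        region = (min(cuts), max(cuts)) if len(cuts) >= 2 else None
        profile = scan_epitopes(translate_amp(ref.sequence, 0))
        alpha = (
            "pseudogene" if profile.has_internal_stop
            else min(profile.total_hits, 7)
        )
        amps.append(
            ReferenceAmp(
                id=ref.id, sequence=ref.sequence,
                baseline_abundance=ref.baseline_abundance,
                alpha_type=alpha, reading_frame_offset=0,
                epitope_region=region,
            )
        )
    return ReferencePanel(amps, k=panel.k)


# ---------------------------------------------------------------------------
# Read simulation


@dataclass(frozen=True)
class EditSpec:
    """Editing-outcome probabilities for one simulated transfection.

    ``dsodn_insert_prob`` is the conditional probability that an editing
    outcome (a firing guide, or a completed excision) captures the dsODN
    instead of / on top of a plain InDel.  ``indel_length_dist`` maps signed
    lengths to probabilities, peaked at -36 as observed for these guides.
    """

    per_guide_indel_probs: Mapping[str, float] = field(
        default_factory=lambda: {"gUp": 0.15, "gDown": 0.15}
    )
    indel_length_dist: Mapping[int, float] = field(
        default_factory=lambda: {
            -45: 0.03, -36: 0.30, -27: 0.05, -18: 0.07, -9: 0.06, -6: 0.08,
            -3: 0.10, -2: 0.06, -1: 0.08, 1: 0.07, 3: 0.05, 6: 0.03, 9: 0.02,
        }
    )
    excision_prob_by_type: Mapping[object, float] = field(
        default_factory=lambda: {7: 0.20, 5: 0.05, 3: 0.02, 1: 0.01}
    )
    dsodn_insert_prob: float = 0.05
    dsodn_orientation_probs: tuple[float, float] = (0.8, 0.2)
    error_rate: float = 0.002
    dsodn: DsodnSpec = DSODN_75

    def __post_init__(self) -> None:
        probs = (
            list(self.per_guide_indel_probs.values())
            + list(self.excision_prob_by_type.values())
            + [self.dsodn_insert_prob, self.error_rate]
            + list(self.dsodn_orientation_probs)
        )
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must be in [0, 1]")
        total = sum(self.indel_length_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("indel_length_dist must sum to 1")
        if 0 in self.indel_length_dist:
            raise ValueError("indel length 0 is not an event")

    @classmethod
    def null(cls) -> "EditSpec":
        return cls(
            per_guide_indel_probs={},
            excision_prob_by_type={},
            dsodn_insert_prob=0.0,
            error_rate=0.0,
        )


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class _PlantedEvent:
    kind: str
    ref_pos: int
    length: int
    inserted_seq: str = ""
    is_dsodn: bool = False

    @property
    def signed_length(self) -> int:
        return self.length if self.kind == "insertion" else -self.length


def _apply_events(seq: str, events: Sequence[_PlantedEvent]) -> str:
    for ev in sorted(events, key=lambda e: -e.ref_pos):
        if ev.kind == "deletion":
            seq = seq[: ev.ref_pos] + seq[ev.ref_pos + ev.length :]
        else:
            seq = seq[: ev.ref_pos] + ev.inserted_seq + seq[ev.ref_pos :]
    return seq


def simulate_sample(
    panel: ReferencePanel,
    spec: EditSpec,
    n_reads: int,
    seed: int,
    guides: Sequence[GuideSpec] | None = None,
    pad: int = 5,
    sample_id: str = "sim",
) -> tuple[list[str], pd.DataFrame]:
    """Draw edited reads from the panel and record per-read truth.

    Reads are sampled proportionally to baseline abundance; excisions delete
    exactly cut-to-cut; single-guide InDels are centered on the expected cut
    with lengths from the spec's distribution; dsODN captures insert the top
    strand or its reverse complement at the junction; substitution errors
    are applied last.  The truth table assigns each planted event to guides
    by the same cut-window geometry the classifier uses, so its tallies are
    the ground truth for every abundance-weighted statistic.
    """
    guides = list(default_guides() if guides is None else guides)
    rng = np.random.default_rng(seed)
    refs = list(panel)
    weights = np.array([r.baseline_abundance for r in refs], dtype=float)
    weights /= weights.sum()

    site_info: list[list[GuideSite]] = []
    for ref in refs:
        sites = [s for g in guides for s in sites_with_windows(g, ref, pad=pad)]
        site_info.append(sites)

    p_fwd, p_rev = spec.dsodn_orientation_probs
    p_fwd_norm = p_fwd / (p_fwd + p_rev) if (p_fwd + p_rev) > 0 else 1.0

    ref_choice = rng.choice(len(refs), size=n_reads, p=weights)
    reads: list[str] = []
    rows = []
    for i in range(n_reads):
        ref = refs[int(ref_choice[i])]
        sites = site_info[int(ref_choice[i])]
        cuts = {s.guide_name: s.cut_window.expected_cut for s in sites}
        events: list[_PlantedEvent] = []
        orientation = ""

        def dsodn_event(pos: int) -> _PlantedEvent:
            nonlocal orientation
            fwd = rng.random() < p_fwd_norm
            orientation = "forward" if fwd else "reverse"
            strand = (
                spec.dsodn.top_strand
                if fwd
                else reverse_complement(spec.dsodn.top_strand)
            )
            return _PlantedEvent(
                "insertion", pos, len(strand), strand, is_dsodn=True
            )

        p_exc = spec.excision_prob_by_type.get(ref.alpha_type, 0.0)
        if len(cuts) >= 2 and rng.random() < p_exc:
            lo, hi = ref.epitope_region
            events.append(_PlantedEvent("deletion", lo, hi - lo))
            if rng.random() < spec.dsodn_insert_prob:
                events.append(dsodn_event(lo))
        else:
            for site in sorted(sites, key=lambda s: -s.cut_window.expected_cut):
                p = spec.per_guide_indel_probs.get(site.guide_name, 0.0)
                if rng.random() >= p:
                    continue
                cut = site.cut_window.expected_cut
                if rng.random() < spec.dsodn_insert_prob:
                    events.append(dsodn_event(cut))
                    continue
                lengths = sorted(spec.indel_length_dist)
                probs = np.array([spec.indel_length_dist[l] for l in lengths])
                signed = int(
                    np.array(lengths)[rng.choice(len(lengths), p=probs / probs.sum())]
                )
                if signed < 0:
                    L = -signed
                    lo = max(6, cut - L // 2)
                    hi = lo + L
                    limit = len(ref.sequence) - 6
                    if hi > limit:
                        hi = limit
                        lo = hi - L
                    events.append(_PlantedEvent("deletion", lo, L))
                else:
                    ins = "".join(
                        "ACGT"[b] for b in rng.integers(0, 4, size=signed)
                    )
                    events.append(_PlantedEvent("insertion", cut, signed, ins))

        seq = _apply_events(ref.sequence, events)
        if spec.error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            mask = rng.random(len(arr)) < spec.error_rate
            if mask.any():
                idx = np.nonzero(mask)[0]
                shifts = rng.integers(1, 4, size=len(idx))
                lut = np.full(256, 0, dtype=np.uint8)
                for bi, b in enumerate(_BASES):
                    lut[b] = bi
                arr[idx] = _BASES[(lut[arr[idx]] + shifts) % 4]
                seq = arr.tobytes().decode()
        reads.append(seq)

        # guide attribution by the same cut-window geometry the caller uses
        event_guides = []
        for ev in events:
            hit = []
            for s in sites:
                w = s.cut_window
                if ev.kind == "deletion":
                    ok = w.overlaps(ev.ref_pos, ev.ref_pos + ev.length)
                else:
                    ok = w.contains_point(ev.ref_pos)
                if ok and s.guide_name not in hit:
                    hit.append(s.guide_name)
            event_guides.append(hit)

        excised = False
        spanning = False
        er = ref.epitope_region
        for ev in events:
            if ev.kind != "deletion":
                continue
            lo, hi = ev.ref_pos, ev.ref_pos + ev.length
            covered = sum(1 for c in cuts.values() if lo <= c <= hi)
            if covered >= 2:
                spanning = True
                if er and lo <= er[0] and er[1] <= hi:
                    excised = True
        if any(ev.is_dsodn for ev in events):
            category = "dsodn_targeted"
        elif spanning:
            category = "multi_guide_excision"
        elif any(event_guides[k] for k in range(len(events))):
            category = "single_guide_indel"
        elif events:
            category = "unassigned_indel"
        else:
            category = "wild_type"

        rows.append(
            {
                "read_id": f"read{i + 1}",
                "source_ref": ref.id,
                "alpha_type": ref.alpha_type,
                "category": category,
                "excised": excised,
                "dsodn_orientation": orientation,
                "n_dels": sum(1 for e in events if e.kind == "deletion"),
                "n_ins": sum(1 for e in events if e.kind == "insertion"),
                "signed_lengths": ";".join(
                    str(e.signed_length) for e in events
                ),
                "event_guides": ";".join("+".join(g) for g in event_guides),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id", "source_ref", "alpha_type", "category", "excised",
            "dsodn_orientation", "n_dels", "n_ins", "signed_lengths",
            "event_guides",
        ],
    )
    return reads, truth


def truth_tallies(truth: pd.DataFrame) -> dict:
    """Ground-truth editing statistics tallied directly from planted reads.

    Uses only the truth table (never the pipeline), with the same
    definitions as the sample report: percentages of reads, per-guide
    efficiencies against reads from site-bearing references, spectrum over
    all planted events, excision frequency per type, dsODN orientation
    share of all insertion events.
    """
    n = len(truth)
    per_read_events = [
        [
            (int(l), set(g.split("+")) if g else set())
            for l, g in zip(
                (row.signed_lengths.split(";") if row.signed_lengths else []),
                (row.event_guides.split(";") if row.event_guides else []),
            )
        ]
        for row in truth.itertuples()
    ]
    edited = sum(
        1 for evs in per_read_events if any(g for _, g in evs)
    )
    dels = sum(
        1 for evs in per_read_events if any(l < 0 and g for l, g in evs)
    )
    ins = sum(
        1 for evs in per_read_events if any(l > 0 and g for l, g in evs)
    )
    spectrum: dict[int, int] = {}
    guide_hits: dict[str, int] = {}
    for evs in per_read_events:
        seen: set[str] = set()
        for l, g in evs:
            if g:
                spectrum[l] = spectrum.get(l, 0) + 1
                seen.update(g)
        for gname in seen:
            guide_hits[gname] = guide_hits.get(gname, 0) + 1
    total_events = sum(spectrum.values())
    all_guides = sorted(guide_hits)
    out = {
        "editing_pct": 100.0 * edited / n if n else None,
        "deletions_pct": 100.0 * dels / n if n else None,
        "insertions_pct": 100.0 * ins / n if n else None,
        "indel_spectrum": {
            l: 100.0 * c / total_events for l, c in sorted(spectrum.items())
        }
        if total_events
        else {},
        "per_guide_efficiency": {
            g: 100.0 * guide_hits[g] / n for g in all_guides
        },
    }
    exc: dict[object, float] = {}
    for t, grp in truth.groupby("alpha_type"):
        if t in (0, "pseudogene"):
            continue
        exc[t] = 100.0 * grp["excised"].sum() / len(grp)
    out["excision_freq_by_type"] = exc
    total_ins_events = int(
        sum(sum(1 for l, _ in evs if l > 0) for evs in per_read_events)
    )
    if total_ins_events:
        fwd = int((truth["dsodn_orientation"] == "forward").sum())
        rev = int((truth["dsodn_orientation"] == "reverse").sum())
        out["dsodn_freq"] = {
            "forward": 100.0 * fwd / total_ins_events,
            "reverse": 100.0 * rev / total_ins_events,
        }
    else:
        out["dsodn_freq"] = {"forward": None, "reverse": None}
    return out
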