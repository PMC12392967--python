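"""sgRNA binding-site location and cut-window models for Cas9 and Cas12a.

A primary ("perfect-seed") site requires an exact match of the PAM motif and
of the PAM-proximal seed (default 12 nt) of the protospacer; mismatches are
tolerated, and counted, only in the PAM-distal remainder.  Degenerate sites
additionally allow mismatches anywhere, up to a total budget (default 3),
reflecting the observation that edits occur at guide binding sites with up
to three mismatches across a gene family.

Cut models
----------
Cas9 (PAM NGG, 3' of the protospacer) cuts predominantly bluntly 3 nt 5' of
the PAM, with evidence for a 1-nt 5' overhang; the attribution window
extends one extra base toward the PAM-distal side.  Cas12a (PAM TTTV, 5' of
the protospacer) cuts in a staggered fashion 18 nt (non-target strand) and
23 nt (target strand) 3' of the PAM, leaving a 4-5 nt 5' overhang; the
window spans both cut positions.  All coordinates are 0-based half-open on
the forward strand; ``expected_cut`` is a between-base index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .refdb import ReferenceAmp, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

DEFAULT_PAM = {"cas9": "NGG", "cas12a": "TTTV"}

__all__ = [
    "GuideSpec",
    "GuideSite",
    "CutWindow",
    "find_sites",
    "find_degenerate_sites",
    "cut_window",
]


@dataclass(frozen=True)
class GuideSpec:
    """An sgRNA: protospacer, nuclease, PAM pattern and seed length."""

    name: str
    protospacer: str
    nuclease: str = "cas9"
    pam_pattern: str | None = None
    seed_length: int = 12

    def __post_init__(self) -> None:
        nuc = self.nuclease.lower()
        if nuc not in DEFAULT_PAM:
            raise ValueError(f"unknown nuclease {self.nuclease!r}")
        object.__setattr__(self, "nuclease", nuc)
        object.__setattr__(self, "protospacer", self.protospacer.upper())
        if set(self.protospacer) - set("ACGT"):
            raise ValueError(f"guide {self.name!r}: protospacer must be ACGT")
        if self.pam_pattern is None:
            object.__setattr__(self, "pam_pattern", DEFAULT_PAM[nuc])
        else:
            object.__setattr__(self, "pam_pattern", self.pam_pattern.upper())
        if not (0 < self.seed_length <= len(self.protospacer)):
            raise ValueError("seed_length must be in [1, protospacer length]")

    @property
    def pam_length(self) -> int:
        return len(self.pam_pattern)


@dataclass(frozen=True)
class CutWindow:
    """Interval within which an InDel is attributed to one guide site."""

    expected_cut: int
    window_start: int
    window_end: int

    def __post_init__(self) -> None:
        if not (self.window_start <= self.expected_cut <= self.window_end):
            raise ValueError("window must contain expected_cut")
        if self.window_end - self.window_start < 1:
            raise ValueError("window width must be >= 1")

    def contains_point(self, pos: int) -> bool:
        """Insertion-point membership; window edges count as inside."""
        return self.window_start <= pos <= self.window_end

    def overlaps(self, start: int, end: int) -> bool:
        return start < self.window_end and self.window_start < end


@dataclass(frozen=True)
class GuideSite:
    """A located protospacer+PAM occurrence on a reference amplicon."""

    guide_name: str
    ref_id: str
    strand: str
    protospacer_start: int
    protospacer_end: int
    pam_start: int
    pam_end: int
    mismatches: int
    seed_perfect: bool
    nuclease: str = "cas9"
    cut_window: CutWindow | None = None


def _pam_matches(pattern: str, seq: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in IUPAC[p] for p, b in zip(pattern, seq)
    )


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _scan_strand(
    guide: GuideSpec, ref: ReferenceAmp, strand: str
) -> list[tuple[int, int, int, int, int, int]]:
    """Yield candidate placements as forward-strand coordinates.

    Returns tuples (proto_start, proto_end, pam_start, pam_end,
    seed_mismatches, nonseed_mismatches).  The reverse strand is handled by
    scanning the reverse complement and mirroring coordinates.
    """
    seq = ref.sequence if strand == "+" else reverse_complement(ref.sequence)
    n = len(seq)
    L = len(guide.protospacer)
    P = guide.pam_length
    s = guide.seed_length
    out = []
    for start in range(0, n - L - P + 1):
        if guide.nuclease == "cas9":
            proto = seq[start : start + L]
            pam = seq[start + L : start + L + P]
            pam_lo, pam_hi = start + L, start + L + P
            seed = proto[L - s :]  # PAM-proximal = 3' end
            seed_ref = guide.protospacer[L - s :]
            rest, rest_ref = proto[: L - s], guide.protospacer[: L - s]
        else:  # cas12a: PAM is 5' of the protospacer
            pam = seq[start : start + P]
            proto = seq[start + P : start + P + L]
            pam_lo, pam_hi = start, start + P
            proto_offset = start + P
            start = proto_offset  # protospacer coordinates
            seed = proto[:s]  # PAM-proximal = 5' end
            seed_ref = guide.protospacer[:s]
            rest, rest_ref = proto[s:], guide.protospacer[s:]
        if not _pam_matches(guide.pam_pattern, pam):
            continue
        seed_mm = _hamming(seed, seed_ref)
        rest_mm = _hamming(rest, rest_ref)
        if strand == "+":
            out.append((start, start + L, pam_lo, pam_hi, seed_mm, rest_mm))
        else:
            out.append(
                (
                    n - (start + L), n - start,
                    n - pam_hi, n - pam_lo,
                    seed_mm, rest_mm,
                )
            )
    return out


def _sites(
    guide: GuideSpec,
    ref: ReferenceAmp,
    max_total_mm: int | None,
    require_seed: bool,
) -> list[GuideSite]:
    sites = []
    for strand in "+-":
        for ps, pe, ams, ame, seed_mm, rest_mm in _scan_strand(guide, ref, strand):
            total = seed_mm + rest_mm
            seed_perfect = seed_mm == 0
            if require_seed and not seed_perfect:
                continue
            # degenerate mode keeps perfect-seed sites regardless of total
            # mismatches so that the primary sites are always a subset
            if max_total_mm is not None and total > max_total_mm and not seed_perfect:
                continue
            sites.append(
                GuideSite(
                    guide_name=guide.name,
                    ref_id=ref.id,
                    strand=strand,
                    protospacer_start=ps,
                    protospacer_end=pe,
                    pam_start=ams,
                    pam_end=ame,
                    mismatches=total,
                    seed_perfect=seed_perfect,
                    nuclease=guide.nuclease,
                )
            )
    sites.sort(key=lambda s: (s.protospacer_start, s.strand))
    return sites


def find_sites(guide: GuideSpec, ref: ReferenceAmp) -> list[GuideSite]:
    """Primary sites: exact PAM and exact PAM-proximal seed on either strand.

    Mismatches outside the seed are counted and reported, not filtered; this
    is how family members that differ from the designed target in the
    PAM-distal region are still recognized as binding sites.
    """
    return _sites(guide, ref, max_total_mm=None, require_seed=True)


def find_degenerate_sites(
    guide: GuideSpec, ref: ReferenceAmp, max_mm: int = 3
) -> list[GuideSite]:
    """Sites with up to ``max_mm`` total mismatches (seed included), plus all
    perfect-seed sites.  Always a superset of :func:`find_sites`."""
    if max_mm > 5:
        raise ValueError("max_mm must be <= 5")
    return _sites(guide, ref, max_total_mm=max_mm, require_seed=False)


def cut_window(site: GuideSite, ref_length: int, pad: int = 5) -> CutWindow:
    """Build the cut-attribution window for a site, clipped to the reference.

    Cas9: blunt cut 3 nt 5' of the PAM; window ``[cut-1-pad, cut+pad)`` on
    the site's strand (the extra base reflects the 1-nt 5' overhang).
    Cas12a: staggered cuts 18 and 23 nt 3' of the PAM; window spans both
    cuts +/- pad.  All output coordinates are on the forward strand.
    """
    if site.nuclease == "cas9":
        if site.strand == "+":
            cut = site.pam_start - 3
            lo, hi = cut - 1 - pad, cut + pad
        else:
            cut = site.pam_end + 3
            lo, hi = cut - pad, cut + 1 + pad
    else:  # cas12a
        if site.strand == "+":
            cut_nt = site.pam_end + 18  # non-target strand
            cut_t = site.pam_end + 23  # target strand
            cut = cut_nt
            lo, hi = cut_nt - pad, cut_t + pad
        else:
            cut_nt = site.pam_start - 18
            cut_t = site.pam_start - 23
            cut = cut_nt
            lo, hi = cut_t - pad, cut_nt + pad
    lo = max(0, lo)
    hi = min(ref_length, hi)
    cut = min(max(cut, lo), hi)
    return CutWindow(expected_cut=cut, window_start=lo, window_end=hi)


def sites_with_windows(
    guide: GuideSpec, ref: ReferenceAmp, pad: int = 5, degenerate_mm: int | None = None
) -> list[GuideSite]:
    """Convenience: locate sites and attach cut windows in one pass."""
    finder = (
        find_sites(guide, ref)
        if degenerate_mm is None
        else find_degenerate_sites(guide, ref, degenerate_mm)
    )
    out = []
    for site in finder:
        win = cut_window(site, len(ref.sequence), pad=pad)
        out.append(
            GuideSite(
                **{
                    **site.__dict__,
                    "cut_window": win,
                }
            )
        )
    return out
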