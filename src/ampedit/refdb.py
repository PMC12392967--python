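"""Reference panels, read dereplication and gene-family screening.

The pipeline's entry point is a set of already-merged amplicon reads and a
panel of wild-type reference amplicons ("reference Amps") for one multi-copy
gene family.  Reads are collapsed into unique sample sequences ("Amps") with
abundances, screened for family membership by k-mer containment against the
panel, and later aligned to their closest reference.
"""

from __future__ import annotations

import gzip
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")

__all__ = [
    "ReferenceAmp",
    "ReferencePanel",
    "Amp",
    "AmpSet",
    "load_reference_panel",
    "write_panel",
    "dereplicate",
    "quantify_abundance",
    "filter_gene_family",
    "read_sequences",
    "write_ampset",
]


@dataclass(frozen=True)
class ReferenceAmp:
    """One wild-type family member amplicon.

    ``alpha_type`` is the archetype index (total count of DQ2.5 epitope hits
    in the translated repetitive region, capped at 7) or the string
    ``"pseudogene"``; ``None`` means not yet annotated.  ``epitope_region``
    is the half-open interval of the epitope-coding block on the amplicon,
    used to decide whether an excision removed the immunogenic region.
    """

    id: str
    sequence: str
    baseline_abundance: float = 0.0
    alpha_type: int | str | None = None
    reading_frame_offset: int = 0
    epitope_region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"reference {self.id!r}: non-ACGT characters {sorted(bad)}"
            )
        if self.baseline_abundance < 0:
            raise ValueError(f"reference {self.id!r}: negative abundance")
        if self.reading_frame_offset not in (0, 1, 2):
            raise ValueError(f"reference {self.id!r}: frame offset must be 0-2")


def _kmers(seq: str, k: int) -> Iterable[str]:
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


@dataclass
class ReferencePanel:
    """An ordered reference panel with a k-mer index for fast screening."""

    amps: list[ReferenceAmp]
    k: int = 12
    kmer_index: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [a.id for a in self.amps]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate reference ids: {dupes}")
        if not self.kmer_index:
            self.kmer_index = self._build_index()

    def _build_index(self) -> dict[str, list[str]]:
        index: dict[str, list[str]] = {}
        for amp in self.amps:
            for kmer in _kmers(amp.sequence, self.k):
                index.setdefault(kmer, []).append(amp.id)
        return index

    def __len__(self) -> int:
        return len(self.amps)

    def __iter__(self):
        return iter(self.amps)

    def get(self, ref_id: str) -> ReferenceAmp:
        for amp in self.amps:
            if amp.id == ref_id:
                return amp
        raise KeyError(ref_id)

    def shared_kmer_counts(self, sequence: str) -> dict[str, int]:
        """Number of distinct k-mers shared between ``sequence`` and each reference."""
        counts: Counter[str] = Counter()
        for kmer in set(_kmers(sequence, self.k)):
            for ref_id in set(self.kmer_index.get(kmer, ())):
                counts[ref_id] += 1
        return dict(counts)


@dataclass(frozen=True)
class Amp:
    """A dereplicated sample sequence with its read count (abundance)."""

    sequence: str
    count: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("Amp count must be >= 1")


@dataclass
class AmpSet:
    """The dereplicated Amps of one sample, with read accounting.

    ``total_reads`` is the number of input reads; retained counts plus
    ``discarded_low_count`` plus ``discarded_offtarget`` always sum to it.
    """

    amps: list[Amp]
    total_reads: int
    sample_id: str = ""
    discarded_low_count: int = 0
    discarded_offtarget: int = 0

    @property
    def retained_reads(self) -> int:
        return sum(a.count for a in self.amps)

    def __len__(self) -> int:
        return len(self.amps)

    def __iter__(self):
        return iter(self.amps)


# ---------------------------------------------------------------------------
# Sequence I/O


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: str | Path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    suffix = Path(name).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    return "fasta"


def read_sequences(
    path: str | Path,
    fmt: str | None = None,
    min_mean_q: float | None = None,
) -> list[str]:
    """Read merged amplicon reads from FASTA or FASTQ (plain or gzip).

    FASTQ qualities are parsed but ignored unless ``min_mean_q`` is given, in
    which case reads with mean Phred quality below the cutoff are dropped
    (documented optional filter; quality control normally happens upstream of
    this pipeline, at the read-merging stage).
    """
    fmt = fmt or _sniff_format(path)
    out: list[str] = []
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, fmt):
            if fmt == "fastq" and min_mean_q is not None:
                quals = record.letter_annotations.get("phred_quality", [])
                if quals and sum(quals) / len(quals) < min_mean_q:
                    continue
            out.append(str(record.seq).upper())
    return out


def _wrap(seq: str, width: int = 80) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def load_reference_panel(
    path: str | Path,
    abundances: str | Path | Mapping[str, float] | None = None,
    k: int = 12,
) -> ReferencePanel:
    """Load a reference panel from FASTA, with optional baseline abundances.

    ``abundances`` may be a 2-column TSV path (id, abundance) or a mapping.
    Abundances are normalized to sum to 1; absent a table they default to
    uniform.  Record ids are the first whitespace-delimited header token.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            rid = record.id
            if rid in seen:
                raise ValueError(f"duplicate reference id {rid!r} in {path}")
            seen.add(rid)
            seq = str(record.seq).upper()
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"record {rid!r}: non-ACGT characters {sorted(bad)}"
                )
            records.append((rid, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")

    if abundances is None:
        weights = {rid: 1.0 for rid, _ in records}
    elif isinstance(abundances, Mapping):
        weights = dict(abundances)
    else:
        weights = {}
        with open(abundances) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                rid, value = line.split("\t")[:2]
                weights[rid] = float(value)
    missing = {rid for rid, _ in records} - set(weights)
    if abundances is not None and missing:
        raise ValueError(f"abundance table missing ids: {sorted(missing)}")
    total = sum(weights[rid] for rid, _ in records)
    if total <= 0:
        raise ValueError("abundances must sum to a positive value")

    amps = [
        ReferenceAmp(id=rid, sequence=seq, baseline_abundance=weights[rid] / total)
        for rid, seq in records
    ]
    return ReferencePanel(amps=amps, k=k)


def write_panel(panel: ReferencePanel, fasta_path: str | Path,
                abundance_path: str | Path | None = None) -> None:
    """Write the panel as 80-column-wrapped FASTA (+ optional abundance TSV)."""
    with open(fasta_path, "w") as handle:
        for amp in panel:
            handle.write(f">{amp.id}\n{_wrap(amp.sequence)}\n")
    if abundance_path is not None:
        with open(abundance_path, "w") as handle:
            for amp in panel:
                handle.write(f"{amp.id}\t{amp.baseline_abundance:.10g}\n")


# ---------------------------------------------------------------------------
# Dereplication and screening


def dereplicate(
    reads: Sequence[str],
    min_count: int = 2,
    sample_id: str = "",
) -> AmpSet:
    """Collapse reads into unique Amps and drop those below ``min_count``.

    The minimum-abundance filter stands in for amplicon denoising: genuinely
    edited molecules are sampled repeatedly while stochastic error sequences
    are mostly singletons.  Amps are ordered by descending count, then by
    sequence, so output is deterministic regardless of read order.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = Counter(r.upper() for r in reads)
    kept = [
        Amp(sequence=seq, count=n, sample_id=sample_id)
        for seq, n in counts.items()
        if n >= min_count
    ]
    kept.sort(key=lambda a: (-a.count, a.sequence))
    retained = sum(a.count for a in kept)
    return AmpSet(
        amps=kept,
        total_reads=len(reads),
        sample_id=sample_id,
        discarded_low_count=len(reads) - retained,
    )


def quantify_abundance(ampset: AmpSet, raw_reads: Sequence[str]) -> AmpSet:
    """Re-count each Amp as the number of raw reads exactly equal to it.

    Mirrors abundance quantification by exact search of raw reads against the
    dereplicated Amp database; reads matching no Amp stay unassigned (tracked
    in ``discarded_low_count``).
    """
    sequences = [a.sequence for a in ampset.amps]
    if len(sequences) != len(set(sequences)):
        raise ValueError("AmpSet sequences must be unique")
    tally = Counter(r.upper() for r in raw_reads)
    amps = [
        replace(a, count=tally[a.sequence])
        for a in ampset.amps
        if tally[a.sequence] >= 1
    ]
    amps.sort(key=lambda a: (-a.count, a.sequence))
    assigned = sum(a.count for a in amps)
    return AmpSet(
        amps=amps,
        total_reads=len(raw_reads),
        sample_id=ampset.sample_id,
        discarded_low_count=len(raw_reads) - assigned,
        discarded_offtarget=ampset.discarded_offtarget,
    )


def filter_gene_family(
    ampset: AmpSet,
    panel: ReferencePanel,
    k: int = 12,
    min_shared_frac: float = 0.5,
) -> AmpSet:
    """Retain Amps whose k-mer containment in the panel passes the threshold.

    An Amp is kept iff the fraction of its k-mers present anywhere in the
    panel index is at least ``min_shared_frac``; this screens out off-target
    amplification products without requiring an external homology search.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if not (0 < min_shared_frac <= 1):
        raise ValueError("min_shared_frac must be in (0, 1]")
    index_panel = panel if panel.k == k else ReferencePanel(list(panel.amps), k=k)
    kept: list[Amp] = []
    discarded = 0
    for amp in ampset.amps:
        if len(amp.sequence) < k:
            warnings.warn(
                f"Amp shorter than k={k} discarded (len {len(amp.sequence)})",
                stacklevel=2,
            )
            discarded += amp.count
            continue
        kmers = list(_kmers(amp.sequence, k))
        shared = sum(1 for km in kmers if km in index_panel.kmer_index)
        if shared / len(kmers) >= min_shared_frac:
            kept.append(amp)
        else:
            discarded += amp.count
    return AmpSet(
        amps=kept,
        total_reads=ampset.total_reads,
        sample_id=ampset.sample_id,
        discarded_low_count=ampset.discarded_low_count,
        discarded_offtarget=ampset.discarded_offtarget + discarded,
    )


def write_ampset(
    ampset: AmpSet,
    fasta_path: str | Path | None = None,
    tsv_path: str | Path | None = None,
) -> None:
    """Dump an AmpSet as size-annotated FASTA and/or a flat TSV."""
    if fasta_path is not None:
        with open(fasta_path, "w") as handle:
            for i, amp in enumerate(ampset.amps, start=1):
                handle.write(f">amp{i};size={amp.count}\n{_wrap(amp.sequence)}\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as handle:
            handle.write("sample_id\tamp_id\tsequence\tcount\n")
            for i, amp in enumerate(ampset.amps, start=1):
                handle.write(
                    f"{ampset.sample_id}\tamp{i}\t{amp.sequence}\t{amp.count}\n"
                )


def write_fastq(reads: Sequence[str], path: str | Path, quality: int = 40) -> None:
    """Write plain sequences as FASTQ with uniform quality."""
    qchar = chr(quality + 33)
    with _open_maybe_gzip(path, "wt") as handle:
        for i, seq in enumerate(reads, start=1):
            handle.write(f"@read{i}\n{seq}\n+\n{qchar * len(seq)}\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
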