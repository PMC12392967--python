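"""End-to-end sample calling: dereplicate → screen → align → classify → report.

The stages mirror the amplicon workflow for multi-copy gene families:
reads are collapsed to unique Amps with abundances, screened for family
membership, assigned to their closest reference by local alignment with
escalation to free-end-gap global alignment for heavily clipped Amps,
and their InDels are normalized toward guide cut windows, attributed to
guides, and summarized into abundance-weighted statistics (editing %,
per-guide efficiency, InDel spectrum, excision frequency by amplicon type,
dsODN orientation frequencies, relative epitope loss).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import align as _align
from .align import DEFAULT_GLOBAL, DEFAULT_LOCAL, Scoring, choose_reference, extract_indels, normalize_indel
from .classify import (
    ClassifiedEdit,
    SampleReport,
    apply_display_threshold,
    assign_events,
    detect_excision,
    excision_frequency_by_type,
    sample_statistics,
)
from .dsodn import DsodnCall, DsodnSpec, detect_dsodn, dsodn_frequency
from .epitopes import DQ25_MOTIFS, relative_epitope_loss
from .guides import GuideSpec, sites_with_windows
from .refdb import (
    AmpSet,
    ReferencePanel,
    dereplicate,
    filter_gene_family,
    load_reference_panel,
    read_sequences,
)

logger = logging.getLogger("ampedit")

SCHEMA_VERSION = 1

__all__ = ["PipelineParams", "RunConfig", "call_sample", "run_pipeline",
           "report_to_dict", "write_report"]


@dataclass(frozen=True)
class PipelineParams:
    """Tunable thresholds, with the defaults used throughout the package."""

    min_count: int = 2
    k: int = 12
    min_shared_frac: float = 0.5
    pad: int = 5
    degenerate_mm: int = 3
    clip_frac: float = 0.15
    top_c: int = 8
    display_threshold: float = 0.5
    scoring_local: Scoring = DEFAULT_LOCAL
    scoring_global: Scoring = DEFAULT_GLOBAL
    min_mean_q: float | None = None


def _site_tables(panel: ReferencePanel, guides: Sequence[GuideSpec],
                 params: PipelineParams):
    """Per-reference guide sites (degenerate included) and the perfect-seed
    guide sets used for per-guide efficiency denominators."""
    sites_by_ref: dict[str, list] = {}
    perfect_by_ref: dict[str, list[str]] = {}
    for ref in panel:
        sites = []
        for guide in guides:
            sites.extend(
                sites_with_windows(
                    guide, ref, pad=params.pad, degenerate_mm=params.degenerate_mm
                )
            )
        sites_by_ref[ref.id] = sites
        perfect_by_ref[ref.id] = sorted(
            {s.guide_name for s in sites if s.seed_perfect}
        )
    return sites_by_ref, perfect_by_ref


def call_sample(
    reads: Sequence[str],
    panel: ReferencePanel,
    guides: Sequence[GuideSpec],
    dsodn_specs: Sequence[DsodnSpec] = (),
    motifs: Mapping[str, str] = DQ25_MOTIFS,
    p31_43: str | None = None,
    params: PipelineParams = PipelineParams(),
    sample_id: str = "sample",
) -> tuple[SampleReport, list[ClassifiedEdit], AmpSet, list[DsodnCall]]:
    """Run the full calling workflow on one sample's merged reads."""
    ampset = dereplicate(reads, min_count=params.min_count, sample_id=sample_id)
    logger.info(
        "%s: %d reads -> %d unique Amps (%d reads below min_count)",
        sample_id, ampset.total_reads, len(ampset), ampset.discarded_low_count,
    )
    ampset = filter_gene_family(
        ampset, panel, k=params.k, min_shared_frac=params.min_shared_frac
    )
    logger.info(
        "%s: family screen kept %d Amps (%d reads off-target)",
        sample_id, len(ampset), ampset.discarded_offtarget,
    )

    sites_by_ref, perfect_by_ref = _site_tables(panel, guides, params)

    edits: list[ClassifiedEdit] = []
    calls: list[DsodnCall] = []
    unalignable = 0
    mode_abundance = {"local": 0, "global": 0}
    for amp in ampset:
        chosen = choose_reference(
            amp, panel,
            scoring_local=params.scoring_local,
            scoring_global=params.scoring_global,
            top_c=params.top_c,
            clip_frac=params.clip_frac,
        )
        if chosen is None:
            unalignable += amp.count
            logger.warning("%s: unalignable Amp (count %d) excluded",
                           sample_id, amp.count)
            continue
        ref, aln = chosen
        mode_abundance[aln.mode] += amp.count
        sites = sites_by_ref[ref.id]
        windows = [s.cut_window for s in sites if s.cut_window]
        events = [
            normalize_indel(ev, ref.sequence, windows)
            for ev in extract_indels(aln)
        ]
        edit = ClassifiedEdit(
            amp=amp,
            reference=ref,
            alignment=aln,
            events=events,
            guide_assignments=assign_events(events, sites),
        )
        detect_excision(edit, sites, tol=params.pad)
        for spec in dsodn_specs:
            call = detect_dsodn(edit, spec, sites, tol=params.pad)
            if call is not None:
                calls.append(call)
                break
        edits.append(edit)

    report = sample_statistics(edits, ampset, perfect_by_ref)
    report.excision_freq_by_type = excision_frequency_by_type(
        edits, panel, tol=params.pad
    )
    report.dsodn_freq = dsodn_frequency(calls, edits)
    loss = relative_epitope_loss(edits, panel, motifs=motifs, p31_43=p31_43)
    report.epitope_loss = loss.per_epitope_loss
    report.combined_epitope_loss = loss.combined_loss
    report.unalignable_reads = unalignable
    total = ampset.total_reads
    if total:
        report.alignment_mode_pct = {
            m: 100.0 * ab / total for m, ab in mode_abundance.items()
        }
        logger.info(
            "%s: %.1f%% of reads aligned locally, additional %.1f%% globally",
            sample_id,
            report.alignment_mode_pct["local"],
            report.alignment_mode_pct["global"],
        )
    return report, edits, ampset, calls


# ---------------------------------------------------------------------------
# Report serialization (percentages formatted to one decimal place)


def _fmt(value):
    if value is None:
        return "NA"
    return round(value, 1)


def report_to_dict(report: SampleReport, display_threshold: float = 0.5) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "sample_id": report.sample_id,
        "family_abundance": report.family_abundance,
        "editing_pct": _fmt(report.editing_pct),
        "deletions_pct": _fmt(report.deletions_pct),
        "insertions_pct": _fmt(report.insertions_pct),
        "per_guide_efficiency": {
            g: _fmt(v) for g, v in report.per_guide_efficiency.items()
        },
        "indel_spectrum": {
            str(k): _fmt(v)
            for k, v in apply_display_threshold(
                report.indel_spectrum, display_threshold
            ).items()
        },
        "excision_freq_by_type": {
            str(t): _fmt(v) for t, v in report.excision_freq_by_type.items()
        },
        "dsodn_freq": {o: _fmt(v) for o, v in report.dsodn_freq.items()},
        "epitope_loss": {m: _fmt(v) for m, v in report.epitope_loss.items()},
        "combined_epitope_loss": _fmt(report.combined_epitope_loss),
        "alignment_mode_pct": {
            m: _fmt(v) for m, v in report.alignment_mode_pct.items()
        },
        "unalignable_reads": report.unalignable_reads,
    }


def write_report(
    report: SampleReport,
    outdir: str | Path,
    display_threshold: float = 0.5,
) -> None:
    """Write the JSON report plus flat TSVs for each statistic family."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = report_to_dict(report, display_threshold)
    (outdir / f"{report.sample_id}.report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )

    def tsv(name: str, header: list[str], rows: list[list]):
        lines = ["\t".join(header)]
        lines += ["\t".join(str(x) for x in row) for row in rows]
        (outdir / f"{report.sample_id}.{name}.tsv").write_text(
            "\n".join(lines) + "\n"
        )

    tsv(
        "summary",
        ["sample_id", "editing_pct", "deletions_pct", "insertions_pct",
         "unalignable_reads"],
        [[report.sample_id, _fmt(report.editing_pct),
          _fmt(report.deletions_pct), _fmt(report.insertions_pct),
          report.unalignable_reads]],
    )
    tsv(
        "per_guide",
        ["guide", "efficiency_pct"],
        [[g, _fmt(v)] for g, v in report.per_guide_efficiency.items()],
    )
    tsv(
        "spectrum",
        ["signed_length", "frequency_pct"],
        [
            [k, _fmt(v)]
            for k, v in apply_display_threshold(
                report.indel_spectrum, display_threshold
            ).items()
        ],
    )
    tsv(
        "excision_by_type",
        ["alpha_type", "excision_pct"],
        [[t, _fmt(v)] for t, v in report.excision_freq_by_type.items()],
    )
    tsv(
        "epitope_loss",
        ["motif", "loss_pct"],
        [[m, _fmt(v)] for m, v in report.epitope_loss.items()]
        + [["combined", _fmt(report.combined_epitope_loss)]],
    )


# ---------------------------------------------------------------------------
# File-driven runs


@dataclass
class RunConfig:
    """A reproducible run: inputs, guide/dsODN/motif specs and thresholds."""

    panel_fasta: str
    reads: list[str]
    output_dir: str = "ampedit_out"
    abundance_tsv: str | None = None
    guides: list[GuideSpec] = field(default_factory=list)
    dsodns: list[DsodnSpec] = field(default_factory=list)
    motifs: dict[str, str] = field(default_factory=lambda: dict(DQ25_MOTIFS))
    p31_43: str | None = None
    params: PipelineParams = PipelineParams()
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "panel_fasta": self.panel_fasta,
            "reads": list(self.reads),
            "output_dir": self.output_dir,
            "abundance_tsv": self.abundance_tsv,
            "guides": [dataclasses.asdict(g) for g in self.guides],
            "dsodns": [dataclasses.asdict(d) for d in self.dsodns],
            "motifs": dict(self.motifs),
            "p31_43": self.p31_43,
            "params": {
                **{
                    f.name: getattr(self.params, f.name)
                    for f in dataclasses.fields(PipelineParams)
                    if f.name not in ("scoring_local", "scoring_global")
                },
                "scoring_local": dataclasses.asdict(self.params.scoring_local),
                "scoring_global": dataclasses.asdict(self.params.scoring_global),
            },
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        params = data.get("params", {})
        kwargs = dict(params)
        if "scoring_local" in kwargs:
            kwargs["scoring_local"] = Scoring(**kwargs["scoring_local"])
        if "scoring_global" in kwargs:
            kwargs["scoring_global"] = Scoring(**kwargs["scoring_global"])
        return cls(
            panel_fasta=data["panel_fasta"],
            reads=list(data["reads"]),
            output_dir=data.get("output_dir", "ampedit_out"),
            abundance_tsv=data.get("abundance_tsv"),
            guides=[GuideSpec(**g) for g in data.get("guides", [])],
            dsodns=[DsodnSpec(**d) for d in data.get("dsodns", [])],
            motifs=dict(data.get("motifs", DQ25_MOTIFS)),
            p31_43=data.get("p31_43"),
            params=PipelineParams(**kwargs),
            seed=int(data.get("seed", 0)),
            log_level=data.get("log_level", "INFO"),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: RunConfig) -> list[SampleReport]:
    """Run every sample in the config and write reports to the output dir.

    Samples are independent (no shared mutable state); reads are conserved
    across stages in the per-stage log accounting.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    panel = load_reference_panel(
        config.panel_fasta, abundances=config.abundance_tsv, k=config.params.k
    )
    reports = []
    for path in config.reads:
        sample_id = Path(Path(path).stem).stem or "sample"
        reads = read_sequences(path, min_mean_q=config.params.min_mean_q)
        report, edits, ampset, calls = call_sample(
            reads, panel, config.guides, config.dsodns,
            motifs=config.motifs, p31_43=config.p31_43,
            params=config.params, sample_id=sample_id,
        )
        write_report(report, config.output_dir, config.params.display_threshold)
        reports.append(report)
    if len(reports) > 1:
        combined = Path(config.output_dir) / "combined_summary.tsv"
        lines = ["sample_id\tediting_pct\tdeletions_pct\tinsertions_pct"]
        for r in reports:
            lines.append(
                f"{r.sample_id}\t{_fmt(r.editing_pct)}"
                f"\t{_fmt(r.deletions_pct)}\t{_fmt(r.insertions_pct)}"
            )
        combined.write_text("\n".join(lines) + "\n")
    return reports
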