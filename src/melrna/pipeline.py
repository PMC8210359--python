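"""End-to-end pipeline: trim -> annotate/filter -> quantify -> 3'-end report.

The pipeline consumes the files a sequencing run plus standard external
tools produce — a raw FASTQ, a RepeatMasker ``.out`` of the trimmed reads
against the repeat library, a SAM with all perfect genomic alignments per
read, the repeat-locus table and the genome FASTA — and assembles one
:class:`PipelineReport` with the summary statistics of the method:
control-read counts and ratios, the TSS-pass fraction, mapping-multiplicity
fractions, locus/family expression (RPM, reads per million 5S reads), the
stand-alone fraction of poorly expressed loci, terminator-category
fractions and the log2(RPM) locus histogram.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate_filter import (
    ControlCounts,
    FilterConfig,
    count_control_reads,
    ratio_to_control,
    select_sine_reads,
    tss_fraction,
)
from .io_formats import Genome, parse_rmsk_out, read_fastq, read_sam_grouped
from .preprocess import TrimConfig, trim_reads
from .quantify import (
    AlignmentIndex,
    LocusIndex,
    aggregate_family,
    classify_standalone,
    count_loci,
    expression_histogram,
    multiplicity_fractions,
    normalize_rpm,
    standalone_summary,
)
from .io_formats import read_locus_table, write_fastq
from .terminator import call_terminator, summarize_terminators

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "StageError", "run_pipeline", "render_report"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Input paths and per-stage parameters for one sample."""

    fastq: str
    rm_out: str
    sam: str
    loci: str
    genome: str
    outdir: str = "melrna_out"
    loci_dialect: str = "ucsc_rmsk"
    trim: TrimConfig = field(default_factory=TrimConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    five_s_label: str = "5S_rRNA"
    flank_bp: int = 5000
    poorly_expressed_max: int = 3
    histogram_bin_width: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        trim = TrimConfig(**raw.pop("trim", {}))
        filt = FilterConfig(**raw.pop("filter", {}))
        return cls(trim=trim, filter=filt, **raw)

    @classmethod
    def from_simulation_dir(cls, simdir: str | Path, outdir: str | Path | None = None,
                            **overrides) -> "PipelineConfig":
        """Point every input at the files a simulation run emitted."""
        simdir = Path(simdir)
        return cls(
            fastq=str(simdir / "reads.fastq"),
            rm_out=str(simdir / "reads.out"),
            sam=str(simdir / "alignments.sam"),
            loci=str(simdir / "loci.tsv"),
            genome=str(simdir / "genome.fa"),
            outdir=str(outdir if outdir is not None else simdir / "pipeline_out"),
            **overrides,
        )

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineReport:
    """All summary statistics of one pipeline run."""

    trim_counts: dict[str, int]
    control_counts: ControlCounts
    control_ratios: dict[str, float]
    tss_pass_fraction: float
    multiplicity_fractions: dict[str, float]
    family_table: pd.DataFrame
    locus_table: pd.DataFrame
    standalone: dict[str, float]
    terminator_table: pd.DataFrame
    histogram: dict
    n_expressed_loci: int
    config_hash: str = ""


def _require(path: str, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise StageError(stage, f"missing input file: {path}")
    return p


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute every stage deterministically and write all intermediates."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- trim ------------------------------------------------------------
    fastq = _require(cfg.fastq, "trim")
    reads, trim_counts = trim_reads(read_fastq(fastq), cfg.trim)
    write_fastq(reads, outdir / "trimmed.fastq")
    reads_by_id = {r.read_id: r for r in reads}
    logger.info("trim: kept %d of %d reads", trim_counts["kept"], sum(trim_counts.values()))

    # --- annotate / filter ------------------------------------------------
    rm_out = _require(cfg.rm_out, "filter")
    alignments = list(parse_rmsk_out(rm_out))
    sine_calls = select_sine_reads(alignments, cfg.filter)
    frac_tss = tss_fraction(alignments, cfg.filter)
    controls = count_control_reads(alignments, cfg.filter, total_reads=len(reads))
    ratios = {
        f"{label}_over_5.8S": ratio_to_control(controls, label, "5.8S_rRNA")
        for label in cfg.filter.control_names
        if label != "5.8S_rRNA"
    }
    pd.DataFrame(
        [(c.read_id, c.subfamily, c.repeat_begin) for c in sine_calls.values()],
        columns=["read_id", "subfamily", "repeat_begin"],
    ).to_csv(outdir / "sine_reads.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"control": list(controls.counts), "count": list(controls.counts.values())}
    ).to_csv(outdir / "control_counts.tsv", sep="\t", index=False)
    logger.info("filter: %d TSS-passing SINE reads, TSS fraction %.3f",
                len(sine_calls), frac_tss)

    # --- quantify ---------------------------------------------------------
    sam = _require(cfg.sam, "quantify")
    loci_path = _require(cfg.loci, "quantify")
    loci = read_locus_table(loci_path, cfg.loci_dialect)
    groups = list(read_sam_grouped(sam))
    # multiplicity statistics refer to the mapped library: the TSS-selected
    # SINE reads (controls are annotated, not genome-mapped)
    mult = multiplicity_fractions(g for g in groups if g.read_id in sine_calls)
    index = LocusIndex(loci, max_tss_offset=cfg.filter.max_tss_offset)
    expressions, assignments = count_loci(
        groups, index, restrict_to=set(sine_calls)
    )
    five_s = controls.counts.get(cfg.five_s_label, 0)
    try:
        expressions = normalize_rpm(expressions, five_s)
    except ValueError as exc:
        raise StageError("quantify", str(exc)) from exc
    family_table = aggregate_family(expressions)
    locus_table = pd.DataFrame(
        {
            "locus_id": [e.locus_id for e in expressions],
            "family": [e.locus.family for e in expressions],
            "subfamily": [e.locus.subfamily for e in expressions],
            "raw_count": [e.raw_count for e in expressions],
            "rpm": [e.rpm for e in expressions],
        }
    )
    locus_table.to_csv(outdir / "locus_expression.tsv", sep="\t", index=False)
    family_table.to_csv(outdir / "family_expression.tsv", sep="\t")
    n_expressed = int((locus_table["raw_count"] > 0).sum())

    # --- stand-alone test (uses ALL unique reads, not just SINE reads) ----
    all_unique = [g.alignments[0] for g in groups if g.multiplicity_bin == "unique"]
    flank_index = AlignmentIndex(all_unique)
    # recompute assignment over all unique reads so host-gene reads assigned
    # to the locus itself are excluded from its flank count
    _, all_assignments = count_loci(groups, index)
    assigned_by_locus: dict[str, set[str]] = {}
    for read_id, locus_id in all_assignments.items():
        if locus_id is not None:
            assigned_by_locus.setdefault(locus_id, set()).add(read_id)
    by_id = {e.locus_id: e for e in expressions}
    poorly = [
        e for e in expressions
        if 0 < e.raw_count <= cfg.poorly_expressed_max
    ]
    calls = [
        classify_standalone(
            e.locus, flank_index, cfg.flank_bp,
            exclude_read_ids=assigned_by_locus.get(e.locus_id, set()),
        )
        for e in poorly
    ]
    standalone = standalone_summary(calls)
    pd.DataFrame(
        [
            (c.locus_id, c.flank_bp, c.n_flank_reads_same_strand, c.is_standalone)
            for c in calls
        ],
        columns=["locus_id", "flank_bp", "n_flank_reads_same_strand", "is_standalone"],
    ).to_csv(outdir / "standalone.tsv", sep="\t", index=False)

    # --- terminator analysis ----------------------------------------------
    genome_path = _require(cfg.genome, "terminators")
    genome = Genome.from_fasta(genome_path)
    term_calls = []
    for group in groups:
        if group.multiplicity_bin != "unique" or group.read_id not in sine_calls:
            continue
        read = reads_by_id.get(group.read_id)
        if read is None:
            continue
        term_calls.append(call_terminator(read, group.alignments[0], genome))
    term_table = summarize_terminators(term_calls)
    pd.DataFrame(
        [(c.read_id, c.window, c.u_run_length, c.category) for c in term_calls],
        columns=["read_id", "window", "u_run_length", "category"],
    ).to_csv(outdir / "terminator_calls.tsv", sep="\t", index=False)
    term_table.to_csv(outdir / "terminator_summary.tsv", sep="\t")

    # --- histogram + manifest ----------------------------------------------
    hist = expression_histogram(expressions, cfg.histogram_bin_width)
    pd.DataFrame(
        {
            "bin_left": np.concatenate([[float("-inf")], hist["bin_edges"][:-1]]),
            "count": np.concatenate([[hist["n_zero"]], hist["counts"]]),
        }
    ).to_csv(outdir / "log2rpm_histogram.tsv", sep="\t", index=False)

    report = PipelineReport(
        trim_counts=trim_counts,
        control_counts=controls,
        control_ratios=ratios,
        tss_pass_fraction=frac_tss,
        multiplicity_fractions=mult,
        family_table=family_table,
        locus_table=locus_table,
        standalone=standalone,
        terminator_table=term_table,
        histogram=hist,
        n_expressed_loci=n_expressed,
        config_hash=cfg.config_hash(),
    )
    manifest = {
        "melrna_version": __version__,
        "config_hash": report.config_hash,
        "n_reads_kept": trim_counts["kept"],
        "n_sine_reads": len(sine_calls),
        "n_expressed_loci": n_expressed,
        "five_s_count": five_s,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report


def render_report(report: PipelineReport, fmt: str, out: str | Path) -> None:
    """Write a human-readable summary (markdown) or one TSV per section."""
    if fmt == "markdown":
        lines = [
            "# melRNA-seq pipeline report",
            "",
            f"config hash: `{report.config_hash}`",
            "",
            "## Trimming",
            "",
        ]
        for key, val in report.trim_counts.items():
            lines.append(f"- {key}: {val}")
        lines += ["", "## Control reads", ""]
        if report.control_counts.counts:
            for label, count in report.control_counts.counts.items():
                lines.append(f"- {label}: {count}")
        else:
            lines.append("- n=0")
        for label, ratio in report.control_ratios.items():
            lines.append(f"- ratio {label}: {ratio:.4g}")
        lines += [
            "",
            f"TSS-pass fraction of SINE-containing reads: {report.tss_pass_fraction:.4g}",
            "",
            "## Mapping multiplicity",
            "",
        ]
        for b, frac in report.multiplicity_fractions.items():
            lines.append(f"- {b}: {frac:.4g}")
        lines += ["", "## Family expression (RPM = reads per million 5S reads)", ""]
        lines.append(report.family_table.to_markdown() if len(report.family_table) else "n=0")
        lines += ["", "## Stand-alone test (poorly expressed loci)", ""]
        if report.standalone["n"]:
            lines.append(
                f"- {report.standalone['n_standalone']} of {report.standalone['n']} "
                f"poorly expressed loci are stand-alone "
                f"(fraction {report.standalone['fraction_standalone']:.4g})"
            )
        else:
            lines.append("- n=0")
        lines += ["", "## Terminator categories", ""]
        lines.append(
            report.terminator_table.to_markdown()
            if len(report.terminator_table)
            else "n=0"
        )
        lines += [
            "",
            f"Expressed loci: {report.n_expressed_loci}",
            "",
        ]
        Path(out).write_text("\n".join(lines))
    elif fmt == "tsv-bundle":
        outdir = Path(out)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([report.trim_counts]).to_csv(outdir / "trim.tsv", sep="\t", index=False)
        pd.DataFrame([report.control_counts.counts]).to_csv(
            outdir / "controls.tsv", sep="\t", index=False
        )
        pd.DataFrame([report.multiplicity_fractions]).to_csv(
            outdir / "multiplicity.tsv", sep="\t", index=False
        )
        report.family_table.to_csv(outdir / "family.tsv", sep="\t")
        report.locus_table.to_csv(outdir / "locus.tsv", sep="\t", index=False)
        pd.DataFrame([report.standalone]).to_csv(
            outdir / "standalone.tsv", sep="\t", index=False
        )
        report.terminator_table.to_csv(outdir / "terminators.tsv", sep="\t")
        pd.DataFrame(
            [{"tss_pass_fraction": report.tss_pass_fraction,
              "n_expressed_loci": report.n_expressed_loci}]
        ).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
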