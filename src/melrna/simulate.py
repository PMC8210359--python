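"""Synthetic-data generator with ground truth for every pipeline stage.

The simulator builds a toy genome carrying divergent SINE copies, then
emulates the RNA biology the sequencing protocol exploits:

* Pol III SINE transcripts start at (or a few bases downstream of) the
  locus 5' end, carry a 5'-triphosphate, and terminate inside a planted
  T-tract terminator, leaving 1-4 templated uridines on the RNA.
* Control RNAs have known 5' chemistries: 5S rRNA (triphosphate, Pol III),
  U2 snRNA (cap, Pol II), 5.8S rRNA (monophosphate, a cleavage product of
  the 45S precursor).
* Background fragments mimic mRNA-degradation products: random genome
  slices with a 5'-monophosphate.
* RppH treatment converts triphosphate/cap ends to monophosphate; without
  it only monophosphate RNAs can be ligated and sequenced, so disabling
  ``rpph_enabled`` drops every triphosphate- and cap-derived read.
* Gel size selection keeps inserts within ``insert_size_range``, and the
  3' sequencing adapter is appended to every surviving insert.

Per-locus expression follows a discrete power law, matching the heavy-
tailed locus-expression distributions seen in vivo.  Every emitted read
has exactly one truth row, so locus counts, TSS-filter decisions, mapping
multiplicities and terminator categories can all be checked exactly.

The B1/B2 consensuses and the 5S/U2 control sequences are synthetic toy
sequences (fixed literals, A-rich 3' tails like real SINEs); the 5.8S
control is the real 158-nt GenBank J01871.1 sequence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    Genome,
    RepeatAlignment,
    SequenceRead,
    SineLocus,
    revcomp,
    write_fastq,
    write_locus_table,
    write_rmsk_out,
)
from .preprocess import DEFAULT_ADAPTER
from .terminator import TERMINATOR_CATEGORIES, classify_terminator

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate",
    "build_genome_with_loci",
    "draw_expression",
    "transcribe_and_ligate",
    "emit_artifacts",
    "CONSENSUS_B1_TOY",
    "CONSENSUS_B2_TOY",
    "CONTROL_SEQUENCES",
    "terminator_category_members",
]

# Synthetic toy consensuses (not biological sequences): ~135-nt B1-like and
# ~190-nt B2-like bodies ending in A-rich tails, final base non-T so the
# planted terminator tract starts exactly at the locus 3' boundary.
CONSENSUS_B1_TOY = (
    "ATACGCTGGAATATACTATACGGCATTCCTTCAGCCAGAATAAAGCTGTGCAACGGGTGTCTACCCCTCC"
    "CTTTGGATGAGATTGAGATTTTGAAACCACACTATTACTTGAGCGCTTACGTACGGAAAAGAAAA"
)
CONSENSUS_B2_TOY = (
    "CGTGCCTAGCAGAAGTGAGGATAAGGGAGGAGGAAGCTAACGGTCCGCTCTAGGCCTAAGAATCCCCTTC"
    "AAGTGAGAGTGACGATCTAATGCAGGTGACACCAACGCTGAGCAATACTCGTGCACATTCGTGCGCGTAA"
    "GTGAATTCCCACCATCGATCGGCGTTTAATAGTAATGATTCAAAAACAAA"
)

# The real 5.8S rRNA (GenBank J01871.1, 158 nt); 5S-like and U2-like
# sequences are synthetic stand-ins of the real lengths (121 and 188 nt).
SEQ_5_8S = (
    "CGACTCTTAGCGGTGGATCACTCGGCTCGTGCGTCGATGAAGAACGCAGCGCTAGCTGCGAGAATTAATG"
    "TGAATTGCAGGACACATTGATCATCGACACTTCGAACGCACTTGCGGCCCCGGGTTCCTCCCGGGGCTAC"
    "GCCTGTCTGAGCGTCGCT"
)
SEQ_5S_TOY = (
    "CACATTTGTTACAGTATCTTGCCAGGTCGGGGTTCTGTGTTCTGCGCTCTGAACCAATCTTCAGGACCAG"
    "TCGCTAGTTTGGAGGTCAGTAAAGTGCCCACTCCTATCCCTGCCCCCACCA"
)
SEQ_U2_TOY = (
    "GCCGGGCTGCCCACCCATGTTAATCTGCCAGAAAACGGGAGTGGCGAGAGCCAGAAGAGCAGCGTTCTGT"
    "TGGAGTAAATGTGAATTGGCTGGCTGAGTCCGGTGGTCCTCTCAGTAGGCCTAGACAGACTAGGGATTAG"
    "ATTAGCAATACAAAGAGTAGATGAGAATTTCATCTGCGCTGAGGCAGC"
)

#: control name -> (sequence, repeat class, 5' chemistry)
CONTROL_SEQUENCES = {
    "5S": (SEQ_5S_TOY, "rRNA", "triphosphate"),
    "5.8S_rRNA": (SEQ_5_8S, "rRNA", "monophosphate"),
    "U2": (SEQ_U2_TOY, "snRNA", "cap"),
}

_BASES = np.array(list("ACGT"))


def terminator_category_members() -> dict[str, list[str]]:
    """All 5-mers per terminator category (enumerated via the classifier)."""
    members: dict[str, list[str]] = {cat: [] for cat in TERMINATOR_CATEGORIES}
    bases = "ACGT"
    for i in range(4**5):
        window = ""
        k = i
        for _ in range(5):
            window += bases[k % 4]
            k //= 4
        members[classify_terminator(window)].append(window)
    for cat in members:
        members[cat].sort()
    return members


def _default_terminator_mix() -> dict[str, float]:
    # T4 and the combined variant mass follow the termination-signal
    # statistics this method reports; T3 and T2 have no member window under
    # the anchored priority rules (earlier rules shadow them) and get zero
    # mass.
    return {
        "T4": 0.31,
        "T5_variant": 0.13,
        "T4_variant": 0.13,
        "T3": 0.0,
        "T3_variant": 0.10,
        "T2": 0.0,
        "other": 0.33,
    }


@dataclass
class SimConfig:
    """Simulation parameters; ``seed`` fully determines all outputs.

    ``tss_offset_probs[k]`` is the probability a transcript starts k bases
    downstream of the locus 5' end; most transcripts start exactly at the
    TSS but the tail extends past the filter threshold so some reads fail
    it.  ``terminator_mix`` gives the planting probabilities of the
    terminator categories downstream of each locus.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 60_000
    consensus_set: dict[str, str] = field(
        default_factory=lambda: {"B1_toy": CONSENSUS_B1_TOY, "B2_toy": CONSENSUS_B2_TOY}
    )
    n_loci: dict[str, int] = field(
        default_factory=lambda: {"B1_toy": 100, "B2_toy": 100}
    )
    divergence: float = 0.03
    fraction_expressed: float = 0.25
    powerlaw_alpha: float = 1.8
    max_transcripts_per_locus: int = 1000
    tss_offset_probs: tuple[float, ...] = (0.8,) + (0.025,) * 8
    terminator_mix: dict[str, float] = field(default_factory=_default_terminator_mix)
    n_background_fragments: int = 50
    n_control_reads: dict[str, int] = field(
        default_factory=lambda: {"5S": 300, "5.8S_rRNA": 1000, "U2": 100}
    )
    rpph_enabled: bool = True
    insert_size_range: tuple[int, int] = (113, 253)
    adapter: str = DEFAULT_ADAPTER

    def __post_init__(self) -> None:
        if abs(sum(self.tss_offset_probs) - 1.0) > 1e-9:
            raise ValueError("tss_offset_probs must sum to 1")
        if abs(sum(self.terminator_mix.values()) - 1.0) > 1e-9:
            raise ValueError("terminator_mix must sum to 1")
        members = terminator_category_members()
        for cat, p in self.terminator_mix.items():
            if p > 0 and not members[cat]:
                raise ValueError(f"terminator category {cat!r} has no member window")
        if not (0 < self.fraction_expressed <= 1):
            raise ValueError("fraction_expressed must be in (0, 1]")


@dataclass
class SimResult:
    """Everything one simulation run produced, in memory."""

    config: SimConfig
    genome: Genome
    loci: list[SineLocus]
    locus_truth: pd.DataFrame  # locus_id, strand, terminator_category, window, n_transcripts
    reads: list[SequenceRead]  # final library (adapter-bearing)
    read_truth: pd.DataFrame  # one row per emitted read
    rmsk_alignments: list[RepeatAlignment]
    sam_records: list[dict]  # read_id, placements, primary index

    def write(self, outdir: str | Path) -> dict[str, Path]:
        return emit_artifacts(self, outdir)


# ---------------------------------------------------------------------------
# Stage 1: genome construction
# ---------------------------------------------------------------------------


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute bases at the given per-base rate (no indels)."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def build_genome_with_loci(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Genome, list[SineLocus], pd.DataFrame]:
    """Random background genome with non-overlapping mutated SINE copies.

    Each copy is the subfamily consensus mutated at ``cfg.divergence``,
    inserted on a random strand, followed on its sense strand by a planted
    5-nt terminator window drawn from ``terminator_mix``.  The copy's last
    base is forced non-T so the planted tract alone defines the terminal
    U-run.  Raises when the placements cannot avoid overlap.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    chrom_seqs = {
        name: "".join(_BASES[rng.integers(0, 4, cfg.chrom_length)])
        for name in chrom_names
    }

    members = terminator_category_members()
    mix_cats = list(cfg.terminator_mix)
    mix_probs = np.array([cfg.terminator_mix[c] for c in mix_cats])

    margin = 20  # spacing between planted blocks and from contig edges
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    loci: list[SineLocus] = []
    truth_rows: list[dict] = []
    max_tries = 1000

    for subfamily in sorted(cfg.n_loci):
        consensus = cfg.consensus_set[subfamily]
        for copy_idx in range(cfg.n_loci[subfamily]):
            copy = _mutate(consensus, cfg.divergence, rng)
            if copy[-1] == "T":
                copy = copy[:-1] + "A"
            category = mix_cats[rng.choice(len(mix_cats), p=mix_probs)]
            window = members[category][rng.integers(0, len(members[category]))]
            block = copy + window
            strand = "+" if rng.random() < 0.5 else "-"
            placed = False
            for _ in range(max_tries):
                chrom = chrom_names[rng.integers(0, len(chrom_names))]
                pos = int(rng.integers(margin, cfg.chrom_length - len(block) - margin))
                span = (pos - margin, pos + len(block) + margin)
                if any(s < span[1] and span[0] < e for s, e in occupied[chrom]):
                    continue
                occupied[chrom].append(span)
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    "could not place loci without overlap; increase chrom_length "
                    "or n_chromosomes"
                )
            if strand == "+":
                insert = block
                locus_start, locus_end = pos, pos + len(copy)
            else:
                insert = revcomp(block)
                locus_start, locus_end = pos + len(window), pos + len(block)
            seq = chrom_seqs[chrom]
            chrom_seqs[chrom] = seq[:pos] + insert + seq[pos + len(insert):]
            locus = SineLocus(
                locus_id=f"{chrom}:{locus_start}-{locus_end}:{strand}:{subfamily}",
                chrom=chrom,
                start=locus_start,
                end=locus_end,
                strand=strand,
                subfamily=subfamily,
                family=subfamily.split("_")[0],
            )
            loci.append(locus)
            truth_rows.append(
                {
                    "locus_id": locus.locus_id,
                    "chrom": chrom,
                    "start": locus_start,
                    "end": locus_end,
                    "strand": strand,
                    "subfamily": subfamily,
                    "terminator_category": category,
                    "terminator_window": window,
                    "n_transcripts": 0,
                }
            )
    genome = Genome(chrom_seqs)
    locus_truth = pd.DataFrame(truth_rows).set_index("locus_id")
    return genome, loci, locus_truth


# ---------------------------------------------------------------------------
# Stage 2: expression draw
# ---------------------------------------------------------------------------


def draw_expression(
    cfg: SimConfig, loci: list[SineLocus], rng: np.random.Generator
) -> dict[str, int]:
    """Per-locus transcript counts: Bernoulli(fraction_expressed) gating a
    discrete power law p(k) proportional to k^-alpha on 1..max_transcripts_per_locus."""
    k = np.arange(1, cfg.max_transcripts_per_locus + 1)
    pmf = k.astype(float) ** (-cfg.powerlaw_alpha)
    pmf /= pmf.sum()
    counts: dict[str, int] = {}
    for locus in loci:
        if rng.random() < cfg.fraction_expressed:
            counts[locus.locus_id] = int(rng.choice(k, p=pmf))
        else:
            counts[locus.locus_id] = 0
    return counts


# ---------------------------------------------------------------------------
# Stage 3: transcription, RppH, ligation, size selection
# ---------------------------------------------------------------------------


def _leading_t_run(window: str) -> int:
    n = 0
    for b in window:
        if b != "T":
            break
        n += 1
    return n


def transcribe_and_ligate(
    cfg: SimConfig,
    genome: Genome,
    loci: list[SineLocus],
    counts: dict[str, int],
    locus_truth: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[list[SequenceRead], pd.DataFrame]:
    """Emit the sequencing library and its per-read truth table.

    All molecules are generated first; the RppH switch and gel size
    selection then filter the list, so the monophosphate reads of an
    RppH(-) library are read-for-read identical to those of the RppH(+)
    library under the same seed.
    """
    offsets = np.arange(len(cfg.tss_offset_probs))
    max_offset_pass = 4  # repeat_begin = offset + 1 must be <= 5
    reads: list[SequenceRead] = []
    rows: list[dict] = []
    by_id = {locus.locus_id: locus for locus in loci}

    for locus_id in sorted(counts):
        n = counts[locus_id]
        if n == 0:
            continue
        locus = by_id[locus_id]
        window = locus_truth.loc[locus_id, "terminator_window"]
        lead = _leading_t_run(window)
        for i in range(n):
            offset = int(rng.choice(offsets, p=np.asarray(cfg.tss_offset_probs)))
            u = int(rng.integers(1, min(4, lead) + 1)) if lead > 0 else 0
            if locus.strand == "+":
                start, end = locus.start + offset, locus.end + u
            else:
                start, end = locus.start - u, locus.end - offset
            insert = genome.fetch(locus.chrom, start, end, locus.strand)
            reads.append(
                SequenceRead(
                    f"sine|{locus_id}|{i}", insert,
                    five_prime_chemistry="triphosphate",
                )
            )
            rows.append(
                {
                    "read_id": f"sine|{locus_id}|{i}",
                    "source": "sine",
                    "locus_id": locus_id,
                    "chemistry": "triphosphate",
                    "chrom": locus.chrom,
                    "start": start,
                    "end": end,
                    "strand": locus.strand,
                    "tss_offset": offset,
                    "u_run": u,
                    "terminator_category": locus_truth.loc[locus_id, "terminator_category"],
                    "passes_tss_filter": offset <= max_offset_pass,
                    "subfamily": locus.subfamily,
                }
            )

    for label in sorted(cfg.n_control_reads):
        seq, _cls, chemistry = CONTROL_SEQUENCES[label]
        for i in range(cfg.n_control_reads[label]):
            start_off = 0 if rng.random() < 0.9 else 1
            end_trunc = int(rng.integers(0, 4))
            insert = seq[start_off : len(seq) - end_trunc]
            reads.append(
                SequenceRead(
                    f"ctrl|{label}|{i}", insert, five_prime_chemistry=chemistry
                )
            )
            rows.append(
                {
                    "read_id": f"ctrl|{label}|{i}",
                    "source": f"control:{label}",
                    "locus_id": "",
                    "chemistry": chemistry,
                    "chrom": "",
                    "start": start_off,
                    "end": len(seq) - end_trunc,
                    "strand": "+",
                    "tss_offset": start_off,
                    "u_run": 0,
                    "terminator_category": "",
                    "passes_tss_filter": False,
                    "subfamily": "",
                }
            )

    lo, hi = cfg.insert_size_range
    chrom_names = sorted(genome.chromosomes)
    for i in range(cfg.n_background_fragments):
        chrom = chrom_names[rng.integers(0, len(chrom_names))]
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(genome.chromosomes[chrom]) - length))
        strand = "+" if rng.random() < 0.5 else "-"
        insert = genome.fetch(chrom, start, start + length, strand)
        reads.append(
            SequenceRead(f"bg|{i}", insert, five_prime_chemistry="monophosphate")
        )
        rows.append(
            {
                "read_id": f"bg|{i}",
                "source": "background",
                "locus_id": "",
                "chemistry": "monophosphate",
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "strand": strand,
                "tss_offset": -1,
                "u_run": 0,
                "terminator_category": "",
                "passes_tss_filter": False,
                "subfamily": "",
            }
        )

    truth = pd.DataFrame(rows)
    if truth.empty:
        return [], truth

    # RppH switch: without treatment, triphosphate/cap ends cannot ligate
    if not cfg.rpph_enabled:
        ligatable = truth["chemistry"] == "monophosphate"
    else:
        ligatable = pd.Series(True, index=truth.index)
    # gel size selection on the insert
    sizes = pd.Series([len(r) for r in reads], index=truth.index)
    keep = ligatable & sizes.between(lo, hi)

    kept_reads = []
    for read, flag in zip(reads, keep):
        if flag:
            kept_reads.append(
                SequenceRead(
                    read.read_id,
                    read.sequence + cfg.adapter,
                    "I" * (len(read.sequence) + len(cfg.adapter)),
                    read.five_prime_chemistry,
                )
            )
    truth = truth[keep.to_numpy()].reset_index(drop=True)
    return kept_reads, truth


# ---------------------------------------------------------------------------
# Stage 4: alignment + repeat-annotation synthesis
# ---------------------------------------------------------------------------


def _find_all_placements(genome: Genome, insert: str) -> list[tuple[str, int, int, str]]:
    """All exact occurrences of the insert in the genome, both strands."""
    placements = []
    rc = revcomp(insert)
    for chrom in sorted(genome.chromosomes):
        seq = genome.chromosomes[chrom]
        for probe, strand in ((insert, "+"), (rc, "-")):
            pos = seq.find(probe)
            while pos != -1:
                placements.append((chrom, pos, pos + len(probe), strand))
                pos = seq.find(probe, pos + 1)
    # a palindromic probe would be reported once per strand; deduplicate
    return sorted(set(placements))


def _synthesize_alignments(
    cfg: SimConfig,
    genome: Genome,
    reads_truth: pd.DataFrame,
    inserts: dict[str, str],
) -> tuple[list[RepeatAlignment], list[dict]]:
    """Repeat annotation and genomic placements, derived from the truth.

    The ``.out`` rows describe each trimmed insert against its source
    consensus: transcripts align from query position 1 with the repeat
    begin reflecting the true TSS offset and the terminal U-tail left
    unaligned (it lies beyond the consensus); control reads align nearly
    end-to-end.  Genomic placements list *all* exact matches of the insert
    so duplicated loci produce multi-mapped reads.
    """
    rmsk: list[RepeatAlignment] = []
    sam: list[dict] = []
    div_pct = cfg.divergence * 100

    for row in reads_truth.itertuples():
        insert = inserts[row.read_id]
        if row.source == "sine":
            consensus_len = len(cfg.consensus_set[row.subfamily])
            family = row.subfamily.split("_")[0]
            rmsk.append(
                RepeatAlignment(
                    sw_score=max(200, 10 * (len(insert) - row.u_run)),
                    pct_div=div_pct,
                    pct_del=0.0,
                    pct_ins=0.0,
                    query_id=row.read_id,
                    query_begin=1,
                    query_end=len(insert) - row.u_run,
                    query_left=row.u_run,
                    strand="plus",
                    repeat_name=row.subfamily,
                    repeat_class_family=f"SINE/{family}",
                    repeat_begin=row.tss_offset + 1,
                    repeat_end=consensus_len,
                    repeat_left=0,
                )
            )
        elif row.source.startswith("control:"):
            label = row.source.split(":", 1)[1]
            seq, cls, _chem = CONTROL_SEQUENCES[label]
            rmsk.append(
                RepeatAlignment(
                    sw_score=max(200, 10 * len(insert)),
                    pct_div=0.0,
                    pct_del=0.0,
                    pct_ins=0.0,
                    query_id=row.read_id,
                    query_begin=1,
                    query_end=len(insert),
                    query_left=0,
                    strand="plus",
                    repeat_name=label,
                    repeat_class_family=cls,
                    repeat_begin=row.start + 1,  # truth start = offset into the RNA
                    repeat_end=row.end,
                    repeat_left=len(seq) - row.end,
                )
            )

        if row.source.startswith("control:"):
            sam.append({"read_id": row.read_id, "placements": [], "primary": None})
        else:
            placements = _find_all_placements(genome, insert)
            true_placement = (row.chrom, row.start, row.end, row.strand)
            assert true_placement in placements, "truth placement must be findable"
            sam.append(
                {
                    "read_id": row.read_id,
                    "placements": placements,
                    "primary": placements.index(true_placement),
                }
            )
    return rmsk, sam


# ---------------------------------------------------------------------------
# Driver + artifact emission
# ---------------------------------------------------------------------------


def simulate(cfg: SimConfig | None = None) -> SimResult:
    """Run the full simulation; deterministic under ``cfg.seed``."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    genome, loci, locus_truth = build_genome_with_loci(cfg, rng)
    counts = draw_expression(cfg, loci, rng)
    reads, read_truth = transcribe_and_ligate(cfg, genome, loci, counts, locus_truth, rng)
    # record the number of *emitted* transcripts per locus (post selection)
    if len(read_truth):
        emitted = read_truth[read_truth["source"] == "sine"]["locus_id"].value_counts()
    else:
        emitted = pd.Series(dtype=int)
    locus_truth["n_transcripts"] = (
        pd.Series(emitted, index=locus_truth.index).fillna(0).astype(int)
    )
    adapter_len = len(cfg.adapter)
    inserts = {r.read_id: r.sequence[:-adapter_len] for r in reads}
    rmsk, sam = _synthesize_alignments(cfg, genome, read_truth, inserts)
    return SimResult(
        config=cfg,
        genome=genome,
        loci=loci,
        locus_truth=locus_truth,
        reads=reads,
        read_truth=read_truth,
        rmsk_alignments=rmsk,
        sam_records=sam,
    )


def _write_sam(result: SimResult, path: Path) -> None:
    import pysam

    lengths = result.genome.lengths()
    names = sorted(lengths)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": lengths[n]} for n in names],
        }
    )
    inserts = {
        r.read_id: r.sequence[: -len(result.config.adapter)] for r in result.reads
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in result.sam_records:
            insert = inserts[rec["read_id"]]
            if not rec["placements"]:
                a = pysam.AlignedSegment(header)
                a.query_name = rec["read_id"]
                a.flag = 4
                a.query_sequence = insert
                out.write(a)
                continue
            for i, (chrom, start, end, strand) in enumerate(rec["placements"]):
                a = pysam.AlignedSegment(header)
                a.query_name = rec["read_id"]
                a.flag = (16 if strand == "-" else 0) | (
                    0 if i == rec["primary"] else 256
                )
                a.reference_id = names.index(chrom)
                a.reference_start = start
                a.mapping_quality = 60 if len(rec["placements"]) == 1 else 1
                a.cigarstring = f"{end - start}M"
                a.query_sequence = insert if strand == "+" else revcomp(insert)
                out.write(a)


def emit_artifacts(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write the library and all sidecar files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fastq": outdir / "reads.fastq",
        "genome": outdir / "genome.fa",
        "loci": outdir / "loci.tsv",
        "rmsk_out": outdir / "reads.out",
        "sam": outdir / "alignments.sam",
        "locus_truth": outdir / "truth_loci.tsv",
        "read_truth": outdir / "truth_reads.tsv",
        "config": outdir / "sim_config.yaml",
    }
    write_fastq(result.reads, paths["fastq"])
    result.genome.to_fasta(paths["genome"])
    write_locus_table(result.loci, paths["loci"], dialect="ucsc_rmsk")
    write_rmsk_out(result.rmsk_alignments, paths["rmsk_out"])
    _write_sam(result, paths["sam"])
    result.locus_truth.to_csv(paths["locus_truth"], sep="\t")
    result.read_truth.to_csv(paths["read_truth"], sep="\t", index=False)
    import yaml

    cfg_dict = dataclasses.asdict(result.config)
    cfg_dict["insert_size_range"] = list(cfg_dict["insert_size_range"])
    cfg_dict["tss_offset_probs"] = list(cfg_dict["tss_offset_probs"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    return paths
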