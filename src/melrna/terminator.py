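"""3'-end analysis: terminal templated uridines and terminator classification.

Pol III terminates transcription at runs of thymidine on the non-template
(sense) strand, leaving a short U-tail on the RNA.  Because this method
sequences RNAs to their exact 3' ends, the terminal read bases locate the
termination site on the genome; the 5-nt sense-strand window starting at
the U-run's template is the termination signal, classified by how closely
it resembles a canonical T-tract.

Categories, tested in this fixed priority order:

T4          first four window positions all T (>=4 consecutive T's)
T5_variant  exactly one non-T among the five positions
T4_variant  exactly one non-T among the first four
T3          first three positions all T
T3_variant  exactly one non-T among the first three
T2          first two positions both T
other       none of the above

The order matters: TTTCT is a T5 variant, not a T4 variant or a T3.  Rules
are anchored at position 1 because the window itself is anchored by where
transcription stopped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io_formats import Genome, GenomeAlignment, SequenceRead

__all__ = [
    "TERMINATOR_CATEGORIES",
    "TerminatorCall",
    "terminal_u_run",
    "extract_termination_window",
    "classify_terminator",
    "call_terminator",
    "summarize_terminators",
    "WINDOW_LENGTH",
]

WINDOW_LENGTH = 5

TERMINATOR_CATEGORIES = (
    "T4",
    "T5_variant",
    "T4_variant",
    "T3",
    "T3_variant",
    "T2",
    "other",
)


@dataclass
class TerminatorCall:
    """Termination-signal call for one read."""

    read_id: str
    window: str
    u_run_length: int
    category: str
    truncated: bool = False  # window clipped by a contig edge


def terminal_u_run(read: SequenceRead, aln: GenomeAlignment, genome: Genome) -> int:
    """Length of the read's terminal templated U-run.

    Counts the maximal suffix of the read consisting of T (U in the RNA)
    whose genomic template on the read's strand is also T; 0 when the read
    does not end in T.  Read T's beyond the aligned length are an error —
    the alignment is expected to cover the read's 3' end without mismatch.
    """
    seq = read.sequence
    suffix_t = len(seq) - len(seq.rstrip("T"))
    if suffix_t == 0:
        return 0
    span = aln.end - aln.start
    if suffix_t > span:
        raise ValueError(
            f"read {read.read_id}: terminal T-run ({suffix_t}) longer than "
            f"its alignment ({span})"
        )
    # genomic sense-strand sequence under the read's last suffix_t bases
    if aln.strand == "+":
        template = genome.fetch(aln.chrom, aln.end - suffix_t, aln.end, "+")
    else:
        template = genome.fetch(aln.chrom, aln.start, aln.start + suffix_t, "-")
    u = 0
    for base in reversed(template):
        if base != "T":
            break
        u += 1
    return u


def extract_termination_window(
    aln: GenomeAlignment,
    u_run_length: int,
    genome: Genome,
    window_length: int = WINDOW_LENGTH,
) -> tuple[str, bool]:
    """Sense-strand genomic window at the termination site.

    The window begins at the first base of the terminal U-run's template
    (or, for reads with no terminal U, immediately after the read's 3'
    end) and reads 5'->3' on the transcript sense, so minus-strand
    alignments are reverse-complemented.  Returns (window, truncated):
    windows clipped by a contig edge come back short with truncated=True.
    """
    u = u_run_length
    if aln.strand == "+":
        start = aln.end - u
        stop = start + window_length
        chrom_len = len(genome.chromosomes[aln.chrom])
        truncated = stop > chrom_len
        window = genome.fetch(aln.chrom, start, min(stop, chrom_len), "+")
    else:
        stop = aln.start + u
        start = stop - window_length
        truncated = start < 0
        window = genome.fetch(aln.chrom, max(start, 0), stop, "-")
    return window, truncated


def classify_terminator(window: str, window_length: int = WINDOW_LENGTH) -> str:
    """Category of a termination-signal window (priority order; see module doc).

    Windows of the wrong length or containing characters outside {A,C,G,T}
    classify as ``other``.
    """
    if len(window) != window_length or any(b not in "ACGT" for b in window):
        return "other"
    non_t_all = [i for i, b in enumerate(window) if b != "T"]
    non_t_4 = [i for i in non_t_all if i < 4]
    non_t_3 = [i for i in non_t_all if i < 3]
    if not non_t_4:
        return "T4"
    if len(non_t_all) == 1:
        return "T5_variant"
    if len(non_t_4) == 1:
        return "T4_variant"
    if not non_t_3:
        return "T3"
    if len(non_t_3) == 1:
        return "T3_variant"
    if window[0] == "T" and window[1] == "T":
        return "T2"
    return "other"


def call_terminator(
    read: SequenceRead, aln: GenomeAlignment, genome: Genome
) -> TerminatorCall:
    """U-run measurement, window extraction and classification for one read."""
    u = terminal_u_run(read, aln, genome)
    window, truncated = extract_termination_window(aln, u, genome)
    category = "other" if truncated else classify_terminator(window)
    return TerminatorCall(
        read_id=read.read_id,
        window=window,
        u_run_length=u,
        category=category,
        truncated=truncated,
    )


def summarize_terminators(calls: Iterable[TerminatorCall]):
    """Per-category counts and fractions as a DataFrame (empty in -> empty out)."""
    import pandas as pd

    calls = list(calls)
    if not calls:
        return pd.DataFrame(columns=["count", "fraction"]).rename_axis("category")
    counts = {cat: 0 for cat in TERMINATOR_CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    total = len(calls)
    return pd.DataFrame(
        {
            "count": pd.Series(counts),
            "fraction": pd.Series({c: n / total for c, n in counts.items()}),
        }
    ).rename_axis("category")
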