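"""Selection of bona fide Pol III transcript reads from RepeatMasker output.

A full-length Pol III SINE transcript starts at (or within a few bases of)
the consensus start, so its read aligns to the sense strand of a SINE
consensus with both the "position in query" start and the "position in
repeat" start small.  Reads passing that anchor are retained as SINE
transcripts; reads matching the sense strand of the internal-control RNAs
(5S rRNA, 5.8S rRNA, U2 snRNA) nearly end-to-end are counted separately
for normalization and for validating the 5'-end chemistry conversion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, NamedTuple

from .io_formats import RepeatAlignment

__all__ = [
    "FilterConfig",
    "ControlCounts",
    "SineReadCall",
    "passes_tss_filter",
    "select_sine_reads",
    "tss_fraction",
    "count_control_reads",
    "ratio_to_control",
    "packaged_5_8S_fasta",
    "UNDEFINED",
]

logger = logging.getLogger(__name__)

#: Sentinel for ratios/fractions whose denominator is zero.
UNDEFINED = math.nan

DEFAULT_CONTROL_NAMES = {
    "5S_rRNA": "5S",
    "5.8S_rRNA": "5.8S_rRNA",
    "U2": "U2",
}


@dataclass(frozen=True)
class FilterConfig:
    """TSS-anchor and control-read selection thresholds.

    ``max_tss_offset`` bounds the 1-based RepeatMasker begin columns, so
    the allowed begins are {1..5} by default: "within 5 bp" of the
    consensus start, including the exact start.  The control rule is
    stricter (begins 1 or 2, both leftovers <= 5) because the control RNAs
    are fixed-length molecules sequenced end to end.
    """

    max_tss_offset: int = 5
    sine_class_prefixes: tuple[str, ...] = ("SINE",)
    control_names: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_NAMES)
    )
    control_max_begin: int = 2
    control_max_left: int = 5

    def __post_init__(self) -> None:
        if self.max_tss_offset < 1:
            raise ValueError("max_tss_offset must be >= 1")
        if self.control_max_begin < 1:
            raise ValueError("control_max_begin must be >= 1")


@dataclass
class ControlCounts:
    """Per-control read tallies plus the total read count they came from."""

    counts: dict[str, int]
    total_reads: int

    def fraction(self, label: str) -> float:
        if self.total_reads == 0:
            return UNDEFINED
        return self.counts.get(label, 0) / self.total_reads


class SineReadCall(NamedTuple):
    read_id: str
    subfamily: str
    repeat_begin: int


def _is_sine(aln: RepeatAlignment, cfg: FilterConfig) -> bool:
    return aln.repeat_class_family.startswith(tuple(cfg.sine_class_prefixes))


def passes_tss_filter(aln: RepeatAlignment, cfg: FilterConfig | None = None) -> bool:
    """True iff the alignment anchors a sense-strand SINE read at the TSS.

    Requires sense-strand match, a SINE class, and both the query start and
    the repeat-consensus start within ``max_tss_offset`` (1-based, so the
    exact start is position 1).
    """
    cfg = cfg or FilterConfig()
    return (
        aln.strand == "plus"
        and _is_sine(aln, cfg)
        and aln.query_begin <= cfg.max_tss_offset
        and aln.repeat_begin <= cfg.max_tss_offset
    )


def select_sine_reads(
    alignments: Iterable[RepeatAlignment], cfg: FilterConfig | None = None
) -> dict[str, SineReadCall]:
    """Read ids passing the TSS filter, each labeled with one SINE subfamily.

    A read with several passing alignments keeps the highest-scoring one
    (ties broken by lower divergence, then lexicographic repeat name), so
    the subfamily call is deterministic.
    """
    cfg = cfg or FilterConfig()
    best: dict[str, tuple[tuple[float, float, str], SineReadCall]] = {}
    for aln in alignments:
        if not passes_tss_filter(aln, cfg):
            continue
        # sort key: maximize sw_score, then minimize pct_div, then name
        key = (-aln.sw_score, aln.pct_div, aln.repeat_name)
        call = SineReadCall(aln.query_id, aln.repeat_name, aln.repeat_begin)
        incumbent = best.get(aln.query_id)
        if incumbent is None or key < incumbent[0]:
            best[aln.query_id] = (key, call)
    return {rid: call for rid, (_, call) in best.items()}


def tss_fraction(
    alignments: Iterable[RepeatAlignment], cfg: FilterConfig | None = None
) -> float:
    """Fraction of SINE-containing reads that pass the TSS filter.

    Computed per read: a read counts in the denominator if any of its
    alignments is a SINE hit, and in the numerator if any passes the
    filter.  Returns NaN when no read contains a SINE alignment.
    """
    cfg = cfg or FilterConfig()
    has_sine: set[str] = set()
    passing: set[str] = set()
    for aln in alignments:
        if _is_sine(aln, cfg):
            has_sine.add(aln.query_id)
            if passes_tss_filter(aln, cfg):
                passing.add(aln.query_id)
    if not has_sine:
        return UNDEFINED
    return len(passing) / len(has_sine)


def count_control_reads(
    alignments: Iterable[RepeatAlignment],
    cfg: FilterConfig | None = None,
    total_reads: int | None = None,
) -> ControlCounts:
    """Count reads matching each internal control nearly end to end.

    A read qualifies for a control when it matches the control's sense
    strand with both begin columns at most ``control_max_begin`` and both
    leftover columns at most ``control_max_left``.  The stock repeat
    library lacks a 5.8S rRNA entry; :func:`packaged_5_8S_fasta` supplies
    one to append before running the annotation.
    """
    cfg = cfg or FilterConfig()
    by_name = {name: label for label, name in cfg.control_names.items()}
    hit_reads: dict[str, set[str]] = {label: set() for label in cfg.control_names}
    seen_names: set[str] = set()
    all_reads: set[str] = set()
    for aln in alignments:
        all_reads.add(aln.query_id)
        label = by_name.get(aln.repeat_name)
        if label is None:
            continue
        seen_names.add(aln.repeat_name)
        if (
            aln.strand == "plus"
            and 1 <= aln.query_begin <= cfg.control_max_begin
            and 1 <= aln.repeat_begin <= cfg.control_max_begin
            and aln.query_left <= cfg.control_max_left
            and aln.repeat_left <= cfg.control_max_left
        ):
            hit_reads[label].add(aln.query_id)
    for label, name in cfg.control_names.items():
        if name not in seen_names:
            logger.warning("control %r (repeat name %r) not seen in any alignment", label, name)
    counts = {label: len(reads) for label, reads in hit_reads.items()}
    return ControlCounts(
        counts=counts,
        total_reads=len(all_reads) if total_reads is None else total_reads,
    )


def ratio_to_control(
    counts: ControlCounts, target_label: str, reference_label: str
) -> float:
    """Read-count ratio target/reference; NaN when the reference count is 0."""
    ref = counts.counts.get(reference_label, 0)
    if ref == 0:
        return UNDEFINED
    return counts.counts.get(target_label, 0) / ref


def packaged_5_8S_fasta() -> str:
    """Path to the packaged 5.8S rRNA FASTA (GenBank J01871.1, 158 nt).

    Stock RepeatMasker libraries lack a 5.8S consensus; append this entry
    to the repeat library before annotation so 5.8S control reads can be
    counted.
    """
    return str(resources.files("melrna").joinpath("data/5.8S_rRNA.fa"))
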