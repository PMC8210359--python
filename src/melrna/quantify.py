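"""Locus- and family-level expression from genome alignments.

Only uniquely mapped reads contribute to locus counts: multi-mapped reads
cannot be attributed to a single genomic copy and are excluded outright
(their subfamily-level information is already captured upstream from the
repeat annotation).  Counts are normalized to reads per million 5S rRNA
reads (RPM) — an internal-control normalization that absorbs both
sequencing depth and 5'-end conversion efficiency, unlike per-million-total
normalization.

A read is assigned to a locus when its 5' end falls inside the locus (or
up to the TSS tolerance upstream of the locus 5' boundary) on the same
strand.  Mere overlap would misattribute reads at nested repeats; anchoring
the 5' end mirrors the TSS-based read selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import (
    GenomeAlignment,
    ReadAlignmentGroup,
    SineLocus,
    MULTIPLICITY_BINS,
    _multiplicity_bin,
)

__all__ = [
    "ReadAlignmentGroup",
    "MULTIPLICITY_BINS",
    "LocusExpression",
    "StandaloneCall",
    "LocusIndex",
    "AlignmentIndex",
    "bin_multiplicity",
    "multiplicity_fractions",
    "assign_read_to_locus",
    "count_loci",
    "normalize_rpm",
    "aggregate_family",
    "classify_standalone",
    "standalone_summary",
    "replicate_correlation",
    "expression_histogram",
    "UNDEFINED",
]

UNDEFINED = math.nan


@dataclass
class LocusExpression:
    """Raw unique-read count and RPM for one locus."""

    locus: SineLocus
    raw_count: int = 0
    rpm: float | None = None

    @property
    def locus_id(self) -> str:
        return self.locus.locus_id


@dataclass
class StandaloneCall:
    """Outcome of the flank test for one (poorly expressed) locus."""

    locus_id: str
    flank_bp: int
    n_flank_reads_same_strand: int
    is_standalone: bool


def bin_multiplicity(group: ReadAlignmentGroup | int) -> str:
    """Mapping-multiplicity class: unique / 2-9 / 10-99 / >=100 / unmapped."""
    n = group if isinstance(group, int) else group.n_alignments
    return _multiplicity_bin(n)


def multiplicity_fractions(groups: Iterable[ReadAlignmentGroup]) -> dict[str, float]:
    """Fraction of reads per multiplicity bin (NaN-free; empty input -> zeros)."""
    counts = dict.fromkeys(MULTIPLICITY_BINS, 0)
    total = 0
    for group in groups:
        counts[group.multiplicity_bin] += 1
        total += 1
    if total == 0:
        return dict.fromkeys(MULTIPLICITY_BINS, 0.0)
    return {b: c / total for b, c in counts.items()}


class LocusIndex:
    """Strand-aware interval index for assigning read 5' ends to loci."""

    def __init__(self, loci: Iterable[SineLocus], max_tss_offset: int = 5):
        self.max_tss_offset = max_tss_offset
        self.loci = list(loci)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for locus in self.loci:
            tree = self._trees.setdefault((locus.chrom, locus.strand), IntervalTree())
            # widen the 5' side by the TSS tolerance
            if locus.strand == "+":
                tree.addi(locus.start - max_tss_offset, locus.end, locus)
            else:
                tree.addi(locus.start, locus.end + max_tss_offset, locus)

    def assign(self, aln: GenomeAlignment) -> SineLocus | None:
        """Locus owning this alignment's 5' end, or None.

        Among overlapping candidates (nested repeats) the locus whose 5'
        boundary is nearest the read 5' end wins; distance ties go to the
        smaller locus, then lexicographic locus_id for determinism.
        """
        tree = self._trees.get((aln.chrom, aln.strand))
        if tree is None:
            return None
        pos = aln.five_prime_pos
        hits = tree[pos]
        if not hits:
            return None
        best = min(
            (iv.data for iv in hits),
            key=lambda loc: (abs(pos - loc.five_prime_boundary), loc.length, loc.locus_id),
        )
        return best


def assign_read_to_locus(
    aln: GenomeAlignment, loci_index: LocusIndex
) -> str | None:
    """locus_id for a unique read's alignment, or None if unassigned."""
    locus = loci_index.assign(aln)
    return locus.locus_id if locus is not None else None


def count_loci(
    groups: Iterable[ReadAlignmentGroup],
    loci_index: LocusIndex,
    restrict_to: set[str] | None = None,
) -> tuple[list[LocusExpression], dict[str, str | None]]:
    """Count uniquely mapped reads per locus.

    Only unique-bin reads contribute; ``restrict_to`` optionally limits
    counting to a read-id subset (the TSS-selected SINE reads).  Returns
    one LocusExpression per locus in the index (zero counts retained) and
    the per-read assignment map (read_id -> locus_id or None), from which
    the conservation law "assigned + unassigned = unique reads" follows.
    """
    counts: dict[str, int] = {locus.locus_id: 0 for locus in loci_index.loci}
    assignments: dict[str, str | None] = {}
    for group in groups:
        if group.multiplicity_bin != "unique":
            continue
        if restrict_to is not None and group.read_id not in restrict_to:
            continue
        locus_id = assign_read_to_locus(group.alignments[0], loci_index)
        assignments[group.read_id] = locus_id
        if locus_id is not None:
            counts[locus_id] += 1
    expressions = [
        LocusExpression(locus=locus, raw_count=counts[locus.locus_id])
        for locus in loci_index.loci
    ]
    return expressions, assignments


def normalize_rpm(
    expressions: Iterable[LocusExpression], fiveS_count: int
) -> list[LocusExpression]:
    """Set rpm = raw_count * 1e6 / fiveS_count on every expression (in place)."""
    if fiveS_count <= 0:
        raise ValueError(
            "cannot normalize: 5S control read count is zero — was the 5S "
            "control present in the repeat annotation?"
        )
    out = list(expressions)
    for expr in out:
        expr.rpm = expr.raw_count * 1e6 / fiveS_count
    return out


def aggregate_family(expressions: Iterable[LocusExpression]):
    """Family-level totals as a DataFrame (raw_count and rpm sums)."""
    import pandas as pd

    rows = [
        {
            "family": e.locus.family,
            "raw_count": e.raw_count,
            "rpm": e.rpm if e.rpm is not None else 0.0,
        }
        for e in expressions
    ]
    if not rows:
        return pd.DataFrame(columns=["raw_count", "rpm"]).rename_axis("family")
    return pd.DataFrame(rows).groupby("family")[["raw_count", "rpm"]].sum()


class AlignmentIndex:
    """Interval index over alignments (typically all uniquely mapped reads)."""

    def __init__(self, alignments: Iterable[GenomeAlignment]):
        self._trees: dict[str, IntervalTree] = {}
        for aln in alignments:
            self._trees.setdefault(aln.chrom, IntervalTree()).addi(
                aln.start, aln.end, aln
            )

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomeAlignment]:
        tree = self._trees.get(chrom)
        if tree is None or start >= end:
            return []
        return [iv.data for iv in tree[start:end]]


def classify_standalone(
    locus: SineLocus,
    unique_alignments: AlignmentIndex,
    flank_bp: int = 5000,
    exclude_read_ids: set[str] | None = None,
) -> StandaloneCall:
    """Flank test: is this locus transcriptionally stand-alone?

    Counts same-strand uniquely mapped reads overlapping the ``flank_bp``
    windows on either side of the locus (the locus body itself excluded).
    Reads assigned to the locus are excluded via ``exclude_read_ids``.  A
    locus with zero such flank reads shows no evidence of being a
    degradation product of a longer host transcript.  Flanks are silently
    truncated at contig edges (interval queries below 0 are clipped).
    """
    exclude = exclude_read_ids or set()
    windows = [
        (max(0, locus.start - flank_bp), locus.start),
        (locus.end, locus.end + flank_bp),
    ]
    flank_read_ids: set[str] = set()
    for start, end in windows:
        for aln in unique_alignments.overlapping(locus.chrom, start, end):
            if aln.strand != locus.strand or aln.read_id in exclude:
                continue
            flank_read_ids.add(aln.read_id)
    n = len(flank_read_ids)
    return StandaloneCall(
        locus_id=locus.locus_id,
        flank_bp=flank_bp,
        n_flank_reads_same_strand=n,
        is_standalone=(n == 0),
    )


def standalone_summary(calls: Iterable[StandaloneCall]) -> dict[str, float]:
    """n, n_standalone and the stand-alone fraction over a set of calls."""
    calls = list(calls)
    n = len(calls)
    n_standalone = sum(1 for c in calls if c.is_standalone)
    return {
        "n": n,
        "n_standalone": n_standalone,
        "fraction_standalone": (n_standalone / n) if n else UNDEFINED,
    }


def replicate_correlation(
    expr_rep1: Iterable[LocusExpression], expr_rep2: Iterable[LocusExpression]
) -> float:
    """Pearson R of paired RPM values over loci expressed in >=1 replicate.

    Both replicates must cover the same locus universe.  Returns NaN when
    fewer than two loci are expressed or either side has zero variance.
    """
    rpm1 = {e.locus_id: e for e in expr_rep1}
    rpm2 = {e.locus_id: e for e in expr_rep2}
    if set(rpm1) != set(rpm2):
        raise ValueError("replicates cover different locus universes")
    pairs = [
        (rpm1[lid].rpm, rpm2[lid].rpm)
        for lid in rpm1
        if rpm1[lid].raw_count > 0 or rpm2[lid].raw_count > 0
    ]
    if len(pairs) < 2:
        return UNDEFINED
    x, y = np.array(pairs).T
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return UNDEFINED
    return float(stats.pearsonr(x, y).statistic)


def expression_histogram(
    expressions: Iterable[LocusExpression], bin_width: float = 1.0
) -> dict:
    """Histogram of log2(RPM) over expressed loci, plus a zero-count bar.

    Loci with no mapped read are reported separately (``n_zero``) as the
    leftmost bar; expressed loci (raw_count > 0) are binned on log2(RPM)
    with ``bin_width``-wide bins aligned to integer multiples.  Bin counts
    plus n_zero sum to the number of loci.
    """
    expressions = list(expressions)
    zero = [e for e in expressions if e.raw_count == 0]
    expressed = [e for e in expressions if e.raw_count > 0]
    if not expressed:
        return {
            "n_zero": len(zero),
            "bin_edges": np.array([]),
            "counts": np.array([], dtype=int),
        }
    log2rpm = np.log2([e.rpm for e in expressed])
    lo = math.floor(log2rpm.min() / bin_width) * bin_width
    hi = math.ceil(log2rpm.max() / bin_width) * bin_width
    if hi == lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(log2rpm, bins=edges)
    return {"n_zero": len(zero), "bin_edges": edges, "counts": counts}
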