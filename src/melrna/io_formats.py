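"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
Internally every genomic interval is 0-based half-open, the convention of BED
and SAM-as-parsed-by-pysam.  The two formats that use 1-based inclusive
coordinates (RepeatMasker ``.out`` and raw SAM text) are converted at the
parser boundary and converted back on write, so downstream code only ever
sees one convention.

RepeatMasker ``.out`` files keep their native 1-based inclusive coordinates
inside :class:`RepeatAlignment` because the selection rules of this method
are stated directly on those printed columns ("position in query start",
"position in repeat start").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SequenceRead",
    "RepeatAlignment",
    "GenomeAlignment",
    "ReadAlignmentGroup",
    "SineLocus",
    "Genome",
    "FormatError",
    "revcomp",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "parse_rmsk_out",
    "write_rmsk_out",
    "read_locus_table",
    "write_locus_table",
    "read_sam_grouped",
    "one_based_closed_to_half_open",
    "half_open_to_one_based_closed",
    "DEFAULT_FAMILY_MAP",
]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-pairs)."""
    return seq.translate(_RC)[::-1]


class FormatError(ValueError):
    """A file did not conform to its declared format."""


def one_based_closed_to_half_open(begin: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return begin - 1, end


def half_open_to_one_based_closed(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

CHEMISTRIES = ("triphosphate", "cap", "monophosphate", "unknown")


@dataclass
class SequenceRead:
    """One sequencing read; the sequenced proxy of one RNA molecule.

    ``five_prime_chemistry`` records the 5' end of the source RNA
    (triphosphate for Pol III transcripts, cap for Pol II, monophosphate for
    cleavage products).  It is simulator-facing metadata: real FASTQ carries
    no such information and parses as ``unknown``.
    """

    read_id: str
    sequence: str
    qualities: str | None = None
    five_prime_chemistry: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )
        if self.five_prime_chemistry not in CHEMISTRIES:
            raise ValueError(f"unknown 5' chemistry {self.five_prime_chemistry!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RepeatAlignment:
    """One RepeatMasker ``.out`` row (1-based inclusive coordinates).

    For ``strand == "complement"`` the repeat-coordinate columns are
    normalized at parse time: ``repeat_begin`` is always the consensus
    position matched by the read's 5'-most base.  On complement hits the
    query start pairs with the *higher* consensus coordinate, so
    ``repeat_begin > repeat_end`` there; plus-strand rows keep
    ``repeat_begin <= repeat_end``.
    """

    sw_score: int
    pct_div: float
    pct_del: float
    pct_ins: float
    query_id: str
    query_begin: int
    query_end: int
    query_left: int
    strand: str  # "plus" | "complement"
    repeat_name: str
    repeat_class_family: str
    repeat_begin: int
    repeat_end: int
    repeat_left: int

    def __post_init__(self) -> None:
        if self.strand not in ("plus", "complement"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not (1 <= self.query_begin <= self.query_end):
            raise ValueError(
                f"query interval [{self.query_begin}, {self.query_end}] invalid"
            )
        if min(self.query_left, self.repeat_begin, self.repeat_end) < 0 or self.repeat_left < 0:
            raise ValueError("negative coordinate in RepeatMasker record")


@dataclass
class GenomeAlignment:
    """One genomic alignment of a read (0-based half-open)."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" | "-"
    is_primary: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.start}-{self.end} for {self.read_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def five_prime_pos(self) -> int:
        """Genomic position of the read's 5' end (0-based)."""
        return self.start if self.strand == "+" else self.end - 1


MULTIPLICITY_BINS = ("unique", "multi_2_9", "multi_10_99", "multi_100_plus", "unmapped")


def _multiplicity_bin(n: int) -> str:
    if n < 0:
        raise ValueError("negative alignment count")
    if n == 0:
        return "unmapped"
    if n == 1:
        return "unique"
    if n <= 9:
        return "multi_2_9"
    if n <= 99:
        return "multi_10_99"
    return "multi_100_plus"


@dataclass
class ReadAlignmentGroup:
    """All genomic alignments of one read, with its mapping-multiplicity class."""

    read_id: str
    alignments: list[GenomeAlignment] = field(default_factory=list)

    @property
    def n_alignments(self) -> int:
        return len(self.alignments)

    @property
    def multiplicity_bin(self) -> str:
        return _multiplicity_bin(self.n_alignments)


DEFAULT_FAMILY_MAP = {
    "B1": "B1",
    "B2": "B2",
    "B3": "B3",
    "B4": "B4",
    "ID": "ID",
    "MIR": "MIR",
}


def family_from_repname(rep_name: str, family_map: dict[str, str] | None = None) -> str:
    """Map a repeat subfamily name to its SINE family by prefix (B1_Mus2 -> B1)."""
    fmap = DEFAULT_FAMILY_MAP if family_map is None else family_map
    for prefix in sorted(fmap, key=len, reverse=True):
        if rep_name.startswith(prefix):
            return fmap[prefix]
    return "other"


@dataclass
class SineLocus:
    """One genomic repeat copy from an rmsk-style locus table (0-based half-open)."""

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    family: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"locus {self.locus_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"locus {self.locus_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime_boundary(self) -> int:
        """0-based genomic position of the locus transcription start."""
        return self.start if self.strand == "+" else self.end - 1


class Genome:
    """In-memory genome: chromosome name -> sequence, with strand-aware fetch."""

    def __init__(self, chromosomes: dict[str, str]):
        self.chromosomes = {name: seq.upper() for name, seq in chromosomes.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Subsequence [start, end); strand "-" returns its reverse complement."""
        seq = self.chromosomes[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"fetch {chrom}:{start}-{end} outside [0, {len(seq)}]")
        sub = seq[start:end]
        return sub if strand == "+" else revcomp(sub)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        return cls(read_fasta(path))

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(self.chromosomes, path)


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path) -> Iterator[SequenceRead]:
    """Stream SequenceReads from a 4-line FASTQ file (order preserved).

    Malformed records (sequence/quality length mismatch, truncation) raise
    :class:`FormatError` naming the offending record number.
    """
    with open(path) as handle:
        parser = FastqGeneralIterator(handle)
        n = 0
        while True:
            try:
                title, seq, qual = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise FormatError(f"{path}: FASTQ record {n + 1}: {exc}") from exc
            n += 1
            read_id = title.split()[0] if title else f"record{n}"
            try:
                yield SequenceRead(read_id, seq.upper(), qual)
            except ValueError as exc:
                raise FormatError(f"{path}: FASTQ record {n}: {exc}") from exc


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> int:
    """Write reads as 4-line FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            qual = read.qualities if read.qualities is not None else "I" * len(read)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> ordered {name: sequence} (name = first word of header)."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"{path}: sequence before first FASTA header")
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for name, seq in seqs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_RMSK_HEADER = (
    "   SW  perc perc perc  query     position in query    matching repeat"
    "       position in repeat\n"
    "score  div. del. ins.  sequence  begin end   (left)   repeat   class/family"
    " begin end    (left)\n"
    "\n"
)


def _strip_paren(token: str) -> int:
    return int(token.strip("()"))


def parse_rmsk_out(path: str | Path) -> Iterator[RepeatAlignment]:
    """Stream RepeatAlignments from a RepeatMasker ``.out`` file.

    The standard 3-line header is skipped; files without a header are
    accepted (detected by an integer first column).  Complement ("C") rows
    print the repeat coordinates as ``(left) end begin``; they are
    normalized here so that ``repeat_begin`` is the consensus position
    matched by the read's 5'-most base (see :class:`RepeatAlignment`).
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            fields = line.split()
            if not fields:
                continue
            try:
                int(fields[0])
            except ValueError:
                continue  # header / banner line
            try:
                yield _parse_rmsk_fields(fields)
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc


def _parse_rmsk_fields(fields: list[str]) -> RepeatAlignment:
    (sw, div, dele, ins, qid, qbeg, qend, qleft, strand_tok, rname, rclass) = fields[:11]
    r1, r2, r3 = fields[11:14]
    if strand_tok == "+":
        strand = "plus"
        rbeg, rend, rleft = int(r1), int(r2), _strip_paren(r3)
    elif strand_tok in ("C", "-"):
        strand = "complement"
        # printed order (left) end begin; the middle (larger) value pairs
        # with the query start on a complement hit
        rleft, rbeg, rend = _strip_paren(r1), int(r2), int(r3)
    else:
        raise ValueError(f"bad strand column {strand_tok!r}")
    return RepeatAlignment(
        sw_score=int(sw),
        pct_div=float(div),
        pct_del=float(dele),
        pct_ins=float(ins),
        query_id=qid,
        query_begin=int(qbeg),
        query_end=int(qend),
        query_left=_strip_paren(qleft),
        strand=strand,
        repeat_name=rname,
        repeat_class_family=rclass,
        repeat_begin=rbeg,
        repeat_end=rend,
        repeat_left=rleft,
    )


def write_rmsk_out(alignments: Iterable[RepeatAlignment], path: str | Path) -> int:
    """Write alignments in RepeatMasker ``.out`` layout; returns count."""
    n = 0
    with open(path, "w") as handle:
        handle.write(_RMSK_HEADER)
        for aln in alignments:
            if aln.strand == "plus":
                strand_tok = "+"
                rcols = f"{aln.repeat_begin} {aln.repeat_end} ({aln.repeat_left})"
            else:
                strand_tok = "C"
                rcols = f"({aln.repeat_left}) {aln.repeat_begin} {aln.repeat_end}"
            handle.write(
                f"{aln.sw_score} {aln.pct_div:.1f} {aln.pct_del:.1f} "
                f"{aln.pct_ins:.1f} {aln.query_id} {aln.query_begin} "
                f"{aln.query_end} ({aln.query_left}) {strand_tok} "
                f"{aln.repeat_name} {aln.repeat_class_family} {rcols}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# Locus tables (UCSC rmsk TSV / BED6)
# ---------------------------------------------------------------------------

_UCSC_COLUMNS = ("genoName", "genoStart", "genoEnd", "strand", "repName", "repClass", "repFamily")


def _make_locus(
    chrom: str,
    start: int,
    end: int,
    strand: str,
    subfamily: str,
    family_map: dict[str, str] | None,
    seen: dict[str, int],
    rowno: int,
) -> SineLocus:
    if start >= end:
        raise FormatError(f"row {rowno}: start {start} >= end {end}")
    base = f"{chrom}:{start}-{end}:{strand}:{subfamily}"
    seen[base] = seen.get(base, 0) + 1
    locus_id = base if seen[base] == 1 else f"{base}#{seen[base]}"
    return SineLocus(
        locus_id=locus_id,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        subfamily=subfamily,
        family=family_from_repname(subfamily, family_map),
    )


def read_locus_table(
    path: str | Path,
    dialect: str = "ucsc_rmsk",
    family_map: dict[str, str] | None = None,
) -> list[SineLocus]:
    """Read a repeat-locus table (both dialects are 0-based half-open).

    ``ucsc_rmsk`` is a TSV with (at least) the UCSC table-browser columns
    genoName/genoStart/genoEnd/strand/repName; ``bed6`` is plain BED.
    Generated locus_ids are ``chrom:start-end:strand:subfamily`` with a
    ``#k`` suffix to disambiguate duplicated rows.
    """
    if dialect not in ("ucsc_rmsk", "bed6"):
        raise ValueError(f"unknown locus table dialect {dialect!r}")
    loci: list[SineLocus] = []
    seen: dict[str, int] = {}
    with open(path) as handle:
        if dialect == "ucsc_rmsk":
            header_line = handle.readline()
            cols = header_line.lstrip("#").rstrip("\n").split("\t")
            try:
                idx = {name: cols.index(name) for name in _UCSC_COLUMNS[:5]}
            except ValueError as exc:
                raise FormatError(f"{path}: missing UCSC rmsk column: {exc}") from exc
            for rowno, line in enumerate(handle, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                loci.append(
                    _make_locus(
                        parts[idx["genoName"]],
                        int(parts[idx["genoStart"]]),
                        int(parts[idx["genoEnd"]]),
                        parts[idx["strand"]],
                        parts[idx["repName"]],
                        family_map,
                        seen,
                        rowno,
                    )
                )
        else:
            for rowno, line in enumerate(handle, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 6:
                    raise FormatError(f"{path}: row {rowno}: BED6 needs 6 columns")
                loci.append(
                    _make_locus(
                        parts[0], int(parts[1]), int(parts[2]), parts[5], parts[3],
                        family_map, seen, rowno,
                    )
                )
    return loci


def write_locus_table(loci: Iterable[SineLocus], path: str | Path, dialect: str = "ucsc_rmsk") -> int:
    if dialect not in ("ucsc_rmsk", "bed6"):
        raise ValueError(f"unknown locus table dialect {dialect!r}")
    n = 0
    with open(path, "w") as handle:
        if dialect == "ucsc_rmsk":
            handle.write("#" + "\t".join(_UCSC_COLUMNS) + "\n")
            for locus in loci:
                handle.write(
                    f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.strand}\t"
                    f"{locus.subfamily}\tSINE\t{locus.family}\n"
                )
                n += 1
        else:
            for locus in loci:
                handle.write(
                    f"{locus.chrom}\t{locus.start}\t{locus.end}\t"
                    f"{locus.subfamily}\t0\t{locus.strand}\n"
                )
                n += 1
    return n


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def read_sam_grouped(path: str | Path, validate: bool = True) -> Iterator[ReadAlignmentGroup]:
    """Group a SAM file's records by read id and stream ReadAlignmentGroups.

    Input order is irrelevant: groups are assembled in a read_id -> records
    map first.  All aligned records of a read count toward its multiplicity,
    whether or not they carry the secondary flag (FLAG 256): mappers asked
    to report all alignments differ in how they mark them.  Unmapped reads
    yield groups with ``n_alignments == 0``.
    """
    import pysam

    groups: dict[str, ReadAlignmentGroup] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=validate) as sam:
        if validate and not sam.header.get("SQ"):
            raise FormatError(f"{path}: SAM header has no @SQ lines")
        for rec in sam:
            group = groups.get(rec.query_name)
            if group is None:
                group = groups[rec.query_name] = ReadAlignmentGroup(rec.query_name)
            if rec.is_unmapped:
                continue
            group.alignments.append(
                GenomeAlignment(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    is_primary=not (rec.is_secondary or rec.is_supplementary),
                )
            )
    yield from groups.values()
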