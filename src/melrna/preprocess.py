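"""3' adapter trimming with discard-if-absent semantics.

The library protocol ligates a known 3' adapter to every RNA, so a read
without the adapter is either longer than the sequencing length or an
artifact; such reads are discarded rather than passed through untrimmed.

Matching is Hamming-style (substitutions only, no indels): for each
candidate cut position the adapter prefix is laid over the read tail and
accepted when the mismatch count stays within ``max_error_rate``.  This is
a deliberate, brute-force-verifiable simplification of cutadapt's
edit-distance alignment; on data without indel sequencing errors the two
agree.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

from .io_formats import SequenceRead

__all__ = ["TrimConfig", "TrimResult", "trim_adapter", "trim_stats", "trim_reads",
           "DEFAULT_ADAPTER"]

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"

KEPT = "kept"
DISCARD_NO_ADAPTER = "discarded_no_adapter"
DISCARD_SHORT = "discarded_short"


@dataclass(frozen=True)
class TrimConfig:
    """Adapter-trimming parameters.

    max_error_rate is the tolerated mismatch fraction of the matched
    length (floor), as in cutadapt; min_overlap is the shortest adapter
    prefix accepted at the read's 3' end; inserts shorter than
    min_insert_length after trimming are discarded as unmappable.
    """

    adapter: str = DEFAULT_ADAPTER
    max_error_rate: float = 0.1
    min_overlap: int = 3
    min_insert_length: int = 15

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if not (0 <= self.max_error_rate < 0.5):
            raise ValueError("max_error_rate must be in [0, 0.5)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass
class TrimResult:
    verdict: str  # KEPT | DISCARD_NO_ADAPTER | DISCARD_SHORT
    read: SequenceRead | None = None
    cut_position: int | None = None


def _find_adapter(sequence: str, cfg: TrimConfig) -> int | None:
    """Leftmost cut position where an adapter prefix matches, else None.

    At cut position i the compared window is sequence[i : i + m] against
    adapter[:m], m = min(len(adapter), len(sequence) - i).  Windows shorter
    than min_overlap are not considered; N matches nothing.
    """
    adapter = cfg.adapter
    alen = len(adapter)
    slen = len(sequence)
    for i in range(slen - cfg.min_overlap + 1):
        m = min(alen, slen - i)
        allowed = int(cfg.max_error_rate * m)
        mismatches = 0
        window = sequence[i : i + m]
        for a, b in zip(window, adapter):
            if a != b or a == "N":
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return i
    return None


def trim_adapter(read: SequenceRead, cfg: TrimConfig | None = None) -> TrimResult:
    """Trim the 3' adapter off one read, or return a discard verdict.

    The leftmost acceptable adapter start wins, so the insert ends at the
    first adapter occurrence.  Reads with no acceptable match are discarded
    (verdict ``discarded_no_adapter``); reads whose insert would be shorter
    than ``min_insert_length`` are discarded (``discarded_short``).
    """
    cfg = cfg or TrimConfig()
    cut = _find_adapter(read.sequence, cfg)
    if cut is None:
        return TrimResult(DISCARD_NO_ADAPTER)
    if cut == 0 or cut < cfg.min_insert_length:  # empty inserts are never keepable
        return TrimResult(DISCARD_SHORT, cut_position=cut)
    trimmed = replace(
        read,
        sequence=read.sequence[:cut],
        qualities=read.qualities[:cut] if read.qualities is not None else None,
    )
    return TrimResult(KEPT, read=trimmed, cut_position=cut)


def trim_stats(results: Iterable[TrimResult]) -> dict[str, int]:
    """Tally verdicts; counts always sum to the number of input reads."""
    counts = {KEPT: 0, DISCARD_NO_ADAPTER: 0, DISCARD_SHORT: 0}
    for res in results:
        counts[res.verdict] += 1
    return counts


def trim_reads(
    reads: Iterable[SequenceRead], cfg: TrimConfig | None = None
) -> tuple[list[SequenceRead], dict[str, int]]:
    """Trim a read stream; returns (kept trimmed reads, verdict counts)."""
    cfg = cfg or TrimConfig()
    kept: list[SequenceRead] = []
    counts = {KEPT: 0, DISCARD_NO_ADAPTER: 0, DISCARD_SHORT: 0}
    for read in reads:
        res = trim_adapter(read, cfg)
        counts[res.verdict] += 1
        if res.verdict == KEPT:
            kept.append(res.read)
    return kept, counts
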