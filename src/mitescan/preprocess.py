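"""Read preprocessing: quality trimming, anchor verification, flank extraction.

Anchored-amplicon read 1 carries the element terminal sequence (the anchor)
at its 5' end followed by flanking host genome.  Preprocessing (i) trims
low-quality 3' tails at a Phred cutoff (QV >= 30 by default, cutadapt-style
partial-sum trimming), (ii) verifies the anchor within a mismatch budget and
strips it, and (iii) trims the remaining flank to a fixed length so that
identical insertion sites yield identical flank strings downstream.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]  # Phred scores

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.read_id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class FlankRead:
    """A verified, anchor-stripped flank trimmed to a fixed length."""

    read_id: str
    line_id: str
    sequence: str
    qualities: tuple[int, ...]


@dataclass
class PreprocessStats:
    n_in: int = 0
    n_quality_pass: int = 0
    n_flanks: int = 0
    n_no_anchor: int = 0
    n_short: int = 0


def _quality_cut(quals: Sequence[int], cutoff: int) -> int:
    """Index at which to cut the 3' tail (cutadapt partial-sum algorithm)."""
    s = 0
    best = 0
    cut = len(quals)
    for i in range(len(quals) - 1, -1, -1):
        s += cutoff - quals[i]
        if s > best:
            best = s
            cut = i
        if s < 0:
            break
    return cut


def quality_filter(
    reads: Iterable[FastqRead],
    qv_min: int = 30,
    min_len: int = 0,
) -> tuple[list[FastqRead], int]:
    """Trim 3' tails below ``qv_min``; drop reads shorter than ``min_len``.

    Idempotent: trimming an already-trimmed read removes nothing further.
    Returns the surviving reads and the number dropped for length.
    """
    out: list[FastqRead] = []
    n_dropped = 0
    for r in reads:
        cut = _quality_cut(r.qualities, qv_min)
        if cut < min_len:
            n_dropped += 1
            continue
        if cut == len(r.sequence):
            out.append(r)
        else:
            out.append(FastqRead(r.read_id, r.sequence[:cut], r.qualities[:cut]))
    return out, n_dropped


def _hamming_at_most(a: str, b: str, k: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > k:
                return False
    return True


def extract_flank(
    reads: Iterable[FastqRead],
    anchor: str,
    line_id: str,
    max_mismatch: int = 1,
    trim_len: int = 100,
) -> tuple[list[FlankRead], PreprocessStats]:
    """Strip the verified anchor and emit fixed-length flanks.

    A read passes when its 5' prefix matches ``anchor`` with at most
    ``max_mismatch`` substitutions; the anchor is removed and the flank
    truncated to ``trim_len`` bases.  Reads failing the anchor check, or
    whose flank is shorter than ``trim_len``, are counted and discarded.
    """
    if len(anchor) < 10:
        raise ValueError("anchor must be at least 10 bases")
    anchor = anchor.upper()
    alen = len(anchor)
    flanks: list[FlankRead] = []
    stats = PreprocessStats()
    for r in reads:
        stats.n_in += 1
        if len(r.sequence) < alen or not _hamming_at_most(
            r.sequence[:alen].upper(), anchor, max_mismatch
        ):
            stats.n_no_anchor += 1
            continue
        flank = r.sequence[alen:]
        if len(flank) < trim_len:
            stats.n_short += 1
            continue
        flanks.append(
            FlankRead(
                read_id=r.read_id,
                line_id=line_id,
                sequence=flank[:trim_len].upper(),
                qualities=r.qualities[alen : alen + trim_len],
            )
        )
    stats.n_flanks = len(flanks)
    return flanks, stats


def preprocess_reads(
    reads: Iterable[FastqRead],
    anchor: str,
    line_id: str,
    qv_min: int = 30,
    trim_len: int = 100,
    max_mismatch: int = 1,
) -> tuple[list[FlankRead], PreprocessStats]:
    """Quality-trim then anchor-verify one line's read-1 stream."""
    reads = list(reads)
    kept, n_short = quality_filter(reads, qv_min=qv_min,
                                   min_len=len(anchor) + trim_len)
    flanks, stats = extract_flank(kept, anchor, line_id,
                                  max_mismatch=max_mismatch, trim_len=trim_len)
    stats.n_in = len(reads)
    stats.n_quality_pass = len(kept)
    stats.n_short += n_short
    return flanks, stats
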