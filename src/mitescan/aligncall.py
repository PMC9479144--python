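"""Reference-based insertion-site detection.

Flank reads (anchor already stripped) are located on the reference genome;
the strand-aware, junction-proximal start coordinate of every alignment is
collected, and insertion loci are called per line by grouping starts that
fall within a fixed window (500 bp by default) and thresholding the
supporting-read count (>= 50 by default).  Loci below the threshold are
retained separately: the reconciliation stage may rescue them when the
reference-free detector independently supports the same locus.

The built-in mapper reports the unique exact occurrence of each flank on
either strand (optionally the unique best occurrence within
``max_mismatch`` edits, via edlib); flanks mapping nowhere or to several
places are dropped and counted.  Pre-computed alignments can be ingested
from SAM instead.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

from .preprocess import FlankRead

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignedStart:
    """Junction-proximal start of one aligned flank (1-based)."""

    chrom: str
    start: int
    strand: str
    line_id: str


@dataclass(frozen=True)
class InsertionSite:
    """A called insertion locus for one line."""

    chrom: str
    position: int  # 1-based junction estimate
    support: int
    method: str  # "cluster" | "align"
    line_id: str

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("site support must be >= 1")


@dataclass
class MapStats:
    n_mapped: int = 0
    n_unmapped: int = 0
    n_multi: int = 0


def _find_all(haystack: str, needle: str, limit: int) -> list[int]:
    """0-based start positions of ``needle`` in ``haystack`` (at most ``limit``)."""
    hits: list[int] = []
    i = haystack.find(needle)
    while i != -1 and len(hits) < limit:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def _locate_exact(seq: str, reference: Mapping[str, str]) -> list[tuple[str, int, str]]:
    """All exact placements of ``seq``: (chrom, junction-proximal 1-based pos, strand).

    Forward hits report the leftmost aligned base; reverse hits report the
    rightmost aligned base (the junction-proximal end of an anchored flank).
    Search stops early once two placements are found (enough to declare
    multi-mapping).
    """
    rc = revcomp(seq)
    hits: list[tuple[str, int, str]] = []
    for chrom, chromseq in reference.items():
        for i in _find_all(chromseq, seq, 2 - len(hits)):
            hits.append((chrom, i + 1, "+"))
        if len(hits) >= 2:
            break
        for i in _find_all(chromseq, rc, 2 - len(hits)):
            hits.append((chrom, i + len(seq), "-"))
        if len(hits) >= 2:
            break
    return hits


def _locate_approx(
    seq: str, reference: Mapping[str, str], max_mismatch: int
) -> list[tuple[str, int, str]]:
    """Best placements of ``seq`` within ``max_mismatch`` edits (edlib, infix mode).

    Equal-cost placements closer than half the flank length are collapsed to
    one (indel alternatives of the same locus); distinct loci remain distinct
    so multi-mapping is still detected.
    """
    import edlib

    best = max_mismatch + 1
    raw: list[tuple[str, int, str, int]] = []
    for chrom, chromseq in reference.items():
        for strand, pattern in (("+", seq), ("-", revcomp(seq))):
            res = edlib.align(pattern, chromseq, mode="HW", task="locations",
                              k=max_mismatch)
            if res["editDistance"] < 0:
                continue
            for s, e in res["locations"]:
                if strand == "+":
                    pos = (s if s is not None else e - len(seq) + 1) + 1
                else:
                    pos = e + 1  # rightmost aligned base, 1-based
                raw.append((chrom, pos, strand, res["editDistance"]))
            best = min(best, res["editDistance"])
    raw = [h for h in raw if h[3] == best]
    collapsed: list[tuple[str, int, str]] = []
    for chrom, pos, strand, _ in sorted(raw):
        if collapsed and collapsed[-1][0] == chrom and collapsed[-1][2] == strand \
                and abs(pos - collapsed[-1][1]) < len(seq) // 2:
            continue
        collapsed.append((chrom, pos, strand))
    return collapsed


def map_flanks(
    flanks: Iterable[FlankRead],
    reference: Mapping[str, str],
    max_mismatch: int = 0,
) -> tuple[list[AlignedStart], MapStats]:
    """Place each flank uniquely on the reference; drop ambiguous/unplaced ones.

    Results are cached per distinct sequence, so dereplicated libraries map in
    near-constant time per site.
    """
    cache: dict[str, list[tuple[str, int, str]]] = {}
    starts: list[AlignedStart] = []
    stats = MapStats()
    for fr in flanks:
        hits = cache.get(fr.sequence)
        if hits is None:
            if max_mismatch == 0:
                hits = _locate_exact(fr.sequence, reference)
            else:
                hits = _locate_approx(fr.sequence, reference, max_mismatch)
            cache[fr.sequence] = hits
        if len(hits) == 1:
            chrom, pos, strand = hits[0]
            starts.append(AlignedStart(chrom, pos, strand, fr.line_id))
            stats.n_mapped += 1
        elif len(hits) == 0:
            stats.n_unmapped += 1
        else:
            stats.n_multi += 1
    return starts, stats


def read_sam_starts(path, line_id: str) -> list[AlignedStart]:
    """Junction-proximal starts from a SAM file (primary, mapped records only).

    Forward alignments contribute their leftmost reference base; reverse
    alignments their rightmost (junction-proximal for anchored flanks).
    """
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        if sam.header.nreferences == 0:
            raise ValueError(f"SAM {path} has no @SQ header sequence lines")
        starts: list[AlignedStart] = []
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_reverse:
                starts.append(
                    AlignedStart(rec.reference_name, rec.reference_end, "-", line_id)
                )
            else:
                starts.append(
                    AlignedStart(rec.reference_name, rec.reference_start + 1, "+",
                                 line_id)
                )
    return starts


def _modal_position(positions: Sequence[int]) -> int:
    counts = Counter(positions)
    return min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]


def call_sites_by_window(
    starts: Sequence[AlignedStart],
    window: int = 500,
    min_reads: int = 50,
) -> tuple[list[InsertionSite], list[InsertionSite]]:
    """Group nearby starts into loci and threshold by supporting reads.

    Per line and chromosome, sorted starts are scanned left to right: a locus
    opens at the first unassigned start and absorbs every start within
    ``window`` bases of that opening start.  The locus position is the modal
    start (tie -> smallest), its support the number of assigned starts.  Loci
    with support >= ``min_reads`` are returned as called sites; the rest as
    sub-threshold loci.  The result is invariant to input permutation, and
    every start is assigned to exactly one locus.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    groups: dict[tuple[str, str], list[int]] = {}
    for st in starts:
        groups.setdefault((st.line_id, st.chrom), []).append(st.start)
    called: list[InsertionSite] = []
    sub: list[InsertionSite] = []
    for (line_id, chrom) in sorted(groups):
        positions = sorted(groups[(line_id, chrom)])
        i, n = 0, len(positions)
        while i < n:
            opening = positions[i]
            j = i
            while j < n and positions[j] <= opening + window:
                j += 1
            members = positions[i:j]
            site = InsertionSite(
                chrom=chrom,
                position=_modal_position(members),
                support=len(members),
                method="align",
                line_id=line_id,
            )
            (called if site.support >= min_reads else sub).append(site)
            i = j
    return called, sub
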