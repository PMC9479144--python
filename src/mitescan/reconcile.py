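"""Reconciliation of the two detectors and cross-line comparison.

Per line, cluster-derived sites are matched positionally (same chromosome,
within a tolerance, 100 bp by default) against alignment-derived sites.
Matches are *common* sites; remaining cluster sites matching a sub-threshold
alignment locus (fewer than the calling threshold but at least one aligned
read) are *rescued* — independently supported by the reference-free method,
they are considered actually present.  The final per-line set is the union
of common and rescued sites; cluster sites with no aligned reads at all are
excluded and reported.  Across lines, final sets are matched by position
(transitive closure, single representative per equivalence class) to produce
Venn-partition counts.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

from .aligncall import InsertionSite, MapStats, map_flanks
from .cluster import ReadCluster
from .preprocess import FlankRead


@dataclass(frozen=True)
class ReconcileCounts:
    """The per-line reconciliation quintet (one Table-1-style row)."""

    line_id: str
    n_cluster: int
    n_align: int
    n_common: int
    n_rescued: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total != self.n_common + self.n_rescued:
            raise ValueError("n_total must equal n_common + n_rescued")
        if self.n_common > min(self.n_cluster, self.n_align):
            raise ValueError("n_common exceeds a marginal count")
        if self.n_rescued > self.n_cluster - self.n_common:
            raise ValueError("n_rescued exceeds unmatched cluster sites")


@dataclass(frozen=True)
class PositionedCluster:
    cluster_id: str
    chrom: str
    position: int
    strand: str


@dataclass
class LocateResult:
    placed: list[PositionedCluster]
    unplaced: list[str]  # cluster_ids with no unique reference placement
    stats: MapStats


def locate_clusters(
    clusters: Sequence[ReadCluster],
    reference: Mapping[str, str],
    max_mismatch: int = 0,
) -> LocateResult:
    """Place each cluster representative uniquely on the reference.

    Uses the same unique-placement rule as flank mapping; clusters whose
    representative is absent or ambiguous are flagged unplaced.
    """
    pseudo = [
        FlankRead(cl.cluster_id, "_rep", cl.representative, ())
        for cl in clusters
    ]
    placed: list[PositionedCluster] = []
    unplaced: list[str] = []
    stats = MapStats()
    for cl, fr in zip(clusters, pseudo):
        starts, st = map_flanks([fr], reference, max_mismatch=max_mismatch)
        stats.n_mapped += st.n_mapped
        stats.n_unmapped += st.n_unmapped
        stats.n_multi += st.n_multi
        if starts:
            a = starts[0]
            placed.append(PositionedCluster(cl.cluster_id, a.chrom, a.start, a.strand))
        else:
            unplaced.append(cl.cluster_id)
    return LocateResult(placed, unplaced, stats)


def _match_one_to_one(
    queries: Sequence[InsertionSite],
    targets: Sequence[InsertionSite],
    tol: int,
) -> dict[int, int]:
    """Greedy one-to-one positional matching; query index -> target index.

    Candidate pairs on the same chromosome within ``tol`` are taken in order
    of increasing distance (ties by position), each site used at most once.
    """
    pairs: list[tuple[int, int, int, int]] = []
    for qi, q in enumerate(queries):
        for ti, t in enumerate(targets):
            if q.chrom == t.chrom and abs(q.position - t.position) <= tol:
                pairs.append((abs(q.position - t.position), q.position, qi, ti))
    pairs.sort()
    used_q: set[int] = set()
    used_t: set[int] = set()
    match: dict[int, int] = {}
    for _, _, qi, ti in pairs:
        if qi in used_q or ti in used_t:
            continue
        match[qi] = ti
        used_q.add(qi)
        used_t.add(ti)
    return match


@dataclass
class LineReconciliation:
    final_sites: list[InsertionSite]
    counts: ReconcileCounts
    unsupported_cluster_sites: list[InsertionSite]  # no aligned reads at all


def reconcile_line(
    cluster_sites: Sequence[InsertionSite],
    align_sites: Sequence[InsertionSite],
    subthreshold_loci: Sequence[InsertionSite],
    tol: int = 100,
) -> LineReconciliation:
    """Merge one line's two site sets and derive the reconciliation counts.

    Common sites keep the alignment-derived position; rescued sites keep the
    sub-threshold locus position.  Cluster sites matching neither are
    excluded from the final set and reported.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    line_ids = {s.line_id for s in
                (*cluster_sites, *align_sites, *subthreshold_loci)}
    if len(line_ids) > 1:
        raise ValueError(f"reconcile_line mixes lines: {sorted(line_ids)}")
    line_id = line_ids.pop() if line_ids else ""

    common_match = _match_one_to_one(cluster_sites, align_sites, tol)
    leftover = [qi for qi in range(len(cluster_sites)) if qi not in common_match]
    rescue_match = _match_one_to_one(
        [cluster_sites[qi] for qi in leftover], subthreshold_loci, tol
    )
    final = [align_sites[ti] for ti in sorted(common_match.values())]
    final += [subthreshold_loci[ti] for ti in sorted(rescue_match.values())]
    final.sort(key=lambda s: (s.chrom, s.position))
    unsupported = [
        cluster_sites[leftover[k]]
        for k in range(len(leftover))
        if k not in rescue_match
    ]
    counts = ReconcileCounts(
        line_id=line_id,
        n_cluster=len(cluster_sites),
        n_align=len(align_sites),
        n_common=len(common_match),
        n_rescued=len(rescue_match),
        n_total=len(common_match) + len(rescue_match),
    )
    return LineReconciliation(final, counts, unsupported)


def overlap_percentage(counts: ReconcileCounts) -> float:
    """Percentage of cluster-derived sites confirmed by alignment (one decimal)."""
    if counts.n_cluster <= 0:
        raise ValueError("n_cluster must be positive")
    return round(100.0 * counts.n_common / counts.n_cluster, 1)


@dataclass
class VennCounts:
    """Counts for every region of the cross-line Venn partition.

    ``region_counts`` maps each non-empty subset of lines to the number of
    site equivalence classes detected in exactly those lines.
    """

    lines: tuple[str, ...]
    region_counts: dict[frozenset, int]

    @property
    def n_classes(self) -> int:
        return sum(self.region_counts.values())

    def common_to_all(self) -> int:
        return self.region_counts.get(frozenset(self.lines), 0)

    def specific_to(self, line_id: str) -> int:
        return self.region_counts.get(frozenset([line_id]), 0)


def compare_lines(
    site_sets: Mapping[str, Sequence[InsertionSite]],
    tol: int = 100,
) -> VennCounts:
    """Match final sites across lines and count every Venn region.

    Sites (all lines pooled) on one chromosome are chained: consecutive
    sorted positions within ``tol`` belong to one equivalence class (the 1-D
    transitive closure of pairwise matching); the class representative is the
    smallest position.  Each class is counted once in the region given by the
    set of lines it appears in.  Symmetric in line order.
    """
    if len(site_sets) < 2:
        raise ValueError("need at least two lines to compare")
    lines = tuple(sorted(site_sets))
    pooled: list[tuple[str, int, str]] = []
    for line_id in lines:
        for s in site_sets[line_id]:
            pooled.append((s.chrom, s.position, line_id))
    pooled.sort()
    region_counts: dict[frozenset, int] = {}
    i, n = 0, len(pooled)
    while i < n:
        chrom = pooled[i][0]
        members = {pooled[i][2]}
        j = i + 1
        while j < n and pooled[j][0] == chrom and pooled[j][1] - pooled[j - 1][1] <= tol:
            members.add(pooled[j][2])
            j += 1
        key = frozenset(members)
        region_counts[key] = region_counts.get(key, 0) + 1
        i = j
    return VennCounts(lines=lines, region_counts=region_counts)
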