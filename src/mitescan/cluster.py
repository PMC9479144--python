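"""Reference-free insertion-site detection by flank clustering.

Fixed-length flanks are dereplicated (distinct sequences with a total
abundance of at least 10 reads are kept, one record per sequence with
per-line counts), then clustered greedily around high-abundance centroids:
sequences are processed in descending total abundance and join the first
cluster whose representative they match at >= 90% ungapped identity over
the full trimmed length, otherwise they found a new cluster.  Each cluster
stands for one insertion site.  Per-line presence/absence is then called by
fractional abundance: a line carries the insertion when the cluster's reads
make up at least 0.01% of that line's total flank count.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import FlankRead


@dataclass
class UniqueSeq:
    """One distinct flank sequence with its per-line read counts."""

    sequence: str
    abundance: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.abundance.values())


@dataclass
class ReadCluster:
    cluster_id: str
    representative: str  # highest-abundance member sequence
    members: list[UniqueSeq]
    reads_per_line: dict[str, int]

    @property
    def total_reads(self) -> int:
        return sum(self.reads_per_line.values())


def dereplicate(flanks: Iterable[FlankRead], min_abund: int = 10) -> list[UniqueSeq]:
    """Collapse identical flanks; keep sequences with total abundance >= ``min_abund``.

    All flanks must share one length (they are trimmed upstream); mixed
    lengths are a hard error because downstream identity is ungapped.
    """
    counts: dict[str, dict[str, int]] = {}
    length: int | None = None
    for fr in flanks:
        if length is None:
            length = len(fr.sequence)
        elif len(fr.sequence) != length:
            raise ValueError(
                f"mixed flank lengths ({length} vs {len(fr.sequence)}); "
                "trim to a single length first"
            )
        per_line = counts.setdefault(fr.sequence, {})
        per_line[fr.line_id] = per_line.get(fr.line_id, 0) + 1
    uniques = [
        UniqueSeq(seq, dict(sorted(ab.items())))
        for seq, ab in counts.items()
        if sum(ab.values()) >= min_abund
    ]
    uniques.sort(key=lambda u: (-u.total, u.sequence))
    return uniques


def _identity(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.count_nonzero(a == b)) / len(a)


def cluster_sequences(
    uniques: list[UniqueSeq],
    min_identity: float = 0.90,
) -> list[ReadCluster]:
    """Greedy centroid clustering of dereplicated flanks.

    Processing order is descending total abundance (tie -> lexicographic on
    sequence), so representatives are always the highest-abundance member of
    their cluster and the outcome is deterministic.  Identity is ungapped
    over the full (equal) length.
    """
    if not 0.0 < min_identity <= 1.0:
        raise ValueError("min_identity must be in (0, 1]")
    ordered = sorted(uniques, key=lambda u: (-u.total, u.sequence))
    reps: list[np.ndarray] = []
    clusters: list[ReadCluster] = []
    for u in ordered:
        arr = np.frombuffer(u.sequence.encode(), dtype=np.uint8)
        assigned = False
        for idx, rep in enumerate(reps):
            if _identity(arr, rep) >= min_identity:
                cl = clusters[idx]
                cl.members.append(u)
                for line, n in u.abundance.items():
                    cl.reads_per_line[line] = cl.reads_per_line.get(line, 0) + n
                assigned = True
                break
        if not assigned:
            reps.append(arr)
            clusters.append(
                ReadCluster(
                    cluster_id=f"cl{len(clusters):05d}",
                    representative=u.sequence,
                    members=[u],
                    reads_per_line=dict(u.abundance),
                )
            )
    return clusters


def call_genotypes(
    clusters: list[ReadCluster],
    reads_per_line_total: Mapping[str, int],
    frac_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Binary presence/absence matrix (lines x clusters) by fractional abundance.

    call(line, cluster) = 1 iff the cluster's reads for that line are at
    least ``frac_threshold`` of the line's total flank count (default 0.01%).
    Row sums are the per-line insertion-site counts.
    """
    lines = sorted(reads_per_line_total)
    for line, tot in reads_per_line_total.items():
        if tot <= 0:
            raise ValueError(f"line {line}: total read count must be positive")
    for cl in clusters:
        for line in cl.reads_per_line:
            if line not in reads_per_line_total:
                raise ValueError(
                    f"line {line} appears in cluster {cl.cluster_id} "
                    "but has no total read count"
                )
    data = np.zeros((len(lines), len(clusters)), dtype=np.int8)
    for j, cl in enumerate(clusters):
        for i, line in enumerate(lines):
            n = cl.reads_per_line.get(line, 0)
            if n > 0 and n / reads_per_line_total[line] >= frac_threshold:
                data[i, j] = 1
    return pd.DataFrame(
        data, index=pd.Index(lines, name="line_id"),
        columns=[cl.cluster_id for cl in clusters],
    )
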