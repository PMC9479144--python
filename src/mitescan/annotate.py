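"""Genic-context annotation of insertion sites.

Classifies each called insertion site as *inside* a gene, *near* a gene
(within ``near_kb`` kilobases of the gene span, boundary inclusive) or
*intergenic*; sub-classifies inside-gene sites by gene substructure
(5'/3' UTR, exon, intron) and near-gene sites by orientation (upstream /
downstream of the gene, resolved by gene strand).  Also computes the
genome-wide base-pair occupancy of the three categories — the neutral
baseline an insertion machinery with no preference would follow — and a
chi-square goodness-of-fit test of the observed category counts against
that baseline.

Coordinates are 1-based inclusive throughout this module.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .aligncall import InsertionSite

CATEGORIES = ("inside", "near", "intergenic")


@dataclass(frozen=True)
class Gene:
    """A gene span with optional exon/UTR substructure (1-based inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GeneSet:
    """Gene models plus the chromosome space they annotate.

    ``chrom_lengths`` defines the annotation space: classifying a site on a
    chromosome absent from it is a hard error (a site on an unknown sequence
    cannot be meaningfully called intergenic).
    """

    def __init__(self, genes: Iterable[Gene], chrom_lengths: Mapping[str, int]):
        self.genes: list[Gene] = sorted(
            genes, key=lambda g: (g.chrom, g.start, g.gene_id)
        )
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths)
        for g in self.genes:
            if g.chrom not in self.chrom_lengths:
                raise ValueError(
                    f"gene {g.gene_id} on {g.chrom} outside annotation space"
                )
            if g.end > self.chrom_lengths[g.chrom]:
                raise ValueError(f"gene {g.gene_id} extends past end of {g.chrom}")
        self._trees: dict[str, IntervalTree] = {}
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end + 1, g
            )
            self._by_chrom.setdefault(g.chrom, []).append(g)

    @classmethod
    def from_gff3(cls, path) -> "GeneSet":
        from .io import read_genes_gff3

        genes, lengths = read_genes_gff3(path)
        return cls(genes, lengths)

    def genes_on(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])

    def overlapping(self, chrom: str, pos: int) -> list[Gene]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[pos]), key=lambda g: g.gene_id)


@dataclass(frozen=True)
class SiteAnnotation:
    site: InsertionSite
    category: str  # inside | near | intergenic
    subfeature: str  # exon | intron | utr5 | utr3 | upstream | downstream | none
    gene_id: str | None
    distance: int | None  # signed; 0 inside; negative upstream of the gene


@dataclass(frozen=True)
class BaselineProportions:
    """Base-pair fractions of the genome in each category (sum to 1)."""

    inside: float
    near: float
    intergenic: float

    def __post_init__(self) -> None:
        total = self.inside + self.near + self.intergenic
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 1")

    def as_dict(self) -> dict[str, float]:
        return {"inside": self.inside, "near": self.near, "intergenic": self.intergenic}


def _contains(iv: tuple[int, int] | None, pos: int) -> bool:
    return iv is not None and iv[0] <= pos <= iv[1]


def _subfeature_inside(gene: Gene, pos: int) -> str:
    if _contains(gene.utr5, pos):
        return "utr5"
    if _contains(gene.utr3, pos):
        return "utr3"
    for s, e in gene.exons:
        if s <= pos <= e:
            return "exon"
    return "intron" if gene.exons else "exon"


def _signed_distance(gene: Gene, pos: int) -> int:
    """Signed distance from ``pos`` to the gene span; negative = upstream."""
    if pos < gene.start:
        d = gene.start - pos
        left_side = True
    elif pos > gene.end:
        d = pos - gene.end
        left_side = False
    else:
        return 0
    upstream = left_side if gene.strand == "+" else not left_side
    return -d if upstream else d


def classify_sites(
    sites: Sequence[InsertionSite],
    geneset: GeneSet,
    near_kb: float = 3.0,
) -> list[SiteAnnotation]:
    """Assign each site its genic category, subfeature, gene and distance.

    Inside takes precedence over near; the nearest gene is chosen by minimal
    distance to the gene span (tie broken by smaller gene_id).  "Within
    ``near_kb`` kb" is inclusive at exactly ``near_kb * 1000`` bases.
    """
    near_bp = int(round(near_kb * 1000))
    out: list[SiteAnnotation] = []
    # precompute per-chrom arrays for nearest-gene queries
    arrays: dict[str, tuple[np.ndarray, np.ndarray, list[Gene]]] = {}
    for chrom in geneset.chrom_lengths:
        gl = geneset.genes_on(chrom)
        arrays[chrom] = (
            np.array([g.start for g in gl], dtype=np.int64),
            np.array([g.end for g in gl], dtype=np.int64),
            gl,
        )
    for site in sites:
        if site.chrom not in geneset.chrom_lengths:
            raise ValueError(f"site chromosome {site.chrom!r} not in annotation space")
        pos = site.position
        hits = geneset.overlapping(site.chrom, pos)
        if hits:
            gene = hits[0]  # smallest gene_id on (rare) overlap
            out.append(
                SiteAnnotation(site, "inside", _subfeature_inside(gene, pos),
                               gene.gene_id, 0)
            )
            continue
        starts, ends, gl = arrays[site.chrom]
        if len(gl) == 0:
            out.append(SiteAnnotation(site, "intergenic", "none", None, None))
            continue
        dist = np.where(pos < starts, starts - pos,
                        np.where(pos > ends, pos - ends, 0))
        dmin = int(dist.min())
        cand = [gl[i] for i in np.flatnonzero(dist == dmin)]
        gene = min(cand, key=lambda g: g.gene_id)
        signed = _signed_distance(gene, pos)
        if dmin <= near_bp:
            sub = "upstream" if signed < 0 else "downstream"
            out.append(SiteAnnotation(site, "near", sub, gene.gene_id, signed))
        else:
            out.append(SiteAnnotation(site, "intergenic", "none", None, signed))
    return out


def summarize_distribution(annotations: Sequence[SiteAnnotation]) -> pd.DataFrame:
    """Per-line category counts and percentages (one decimal), plus totals.

    Returns one row per line with columns ``n_<cat>``, ``pct_<cat>`` and
    ``total``; counts always partition the line's site total.
    """
    if not annotations:
        raise ValueError("no annotations to summarize")
    rows = []
    by_line: dict[str, list[SiteAnnotation]] = {}
    for a in annotations:
        by_line.setdefault(a.site.line_id, []).append(a)
    for line_id in sorted(by_line):
        anns = by_line[line_id]
        total = len(anns)
        row: dict[str, object] = {"line_id": line_id}
        for cat in CATEGORIES:
            n = sum(1 for a in anns if a.category == cat)
            row[f"n_{cat}"] = n
            row[f"pct_{cat}"] = round(100.0 * n / total, 1)
        row["total"] = total
        rows.append(row)
    return pd.DataFrame(rows)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ls, le = merged[-1]
        if s <= le + 1:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def genome_baseline(
    geneset: GeneSet,
    near_kb: float = 3.0,
) -> BaselineProportions:
    """Base-pair fractions of the genome inside genes, near genes, intergenic.

    Gene spans are merged; near-flanks are the ``near_kb``-kb extensions of
    the merged spans minus the spans themselves (overlapping flanks counted
    once); intergenic is the remainder.  The three partition the genome.
    """
    near_bp = int(round(near_kb * 1000))
    total = sum(geneset.chrom_lengths.values())
    if total <= 0:
        raise ValueError("empty genome")
    inside_bp = 0
    extended_bp = 0
    for chrom, length in geneset.chrom_lengths.items():
        spans = [(g.start, g.end) for g in geneset.genes_on(chrom)]
        inside_bp += sum(e - s + 1 for s, e in _merge(spans))
        ext = [(max(1, s - near_bp), min(length, e + near_bp)) for s, e in spans]
        extended_bp += sum(e - s + 1 for s, e in _merge(ext))
    near = extended_bp - inside_bp
    return BaselineProportions(
        inside=inside_bp / total,
        near=near / total,
        intergenic=(total - extended_bp) / total,
    )


@dataclass(frozen=True)
class PreferenceTest:
    statistic: float
    df: int
    pvalue: float
    residuals: dict[str, float] = field(hash=False)


def preference_test(
    observed: Mapping[str, int],
    baseline: BaselineProportions,
) -> PreferenceTest:
    """Chi-square goodness-of-fit of observed category counts vs the baseline.

    Expected counts are ``total * baseline fraction``; standardized residuals
    ``(O - E)/sqrt(E)`` give the direction of the departure per category.
    """
    counts = np.array([observed.get(c, 0) for c in CATEGORIES], dtype=float)
    total = counts.sum()
    if total < 1:
        raise ValueError("need at least one observed site")
    fracs = np.array([getattr(baseline, c) for c in CATEGORIES])
    expected = total * fracs
    if np.any(expected <= 0):
        raise ValueError("expected count of zero; baseline fraction must be positive")
    stat, p = stats.chisquare(counts, expected)
    resid = (counts - expected) / np.sqrt(expected)
    return PreferenceTest(
        statistic=float(stat),
        df=len(CATEGORIES) - 1,
        pvalue=float(p),
        residuals={c: float(r) for c, r in zip(CATEGORIES, resid)},
    )
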