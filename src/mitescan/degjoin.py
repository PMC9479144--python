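"""Join differentially expressed genes (DEGs) with insertion sites.

Differential-expression calling happens upstream (the module consumes a
results table: gene_id, log2 fold-change, adjusted p, direction); here each
significant DEG is paired with every insertion site falling inside its gene
span or within 3 kb of it, using the same span-boundary, boundary-inclusive
distance convention as the annotation module.  The summary reports how many
distinct DEGs have a proximal insertion and what fraction of all DEGs that
is — in the source study a fraction below half a percent, arguing that mPing
rarely drives the expression differences.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import pandas as pd

from .aligncall import InsertionSite
from .annotate import GeneSet


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log2fc: float
    padj: float
    direction: str  # "up" | "down"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"bad direction {self.direction!r}")
        if (self.log2fc > 0) != (self.direction == "up"):
            raise ValueError(
                f"DEG {self.gene_id}: direction {self.direction} inconsistent "
                f"with log2fc {self.log2fc}"
            )


@dataclass(frozen=True)
class ProximalDEG:
    deg: DEGRecord
    site: InsertionSite
    relation: str  # "inside" | "near"
    distance: int  # 0 if inside, else 1..near_kb*1000


def read_deg_table(path, padj_max: float = 0.05) -> tuple[list[DEGRecord], int]:
    """Load a DEG TSV (gene_id, log2fc, padj, direction); keep significant rows.

    Returns the significant records and the total row count (the fraction
    denominator convention is the caller's choice).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "padj", "direction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    degs = [
        DEGRecord(str(r.gene_id), float(r.log2fc), float(r.padj), str(r.direction))
        for r in df.itertuples()
        if r.padj <= padj_max and r.direction in ("up", "down")
    ]
    return degs, len(df)


@dataclass
class JoinResult:
    records: list[ProximalDEG]
    unresolved_gene_ids: list[str]  # DEG ids absent from the annotation


def join_deg_insertions(
    degs: Sequence[DEGRecord],
    sites: Sequence[InsertionSite],
    geneset: GeneSet,
    near_kb: float = 3.0,
) -> JoinResult:
    """One record per (DEG, site) pair with the site inside or near the gene.

    DEGs whose gene_id is absent from the gene models are warned about,
    skipped, and reported in the result.
    """
    near_bp = int(round(near_kb * 1000))
    by_id = {g.gene_id: g for g in geneset.genes}
    by_chrom: dict[str, list[InsertionSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    records: list[ProximalDEG] = []
    unresolved: list[str] = []
    for deg in degs:
        gene = by_id.get(deg.gene_id)
        if gene is None:
            unresolved.append(deg.gene_id)
            continue
        for site in by_chrom.get(gene.chrom, []):
            if gene.start <= site.position <= gene.end:
                records.append(ProximalDEG(deg, site, "inside", 0))
            else:
                d = (gene.start - site.position if site.position < gene.start
                     else site.position - gene.end)
                if d <= near_bp:
                    records.append(ProximalDEG(deg, site, "near", d))
    if unresolved:
        warnings.warn(
            f"{len(unresolved)} DEG gene_id(s) not found in gene models; skipped",
            stacklevel=2,
        )
    return JoinResult(records, unresolved)


def summarize_join(
    proximal: Sequence[ProximalDEG],
    n_degs_total: int,
) -> dict:
    """Distinct proximal-DEG count, percentage of all DEGs, and breakdowns.

    Percentage is 100 * distinct count / ``n_degs_total``, rounded to two
    decimals; breakdowns count distinct DEGs by relation and by regulation
    direction.
    """
    if n_degs_total < 1:
        raise ValueError("n_degs_total must be >= 1")
    distinct = {p.deg.gene_id for p in proximal}
    by_relation = {
        rel: len({p.deg.gene_id for p in proximal if p.relation == rel})
        for rel in ("inside", "near")
    }
    by_direction = {
        d: len({p.deg.gene_id for p in proximal if p.deg.direction == d})
        for d in ("up", "down")
    }
    return {
        "n_proximal_degs": len(distinct),
        "n_degs_total": n_degs_total,
        "percent": round(100.0 * len(distinct) / n_degs_total, 2),
        "n_pairs": len(proximal),
        "by_relation": by_relation,
        "by_direction": by_direction,
    }
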