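"""End-to-end pipeline: simulate -> preprocess -> both detectors ->
reconcile -> annotate -> DEG join.

Every stage reads its inputs from, and writes its outputs to, one run
directory, so the pipeline is resumable per stage: rerunning any later
stage from the saved intermediates reproduces the end-to-end result.  A
manifest (JSON) records the full parameterization and a SHA-256 checksum of
every output file; identical configuration and seed give identical
checksums.

Defaults equal the source protocol's stated values: Phred cutoff 30,
dereplication abundance 10, presence fraction 0.01%, 500-bp window, 50-read
threshold, 3-kb near-gene distance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate as ann
from . import io as mio
from .aligncall import InsertionSite, call_sites_by_window, map_flanks
from .cluster import ReadCluster, UniqueSeq, call_genotypes, cluster_sequences, dereplicate
from .degjoin import join_deg_insertions, read_deg_table, summarize_join
from .preprocess import FlankRead, preprocess_reads
from .reconcile import (
    compare_lines,
    locate_clusters,
    overlap_percentage,
    reconcile_line,
)
from .simulate import MpingElement, SimulationConfig, simulate_dataset


@dataclass
class PipelineConfig:
    """All pipeline parameters plus the simulation conditions."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    qv_min: int = 30
    trim_len: int = 100
    anchor_mismatch: int = 1
    min_abund: int = 10
    min_identity: float = 0.90
    frac_threshold: float = 1e-4
    window: int = 500
    min_reads: int = 50
    map_mismatch: int = 0
    tol: int = 100
    near_kb: float = 3.0
    padj_max: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        self.validate()

    def validate(self) -> None:
        self.sim.validate()
        checks = [
            (self.qv_min >= 0, "qv_min must be non-negative"),
            (self.trim_len > 0, "trim_len must be positive"),
            (self.anchor_mismatch >= 0, "anchor_mismatch must be non-negative"),
            (self.min_abund >= 1, "min_abund must be >= 1"),
            (0 < self.min_identity <= 1, "min_identity must be in (0, 1]"),
            (0 < self.frac_threshold < 1, "frac_threshold must be in (0, 1)"),
            (self.window > 0, "window must be positive"),
            (self.min_reads >= 1, "min_reads must be >= 1"),
            (self.map_mismatch >= 0, "map_mismatch must be non-negative"),
            (self.tol >= 0, "tol must be non-negative"),
            (self.near_kb > 0, "near_kb must be positive"),
            (0 < self.padj_max <= 1, "padj_max must be in (0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim_data = dict(data.pop("simulate", {}))
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(sim_data) - sim_fields
        if unknown:
            raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
        for key in ("gene_length_range", "fragment_size_range", "insertion_bias",
                    "lines"):
            if key in sim_data and isinstance(sim_data[key], list):
                sim_data[key] = tuple(sim_data[key])
        own_fields = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(data) - own_fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=SimulationConfig(**sim_data), **data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


# ---------------------------------------------------------------- stages


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    ds = simulate_dataset(cfg.sim)
    mio.write_fasta(outdir / "genome.fa", ds.genome)
    mio.write_fasta(outdir / "element.fa", {"mping_synthetic": ds.element.sequence})
    mio.write_gff3(outdir / "genes.gff3", ds.genes,
                   {c: len(s) for c, s in ds.genome.items()})
    for line in cfg.sim.lines:
        mio.write_bed6(
            outdir / f"truth_{line}.bed",
            [(t.chrom, t.position, f"{t.category}", 0, t.strand)
             for t in ds.truth_for(line)],
        )
        mio.write_fastq(outdir / f"reads_{line}_R1.fastq",
                        (p[0] for p in ds.reads[line]))
        mio.write_fastq(outdir / f"reads_{line}_R2.fastq",
                        (p[1] for p in ds.reads[line]))
    if ds.deg_table is not None:
        mio.write_tsv(outdir / "deg.tsv", ds.deg_table)


def _anchor(outdir: Path) -> str:
    element = mio.read_fasta(outdir / "element.fa")
    seq = next(iter(element.values()))
    return MpingElement.from_sequence(seq).anchor


def stage_preprocess(cfg: PipelineConfig, outdir: Path) -> None:
    anchor = _anchor(outdir)
    rows = []
    for line in cfg.sim.lines:
        reads = mio.read_fastq(outdir / f"reads_{line}_R1.fastq")
        flanks, stats = preprocess_reads(
            reads, anchor, line, qv_min=cfg.qv_min, trim_len=cfg.trim_len,
            max_mismatch=cfg.anchor_mismatch,
        )
        mio.write_fastq(
            outdir / f"flanks_{line}.fastq",
            (FlankRead(f.read_id, line, f.sequence, f.qualities) for f in flanks),
        )
        rows.append({
            "line_id": line, "n_in": stats.n_in,
            "n_quality_pass": stats.n_quality_pass,
            "n_no_anchor": stats.n_no_anchor, "n_short": stats.n_short,
            "n_flanks": stats.n_flanks,
        })
    mio.write_tsv(outdir / "preprocess_summary.tsv", pd.DataFrame(rows))


def _load_flanks(cfg: PipelineConfig, outdir: Path) -> list[FlankRead]:
    flanks: list[FlankRead] = []
    for line in cfg.sim.lines:
        for r in mio.read_fastq(outdir / f"flanks_{line}.fastq"):
            flanks.append(FlankRead(r.read_id, line, r.sequence, r.qualities))
    return flanks


def stage_cluster(cfg: PipelineConfig, outdir: Path) -> None:
    flanks = _load_flanks(cfg, outdir)
    totals = {line: 0 for line in cfg.sim.lines}
    for f in flanks:
        totals[f.line_id] += 1
    uniques = dereplicate(flanks, min_abund=cfg.min_abund)
    clusters = cluster_sequences(uniques, min_identity=cfg.min_identity)
    genotypes = call_genotypes(
        clusters, {k: v for k, v in totals.items() if v > 0},
        frac_threshold=cfg.frac_threshold,
    )
    rows = []
    for cl in clusters:
        row = {"cluster_id": cl.cluster_id, "representative": cl.representative}
        for line in cfg.sim.lines:
            row[line] = cl.reads_per_line.get(line, 0)
        rows.append(row)
    mio.write_tsv(outdir / "clusters.tsv", pd.DataFrame(rows))
    genotypes.reset_index().to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
    mio.write_fasta(
        outdir / "representatives.fasta",
        {cl.cluster_id: cl.representative for cl in clusters},
    )


def stage_aligncall(cfg: PipelineConfig, outdir: Path) -> None:
    reference = mio.read_fasta(outdir / "genome.fa")
    flanks = _load_flanks(cfg, outdir)
    starts, stats = map_flanks(flanks, reference, max_mismatch=cfg.map_mismatch)
    called, sub = call_sites_by_window(starts, window=cfg.window,
                                       min_reads=cfg.min_reads)
    for line in cfg.sim.lines:
        mio.write_bed6(
            outdir / f"align_sites_{line}.bed",
            [(s.chrom, s.position, s.method, s.support, "+")
             for s in called if s.line_id == line],
        )
        mio.write_bed6(
            outdir / f"subthreshold_{line}.bed",
            [(s.chrom, s.position, s.method, s.support, "+")
             for s in sub if s.line_id == line],
        )
    mio.write_tsv(
        outdir / "mapping_summary.tsv",
        pd.DataFrame([{"n_mapped": stats.n_mapped, "n_unmapped": stats.n_unmapped,
                       "n_multi": stats.n_multi}]),
    )


def _read_sites(path, line_id: str) -> list[InsertionSite]:
    return [
        InsertionSite(chrom, pos, max(score, 1), name, line_id)
        for chrom, pos, name, score, _ in mio.read_bed6(path)
    ]


def _load_clusters(cfg: PipelineConfig, outdir: Path) -> list[ReadCluster]:
    df = pd.read_csv(outdir / "clusters.tsv", sep="\t")
    clusters = []
    for d in df.to_dict("records"):
        reads_per_line = {line: int(d[line]) for line in cfg.sim.lines
                          if line in d and int(d[line]) > 0}
        clusters.append(ReadCluster(
            cluster_id=str(d["cluster_id"]),
            representative=str(d["representative"]),
            members=[UniqueSeq(str(d["representative"]), dict(reads_per_line))],
            reads_per_line=reads_per_line,
        ))
    return clusters


def stage_reconcile(cfg: PipelineConfig, outdir: Path) -> None:
    reference = mio.read_fasta(outdir / "genome.fa")
    clusters = _load_clusters(cfg, outdir)
    genotypes = pd.read_csv(outdir / "genotypes.tsv", sep="\t").set_index("line_id")
    located = locate_clusters(clusters, reference, max_mismatch=cfg.map_mismatch)
    pos_by_id = {p.cluster_id: p for p in located.placed}
    table_rows = []
    final_sets: dict[str, list[InsertionSite]] = {}
    for line in cfg.sim.lines:
        cluster_sites = []
        for cl in clusters:
            placed = pos_by_id.get(cl.cluster_id)
            if placed is None or cl.cluster_id not in genotypes.columns:
                continue
            if int(genotypes.loc[line, cl.cluster_id]) == 1:
                cluster_sites.append(InsertionSite(
                    placed.chrom, placed.position,
                    cl.reads_per_line.get(line, 1) or 1, "cluster", line,
                ))
        align_sites = _read_sites(outdir / f"align_sites_{line}.bed", line)
        sub = _read_sites(outdir / f"subthreshold_{line}.bed", line)
        rec = reconcile_line(cluster_sites, align_sites, sub, tol=cfg.tol)
        final_sets[line] = rec.final_sites
        mio.write_bed6(
            outdir / f"final_{line}.bed",
            [(s.chrom, s.position, s.method, s.support, "+")
             for s in rec.final_sites],
        )
        c = rec.counts
        table_rows.append({
            "line_id": line, "n_cluster": c.n_cluster, "n_align": c.n_align,
            "n_common": c.n_common,
            "pct_common": overlap_percentage(c) if c.n_cluster else float("nan"),
            "n_rescued": c.n_rescued, "n_total": c.n_total,
        })
    mio.write_tsv(outdir / "table1.tsv", pd.DataFrame(table_rows))
    if len(final_sets) >= 2:
        venn = compare_lines(final_sets, tol=cfg.tol)
        rows = [
            {"lines": "+".join(sorted(k)), "n_sites": v}
            for k, v in sorted(venn.region_counts.items(),
                               key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
        mio.write_tsv(outdir / "venn.tsv", pd.DataFrame(rows))
    with open(outdir / "unplaced_clusters.txt", "w") as fh:
        for cid in located.unplaced:
            fh.write(cid + "\n")


def stage_annotate(cfg: PipelineConfig, outdir: Path) -> None:
    geneset = ann.GeneSet.from_gff3(outdir / "genes.gff3")
    annotations = []
    for line in cfg.sim.lines:
        sites = _read_sites(outdir / f"final_{line}.bed", line)
        annotations.extend(ann.classify_sites(sites, geneset, near_kb=cfg.near_kb))
    rows = [{
        "line_id": a.site.line_id, "chrom": a.site.chrom,
        "position": a.site.position, "support": a.site.support,
        "category": a.category, "subfeature": a.subfeature,
        "gene_id": a.gene_id if a.gene_id else ".",
        "distance": a.distance if a.distance is not None else ".",
    } for a in annotations]
    mio.write_tsv(outdir / "annotations.tsv", pd.DataFrame(rows))
    if annotations:
        mio.write_tsv(outdir / "table2.tsv", ann.summarize_distribution(annotations))
    baseline = ann.genome_baseline(geneset, near_kb=cfg.near_kb)
    mio.write_tsv(
        outdir / "baseline.tsv",
        pd.DataFrame([{k: round(100 * v, 1)
                       for k, v in baseline.as_dict().items()}]),
    )
    pref_rows = []
    for line in cfg.sim.lines:
        obs = {c: sum(1 for a in annotations
                      if a.site.line_id == line and a.category == c)
               for c in ann.CATEGORIES}
        if sum(obs.values()) == 0:
            continue
        t = ann.preference_test(obs, baseline)
        pref_rows.append({
            "line_id": line, "chi2": round(t.statistic, 3), "df": t.df,
            "pvalue": f"{t.pvalue:.3e}",
            **{f"resid_{c}": round(t.residuals[c], 3) for c in ann.CATEGORIES},
        })
    if pref_rows:
        mio.write_tsv(outdir / "preference.tsv", pd.DataFrame(pref_rows))


def stage_degjoin(cfg: PipelineConfig, outdir: Path) -> None:
    geneset = ann.GeneSet.from_gff3(outdir / "genes.gff3")
    deg_path = outdir / "deg.tsv"
    if not deg_path.exists():
        return
    degs, n_total = read_deg_table(deg_path, padj_max=cfg.padj_max)
    pair_rows, summary_rows = [], []
    for line in cfg.sim.lines:
        sites = _read_sites(outdir / f"final_{line}.bed", line)
        result = join_deg_insertions(degs, sites, geneset, near_kb=cfg.near_kb)
        for p in result.records:
            pair_rows.append({
                "line_id": line, "gene_id": p.deg.gene_id,
                "direction": p.deg.direction, "log2fc": p.deg.log2fc,
                "chrom": p.site.chrom, "position": p.site.position,
                "relation": p.relation, "distance": p.distance,
            })
        s = summarize_join(result.records, n_total)
        summary_rows.append({
            "line_id": line, "n_proximal_degs": s["n_proximal_degs"],
            "n_degs_total": s["n_degs_total"], "percent": s["percent"],
            "n_inside": s["by_relation"]["inside"],
            "n_near": s["by_relation"]["near"],
            "n_up": s["by_direction"]["up"], "n_down": s["by_direction"]["down"],
            "n_unresolved": len(result.unresolved_gene_ids),
        })
    mio.write_tsv(outdir / "proximal_degs.tsv", pd.DataFrame(pair_rows))
    mio.write_tsv(outdir / "degjoin_summary.tsv", pd.DataFrame(summary_rows))


STAGES = [
    ("simulate", stage_simulate),
    ("preprocess", stage_preprocess),
    ("cluster", stage_cluster),
    ("aligncall", stage_aligncall),
    ("reconcile", stage_reconcile),
    ("annotate", stage_annotate),
    ("degjoin", stage_degjoin),
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict


def run_pipeline(cfg: PipelineConfig, outdir) -> PipelineResult:
    """Run every stage in dependency order and write the run manifest."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, fn in STAGES:
        try:
            fn(cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    files = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "parameters": dataclasses.asdict(cfg),
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
    return PipelineResult(outdir, manifest)
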