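"""Synthetic data with planted truth for the whole pipeline.

Generates a toy multi-chromosome genome with non-overlapping gene models
(exons, introns, UTRs), plants 430-bp MITE copies — 15-bp terminal inverted
repeats (TIRs), 3-bp target-site duplication (TSD) — at positions drawn with
a configurable genic-context bias, and simulates the anchored-amplicon
library: read 1 of every pair begins with the element terminal sequence (the
anchor a terminus-specific nested primer would leave) and runs outward into
flanking genome; read 2 comes from the far end of a 400-600 bp fragment.
Per-copy pair counts are Poisson around the configured coverage and bases
are substituted at a configurable error rate.  A matching differential-
expression table is produced with designated up-regulated (storage-protein-
like) and down-regulated (photosynthesis-like) genes.

Everything is deterministic for a fixed seed; the truth set records, for
every planted copy, the junction position, strand, TSD and the genic
category under the same classification rules the annotation module applies.
"""

from __future__ import annotations

import zlib
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aligncall import revcomp
from .annotate import Gene, GeneSet
from .preprocess import FastqRead

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

ELEMENT_LENGTH = 430
TIR_LENGTH = 15
TSD_LENGTH = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    ``n_insertions`` is the per-line copy number; ``shared_fraction`` of
    each line's sites is common to all lines (the rest are line-specific).
    ``insertion_bias`` gives the sampling weights of the genic categories,
    defaulting to the near-gene-skewed landscape the element family shows.
    """

    n_chromosomes: int = 2
    chrom_length: int = 150_000
    n_genes: int = 16
    gene_length_range: tuple[int, int] = (4_000, 6_600)
    n_insertions: int = 30
    insertion_bias: tuple[float, float, float] = (0.15, 0.55, 0.30)  # inside/near/intergenic
    lines: tuple[str, ...] = ("C1", "HP1", "HP2")
    shared_fraction: float = 0.6
    coverage_per_site: float = 100.0
    read_length: int = 150
    fragment_size_range: tuple[int, int] = (400, 600)
    error_rate: float = 0.001
    base_quality: int = 37
    near_kb: float = 3.0
    min_site_separation: int = 800
    edge_margin: int = 700
    n_deg_up: int = 4
    n_deg_down: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if self.n_genes < 0 or self.n_insertions < 0:
            raise ValueError("counts must be non-negative")
        if abs(sum(self.insertion_bias) - 1.0) > 1e-9:
            raise ValueError("insertion_bias weights must sum to 1")
        if any(w < 0 for w in self.insertion_bias):
            raise ValueError("insertion_bias weights must be non-negative")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.coverage_per_site < 0:
            raise ValueError("coverage_per_site must be non-negative")
        lo, hi = self.fragment_size_range
        if not 0 < lo <= hi:
            raise ValueError("bad fragment_size_range")
        if self.read_length <= TIR_LENGTH:
            raise ValueError("read_length must exceed the anchor length")
        glo, ghi = self.gene_length_range
        if not 0 < glo <= ghi:
            raise ValueError("bad gene_length_range")
        if len(self.lines) != len(set(self.lines)) or not self.lines:
            raise ValueError("lines must be unique and non-empty")


@dataclass(frozen=True)
class MpingElement:
    """A 430-bp MITE with 15-bp TIRs: starts with the TIR, ends with its
    reverse complement."""

    sequence: str
    tir: str
    tsd_length: int = TSD_LENGTH

    def __post_init__(self) -> None:
        if len(self.sequence) != ELEMENT_LENGTH:
            raise ValueError(f"element must be {ELEMENT_LENGTH} bp")
        if len(self.tir) != TIR_LENGTH:
            raise ValueError(f"TIR must be {TIR_LENGTH} bp")
        if not self.sequence.startswith(self.tir):
            raise ValueError("element must start with its TIR")
        if not self.sequence.endswith(revcomp(self.tir)):
            raise ValueError("element must end with the reverse complement of its TIR")

    @property
    def anchor(self) -> str:
        """The terminal 15-mer a terminus-anchored read 1 begins with."""
        return self.sequence[-TIR_LENGTH:]

    @classmethod
    def synthetic(cls, seed: int = 0) -> "MpingElement":
        """A random element with enforced TIR structure (the real element
        sequence can be supplied instead via ``from_sequence``)."""
        rng = np.random.default_rng([seed, 1])
        tir = _random_dna(rng, TIR_LENGTH)
        core = _random_dna(rng, ELEMENT_LENGTH - 2 * TIR_LENGTH)
        return cls(tir + core + revcomp(tir), tir)

    @classmethod
    def from_sequence(cls, sequence: str) -> "MpingElement":
        sequence = sequence.upper()
        return cls(sequence, sequence[:TIR_LENGTH])


@dataclass(frozen=True)
class TruthRecord:
    """One planted insertion: junction base (1-based, immediately 5' of the
    element), strand, TSD, genic category and the lines carrying it."""

    chrom: str
    position: int
    strand: str
    tsd: str
    category: str
    lines: tuple[str, ...]


@dataclass(frozen=True)
class PlantedCopy:
    """Per-line bookkeeping: where one element copy sits in the mutated
    chromosome (0-based [start, end) of the element itself)."""

    chrom: str
    truth_position: int
    strand: str
    mut_start: int
    mut_end: int


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


# ---------------------------------------------------------------- genome


def generate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[Gene]]:
    """Random chromosomes plus non-overlapping gene models with substructure."""
    config.validate()
    if config.n_genes * config.gene_length_range[1] > (
        config.n_chromosomes * config.chrom_length
    ):
        raise ValueError("cannot place genes: total gene length exceeds genome")
    rng = np.random.default_rng([config.seed, 0])
    genome = {
        f"chr{i + 1}": _random_dna(rng, config.chrom_length)
        for i in range(config.n_chromosomes)
    }
    chroms = list(genome)
    per_chrom = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes % len(chroms)):
        per_chrom[i] += 1
    placed: list[tuple[str, int, int]] = []
    min_gap = 500
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        lengths = rng.integers(
            config.gene_length_range[0], config.gene_length_range[1] + 1, size=k
        )
        slack = config.chrom_length - int(lengths.sum()) - (k + 1) * min_gap
        if slack < 0:
            raise ValueError(f"cannot place {k} genes on {chrom}: too little room")
        gaps = rng.multinomial(slack, [1.0 / (k + 1)] * (k + 1))
        pos = 0
        for g, ln in zip(gaps, lengths):
            start = pos + int(g) + min_gap + 1  # 1-based
            placed.append((chrom, start, start + int(ln) - 1))
            pos = start + int(ln) - 1
    placed.sort()
    genes = [
        _gene_structure(rng, f"gene_{i + 1:04d}", chrom, s, e)
        for i, (chrom, s, e) in enumerate(placed)
    ]
    return genome, genes


def _gene_structure(
    rng: np.random.Generator, gene_id: str, chrom: str, start: int, end: int
) -> Gene:
    length = end - start + 1
    strand = "+" if rng.random() < 0.5 else "-"
    max_exons = max(1, min(3, (length - 60) // 210))
    k = int(rng.integers(1, max_exons + 1))
    min_block = k * 150 + (k - 1) * 60
    extra = length - min_block
    shares = rng.multinomial(extra, [1.0 / (2 * k - 1)] * (2 * k - 1))
    sizes = []
    for i in range(2 * k - 1):
        base = 150 if i % 2 == 0 else 60
        sizes.append(base + int(shares[i]))
    exons = []
    pos = start
    for i, sz in enumerate(sizes):
        if i % 2 == 0:
            exons.append((pos, pos + sz - 1))
        pos += sz
    u5 = int(rng.integers(30, 121))
    u3 = int(rng.integers(30, 121))
    first, last = exons[0], exons[-1]
    u5 = min(u5, first[1] - first[0] - 29)
    u3 = min(u3, last[1] - last[0] - 29)
    left = (start, start + u5 - 1)
    right = (end - u3 + 1, end)
    utr5, utr3 = (left, right) if strand == "+" else (right, left)
    return Gene(gene_id, chrom, start, end, strand, tuple(exons), utr5, utr3)


# ---------------------------------------------------------------- planting


def _category_labels(
    geneset: GeneSet, chrom: str, near_kb: float
) -> np.ndarray:
    """Per-base category codes for one chromosome (index 1..L used).

    0 = intergenic, 1 = near, 2 = inside — identical boundary conventions
    (span-inclusive, near inclusive at exactly near_kb * 1000) to
    ``annotate.classify_sites``.
    """
    near_bp = int(round(near_kb * 1000))
    length = geneset.chrom_lengths[chrom]
    lab = np.zeros(length + 1, dtype=np.int8)
    for g in geneset.genes_on(chrom):
        lab[max(1, g.start - near_bp): g.start] = np.maximum(
            lab[max(1, g.start - near_bp): g.start], 1
        )
        lab[g.end + 1: min(length, g.end + near_bp) + 1] = np.maximum(
            lab[g.end + 1: min(length, g.end + near_bp) + 1], 1
        )
    for g in geneset.genes_on(chrom):
        lab[g.start: g.end + 1] = 2
    return lab


_CAT_CODE = {"inside": 2, "near": 1, "intergenic": 0}
_CODE_CAT = {v: k for k, v in _CAT_CODE.items()}


def plant_insertions(
    genome: Mapping[str, str],
    genes: Sequence[Gene],
    element: MpingElement,
    config: SimulationConfig,
) -> tuple[dict[str, dict[str, str]], list[TruthRecord], dict[str, list[PlantedCopy]]]:
    """Plant element copies (with TSD) per line; return mutated genomes + truth.

    A global pool of distinct sites is drawn — category by ``insertion_bias``,
    position uniform over that category's eligible bases, all sites at least
    ``min_site_separation`` apart and away from chromosome ends — and
    assigned to lines: the first ``shared_fraction`` of each line's quota is
    common to every line, the remainder line-specific.  Each planted copy
    duplicates the 3-bp target site, so every mutated chromosome grows by
    433 bp per copy.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    geneset = GeneSet(genes, chrom_lengths)
    n_shared = int(round(config.shared_fraction * config.n_insertions))
    n_specific = config.n_insertions - n_shared
    n_distinct = n_shared + n_specific * len(config.lines)

    # eligible 1-based positions per category, pooled over chromosomes
    margin = max(config.edge_margin, TSD_LENGTH + 1)
    eligible: dict[int, list[tuple[str, np.ndarray]]] = {0: [], 1: [], 2: []}
    for chrom in genome:
        lab = _category_labels(geneset, chrom, config.near_kb)
        lo, hi = margin, chrom_lengths[chrom] - margin
        if hi < lo:
            continue
        window = lab[lo: hi + 1]
        for code in (0, 1, 2):
            idx = np.flatnonzero(window == code) + lo
            if len(idx):
                eligible[code].append((chrom, idx))

    chosen: dict[str, list[int]] = {c: [] for c in genome}
    records: list[tuple[str, int, str, str, str]] = []
    bias_codes = np.array([2, 1, 0])  # weights are (inside, near, intergenic)
    categories = bias_codes[rng.choice(3, size=n_distinct,
                                       p=list(config.insertion_bias))]
    for code in categories:
        pools = eligible[int(code)]
        if not pools:
            raise ValueError(
                f"no eligible loci for category {_CODE_CAT[int(code)]!r}"
            )
        sizes = np.array([len(idx) for _, idx in pools])
        placed = False
        for _ in range(2000):
            pi = rng.choice(len(pools), p=sizes / sizes.sum())
            chrom, idx = pools[pi]
            pos = int(idx[rng.integers(len(idx))])
            if all(abs(pos - q) >= config.min_site_separation
                   for q in chosen[chrom]):
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place an insertion of category "
                f"{_CODE_CAT[int(code)]!r} at the requested separation"
            )
        chosen[chrom].append(pos)
        strand = "+" if rng.random() < 0.5 else "-"
        tsd = genome[chrom][pos - TSD_LENGTH: pos]
        records.append((chrom, pos, strand, tsd, _CODE_CAT[int(code)]))

    membership: list[tuple[str, ...]] = [tuple(config.lines)] * n_shared
    for line in config.lines:
        membership += [(line,)] * n_specific
    truth = [
        TruthRecord(chrom, pos, strand, tsd, cat, lines)
        for (chrom, pos, strand, tsd, cat), lines in zip(records, membership)
    ]
    truth.sort(key=lambda t: (t.chrom, t.position))

    mutated: dict[str, dict[str, str]] = {}
    placements: dict[str, list[PlantedCopy]] = {}
    for line in config.lines:
        mine = [t for t in truth if line in t.lines]
        mutated[line], placements[line] = _apply_insertions(genome, mine, element)
    return mutated, truth, placements


def _apply_insertions(
    genome: Mapping[str, str],
    truth: Sequence[TruthRecord],
    element: MpingElement,
) -> tuple[dict[str, str], list[PlantedCopy]]:
    mutated: dict[str, str] = {}
    copies: list[PlantedCopy] = []
    growth = ELEMENT_LENGTH + TSD_LENGTH
    for chrom, seq in genome.items():
        mine = sorted((t for t in truth if t.chrom == chrom),
                      key=lambda t: t.position)
        parts: list[str] = []
        prev = 0
        for k, t in enumerate(mine):
            ins = element.sequence if t.strand == "+" else revcomp(element.sequence)
            parts.append(seq[prev: t.position])
            parts.append(ins)
            prev = t.position - TSD_LENGTH  # re-emit the 3-bp target site
            mut_start = t.position + growth * k
            copies.append(
                PlantedCopy(chrom, t.position, t.strand,
                            mut_start, mut_start + ELEMENT_LENGTH)
            )
        parts.append(seq[prev:])
        mutated[chrom] = "".join(parts)
    return mutated, copies


def excise_insertions(
    mutated: Mapping[str, str],
    copies: Sequence[PlantedCopy],
) -> dict[str, str]:
    """Remove every planted element plus its duplicated target site;
    inverse of ``_apply_insertions`` (used to verify round-tripping)."""
    out: dict[str, str] = {}
    for chrom, seq in mutated.items():
        cuts = sorted(
            (c.mut_start, c.mut_end + TSD_LENGTH)
            for c in copies if c.chrom == chrom
        )
        parts: list[str] = []
        prev = 0
        for s, e in cuts:
            parts.append(seq[prev:s])
            prev = e
        parts.append(seq[prev:])
        out[chrom] = "".join(parts)
    return out


# ---------------------------------------------------------------- library


def _add_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_library(
    mutated_genome: Mapping[str, str],
    copies: Sequence[PlantedCopy],
    element: MpingElement,
    config: SimulationConfig,
    line_id: str,
) -> list[tuple[FastqRead, FastqRead]]:
    """Anchored-amplicon read pairs for one line.

    Read 1 starts with the element terminal 15-mer and reads outward into
    the flank; the side follows the element orientation (the nested primer
    targets one terminus).  Read 2 sits at the far end of a fragment drawn
    uniformly from ``fragment_size_range``.  Pair counts per planted copy
    are Poisson(``coverage_per_site``); substitutions occur at
    ``error_rate`` per base; qualities are constant ``base_quality``.
    """
    config.validate()
    rng = np.random.default_rng(
        [config.seed, 3, zlib.crc32(line_id.encode()) % (2**31)]
    )
    rl = config.read_length
    quals = (config.base_quality,) * rl
    pairs: list[tuple[FastqRead, FastqRead]] = []
    for k, copy in enumerate(sorted(copies, key=lambda c: (c.chrom, c.mut_start))):
        m = mutated_genome[copy.chrom]
        n_pairs = int(rng.poisson(config.coverage_per_site))
        for j in range(n_pairs):
            f = int(rng.integers(config.fragment_size_range[0],
                                 config.fragment_size_range[1] + 1))
            if copy.strand == "+":  # primer at right terminus, read rightward
                a = copy.mut_end - TIR_LENGTH
                r1 = m[a: a + rl]
                frag = m[a: a + f]
                r2 = revcomp(frag[-rl:])
            else:  # element inverted: primer terminus faces left, read leftward
                b = copy.mut_start + TIR_LENGTH
                r1 = revcomp(m[b - rl: b])
                r2 = m[b - f: b - f + rl]
            rid = f"{line_id}.s{k:03d}.p{j:04d}"
            pairs.append(
                (
                    FastqRead(rid + "/1", _add_errors(r1, rng, config.error_rate), quals),
                    FastqRead(rid + "/2", _add_errors(r2, rng, config.error_rate), quals),
                )
            )
    return pairs


# ---------------------------------------------------------------- DEG table


def simulate_deg_table(
    genes: Sequence[Gene],
    config: SimulationConfig,
) -> pd.DataFrame:
    """A differential-expression results table over the toy gene set.

    ``n_deg_up`` genes play the storage-protein role (up-regulated in the HP
    lines), ``n_deg_down`` the photosynthesis role (down-regulated); all
    other genes get null effects with non-significant adjusted p-values.
    Columns: gene_id, log2fc, padj, direction (up / down / ns).
    """
    if not genes:
        raise ValueError("gene list is empty")
    if config.n_deg_up + config.n_deg_down > len(genes):
        raise ValueError("more designated DEGs than genes")
    rng = np.random.default_rng([config.seed, 4])
    ids = [g.gene_id for g in genes]
    order = rng.permutation(len(ids))
    up = {ids[i] for i in order[: config.n_deg_up]}
    down = {ids[i] for i in order[config.n_deg_up: config.n_deg_up + config.n_deg_down]}
    rows = []
    for gid in ids:
        if gid in up:
            rows.append((gid, round(float(rng.uniform(1.5, 4.0)), 3),
                         float(10 ** rng.uniform(-8, -3)), "up"))
        elif gid in down:
            rows.append((gid, round(-float(rng.uniform(1.5, 4.0)), 3),
                         float(10 ** rng.uniform(-8, -3)), "down"))
        else:
            rows.append((gid, round(float(rng.normal(0.0, 0.3)), 3),
                         float(rng.uniform(0.2, 1.0)), "ns"))
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj", "direction"])
    df["padj"] = df["padj"].map(lambda p: float(f"{p:.3e}"))
    return df


# ---------------------------------------------------------------- bundle


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    element: MpingElement
    genome: dict[str, str]
    genes: list[Gene]
    geneset: GeneSet = field(repr=False)
    mutated: dict[str, dict[str, str]] = field(repr=False)
    truth: list[TruthRecord] = field(default_factory=list)
    placements: dict[str, list[PlantedCopy]] = field(default_factory=dict)
    reads: dict[str, list[tuple[FastqRead, FastqRead]]] = field(
        default_factory=dict, repr=False
    )
    deg_table: pd.DataFrame | None = None

    @property
    def anchor(self) -> str:
        return self.element.anchor

    def truth_for(self, line_id: str) -> list[TruthRecord]:
        return [t for t in self.truth if line_id in t.lines]


def simulate_dataset(
    config: SimulationConfig,
    element: MpingElement | None = None,
) -> SimulatedDataset:
    """Run every generator stage and return the full bundle."""
    config.validate()
    if element is None:
        element = MpingElement.synthetic(config.seed)
    genome, genes = generate_genome(config)
    geneset = GeneSet(genes, {c: len(s) for c, s in genome.items()})
    mutated, truth, placements = plant_insertions(genome, genes, element, config)
    reads = {
        line: simulate_library(mutated[line], placements[line], element, config, line)
        for line in config.lines
    }
    deg = simulate_deg_table(genes, config) if genes else None
    return SimulatedDataset(
        config=config, element=element, genome=genome, genes=genes,
        geneset=geneset, mutated=mutated, truth=truth,
        placements=placements, reads=reads, deg_table=deg,
    )
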