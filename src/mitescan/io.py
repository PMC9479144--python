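"""Format readers and writers shared by all pipeline stages.

FASTA and FASTQ go through Biopython, GFF3 through gffutils; BED6 output is
0-based half-open, TSVs are UTF-8 tab-delimited with a header row.
Positions everywhere else in the package are 1-based inclusive.
"""

from __future__ import annotations

import gzip
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import Gene
from .preprocess import FastqRead


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA


def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------- FASTQ


def read_fastq(path) -> list[FastqRead]:
    """Phred+33 FASTQ; a malformed record is a hard error naming the spot."""
    reads: list[FastqRead] = []
    last_good = "<start of file>"
    try:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                reads.append(
                    FastqRead(
                        rec.id,
                        str(rec.seq),
                        tuple(rec.letter_annotations["phred_quality"]),
                    )
                )
                last_good = rec.id
    except ValueError as exc:
        raise ValueError(
            f"malformed FASTQ record in {path} after read {last_good!r}: {exc}"
        ) from exc
    return reads


def write_fastq(path, reads: Iterable[FastqRead]) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------- GFF3


def write_gff3(path, genes: Sequence[Gene], chrom_lengths: Mapping[str, int]) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for chrom in chrom_lengths:
            fh.write(f"##sequence-region {chrom} 1 {chrom_lengths[chrom]}\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            def row(ftype, s, e, attrs):
                fh.write(
                    f"{g.chrom}\tmitescan\t{ftype}\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
            row("gene", g.start, g.end, f"ID={g.gene_id}")
            mrna = f"{g.gene_id}.t1"
            row("mRNA", g.start, g.end, f"ID={mrna};Parent={g.gene_id}")
            for i, (s, e) in enumerate(g.exons, 1):
                row("exon", s, e, f"ID={mrna}.exon{i};Parent={mrna}")
            if g.utr5:
                row("five_prime_UTR", g.utr5[0], g.utr5[1],
                    f"ID={mrna}.utr5;Parent={mrna}")
            if g.utr3:
                row("three_prime_UTR", g.utr3[0], g.utr3[1],
                    f"ID={mrna}.utr3;Parent={mrna}")


def read_genes_gff3(path) -> tuple[list[Gene], dict[str, int]]:
    """Load gene models (gene spans + exon/UTR substructure) from GFF3.

    Chromosome lengths come from ##sequence-region directives; if absent,
    each chromosome's length defaults to the maximum feature end seen.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique", force=True,
    )
    lengths: dict[str, int] = {}
    for d in db.directives:
        parts = d.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            lengths[parts[1]] = int(parts[3])
    genes: list[Gene] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = tuple(sorted(
            (c.start, c.end)
            for c in db.children(g, featuretype="exon", level=None)
        ))
        utrs5 = [(c.start, c.end)
                 for c in db.children(g, featuretype="five_prime_UTR", level=None)]
        utrs3 = [(c.start, c.end)
                 for c in db.children(g, featuretype="three_prime_UTR", level=None)]
        genes.append(
            Gene(
                gene_id=g.id, chrom=g.seqid, start=g.start, end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
                exons=exons,
                utr5=utrs5[0] if utrs5 else None,
                utr3=utrs3[0] if utrs3 else None,
            )
        )
        lengths.setdefault(g.seqid, 0)
        lengths[g.seqid] = max(lengths[g.seqid], g.end)
    return genes, lengths


# ---------------------------------------------------------------- BED


def write_bed6(path, rows: Iterable[tuple[str, int, str, int, str]]) -> None:
    """Write (chrom, 1-based position, name, score, strand) rows as BED6
    single-base intervals (0-based half-open)."""
    with _open_text(path, "wt") as fh:
        for chrom, pos, name, score, strand in rows:
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{name}\t{score}\t{strand}\n")


def read_bed6(path) -> list[tuple[str, int, str, int, str]]:
    """Read single-base BED6 back to (chrom, 1-based position, name, score, strand)."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]) + 1, f[3], int(float(f[4])), f[5]))
    return out


# ---------------------------------------------------------------- TSV


def write_tsv(path, df) -> None:
    df.to_csv(path, sep="\t", index=False)
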