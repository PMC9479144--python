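"""Genic-context classification, baseline occupancy and preference testing."""

import numpy as np
import pytest

from mitescan.aligncall import InsertionSite
from mitescan.annotate import (
    BaselineProportions,
    Gene,
    GeneSet,
    SiteAnnotation,
    classify_sites,
    genome_baseline,
    preference_test,
    summarize_distribution,
)


def _site(pos, chrom="chr1", line="L1"):
    return InsertionSite(chrom, pos, 1, "align", line)


@pytest.fixture()
def geneset():
    # gene with exons 10_000-10_499 and 11_000-11_999, intron between;
    # UTRs at the span edges; second gene on the minus strand
    g1 = Gene("gA", "chr1", 10_000, 11_999, "+",
              exons=((10_000, 10_499), (11_000, 11_999)),
              utr5=(10_000, 10_099), utr3=(11_900, 11_999))
    g2 = Gene("gB", "chr1", 50_000, 51_999, "-",
              exons=((50_000, 51_999),),
              utr5=(51_900, 51_999), utr3=(50_000, 50_099))
    return GeneSet([g1, g2], {"chr1": 100_000, "chrEmpty": 10_000})


class TestClassifySites:
    @pytest.mark.parametrize(
        "pos,category,subfeature,gene_id",
        [
            (10_700, "inside", "intron", "gA"),  # between the exons
            (10_050, "inside", "utr5", "gA"),
            (11_950, "inside", "utr3", "gA"),
            (10_200, "inside", "exon", "gA"),
            (7_000, "near", "upstream", "gA"),  # 3000 upstream, inclusive
            (6_999, "intergenic", "none", None),  # 3001 away
            (53_000, "near", "upstream", "gB"),  # minus strand: right side is upstream
            (49_000, "near", "downstream", "gB"),
            (30_000, "intergenic", "none", None),
        ],
    )
    def test_categories_and_subfeatures(self, geneset, pos, category,
                                        subfeature, gene_id):
        (a,) = classify_sites([_site(pos)], geneset)
        assert (a.category, a.subfeature, a.gene_id) == \
            (category, subfeature, gene_id)

    def test_boundary_is_inclusive_at_3kb(self, geneset):
        (a,) = classify_sites([_site(10_000 - 3_000)], geneset)
        assert a.category == "near" and a.distance == -3_000

    def test_unknown_chromosome_is_error(self, geneset):
        with pytest.raises(ValueError, match="annotation space"):
            classify_sites([_site(5, chrom="chrX")], geneset)

    def test_geneless_chromosome_is_intergenic(self, geneset):
        (a,) = classify_sites([_site(5_000, chrom="chrEmpty")], geneset)
        assert a.category == "intergenic" and a.distance is None

    def test_invariant_to_gene_record_order(self):
        genes = [
            Gene(f"g{i}", "chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 999)
            for i in range(5)
        ]
        sites = [_site(p) for p in (500, 10_500, 22_000, 35_500, 99_000)]
        fwd = classify_sites(sites, GeneSet(genes, {"chr1": 100_000}))
        rev = classify_sites(sites, GeneSet(genes[::-1], {"chr1": 100_000}))
        assert fwd == rev


class TestSummarizeDistribution:
    def _anns(self, counts, line="L1"):
        out = []
        pos = 1
        for cat, n in counts.items():
            for _ in range(n):
                out.append(SiteAnnotation(_site(pos, line=line), cat, "none",
                                          None, None))
                pos += 1
        return out

    def test_counts_partition_total(self):
        df = summarize_distribution(
            self._anns({"inside": 5, "near": 7, "intergenic": 3})
        )
        row = df.iloc[0]
        assert row.n_inside + row.n_near + row.n_intergenic == row.total == 15

    def test_single_category_is_100_percent(self):
        df = summarize_distribution(self._anns({"inside": 9}))
        row = df.iloc[0]
        assert (row.pct_inside, row.pct_near, row.pct_intergenic) == \
            (100.0, 0.0, 0.0)


class TestGenomeBaseline:
    def test_hand_computed_single_gene(self):
        gs = GeneSet([Gene("g", "chr1", 49_501, 50_500)], {"chr1": 100_000})
        b = genome_baseline(gs, near_kb=3)
        assert b.inside == pytest.approx(0.01)
        assert b.near == pytest.approx(0.06)
        assert b.intergenic == pytest.approx(0.93)

    def test_no_genes(self):
        b = genome_baseline(GeneSet([], {"chr1": 50_000}))
        assert (b.inside, b.near, b.intergenic) == (0.0, 0.0, 1.0)

    def test_overlapping_flanks_not_double_counted(self):
        # two genes 2 kb apart: their 3-kb flanks overlap between them
        gs = GeneSet(
            [Gene("g1", "chr1", 10_000, 10_999),
             Gene("g2", "chr1", 13_000, 13_999)],
            {"chr1": 100_000},
        )
        b = genome_baseline(gs, near_kb=3)
        oracle = _per_base_oracle(gs, 3_000)
        assert b.inside == pytest.approx(oracle[0])
        assert b.near == pytest.approx(oracle[1])
        assert b.intergenic == pytest.approx(oracle[2])

    def test_fractions_sum_to_one(self, geneset):
        b = genome_baseline(geneset)
        assert b.inside + b.near + b.intergenic == pytest.approx(1.0)


def _per_base_oracle(geneset: GeneSet, near_bp: int):
    """Label every base of every chromosome independently."""
    n_inside = n_near = n_total = 0
    for chrom, length in geneset.chrom_lengths.items():
        lab = np.zeros(length + 1, dtype=np.int8)
        for g in geneset.genes_on(chrom):
            lo = max(1, g.start - near_bp)
            hi = min(length, g.end + near_bp)
            lab[lo: hi + 1] = np.maximum(lab[lo: hi + 1], 1)
        for g in geneset.genes_on(chrom):
            lab[g.start: g.end + 1] = 2
        n_inside += int((lab[1:] == 2).sum())
        n_near += int((lab[1:] == 1).sum())
        n_total += length
    return (n_inside / n_total, n_near / n_total,
            (n_total - n_inside - n_near) / n_total)


class TestPreferenceTest:
    BASE = BaselineProportions(0.25, 0.35, 0.40)

    def test_proportional_observation_is_null(self):
        t = preference_test({"inside": 25, "near": 35, "intergenic": 40},
                            self.BASE)
        assert t.statistic == pytest.approx(0.0)
        assert t.pvalue == pytest.approx(1.0)

    def test_concentrated_observation_statistic_2n(self):
        uniform = BaselineProportions(1 / 3, 1 / 3, 1 / 3)
        n = 90
        t = preference_test({"inside": 0, "near": n, "intergenic": 0}, uniform)
        assert t.statistic == pytest.approx(2 * n)
        assert t.df == 2
        assert t.residuals["near"] > 0 > t.residuals["inside"]

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            preference_test({"inside": 0, "near": 0, "intergenic": 0}, self.BASE)

    def test_null_rejection_rate_calibrated(self):
        """Sites drawn from the baseline itself: p-values uniform, rejection
        rate at alpha=0.05 close to 0.05."""
        rng = np.random.default_rng(99)
        fracs = [self.BASE.inside, self.BASE.near, self.BASE.intergenic]
        reject = 0
        reps = 400
        for _ in range(reps):
            counts = rng.multinomial(500, fracs)
            t = preference_test(
                dict(zip(("inside", "near", "intergenic"), counts)), self.BASE
            )
            reject += t.pvalue < 0.05
        assert 0.02 <= reject / reps <= 0.09


class TestGff3Roundtrip:
    def test_geneset_roundtrips_through_gff3(self, tmp_path, small_dataset):
        from mitescan import io as mio

        path = tmp_path / "genes.gff3"
        lengths = {c: len(s) for c, s in small_dataset.genome.items()}
        mio.write_gff3(path, small_dataset.genes, lengths)
        gs = GeneSet.from_gff3(path)
        assert gs.chrom_lengths == lengths
        assert len(gs.genes) == len(small_dataset.genes)
        for got, exp in zip(gs.genes, small_dataset.genes):
            assert (got.gene_id, got.chrom, got.start, got.end, got.strand,
                    got.exons, got.utr5, got.utr3) == \
                (exp.gene_id, exp.chrom, exp.start, exp.end, exp.strand,
                 exp.exons, exp.utr5, exp.utr3)
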