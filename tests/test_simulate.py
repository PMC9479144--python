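"""Generator contracts: genome/gene structure, TSD mechanics, anchored reads,
planted-truth consistency with the annotation rules."""

import dataclasses

import pytest

from mitescan import io as mio
from mitescan.aligncall import InsertionSite, revcomp
from mitescan.annotate import GeneSet, classify_sites
from mitescan.simulate import (
    ELEMENT_LENGTH,
    TIR_LENGTH,
    TSD_LENGTH,
    MpingElement,
    SimulationConfig,
    excise_insertions,
    generate_genome,
    plant_insertions,
    simulate_dataset,
    simulate_deg_table,
    simulate_library,
)


def _cfg(**kw) -> SimulationConfig:
    base = dict(n_chromosomes=2, chrom_length=100_000, n_genes=20,
                gene_length_range=(1_000, 3_000), n_deg_up=4, n_deg_down=6,
                seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenerateGenome:
    def test_counts_forced_by_config(self, tmp_path):
        genome, genes = generate_genome(_cfg())
        assert len(genome) == 2
        assert all(len(s) == 100_000 for s in genome.values())
        assert len(genes) == 20
        mio.write_fasta(tmp_path / "g.fa", genome)
        assert len(mio.read_fasta(tmp_path / "g.fa")) == 2

    def test_same_seed_byte_identical(self, tmp_path):
        out = []
        for name in ("a", "b"):
            genome, genes = generate_genome(_cfg())
            mio.write_fasta(tmp_path / f"{name}.fa", genome)
            mio.write_gff3(tmp_path / f"{name}.gff3", genes,
                           {c: len(s) for c, s in genome.items()})
            out.append(((tmp_path / f"{name}.fa").read_bytes(),
                        (tmp_path / f"{name}.gff3").read_bytes()))
        assert out[0] == out[1]

    def test_zero_genes_gives_header_only_gff(self, tmp_path):
        genome, genes = generate_genome(_cfg(n_genes=0))
        assert genes == []
        mio.write_gff3(tmp_path / "g.gff3", genes,
                       {c: len(s) for c, s in genome.items()})
        lines = (tmp_path / "g.gff3").read_text().splitlines()
        assert all(ln.startswith("#") for ln in lines)

    def test_gene_structure_well_formed(self):
        genome, genes = generate_genome(_cfg())
        prev_end = {}
        for g in genes:
            assert 1 <= g.start <= g.end <= len(genome[g.chrom])
            assert len(g.exons) >= 1
            assert g.utr5 is not None and g.utr3 is not None
            assert g.start > prev_end.get(g.chrom, 0), "genes overlap"
            prev_end[g.chrom] = g.end

    def test_impossible_placement_rejected(self):
        with pytest.raises(ValueError, match="cannot place"):
            generate_genome(_cfg(n_chromosomes=1, chrom_length=10_000,
                                 n_genes=10, gene_length_range=(2_000, 2_000)))


class TestElement:
    def test_tir_structure(self):
        el = MpingElement.synthetic(3)
        assert len(el.sequence) == ELEMENT_LENGTH
        assert el.sequence.startswith(el.tir)
        assert el.sequence.endswith(revcomp(el.tir))
        assert el.anchor == el.sequence[-TIR_LENGTH:]

    def test_malformed_element_rejected(self):
        with pytest.raises(ValueError):
            MpingElement("A" * ELEMENT_LENGTH, "C" * TIR_LENGTH)


class TestPlantInsertions:
    def test_mutated_length_grows_by_433_per_copy(self):
        cfg = _cfg(n_insertions=1, lines=("L1",), shared_fraction=1.0)
        genome, genes = generate_genome(cfg)
        el = MpingElement.synthetic(cfg.seed)
        mutated, truth, placements = plant_insertions(genome, genes, el, cfg)
        assert len(truth) == 1
        t = truth[0]
        grown = {c for c, s in mutated["L1"].items()
                 if len(s) != len(genome[c])}
        assert grown == {t.chrom}
        assert len(mutated["L1"][t.chrom]) == len(genome[t.chrom]) + 433
        assert len(t.tsd) == TSD_LENGTH

    def test_zero_insertions_identity(self):
        cfg = _cfg(n_insertions=0)
        genome, genes = generate_genome(cfg)
        el = MpingElement.synthetic(cfg.seed)
        mutated, truth, _ = plant_insertions(genome, genes, el, cfg)
        assert truth == []
        for line in cfg.lines:
            assert mutated[line] == genome

    def test_excision_restores_original(self, small_dataset):
        for line in small_dataset.config.lines:
            restored = excise_insertions(
                small_dataset.mutated[line], small_dataset.placements[line]
            )
            assert restored == small_dataset.genome

    def test_truth_categories_match_classifier(self):
        cfg = _cfg(n_insertions=50, lines=("L1",), shared_fraction=1.0,
                   insertion_bias=(0.2, 0.5, 0.3), seed=5)
        genome, genes = generate_genome(cfg)
        el = MpingElement.synthetic(cfg.seed)
        _, truth, _ = plant_insertions(genome, genes, el, cfg)
        geneset = GeneSet(genes, {c: len(s) for c, s in genome.items()})
        sites = [InsertionSite(t.chrom, t.position, 1, "align", "L1")
                 for t in truth]
        anns = classify_sites(sites, geneset, near_kb=cfg.near_kb)
        assert [a.category for a in anns] == [t.category for t in truth]

    def test_impossible_category_rejected(self):
        cfg = _cfg(n_genes=0, insertion_bias=(1.0, 0.0, 0.0), n_insertions=1)
        genome, genes = generate_genome(cfg)
        el = MpingElement.synthetic(cfg.seed)
        with pytest.raises(ValueError, match="no eligible loci"):
            plant_insertions(genome, genes, el, cfg)


class TestSimulateLibrary:
    def test_anchor_prefix_shared_by_all_read1(self, small_dataset):
        anchor = small_dataset.anchor
        for line, pairs in small_dataset.reads.items():
            assert pairs, f"no reads for {line}"
            for r1, _ in pairs:
                assert r1.sequence.startswith(anchor)

    def test_zero_coverage_empty_library(self, small_config):
        cfg = dataclasses.replace(small_config, coverage_per_site=0.0)
        ds = simulate_dataset(cfg)
        assert all(len(p) == 0 for p in ds.reads.values())

    def test_flanks_recover_truth_junctions_exactly(self, small_dataset):
        """Brute-force exact search of every error-free read-1 flank against
        the original genome must land adjacent to a planted junction."""
        anchor = small_dataset.anchor
        truth_pos = {(t.chrom, t.position) for t in small_dataset.truth}
        for line, pairs in small_dataset.reads.items():
            for r1, _ in pairs:
                flank = r1.sequence[len(anchor):]
                hit = None
                for chrom, seq in small_dataset.genome.items():
                    i = seq.find(flank)
                    if i != -1:
                        hit = (chrom, i + TSD_LENGTH)  # right flank starts at TSD copy
                        break
                    i = seq.find(revcomp(flank))
                    if i != -1:
                        hit = (chrom, i + len(flank))
                        break
                assert hit in truth_pos, f"flank of {r1.read_id} off-junction"

    def test_pair_count_near_poisson_mean(self, small_dataset):
        cfg = small_dataset.config
        for line in cfg.lines:
            n_sites = len(small_dataset.truth_for(line))
            n_pairs = len(small_dataset.reads[line])
            mean = n_sites * cfg.coverage_per_site
            assert abs(n_pairs - mean) < 5 * (mean ** 0.5)


class TestDegTable:
    def test_designated_effects_forced(self):
        cfg = _cfg(n_genes=10, n_deg_up=2, n_deg_down=3)
        _, genes = generate_genome(cfg)
        df = simulate_deg_table(genes, cfg)
        sig = df[df.padj <= 0.05]
        assert (sig.direction == "up").sum() == 2
        assert (sig.direction == "down").sum() == 3
        assert ((df.log2fc > 0) == (df.direction == "up")).loc[
            df.direction.isin(["up", "down"])].all()

    def test_zero_designated_zero_flagged(self):
        cfg = _cfg(n_genes=10, n_deg_up=0, n_deg_down=0)
        _, genes = generate_genome(cfg)
        df = simulate_deg_table(genes, cfg)
        assert (df.padj <= 0.05).sum() == 0

    def test_seeded_rerun_identical(self):
        cfg = _cfg(n_genes=10)
        _, genes = generate_genome(cfg)
        assert simulate_deg_table(genes, cfg).equals(simulate_deg_table(genes, cfg))
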