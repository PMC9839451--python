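"""Determinism, planted truth and distributional shape of the simulator."""
import numpy as np
import pytest

from spurcatch.annotation_io import gene_body, read_bedgraph, read_gtf
from spurcatch.ctss import intragenic_sense_signal
from spurcatch.exon_ratio import exon_ratio_statistic
from spurcatch.annotation_io import PipelineParams
from spurcatch.synthetic_data import (
    SimConfig,
    TruthTable,
    _negbin,
    simulate_cage,
    simulate_chip,
    simulate_genome,
    simulate_rnaseq_counts,
    write_dataset,
)


class TestGenome:
    def test_fixed_seed_is_byte_identical(self):
        cfg = SimConfig(n_genes=60, seed=17)
        a, b = simulate_genome(cfg), simulate_genome(cfg)
        assert a.sequences == b.sequences
        assert a.genes == b.genes
        assert a.truth == b.truth

    def test_zero_spurious_fraction(self):
        sim = simulate_genome(SimConfig(n_genes=60, fraction_spurious=0.0))
        assert sim.truth.spurious_genes == set()
        assert all(not t.cryptic_positions for t in sim.truth.genes.values())

    def test_spurious_count_is_rounded_fraction(self):
        sim = simulate_genome(SimConfig(n_genes=100, fraction_spurious=0.10))
        assert len(sim.truth.spurious_genes) == 10

    def test_cryptic_sites_inside_sense_body(self, small_sim):
        by_id = {g.gene_id: g for g in small_sim.genes}
        n_sites = 0
        for gid, truth in small_sim.truth.genes.items():
            if not truth.is_spurious:
                assert truth.cryptic_positions == ()
                continue
            body = gene_body(by_id[gid], "exon2_to_tes")
            for p in truth.cryptic_positions:
                n_sites += 1
                assert body.start < p < body.end - 1
        assert n_sites >= len(small_sim.truth.spurious_genes)

    def test_motif_planted_on_sense_strand(self, small_config, small_sim):
        from Bio.Seq import Seq
        motif = small_config.motif_consensus
        by_id = {g.gene_id: g for g in small_sim.genes}
        for gid, truth in small_sim.truth.genes.items():
            gene = by_id[gid]
            seq = small_sim.sequences[gene.chrom]
            for p in truth.cryptic_positions:
                if gene.strand == "+":
                    assert seq[p:p + len(motif)] == motif
                else:
                    genomic = seq[p - len(motif) + 1:p + 1]
                    assert str(Seq(genomic).reverse_complement()) == motif

    def test_background_cpg_frequency_depleted(self, small_sim):
        seq = small_sim.sequences[small_sim.genes[0].chrom]
        freq = seq.count("CG") / (len(seq) - 1)
        assert freq == pytest.approx(0.01, abs=0.003)

    def test_fixed_chrom_budget_can_overflow(self):
        with pytest.raises(ValueError, match="budget"):
            simulate_genome(SimConfig(n_genes=60, chrom_len=10_000))


class TestRnaseqCounts:
    def test_null_effect_leaves_ratio_difference_near_zero(self):
        cfg = SimConfig(n_genes=200, spurious_effect=1.0, seed=5)
        sim = simulate_genome(cfg)
        matrix = simulate_rnaseq_counts(cfg, sim)
        params = PipelineParams()
        deltas = []
        for gene_id, sub in matrix.counts.groupby("gene_id"):
            sub = sub.sort_values("exon_index")
            lens = sub["exon_len"].to_numpy()
            stats = {}
            for sample in ("Ctrl_1", "KO_1"):
                total = matrix.total_mapped(sample)
                stats[sample] = exon_ratio_statistic(
                    sub[sample].to_numpy(), lens, total, params)
            deltas.append(stats["KO_1"] - stats["Ctrl_1"])
        assert abs(np.mean(deltas)) < 0.2

    def test_effect_four_shifts_ratio_by_two(self):
        cfg = SimConfig(n_genes=400, fraction_spurious=0.5, seed=8)
        sim = simulate_genome(cfg)
        matrix = simulate_rnaseq_counts(cfg, sim)
        params = PipelineParams()
        deltas = []
        for gene_id, sub in matrix.counts.groupby("gene_id"):
            if not sim.truth.genes[gene_id].is_spurious:
                continue
            sub = sub.sort_values("exon_index")
            lens = sub["exon_len"].to_numpy()
            ko = exon_ratio_statistic(sub["KO_1"].to_numpy(), lens,
                                      matrix.total_mapped("KO_1"), params)
            ctrl = exon_ratio_statistic(sub["Ctrl_1"].to_numpy(), lens,
                                        matrix.total_mapped("Ctrl_1"), params)
            deltas.append(ko - ctrl)
        # log2(4) = 2 in expectation
        assert np.mean(deltas) == pytest.approx(2.0, abs=0.15)

    def test_dispersion_zero_limit_is_poisson(self):
        rng = np.random.default_rng(0)
        draws = _negbin(rng, np.full(10_000, 10.0), dispersion=1e-12)
        assert draws.var() == pytest.approx(draws.mean(), rel=0.1)

    def test_dispersion_inflates_variance(self):
        rng = np.random.default_rng(0)
        draws = _negbin(rng, np.full(10_000, 100.0), dispersion=0.1)
        # var = mu + 0.1 mu^2 = 1100
        assert draws.var() == pytest.approx(1100, rel=0.15)


class TestCage:
    def test_control_gene_bodies_are_quiet(self, small_sim, small_cage):
        for cs in small_cage.values():
            if cs.condition != "Ctrl":
                continue
            for gene in small_sim.genes:
                _, _, positions = intragenic_sense_signal(gene, cs, min_tags=8)
                assert positions == []

    def test_planted_ko_positions_exceed_threshold(self, small_sim, small_cage):
        ko_sets = [cs for cs in small_cage.values() if cs.condition == "KO"]
        missed = 0
        total = 0
        for gid, truth in small_sim.truth.genes.items():
            for p in truth.cryptic_positions:
                total += 1
                gene = next(g for g in small_sim.genes if g.gene_id == gid)
                if not any(cs.tags_at(gene.chrom, p, gene.strand) > 8 for cs in ko_sets):
                    missed += 1
        # Poisson(30) mass at or below 8 is ~6e-7 per sample
        assert total > 0 and missed == 0

    def test_minus_strand_genes_tagged_on_minus(self, small_sim, small_cage):
        cs = next(iter(small_cage.values()))
        minus = next(g for g in small_sim.genes
                     if g.strand == "-" and
                     small_sim.truth.genes[g.gene_id].expression > 20)
        pos, tags = cs.lookup(minus.chrom, "-")
        near_tss = tags[(pos >= minus.tss - 2) & (pos <= minus.tss + 2)]
        assert near_tss.sum() > 0

    def test_tag_conservation(self, small_cage):
        for cs in small_cage.values():
            assert cs.total_tags == cs.records["tags"].sum()


class TestChip:
    def test_input_mean_matches_rate(self, small_config, small_chip):
        track = small_chip["input_Ctrl"]
        values = np.concatenate([track.get(c) for c in track.chroms])
        assert values.mean() == pytest.approx(small_config.input_rate, rel=0.05)

    def test_no_spurious_genes_means_balanced_pser5(self):
        cfg = SimConfig(n_genes=60, fraction_spurious=0.0, seed=3)
        sim = simulate_genome(cfg)
        chip = simulate_chip(cfg, sim)
        ratio = chip["pSer5_KO"].total_mass / chip["pSer5_Ctrl"].total_mass
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_ko_reduces_body_marks_on_spurious_genes(self, small_sim, small_chip):
        truth = small_sim.truth
        for mark in ("5hmC", "H3K36me3"):
            ko, ctrl = small_chip[f"{mark}_KO"], small_chip[f"{mark}_Ctrl"]
            ratios = []
            for gene in small_sim.genes:
                if not truth.genes[gene.gene_id].is_spurious:
                    continue
                span = gene.span
                k = ko.get(gene.chrom)[span.start:span.end].mean()
                c = ctrl.get(gene.chrom)[span.start:span.end].mean()
                ratios.append(k / c)
            assert np.mean(ratios) == pytest.approx(0.3, abs=0.1)

    def test_tracks_are_nonnegative_integers(self, small_chip):
        for track in small_chip.values():
            for chrom in track.chroms:
                arr = track.get(chrom)
                assert arr.min() >= 0
                assert np.issubdtype(arr.dtype, np.integer)


class TestDatasetFiles:
    def test_write_dataset_round_trips(self, tmp_path):
        cfg = SimConfig(n_genes=40, seed=2)
        sim = write_dataset(tmp_path, cfg)
        assert read_gtf(tmp_path / "genes.gtf") == sim.genes
        truth = TruthTable.from_json(tmp_path / "truth.json")
        assert truth == sim.truth
        track = read_bedgraph(tmp_path / "input_Ctrl.bedgraph")
        from spurcatch.synthetic_data import simulate_chip as sc
        assert track.allclose(sc(cfg, sim)["input_Ctrl"])
        assert (tmp_path / "ctss_KO_1.bed").exists()
        assert (tmp_path / "exon_counts.tsv").exists()
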