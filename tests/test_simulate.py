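"""The synthetic-data generator: mask geometry, planted truth consistency,
expression calibration, determinism."""

import math

import numpy as np
import pytest
from conftest import small_sim_config

from linccat.expression import build_expression_matrix, expression_tiers
from linccat.intervals import gap_distance
from linccat.orf import find_large_orfs
from linccat.simulate import (
    GenerationError,
    SimConfig,
    expected_count,
    generate_genome,
    simulate,
    simulate_snp_table,
)


class TestGenerateGenome:
    def test_mask_fraction_close_to_target(self):
        cfg = SimConfig(seed=3, unmappable_fraction=0.15)
        genome = generate_genome(cfg)
        assert genome.genome_size == 2_000_000
        target = 0.85 * 2_000_000
        assert abs(genome.mappable_size - target) <= 0.05 * target

    def test_zero_unmappable_covers_everything(self):
        genome = generate_genome(SimConfig(seed=1, unmappable_fraction=0.0))
        assert genome.mappable_size == genome.genome_size

    def test_same_seed_identical_masks(self):
        a = generate_genome(SimConfig(seed=9))
        b = generate_genome(SimConfig(seed=9))
        assert a.mappability_mask == b.mappability_mask


class TestPlantedTruth:
    def test_labels_partition_candidates(self, small_sim):
        cfg_counts = small_sim.cfg.counts
        by_cat = {}
        for t in small_sim.candidates:
            by_cat.setdefault(small_sim.truth[t.id].category, 0)
            by_cat[small_sim.truth[t.id].category] += 1
        expected = {k: v for k, v in cfg_counts.items() if k != "protein_coding"}
        assert by_cat == expected
        assert len(small_sim.genes) == cfg_counts["protein_coding"]

    def test_true_lincRNAs_are_orf_free(self, small_sim):
        seqs = small_sim.transcript_sequences()
        for t in small_sim.candidates:
            if small_sim.truth[t.id].category == "true_lincRNA":
                assert find_large_orfs(seqs[t.id]) == []

    def test_genes_carry_large_orfs(self, small_sim):
        seqs = small_sim.transcript_sequences()
        for g in small_sim.genes:
            assert find_large_orfs(seqs[g.id])

    def test_proximity_decoys_near_a_gene_others_far(self, small_sim):
        for t in small_sim.candidates:
            cat = small_sim.truth[t.id].category
            dists = [gap_distance(t, g) for g in small_sim.genes]
            if cat == "proximity_decoy":
                assert min(dists) <= 1000
            elif cat in ("true_lincRNA", "low_expression_decoy"):
                assert min(dists) > 1000

    def test_short_decoys_below_200nt(self, small_sim):
        for t in small_sim.candidates:
            if small_sim.truth[t.id].category == "short_decoy":
                assert t.exonic_length < 200

    def test_exons_lie_in_mappable_space(self, small_sim):
        mask = small_sim.genome.mappability_mask
        for t in small_sim.candidates:
            for s, e in t.exons:
                assert any(ms <= s and e <= me for ms, me in mask[t.chrom])


class TestReads:
    def test_expected_count_formula(self):
        # FPKM 10, 1 kb transcript, 1M mapped reads -> mean count 10
        assert expected_count(10.0, 1000, 1_000_000) == pytest.approx(10.0)

    def test_counts_track_planted_means(self, small_sim):
        """Realized counts are Poisson around the planted FPKM-implied
        means: standardized residuals behave like unit-variance noise."""
        matrix = build_expression_matrix(
            small_sim.reads_by_dataset,
            small_sim.candidates + small_sim.genes,
            small_sim.datasets,
        )
        lengths = {
            t.id: t.exonic_length
            for t in small_sim.candidates + small_sim.genes
        }
        z = []
        for ds in small_sim.datasets:
            for tid in matrix.counts.index:
                mean = expected_count(
                    float(small_sim.planted_fpkm.loc[tid, ds.dataset_id]),
                    lengths[tid],
                    ds.total_mapped_reads,
                )
                if mean >= 10:
                    obs = matrix.counts.loc[tid, ds.dataset_id]
                    z.append((obs - mean) / math.sqrt(mean))
        z = np.array(z)
        assert len(z) > 100
        assert abs(z.mean()) < 0.2
        assert (np.abs(z) < 4).mean() > 0.99

    def test_junction_reads_are_split(self, small_sim):
        spliced = [t for t in small_sim.candidates if t.n_exons >= 2]
        split_found = any(
            r.is_split
            for reads in small_sim.reads_by_dataset.values()
            for r in reads
        )
        assert spliced and split_found
        # a split read's gap must equal an intron of some feature
        for reads in small_sim.reads_by_dataset.values():
            for r in reads:
                if r.is_split:
                    gaps = [
                        (r.blocks[i][1], r.blocks[i + 1][0])
                        for i in range(len(r.blocks) - 1)
                    ]
                    assert all(g[1] > g[0] for g in gaps)

    def test_low_expression_decoys_below_fpkm1_everywhere(self, small_sim):
        matrix = build_expression_matrix(
            small_sim.reads_by_dataset,
            small_sim.candidates + small_sim.genes,
            small_sim.datasets,
        )
        tiers = expression_tiers(matrix)
        for tid, lab in small_sim.truth.items():
            if lab.category == "low_expression_decoy":
                assert tiers[tid] == "fail"
                assert (matrix.fpkm.loc[tid] <= 1.0).all()


class TestSnpTable:
    def test_planted_fold_recovered(self, small_sim):
        cfg = small_sim.cfg
        snps = small_sim.snps
        linc_exons = {}
        for t in small_sim.candidates:
            if small_sim.truth[t.id].category == "true_lincRNA":
                linc_exons.setdefault(t.chrom, []).extend(t.exons)
        in_linc = np.zeros(len(snps), dtype=bool)
        for i, row in snps.iterrows():
            in_linc[i] = any(
                s <= row.pos < e for s, e in linc_exons.get(row.chrom, [])
            )
        rate_in = snps[in_linc]["trait_associated"].mean()
        rate_out = snps[~in_linc]["trait_associated"].mean()
        fold = rate_in / rate_out
        n_in = int(in_linc.sum())
        sd = cfg.tas_enrichment_fold * math.sqrt(
            1 / max(1, rate_in * n_in) + 1 / max(1, rate_out * (len(snps) - n_in))
        )
        assert abs(fold - cfg.tas_enrichment_fold) <= 3 * sd

    def test_same_rng_identical_table(self, small_sim):
        cfg = small_sim.cfg
        linc_exons = {"chr1": [(1000, 2000)]}
        a = simulate_snp_table(cfg, small_sim.genome, linc_exons, np.random.default_rng(3))
        b = simulate_snp_table(cfg, small_sim.genome, linc_exons, np.random.default_rng(3))
        assert a.equals(b)


class TestDeterminismAndErrors:
    def test_same_seed_same_everything(self):
        cfg = small_sim_config(seed=11)
        a = simulate(cfg)
        b = simulate(small_sim_config(seed=11))
        assert a.sequences == b.sequences
        assert [t.exons for t in a.candidates] == [t.exons for t in b.candidates]
        assert a.snps.equals(b.snps)
        for ds in a.reads_by_dataset:
            ra = [(r.chrom, tuple(r.blocks)) for r in a.reads_by_dataset[ds]]
            rb = [(r.chrom, tuple(r.blocks)) for r in b.reads_by_dataset[ds]]
            assert ra == rb

    def test_infeasible_config_raises(self):
        cfg = small_sim_config(seed=2)
        cfg.chrom_length = 30_000  # far too small for the requested features
        with pytest.raises(GenerationError):
            simulate(cfg)

    def test_orf_neighbors_require_hosts(self):
        with pytest.raises(ValueError, match="host"):
            SimConfig(counts={"large_orf_decoy": 1, "orf_neighbor_decoy": 2})
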