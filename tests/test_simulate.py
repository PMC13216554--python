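import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from ceekit import io as cio
from ceekit.popgen import af_bin, classify_variant
from ceekit.simulate import (
    SimConfig,
    simulate_enrichment_dataset,
    simulate_genome,
    simulate_interactions,
    simulate_ortholog_pairs,
    simulate_starr_counts,
    simulate_tf_peaks,
    simulate_variants,
    write_genome_files,
)

SMALL = dict(
    n_chroms=1, chrom_length=1_000_000, n_genes=12, n_planted_cees=4,
    n_ortholog_pairs=2, ortholog_codons=100,
)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        cfg = SimConfig(seed=7, **SMALL)
        a = simulate_genome(cfg)
        b = simulate_genome(cfg)
        assert a.sequences == b.sequences
        assert [e.interval for e in a.exons] == [e.interval for e in b.exons]
        pa, ia = simulate_tf_peaks(cfg, a)
        pb, ib = simulate_tf_peaks(cfg, b)
        assert ia == ib
        assert [(p.interval, p.tf_name, p.summit) for p in pa] == [
            (p.interval, p.tf_name, p.summit) for p in pb
        ]

    def test_distinct_seeds_differ(self):
        a = simulate_genome(SimConfig(seed=1, **SMALL))
        b = simulate_genome(SimConfig(seed=2, **SMALL))
        assert a.sequences != b.sequences


class TestGenome:
    def test_gene_count_and_clean_cds(self, default_genome, default_config):
        assert len(default_genome.genes) == default_config.n_genes
        for gid, cds in default_genome.gene_cds.items():
            aa = str(Seq(cds).translate())
            assert aa.startswith("M")
            assert aa.endswith("*")
            assert "*" not in aa[:-1]

    def test_exon_cds_matches_genome_sequence(self, default_genome):
        from ceekit.core import reverse_complement

        for ex in default_genome.exons:
            iv = ex.interval
            chunk = default_genome.sequences[iv.chrom][iv.start : iv.end]
            expected = reverse_complement(chunk) if iv.strand == "-" else chunk
            assert ex.cds_seq == expected

    def test_tss_tes_at_gene_ends(self, default_genome):
        by_pos = {(t.chrom, t.position, t.strand) for t in default_genome.tss}
        for gid, gene in default_genome.genes.items():
            pos = gene.start if gene.strand == "+" else gene.end - 1
            assert (gene.chrom, pos, gene.strand) in by_pos

    def test_files_roundtrip_through_readers(self, default_genome, tmp_path):
        write_genome_files(default_genome, str(tmp_path))
        fa = cio.read_fasta(str(tmp_path / "genome.fa"))
        assert fa == default_genome.sequences
        exons = cio.read_gff_exons(str(tmp_path / "genes.gff3"))
        assert len(exons) == len(default_genome.exons)
        got = {(e.interval.chrom, e.interval.start, e.interval.end, e.interval.strand)
               for e in exons}
        want = {(e.interval.chrom, e.interval.start, e.interval.end, e.interval.strand)
                for e in default_genome.exons}
        assert got == want
        assert all(e.tsl == 1 for e in exons)
        sizes = cio.read_chrom_sizes(str(tmp_path / "chrom.sizes"))
        assert sizes == default_genome.chrom_sizes


class TestTfPeaks:
    def test_planted_clusters_satisfy_caller_contract(self, default_config):
        """>=10 distinct TFs overlap and >=50% of summits fall inside the exon
        for essentially every planted cluster (Monte-Carlo over 500 draws)."""
        rng = np.random.default_rng(99)
        n_ok = 0
        draws = 500
        exon_len = 200
        for _ in range(draws):
            summits = rng.normal(0.0, default_config.summit_jitter_sd,
                                 default_config.tfs_per_cluster)
            inside = np.abs(summits) < exon_len / 2
            if inside.sum() >= 10 and inside.mean() >= 0.5:
                n_ok += 1
        assert n_ok / draws > 0.99

    def test_background_count_matches_poisson_rate(self):
        cfg = SimConfig(seed=0, **{**SMALL, "n_planted_cees": 0})
        counts = []
        for seed in range(5):
            c = SimConfig(seed=seed, **{**SMALL, "n_planted_cees": 0})
            g = simulate_genome(c)
            peaks, planted = simulate_tf_peaks(c, g)
            assert planted == []
            counts.append(len(peaks))
        lam = cfg.background_peaks_per_mb * cfg.n_chroms * cfg.chrom_length / 1e6
        # mean of 5 Poisson draws within 4 SD of the configured rate
        assert abs(np.mean(counts) - lam) < 4 * np.sqrt(lam / 5)

    def test_planted_ids_exist_in_genome(self, default_genome, default_peaks):
        _, planted = default_peaks
        names = {e.interval.name for e in default_genome.exons}
        assert set(planted) <= names


@pytest.fixture(scope="module")
def variant_sim():
    cfg = SimConfig(seed=13, snv_rate=0.2, **SMALL)
    genome = simulate_genome(cfg)
    variants, truth = simulate_variants(cfg, genome)
    return cfg, genome, variants, truth


@pytest.fixture(scope="module")
def starr_sim():
    cfg = SimConfig(seed=5, n_cee_inserts=250)
    table, truth = simulate_starr_counts(cfg)
    return cfg, table, truth


class TestVariants:
    def test_ref_matches_genome(self, variant_sim):
        _, genome, variants, _ = variant_sim
        assert all(
            genome.sequences[v.chrom][v.pos] == v.ref for v in variants
        )

    def test_consequence_labels_cross_validate(self, variant_sim):
        """Generator truth agrees with classify_variant for every variant."""
        _, genome, _, truth = variant_sim
        for row in truth.itertuples(index=False):
            cds = genome.gene_cds[row.gene_id]
            got = classify_variant(
                cds, row.codon_index, row.position_in_codon, row.cds_ref, row.cds_alt
            )
            assert got == row.consequence

    def test_af_spectrum_matches_mixture(self):
        cfg = SimConfig(seed=21, snv_rate=0.45, **SMALL)
        genome = simulate_genome(cfg)
        _, truth = simulate_variants(cfg, genome)
        assert len(truth) > 3000
        bins = truth["af"].map(af_bin).value_counts(normalize=True)
        for name, w in zip(
            ("ultra_rare", "rare", "low_frequency", "common"), cfg.af_weights
        ):
            assert abs(bins.get(name, 0.0) - w) < 0.02

    def test_vcf_roundtrip(self, variant_sim, tmp_path):
        _, genome, variants, _ = variant_sim
        path = str(tmp_path / "v.vcf")
        cio.write_vcf(variants, path, genome.chrom_sizes)
        back = cio.read_vcf(path)
        assert len(back) == len(variants)
        assert {(v.chrom, v.pos, v.ref, v.alt) for v in back} == {
            (v.chrom, v.pos, v.ref, v.alt) for v in variants
        }


class TestStarrGenerator:
    def test_input_depth_calibration(self):
        cfg = SimConfig(seed=8, n_cee_inserts=1000, insert_depth_cv=0.0)
        table, _ = simulate_starr_counts(cfg)
        mean = table.counts[table.input_samples].to_numpy().mean()
        assert abs(mean - cfg.input_depth) / cfg.input_depth < 0.05

    def test_activity_estimates_track_planted_truth(self, starr_sim):
        from ceekit.starr import activity_records, filter_inserts

        cfg, table, truth = starr_sim
        kept, _ = filter_inserts(table)
        records = activity_records(table, kept)
        err = records["log2fc"] - truth.loc[records.index, "activity"]
        assert len(records) > 200
        assert abs(err.mean()) < 0.1

    def test_truth_ids_exist_in_counts(self, starr_sim):
        _, table, truth = starr_sim
        assert truth.index.equals(table.counts.index)
        assert set(table.pairs["variant"]) <= set(table.counts.index)
        assert set(table.pairs["reference"]) <= set(table.counts.index)


class TestOrthologGenerator:
    def test_constructive_counts(self, rng):
        cfg = SimConfig(seed=3, n_ortholog_pairs=3, ortholog_codons=150)
        from ceekit.popgen import neigojobori_dnds

        for p in simulate_ortholog_pairs(cfg):
            d = neigojobori_dnds(p["seq_a"], p["seq_b"])
            assert d.nd == p["nd_true"]
            assert d.sd == p["sd_true"]

    def test_zero_targets_give_identical_sequences(self):
        cfg = SimConfig(seed=3, n_ortholog_pairs=2, ortholog_codons=50,
                        target_dn=0.0, target_ds=0.0)
        for p in simulate_ortholog_pairs(cfg):
            assert p["seq_a"] == p["seq_b"]

    def test_pure_synonymous_divergence(self):
        from ceekit.popgen import neigojobori_dnds

        cfg = SimConfig(seed=9, n_ortholog_pairs=2, ortholog_codons=200,
                        target_dn=0.0, target_ds=0.05)
        for p in simulate_ortholog_pairs(cfg):
            d = neigojobori_dnds(p["seq_a"], p["seq_b"])
            assert d.nd == 0
            assert d.dn == 0
            assert d.sd > 0


class TestEnrichmentDataset:
    def test_planted_observed_consistent(self):
        ds = simulate_enrichment_dataset(seed=4)
        from ceekit.core import MergedIntervals

        idx = MergedIntervals(ds.targets)
        observed = sum(idx.overlaps_interval(q) for q in ds.query)
        assert observed == ds.planted_observed
        assert ds.planted_observed == pytest.approx(
            ds.planted_fold * ds.expected_overlap, abs=1.5
        )


class TestInteractionsGenerator:
    def test_truth_recovered_by_pipeline(self, default_config, default_genome,
                                         default_peaks):
        from ceekit.interactions import overlap_evidence, robust_pairs

        _, planted = default_peaks
        elements, re2g, pchic, eqtl, truth = simulate_interactions(
            default_config, default_genome, planted
        )
        ev = overlap_evidence(elements, re2g, pchic, eqtl)
        pairs = robust_pairs(ev, elements, default_genome.genes)
        merged = pairs.merge(truth, on=["element", "gene"], how="right",
                             suffixes=("", "_true"))
        assert not merged["robust"].isna().any()
        assert (merged["robust"] == merged["robust_true"]).all()
        assert (merged["relation"] == merged["relation_true"]).all()
        assert (merged["n_sources"] == merged["n_sources_true"]).all()
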