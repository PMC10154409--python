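"""Generator contracts: determinism, round-trips and planted parameters."""

import filecmp
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from subteloscan import io as sio
from subteloscan.chip import classify_telomeric_batch
from subteloscan.hic import parse_valid_pairs
from subteloscan.simulate import (
    DESpec,
    InsertionSpec,
    PairSpec,
    ReadSpec,
    SimulationConfig,
    TEFamilySpec,
    VariantSpec,
    simulate_all,
    simulate_de_table,
    simulate_genome,
    simulate_reads,
    simulate_valid_pairs,
    synthetic_consensus_library,
)


def small_config(seed=3):
    cfg = SimulationConfig(seed=seed)
    cfg.reads = ReadSpec(n_reads=2_000, telomeric_fraction=0.02)
    cfg.pairs = PairSpec(n_pairs=5_000)
    cfg.variants = VariantSpec(n_baseline=50, n_case=80)
    cfg.insertions = InsertionSpec(n_case=15, n_shared=10)
    return cfg


class TestDeterminismAndRoundTrip:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        p1 = simulate_all(small_config(), tmp_path / "a")
        p2 = simulate_all(small_config(), tmp_path / "b")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_different_seed_differs(self, tmp_path):
        p1 = simulate_all(small_config(1), tmp_path / "a")
        p2 = simulate_all(small_config(2), tmp_path / "b")
        assert not filecmp.cmp(p1["de_table"], p2["de_table"], shallow=False)

    def test_emitted_files_round_trip(self, tmp_path):
        cfg = small_config()
        paths = simulate_all(cfg, tmp_path / "d")
        assembly = sio.read_chrom_sizes(paths["chrom_sizes"])
        assert assembly.names == list(cfg.chromosome_lengths)
        genes = sio.read_bed12(paths["genes"])
        assert genes and all(g.exons for g in genes)
        te = sio.read_bed6_named(paths["te_bed"])
        assert len(te) == sum(f.copies for f in cfg.te_families)
        reads = list(sio.read_sequences(paths["reads"]))
        assert len(reads) == cfg.reads.n_reads
        pairs, stats = parse_valid_pairs(paths["pairs"], assembly)
        assert stats.n_pairs == cfg.pairs.n_pairs and not stats.n_malformed
        case_vars, case_ins, bad = sio.read_vcf_minimal(paths["case_vcf"])
        truth = json.loads(Path(paths["truth"]).read_text())
        assert bad == 0
        assert len(case_ins) == cfg.insertions.n_case + cfg.insertions.n_shared
        assert len(case_vars) == cfg.variants.n_baseline + cfg.variants.n_case
        assert set(truth["insertion_families"]) == {
            f"case_ins_{i}" for i in range(cfg.insertions.n_case)}


class TestGenomePlanting:
    def test_uniform_placement_matches_zone_fraction(self):
        cfg = SimulationConfig(seed=11)
        cfg.te_families = [TEFamilySpec("fam", "LINE", 4_000, telomere_bias=1.0)]
        genome = simulate_genome(cfg)
        frac = np.mean(list(genome.te_subtelomeric.values()))
        t = cfg.subtelomere_threshold
        zone_frac = sum(2 * min(t, c.length // 2) for c in genome.assembly
                        ) / genome.assembly.total_length
        se = np.sqrt(zone_frac * (1 - zone_frac) / 4_000)
        assert abs(frac - zone_frac) < 3 * se

    def test_biased_placement_matches_mixture_arithmetic(self):
        """rho = 5 with a 10% zone gives a subtelomeric fraction near
        5*0.1/(5*0.1+0.9) = 35.7% (per-chromosome mixture, pooled)."""
        cfg = SimulationConfig(seed=13)
        cfg.chromosome_lengths = {"chr1": 10_000_000}
        cfg.subtelomere_bp = 500_000  # zone fraction 2*0.5/10 = 10%
        cfg.te_families = [TEFamilySpec("fam", "LINE", 4_000, telomere_bias=5.0)]
        genome = simulate_genome(cfg)
        frac = np.mean(list(genome.te_subtelomeric.values()))
        expect = 5 * 0.1 / (5 * 0.1 + 0.9)
        se = np.sqrt(expect * (1 - expect) / 4_000)
        assert abs(frac - expect) < 3 * se

    def test_zero_copies_gives_no_instances(self):
        cfg = SimulationConfig(seed=1)
        cfg.te_families = [TEFamilySpec("fam", "LINE", 0)]
        assert simulate_genome(cfg).te_instances == []


class TestDEPlanting:
    def test_null_factor_labels_independent_of_position(self):
        cfg = SimulationConfig(seed=17)
        cfg.te_families = [TEFamilySpec("fam", "LINE", 3_000)]
        cfg.de = DESpec(enrichment_factor=1.0)
        genome = simulate_genome(cfg)
        table, labels = simulate_de_table(genome)
        up = np.array([labels[t.id] == "up" for t in genome.te_instances])
        sub = np.array([genome.te_subtelomeric[t.id]
                        for t in genome.te_instances])
        rate_in = up[sub].mean()
        rate_out = up[~sub].mean()
        se = np.sqrt(0.05 * 0.95 * (1 / sub.sum() + 1 / (~sub).sum()))
        assert abs(rate_in - rate_out) < 4 * se

    def test_planted_factor_scales_subtelomeric_up_rate(self):
        cfg = SimulationConfig(seed=19)
        cfg.chromosome_lengths = {"chr1": 10_000_000}
        cfg.subtelomere_bp = 1_000_000
        cfg.te_families = [TEFamilySpec("fam", "LINE", 5_000, telomere_bias=3.0)]
        cfg.de = DESpec(fraction_up=0.02, enrichment_factor=5.0,
                        expressed_fraction=1.0)
        genome = simulate_genome(cfg)
        _, labels = simulate_de_table(genome)
        up = np.array([labels[t.id] == "up" for t in genome.te_instances])
        sub = np.array([genome.te_subtelomeric[t.id]
                        for t in genome.te_instances])
        expect = 0.10  # 5 x 0.02
        se = np.sqrt(expect * (1 - expect) / sub.sum())
        assert abs(up[sub].mean() - expect) < 3 * se

    def test_labelled_rows_pass_filters_and_unlabelled_fail(self):
        cfg = SimulationConfig(seed=23)
        genome = simulate_genome(cfg)
        table, labels = simulate_de_table(genome)
        t = table.set_index("instance_id")
        for tid, label in labels.items():
            row = t.loc[tid]
            if label == "up":
                assert row.log2fc > np.log2(1.5) and row.pvalue < 0.05
                assert row.unique_reads >= 5
            elif label == "none":
                assert abs(row.log2fc) <= np.log2(1.5) or row.pvalue >= 0.05


class TestReadsPlanting:
    def test_zero_fraction_means_no_telomeric(self):
        cfg = small_config()
        cfg.reads = ReadSpec(n_reads=500, telomeric_fraction=0.0)
        reads, truth = simulate_reads(cfg)
        assert truth == set()
        assert not classify_telomeric_batch([s for _, s in reads]).any()

    def test_classifier_recovers_planted_labels_exactly_at_zero_subs(self):
        cfg = small_config()
        cfg.reads = ReadSpec(n_reads=3_000, telomeric_fraction=0.05,
                             substitution_rate=0.0)
        reads, truth = simulate_reads(cfg)
        hits = classify_telomeric_batch([s for _, s in reads])
        called = {rid for (rid, _), h in zip(reads, hits) if h}
        assert called == truth


class TestPairsPlanting:
    def test_trans_fraction_zero_is_all_cis(self):
        cfg = small_config()
        cfg.pairs = PairSpec(n_pairs=2_000, trans_fraction=0.0)
        lines, truth = simulate_valid_pairs(cfg)
        assert truth["n_trans"] == 0
        assert all(l.split()[1] == l.split()[4] for l in lines)

    def test_neutral_boost_anchor_zone_rate_matches_uniform(self):
        cfg = small_config()
        cfg.pairs = PairSpec(n_pairs=20_000, boost=1.0)
        _, truth = simulate_valid_pairs(cfg)
        S = truth["boost_zone_bp"] * 2 * 5 / cfg.assembly().total_length
        se = np.sqrt(S * (1 - S) / 20_000)
        assert abs(truth["anchor_in_zone"] / 20_000 - S) < 3 * se


class TestConfig:
    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SimulationConfig.from_dict({"seed": 1, "bogus": 2})

    def test_dict_round_trip(self):
        cfg = small_config()
        again = SimulationConfig.from_dict(cfg.to_dict())
        assert again.to_dict() == cfg.to_dict()

    def test_scaled_thresholds_proportional(self):
        cfg = SimulationConfig()
        # miniature median 12 Mb vs mouse 130 Mb
        assert cfg.scaled(1_000_000) == round(1_000_000 * 12 / 130)
        assert cfg.scale_factor == pytest.approx(12 / 130)
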