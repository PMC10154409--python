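"""DE filtering, distance partition, expected counts, the exact Fisher test
against a Fraction enumeration oracle and scipy, and the enrichment scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subteloscan.genome import GenomeAssembly, ChromosomeRecord, GenomicInterval
from subteloscan.simulate import simulate_enrichment_table
from subteloscan.te_enrichment import (
    TEInstanceRecord,
    benjamini_hochberg,
    enrichment_scan,
    expected_subtelomeric_count,
    filter_de_instances,
    fisher_enrichment,
    split_by_distance,
)

from conftest import fisher_oracle


def de_row(iid, log2fc, pvalue, unique_reads, superfamily="LINE"):
    return {
        "instance_id": iid, "family": "L1MdTf_I", "superfamily": superfamily,
        "chrom": "chr1", "start": 0, "end": 100,
        "log2fc": log2fc, "pvalue": pvalue, "unique_reads": unique_reads,
    }


class TestFilter:
    @pytest.mark.parametrize(
        "log2fc,pvalue,reads,direction,kept",
        [
            (1.0, 0.01, 10, "up", True),    # FC 2.0 passes all filters
            (1.0, 0.01, 4, "up", False),    # < 5 uniquely mapped reads
            (np.log2(1.4), 0.001, 50, "up", False),  # below fold-change cutoff
            (-1.0, 0.01, 10, "down", True),
            (-1.0, 0.01, 10, "up", False),
            (1.0, 0.05, 10, "up", False),   # p cutoff is strict
            (np.log2(1.5), 0.01, 10, "up", False),   # FC cutoff is strict
        ],
    )
    def test_filter_rules(self, log2fc, pvalue, reads, direction, kept):
        table = pd.DataFrame([de_row("t1", log2fc, pvalue, reads)])
        got = filter_de_instances(table, direction=direction)
        assert ("t1" in got) is kept

    def test_duplicate_ids_rejected(self):
        table = pd.DataFrame([de_row("t1", 1, 0.01, 9), de_row("t1", 1, 0.01, 9)])
        with pytest.raises(ValueError, match="duplicate"):
            filter_de_instances(table)


class TestSplitAndExpected:
    @pytest.fixture
    def assembly(self):
        return GenomeAssembly([ChromosomeRecord("chr1", 1_000_000)])

    def test_partition_is_disjoint_and_complete(self, assembly, rng):
        tes = [
            TEInstanceRecord(f"t{i}", GenomicInterval(
                "chr1", int(p), int(p) + 100), "f", "LINE")
            for i, p in enumerate(rng.integers(0, 999_000, size=50))
        ]
        sub, non = split_by_distance(tes, assembly, 100_000)
        assert sub | non == set(tes) and not (sub & non)
        assert all(te.locus.start < 100_000
                   or te.locus.start > 1_000_000 - 100_001 for te in sub)

    def test_threshold_saturation(self, assembly):
        tes = [TEInstanceRecord("a", GenomicInterval("chr1", 500_000, 500_100),
                                "f", "LINE")]
        sub, non = split_by_distance(tes, assembly, 600_000)
        assert sub == set(tes) and non == set()

    def test_empty_input(self, assembly):
        assert split_by_distance([], assembly, 1000) == (set(), set())

    @pytest.mark.parametrize(
        "n_de,bg_sub,bg_tot,expected",
        [(50, 100, 1000, 5.0), (0, 7, 100, 0.0), (50, 1000, 1000, 50.0)],
    )
    def test_expected_count(self, n_de, bg_sub, bg_tot, expected):
        assert expected_subtelomeric_count(n_de, bg_sub, bg_tot) == expected

    def test_zero_background_raises(self):
        with pytest.raises(ValueError):
            expected_subtelomeric_count(10, 0, 0)


class TestFisher:
    def test_worked_example_eight_two(self):
        _, p = fisher_enrichment(8, 2, 2, 8)
        assert p == pytest.approx(4252 / 184756, abs=1e-15)

    def test_symmetric_table(self):
        odds, p = fisher_enrichment(5, 5, 5, 5)
        assert odds == 1.0 and p == 1.0

    def test_odds_ratio_cross_product(self):
        odds, _ = fisher_enrichment(20, 30, 80, 870)
        assert odds == pytest.approx(7.25)

    def test_zero_denominator_gives_infinite_odds(self):
        odds, _ = fisher_enrichment(5, 0, 3, 7)
        assert odds == np.inf

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(-1, 2, 3, 4)

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = rng.integers(0, 9, size=4)
            _, p = fisher_enrichment(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(fisher_oracle(int(a), int(b), int(c), int(d)),
                                      abs=1e-12)

    def test_matches_scipy_cross_check(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
            _, p = fisher_enrichment(a, b, c, d)
            sp = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert p == pytest.approx(sp, rel=1e-6, abs=1e-9)

    def test_large_table_log_space_path_matches_scipy(self):
        _, p = fisher_enrichment(300, 2700, 290, 2710)
        sp = stats.fisher_exact([[300, 2700], [290, 2710]])[1]
        assert p == pytest.approx(sp, rel=1e-8)


class TestScan:
    @pytest.fixture
    def assembly(self):
        return GenomeAssembly([ChromosomeRecord("chr1", 1_000_000)])

    def _make_inputs(self, rng, n=400, biased=True):
        rows, tes = [], []
        for i in range(n):
            subtel = i < n // 10  # 10% of instances subtelomeric
            start = int(rng.integers(0, 50_000)) if subtel else int(
                rng.integers(50_000, 950_000))
            te = TEInstanceRecord(f"t{i}", GenomicInterval(
                "chr1", start, start + 100), "L1MdTf_I", "LINE")
            tes.append(te)
            # plant up-labels 5x more often in the subtelomere
            p_up = 0.5 if (subtel and biased) else 0.1
            up = rng.random() < p_up
            rows.append(de_row(
                f"t{i}", 1.5 if up else 0.0, 0.001 if up else 0.5, 50))
            rows[-1].update(chrom="chr1", start=start, end=start + 100)
        return pd.DataFrame(rows), tes

    def test_planted_bias_detected(self, assembly, rng):
        table, tes = self._make_inputs(rng, biased=True)
        results = enrichment_scan(table, tes, assembly, [50_000],
                                  directions=("up",))
        (r,) = results
        assert r.adjusted_p < 0.05
        assert r.observed > r.expected

    def test_empty_de_set_is_null(self, assembly, rng):
        table, tes = self._make_inputs(rng)
        table["pvalue"] = 0.9  # nothing passes the DE filter
        results = enrichment_scan(table, tes, assembly, [50_000])
        assert all(r.observed == 0 and r.p_value == 1.0 for r in results)

    def test_unknown_superfamily_warns_and_skips(self, assembly, rng):
        table, tes = self._make_inputs(rng)
        with pytest.warns(UserWarning, match="absent"):
            results = enrichment_scan(table, tes, assembly, [50_000],
                                      superfamilies=["LINE", "SINE"])
        assert {r.superfamily for r in results} == {"LINE"}

    def test_one_result_per_cell_and_adjustment(self, assembly, rng):
        table, tes = self._make_inputs(rng)
        results = enrichment_scan(table, tes, assembly, [10_000, 50_000])
        assert len(results) == 1 * 2 * 2  # superfamily x direction x threshold
        for r in results:
            assert r.adjusted_p >= r.p_value - 1e-15

    def test_bh_adjustment_matches_manual(self):
        ps = [0.01, 0.02, 0.03, 0.5]
        adj = benjamini_hochberg(ps)
        manual = [0.04, 0.04, 0.04, 0.5]
        assert np.allclose(adj, manual)


class TestCalibration:
    def test_uniform_placement_mean_observed_matches_expected(self, rng):
        """Under uniform placement the mean observed subtelomeric DE count
        converges to the density-based expectation (3 SE at 1000 reps)."""
        n_de, n_bg, f = 50, 950, 0.1
        obs = []
        for _ in range(1000):
            de_sub, _, bg_sub, bg_non = simulate_enrichment_table(
                n_bg, n_de, f, 1.0, rng)
            obs.append(de_sub)
        expected = expected_subtelomeric_count(n_de, int(n_bg * f), n_bg)
        se = np.std(obs, ddof=1) / np.sqrt(len(obs))
        assert abs(np.mean(obs) - expected) < 3 * se + 1e-9
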