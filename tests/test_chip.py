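"""Telomeric-read classification, read-rate normalisation, peak classes and
the flanking-gene metagene."""

import numpy as np
import pytest

from subteloscan.chip import (
    PeakRecord,
    TelomericReadParams,
    classify_peaks,
    classify_telomeric_batch,
    is_telomeric_read,
    metagene_flanking_fc,
    telomeric_read_rate,
)
from subteloscan.genome import GenomeAssembly, ChromosomeRecord, GenomicInterval
from subteloscan.retro import reverse_complement
from subteloscan.te_enrichment import TEInstanceRecord

from conftest import make_gene

TRACT = "TTAGGG" * 30


class TestTelomericRead:
    def test_pure_repeat_and_reverse_complement(self):
        assert is_telomeric_read("TTAGGG" * 25)
        assert is_telomeric_read("CCCTAA" * 25)

    @pytest.mark.parametrize("offset", range(6))
    def test_any_phase_offset_is_telomeric(self, offset):
        assert is_telomeric_read(TRACT[offset : offset + 150])

    def test_partial_repeat_below_coverage_fails(self, rng):
        tail = "".join("ACGT"[i] for i in rng.integers(0, 4, size=90))
        read = "TTAGGG" * 10 + tail  # coverage 60/150 = 0.4 < 0.7
        assert not is_telomeric_read(read)
        assert is_telomeric_read(read, TelomericReadParams(
            min_coverage_fraction=0.4))

    def test_read_shorter_than_unit_is_false(self):
        assert not is_telomeric_read("TTAGG")

    def test_one_mismatch_per_unit_needs_allowance(self):
        read = "".join("TTAGGC" for _ in range(25))  # 1 mismatch per unit
        assert not is_telomeric_read(read)
        assert is_telomeric_read(read, TelomericReadParams(
            max_mismatches_per_unit=1))

    def test_reverse_complement_invariance(self, rng):
        reads = [TRACT[2:152],
                 "".join("ACGT"[i] for i in rng.integers(0, 4, size=150))]
        for r in reads:
            assert is_telomeric_read(r) == is_telomeric_read(
                reverse_complement(r))

    def test_batch_agrees_with_scalar(self, rng):
        seqs = []
        for i in range(200):
            if i % 3 == 0:
                off = int(rng.integers(0, 6))
                s = TRACT[off : off + 150]
                seqs.append(s if i % 2 else reverse_complement(s))
            else:
                seqs.append("".join("ACGT"[j]
                                    for j in rng.integers(0, 4, size=150)))
        batch = classify_telomeric_batch(seqs)
        scalar = np.array([is_telomeric_read(s) for s in seqs])
        assert (batch == scalar).all()


class TestReadRate:
    def test_per_million_arithmetic(self):
        reads = [(f"t{i}", TRACT[:150]) for i in range(316)] + [
            (f"b{i}", "ACGT" * 38) for i in range(684)
        ]
        n_telo, n_total, per_million, ids = telomeric_read_rate(reads)
        assert (n_telo, n_total) == (316, 1000)
        assert per_million == pytest.approx(316_000)
        assert set(ids) == {f"t{i}" for i in range(316)}

    def test_empty_stream_raises(self):
        with pytest.raises(ValueError):
            telomeric_read_rate([])


class TestClassifyPeaks:
    @pytest.fixture
    def assembly(self):
        return GenomeAssembly([ChromosomeRecord("chr1", 1_000_000)])

    @pytest.fixture
    def te(self):
        return [TEInstanceRecord("t1", GenomicInterval("chr1", 10_000, 11_000),
                                 "L1", "LINE"),
                TEInstanceRecord("t2", GenomicInterval(
                    "chr1", 500_000, 501_000), "L1", "LINE")]

    def test_conjunction_and_tally_consistency(self, assembly, te):
        peaks = [
            PeakRecord(GenomicInterval("chr1", 10_500, 10_600), "decreased"),
            PeakRecord(GenomicInterval("chr1", 500_500, 500_600), "decreased"),
            PeakRecord(GenomicInterval("chr1", 20_000, 20_100), "decreased"),
            PeakRecord(GenomicInterval("chr1", 600_000, 600_100), "decreased"),
        ]
        c = classify_peaks(peaks, te, assembly, 100_000)
        assert c["on_retrotransposon"] == 2
        assert c["subtelomeric"] == 2
        assert c["subtelomeric_retrotransposon"] == 1
        assert c["other"] == 1
        # 2x2 cells sum to total; conjunction bounded by both margins
        assert (c["subtelomeric_retrotransposon"] + c["te_only"]
                + c["subtelomeric_only"] + c["other"]) == c["total"]
        assert c["subtelomeric_retrotransposon"] <= min(
            c["on_retrotransposon"], c["subtelomeric"])

    def test_single_base_overlap_counts(self, assembly, te):
        peak = PeakRecord(GenomicInterval("chr1", 10_999, 12_000), "increased")
        assert classify_peaks([peak], te, assembly, 1000)[
            "on_retrotransposon"] == 1
        peak = PeakRecord(GenomicInterval("chr1", 11_000, 12_000), "increased")
        assert classify_peaks([peak], te, assembly, 1000)[
            "on_retrotransposon"] == 0

    def test_subtelomeric_percentage_of_printed_counts(self, assembly):
        """512 decreased peaks of which 200 subtelomeric give 39% (39.06)."""
        peaks = []
        for i in range(200):  # inside the 100 kb window
            s = 10_000 + i * 100
            peaks.append(PeakRecord(GenomicInterval("chr1", s, s + 50),
                                    "decreased"))
        for i in range(312):  # mid-chromosome
            s = 300_000 + i * 100
            peaks.append(PeakRecord(GenomicInterval("chr1", s, s + 50),
                                    "decreased"))
        c = classify_peaks(peaks, [], assembly, 100_000)
        assert c["total"] == 512 and c["subtelomeric"] == 200
        assert c["subtelomeric_percent"] == pytest.approx(39.0625)
        assert round(c["subtelomeric_percent"]) == 39


class TestMetagene:
    def test_median_of_flanking_genes(self):
        genes = [make_gene(f"g{i}", "chr1", 100_000 + i * 30_000)
                 for i in range(3)]
        # gene TSSs at 100k, 130k, 160k; peak right of all of them
        peaks = [PeakRecord(GenomicInterval("chr1", 200_000, 201_000),
                            "decreased")]
        fc = {"g0": 1.0, "g1": 2.0, "g2": 3.0}
        table = metagene_flanking_fc(peaks, genes, fc, [150_000])
        row = table[(table.direction == "decreased")
                    & (table.side == "5prime")].iloc[0]
        assert row.n_genes == 3 and row.median_log2fc == 2.0
        row3 = table[(table.direction == "decreased")
                     & (table.side == "3prime")].iloc[0]
        assert row3.n_genes == 0 and np.isnan(row3.median_log2fc)

    def test_no_peaks_gives_empty_cells(self):
        genes = [make_gene("g0", "chr1", 100_000)]
        table = metagene_flanking_fc([], genes, {"g0": 1.0}, [10_000])
        assert (table.n_genes == 0).all()
        assert table.median_log2fc.isna().all()

    def test_window_boundary_is_inclusive(self):
        genes = [make_gene("g0", "chr1", 100_000)]
        peak = PeakRecord(GenomicInterval("chr1", 150_000, 151_000),
                          "increased")
        # TSS at 100000, peak start 150000, distance exactly 50000
        t = metagene_flanking_fc([peak], genes, {"g0": 1.0}, [50_000])
        row = t[(t.direction == "increased") & (t.side == "5prime")].iloc[0]
        assert row.n_genes == 1
        t2 = metagene_flanking_fc([peak], genes, {"g0": 1.0}, [49_999])
        row2 = t2[(t2.direction == "increased") & (t2.side == "5prime")].iloc[0]
        assert row2.n_genes == 0

    def test_planted_signal_decays_with_window(self, rng):
        """Genes planted at +1 log2FC next to decreased peaks dominate small
        windows; distant background genes at 0 pull large-window medians
        toward 0."""
        genes, fc = [], {}
        peaks = []
        for i in range(10):
            base = 1_000_000 * i + 500_000
            peaks.append(PeakRecord(
                GenomicInterval("chr1", base, base + 1_000), "decreased"))
            near = make_gene(f"near{i}", "chr1", base - 5_000, length=2_000)
            genes.append(near)
            fc[near.id] = 1.0
            for j in range(3):
                far = make_gene(f"far{i}_{j}", "chr1",
                                base - 400_000 - j * 50_000, length=2_000)
                genes.append(far)
                fc[far.id] = 0.0
        table = metagene_flanking_fc(peaks, genes, fc, [10_000, 1_000_000])
        small = table[(table.side == "5prime")
                      & (table.window_bp == 10_000)
                      & (table.direction == "decreased")].iloc[0]
        large = table[(table.side == "5prime")
                      & (table.window_bp == 1_000_000)
                      & (table.direction == "decreased")].iloc[0]
        assert small.median_log2fc == 1.0
        assert large.median_log2fc == 0.0

    def test_invariant_to_peak_order(self, rng):
        genes = [make_gene(f"g{i}", "chr1", 50_000 * (i + 1)) for i in range(8)]
        fc = {g.id: float(i) for i, g in enumerate(genes)}
        peaks = [PeakRecord(GenomicInterval("chr1", 120_000 + 30_000 * i,
                                            121_000 + 30_000 * i), "decreased")
                 for i in range(5)]
        t1 = metagene_flanking_fc(peaks, genes, fc, [40_000, 80_000])
        t2 = metagene_flanking_fc(peaks[::-1], genes, fc, [40_000, 80_000])
        assert t1.equals(t2)
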