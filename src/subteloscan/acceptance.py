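"""Self-contained validation studies over the pipeline's synthetic data.

Each function recomputes one headline quantity from scratch — simulating the
inputs, running the analysis, and measuring the result — and is shared by the
test suite and the reproduction script.
"""

from __future__ import annotations

import filecmp
import math
from fractions import Fraction
from pathlib import Path

import numpy as np

from .chip import PeakRecord, classify_peaks, classify_telomeric_batch
from .genome import (
    ChromosomeRecord,
    GeneCategoryIndex,
    GenomeAssembly,
    GenomicInterval,
)
from .hic import arm_window_counts, estimate_boost, parse_valid_pairs
from .retro import InsertionCall, classify_insertion_family, insertion_burden_test
from .simulate import (
    InsertionSpec,
    PairSpec,
    ReadSpec,
    SimulationConfig,
    VariantSpec,
    planted_config,
    simulate_enrichment_table,
    simulate_reads,
    simulate_valid_pairs,
    synthetic_consensus_library,
)
from .te_enrichment import fisher_enrichment


def peak_tally_worked_example() -> float:
    """Subtelomeric percentage of 512 decreased peaks of which 200 lie in the
    subtelomere (and 123 of those on retrotransposons), via the peak tally."""
    assembly = GenomeAssembly([ChromosomeRecord("chr1", 1_000_000)])
    window = 100_000
    peaks, tes = [], []
    for i in range(200):  # subtelomeric peaks; first 123 on a TE copy
        s = 1_000 + i * 400
        peaks.append(PeakRecord(GenomicInterval("chr1", s, s + 200),
                                "decreased"))
        if i < 123:
            from .te_enrichment import TEInstanceRecord

            tes.append(TEInstanceRecord(
                f"te{i}", GenomicInterval("chr1", s + 50, s + 150),
                "L1MdTf_I", "LINE"))
    for i in range(312):  # interior peaks, off any TE
        s = 400_000 + i * 300
        peaks.append(PeakRecord(GenomicInterval("chr1", s, s + 200),
                                "decreased"))
    tally = classify_peaks(peaks, tes, assembly, window)
    assert tally["total"] == 512 and tally["subtelomeric"] == 200
    assert tally["subtelomeric_retrotransposon"] == 123
    return tally["subtelomeric_percent"]


def fisher_oracle_sweep(max_n: int = 30) -> float:
    """Max |p_implementation - p_enumeration| over every 2x2 table with
    total count <= max_n; the oracle enumerates fixed-margin tables with
    Fraction arithmetic."""
    worst = 0.0
    for n in range(0, max_n + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    _, p = fisher_enrichment(a, b, c, d)
                    r1, r2, c1 = a + b, c + d, a + c
                    if r1 + r2 == 0:
                        oracle = 1.0
                    else:
                        lo, hi = max(0, c1 - r2), min(r1, c1)
                        total = math.comb(r1 + r2, c1)
                        probs = [
                            Fraction(math.comb(r1, k) * math.comb(r2, c1 - k),
                                     total)
                            for k in range(lo, hi + 1)
                        ]
                        p_obs = probs[a - lo]
                        oracle = float(min(
                            Fraction(1),
                            sum(q for q in probs if q <= p_obs)))
                    worst = max(worst, abs(p - oracle))
    return worst


def null_type_one_error(seed: int, n_reps: int = 1_000,
                        n_background: int = 3_000, n_de: int = 300,
                        subtelomere_fraction: float = 0.1) -> float:
    """Fraction of unadjusted p < 0.05 under the null generator (no
    positional bias), at genome-scale table sizes."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        table = simulate_enrichment_table(
            n_background, n_de, subtelomere_fraction, 1.0, rng)
        hits += fisher_enrichment(*table)[1] < 0.05
    return hits / n_reps


def planted_enrichment_power(seed: int, n_reps: int = 200,
                             n_background: int = 950, n_de: int = 50,
                             subtelomere_fraction: float = 0.1,
                             factor: float = 5.0) -> float:
    """Detection rate (p < 0.05) with a planted enrichment factor."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        table = simulate_enrichment_table(
            n_background, n_de, subtelomere_fraction, factor, rng)
        hits += fisher_enrichment(*table)[1] < 0.05
    return hits / n_reps


def telomeric_read_recovery(seed: int, n_reads: int = 100_000
                            ) -> tuple[float, float]:
    """(label recovery rate on planted telomeric reads at substitution 0,
    false-positive rate on uniform-random reads)."""
    cfg = SimulationConfig(seed=seed)
    cfg.reads = ReadSpec(n_reads=n_reads, telomeric_fraction=0.01,
                         substitution_rate=0.0)
    reads, truth = simulate_reads(cfg)
    hits = classify_telomeric_batch([s for _, s in reads])
    called = {rid for (rid, _), h in zip(reads, hits) if h}
    recovery = 1.0 if not truth else len(called & truth) / len(truth)
    false_calls = len(called - truth)
    n_background = n_reads - len(truth)
    return recovery, false_calls / n_background


def insertion_family_recovery(seed: int, n_insertions: int = 500,
                              substitution_rate: float = 0.05,
                              length: int = 300, k: int = 15) -> float:
    """Fraction of consensus-derived insertions assigned to their true
    family at the package defaults."""
    library = synthetic_consensus_library()
    rng = np.random.default_rng(seed)
    families = [f for f in library
                if len(library.entries[f]) >= length + 10]
    correct = 0
    for _ in range(n_insertions):
        fam = families[int(rng.integers(0, len(families)))]
        consensus = library.entries[fam]
        start = int(rng.integers(0, len(consensus) - length))
        seq = list(consensus[start:start + length])
        for j in range(length):
            if rng.random() < substitution_rate:
                seq[j] = "ACGT"[("ACGT".index(seq[j])
                                 + int(rng.integers(1, 4))) % 4]
        if rng.random() < 0.5:
            from .retro import reverse_complement

            seq = list(reverse_complement("".join(seq)))
        a = classify_insertion_family(InsertionCall("chr1", 1, "".join(seq)),
                                      library, k=k)
        correct += a.family == fam
    return correct / n_insertions


def burden_oracle_sweep(max_n: int = 60) -> float:
    """Max |p - enumeration| for the equal-exposure burden test over every
    split of every total n <= max_n."""
    worst = 0.0
    for n in range(1, max_n + 1):
        pmf = [Fraction(math.comb(n, k), 2 ** n) for k in range(n + 1)]
        for k in range(n + 1):
            oracle = float(min(Fraction(1),
                               sum(q for q in pmf if q <= pmf[k])))
            worst = max(worst, abs(insertion_burden_test(k, n - k) - oracle))
    return worst


def hic_boost_recovery(seed: int, n_pairs: int = 100_000,
                       boost: float = 2.0) -> float:
    """Planted subtelomeric anchor boost recovered from arm-window counts of
    a boosted vs a neutral sample."""
    cfg = SimulationConfig(seed=seed)
    assembly = cfg.assembly()
    zone = cfg.scaled(5_000_000)
    exclusion = cfg.scaled(100_000)
    runs = {}
    for b in (1.0, boost):
        cfg.pairs = PairSpec(n_pairs=n_pairs, boost=b)
        lines, _ = simulate_valid_pairs(cfg, assembly)
        pairs, stats = parse_valid_pairs(lines, assembly)
        counts = arm_window_counts(pairs, assembly, [zone], exclusion,
                                   cis_only=True)
        runs[b] = (counts, stats.n_pairs)
    return estimate_boost(runs[boost][0], runs[1.0][0],
                          runs[boost][1], runs[1.0][1], zone)


def category_partition_mismatches(seed: int, n_positions: int = 10_000) -> int:
    """Positions of a simulated genome where the interval-index classifier
    disagrees with a brute-force per-gene linear scan."""
    from .genome import GenomicCategory

    genome_cfg = SimulationConfig(seed=seed)
    from .simulate import simulate_genome

    genome = simulate_genome(genome_cfg)
    index = GeneCategoryIndex(genome.genes)
    rng = np.random.default_rng(seed + 1)
    names = genome.assembly.names
    mismatches = 0
    for _ in range(n_positions):
        chrom = names[int(rng.integers(0, len(names)))]
        pos = int(rng.integers(0, genome.assembly[chrom].length))
        if index.classify(chrom, pos) != _brute_force(pos, chrom,
                                                      genome.genes):
            mismatches += 1
    return mismatches


def _brute_force(pos, chrom, genes, promoter_radius=2_000, proximal=10_000,
                 distal=100_000):
    from .genome import GenomicCategory as C

    on_chrom = [g for g in genes if g.body.chrom == chrom]
    for g in on_chrom:
        if abs(pos - g.tss) < promoter_radius:
            return C.PROMOTER
    for g in on_chrom:
        for ex in g.exons:
            if ex.start <= pos < ex.end:
                return C.EXON
    for g in on_chrom:
        if g.body.start <= pos < g.body.end:
            return C.INTRON
    if not on_chrom:
        return C.GENE_DESERT
    best = None
    for g in on_chrom:
        d = (g.body.start - pos) if pos < g.body.start else pos - (g.body.end - 1)
        key = (d, abs(pos - g.tss), g.id)
        if best is None or key < best[0]:
            best = (key, g, d)
    _, gene, d = best
    if d > distal:
        return C.GENE_DESERT
    left = pos < gene.body.start
    upstream = left if gene.strand == "+" else not left
    if upstream:
        if d < promoter_radius:
            return C.INTERGENIC_OTHER
        return (C.FIVE_PRIME_PROXIMAL if d < proximal
                else C.FIVE_PRIME_DISTAL if d <= distal
                else C.GENE_DESERT)
    return (C.THREE_PRIME_PROXIMAL if d < proximal
            else C.THREE_PRIME_DISTAL if d <= distal
            else C.GENE_DESERT)


def run_all_determinism(seed: int, workdir: str | Path) -> bool:
    """Whether two same-seed pipeline runs produce byte-identical tables."""
    from .pipeline import RunConfig, run_pipeline

    workdir = Path(workdir)
    outputs = []
    for tag in ("a", "b"):
        sim = planted_config(seed)
        sim.reads = ReadSpec(n_reads=5_000, telomeric_fraction=0.01)
        sim.pairs = PairSpec(n_pairs=20_000, boost=2.0)
        sim.variants = VariantSpec(n_baseline=100, n_case=200)
        sim.insertions = InsertionSpec(n_case=30, n_shared=20)
        cfg = RunConfig(seed=seed, outdir=str(workdir / tag), sim=sim)
        run_pipeline(cfg)
        outputs.append(sorted((workdir / tag / "tables").glob("*.tsv")))
    names_a = [p.name for p in outputs[0]]
    names_b = [p.name for p in outputs[1]]
    if names_a != names_b or not names_a:
        return False
    return all(filecmp.cmp(x, y, shallow=False)
               for x, y in zip(outputs[0], outputs[1]))


def variant_spectrum_chisq(seed: int, n_case: int = 5_000) -> float:
    """Chi-square goodness-of-fit p of the recovered somatic variant category
    spectrum against the planted weights."""
    from scipy import stats as sps

    from .simulate import simulate_genome, simulate_variants_and_insertions
    from .variants import subtract_baseline, variant_category_counts, VariantRecord

    cfg = SimulationConfig(seed=seed)
    cfg.variants = VariantSpec(n_baseline=100, n_case=n_case)
    cfg.insertions = InsertionSpec(n_case=5, n_shared=5)
    genome = simulate_genome(cfg)
    library = synthetic_consensus_library()
    case_rows, control_rows, truth = simulate_variants_and_insertions(
        cfg, genome, library)
    to_record = lambda rows: [
        VariantRecord(r[0], r[1], r[3], r[4])
        for r in rows if not r[4].startswith("<")
    ]
    somatic = subtract_baseline(to_record(case_rows), to_record(control_rows))
    index = GeneCategoryIndex(genome.genes)
    counts, _ = variant_category_counts(somatic, index, genome.assembly)
    observed = counts.sum(axis=1)
    weights = cfg.variants.category_weights
    cats = [c for c in observed.index if weights.get(c, 0) > 0]
    obs = observed[cats].to_numpy(float)
    exp = np.array([weights[c] for c in cats]) * obs.sum()
    return float(sps.chisquare(obs, exp).pvalue)
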