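"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np
import pytest

from subteloscan.genome import (
    ChromosomeRecord,
    GenomeAssembly,
    GeneModel,
    GenomicCategory,
    GenomicInterval,
)


@pytest.fixture
def assembly() -> GenomeAssembly:
    return GenomeAssembly(
        [
            ChromosomeRecord("chr1", 2_000_000),
            ChromosomeRecord("chr2", 1_000_000),
            ChromosomeRecord("chr3", 400_000),
        ]
    )


def make_gene(gid, chrom, start, length=20_000, strand="+", n_exons=2):
    body = GenomicInterval(chrom, start, start + length, strand)
    ex_len = length // (2 * n_exons)
    exons = tuple(
        GenomicInterval(chrom, start + i * (length // n_exons),
                        start + i * (length // n_exons) + ex_len, strand)
        for i in range(n_exons)
    )
    return GeneModel(gid, body, exons)


@pytest.fixture
def gene_set():
    # two genes on chr1 far apart, one minus-strand gene on chr2; chr3 empty
    return [
        make_gene("gA", "chr1", 500_000, strand="+"),
        make_gene("gB", "chr1", 1_200_000, strand="+"),
        make_gene("gC", "chr2", 400_000, strand="-"),
    ]


# ------------------------------------------------------- independent oracles

def brute_force_category(pos, chrom, genes, promoter_radius=2_000,
                         proximal=10_000, distal=100_000):
    """Linear-scan reference classifier: same contract as GeneCategoryIndex,
    written as a plain per-gene loop."""
    on_chrom = [g for g in genes if g.body.chrom == chrom]
    for g in on_chrom:
        if abs(pos - g.tss) < promoter_radius:
            return GenomicCategory.PROMOTER
    for g in on_chrom:
        for ex in g.exons:
            if ex.start <= pos < ex.end:
                return GenomicCategory.EXON
    for g in on_chrom:
        if g.body.start <= pos < g.body.end:
            return GenomicCategory.INTRON
    if not on_chrom:
        return GenomicCategory.GENE_DESERT
    best = None
    for g in on_chrom:
        if pos < g.body.start:
            d = g.body.start - pos
        else:
            d = pos - (g.body.end - 1)
        key = (d, abs(pos - g.tss), g.id)
        if best is None or key < best[0]:
            best = (key, g, d)
    _, gene, d = best
    if d > distal:
        return GenomicCategory.GENE_DESERT
    left_of_gene = pos < gene.body.start
    upstream = left_of_gene if gene.strand == "+" else not left_of_gene
    if upstream:
        if d < promoter_radius:
            return GenomicCategory.INTERGENIC_OTHER
        if d < proximal:
            return GenomicCategory.FIVE_PRIME_PROXIMAL
        if d <= distal:
            return GenomicCategory.FIVE_PRIME_DISTAL
    else:
        if d < proximal:
            return GenomicCategory.THREE_PRIME_PROXIMAL
        if d <= distal:
            return GenomicCategory.THREE_PRIME_DISTAL
    return GenomicCategory.INTERGENIC_OTHER


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by full fixed-margin enumeration, using the
    factorial form of the hypergeometric probability and Fraction arithmetic
    (independent of the package's binomial-coefficient route)."""
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if n == 0:
        return 1.0

    def prob(k):
        # table (k, r1-k, c1-k, r2-c1+k)
        return Fraction(
            factorial(r1) * factorial(r2) * factorial(c1) * factorial(c2),
            factorial(n) * factorial(k) * factorial(r1 - k)
            * factorial(c1 - k) * factorial(r2 - c1 + k),
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return float(sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs))


def binom_two_sided_oracle(k, n, p=0.5):
    """Two-sided exact binomial p by pmf enumeration with Fractions."""
    pf = Fraction(*Fraction(p).as_integer_ratio())

    def pmf(i):
        return (Fraction(factorial(n), factorial(i) * factorial(n - i))
                * pf ** i * (1 - pf) ** (n - i))

    p_obs = pmf(k)
    return float(min(1, sum(pmf(i) for i in range(n + 1) if pmf(i) <= p_obs)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
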