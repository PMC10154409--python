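"""Genome coordinate frame: chromosome-end distances, subtelomere membership,
arm assignment, and the gene-relative genomic-category classifier.

All internal coordinates are 0-based half-open (BED convention).  Distances to
chromosome ends treat both ends identically: mouse chromosomes are acrocentric
and the analyses this package implements never distinguish p from q ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree


class CoordinateError(ValueError):
    """A position or interval falls outside its chromosome."""


@dataclass(frozen=True)
class ChromosomeRecord:
    name: str
    length: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("chromosome name must be non-empty")
        if self.length <= 0:
            raise ValueError(f"chromosome length must be > 0, got {self.length}")


class GenomeAssembly:
    """Ordered collection of chromosomes with unique names."""

    def __init__(self, chromosomes: Iterable[ChromosomeRecord]):
        self.chromosomes: list[ChromosomeRecord] = list(chromosomes)
        if not self.chromosomes:
            raise ValueError("assembly needs at least one chromosome")
        self._by_name = {c.name: c for c in self.chromosomes}
        if len(self._by_name) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names in assembly")

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __getitem__(self, name: str) -> ChromosomeRecord:
        try:
            return self._by_name[name]
        except KeyError:
            raise LookupError(f"unknown chromosome {name!r}") from None

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene body with exons; the TSS is the strand-aware 5' base."""

    id: str
    body: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.body.strand == ".":
            warnings.warn(
                f"gene {self.id} is unstranded; treating as + strand",
                stacklevel=2,
            )
            object.__setattr__(
                self,
                "body",
                GenomicInterval(self.body.chrom, self.body.start, self.body.end, "+"),
            )
        for ex in self.exons:
            if not (
                ex.chrom == self.body.chrom
                and self.body.start <= ex.start
                and ex.end <= self.body.end
            ):
                raise ValueError(f"exon {ex} outside gene body of {self.id}")

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.body.start if self.strand == "+" else self.body.end - 1


class GenomicCategory(str, Enum):
    PROMOTER = "promoter"
    FIVE_PRIME_PROXIMAL = "five_prime_proximal"
    FIVE_PRIME_DISTAL = "five_prime_distal"
    EXON = "exon"
    INTRON = "intron"
    THREE_PRIME_PROXIMAL = "three_prime_proximal"
    THREE_PRIME_DISTAL = "three_prime_distal"
    GENE_DESERT = "gene_desert"
    INTERGENIC_OTHER = "intergenic_other"


CATEGORY_ORDER: tuple[GenomicCategory, ...] = tuple(GenomicCategory)


def distance_to_nearest_end(position: int, chrom: ChromosomeRecord) -> int:
    """Distance in bp from a 0-based position to the nearer chromosome end.

    Symmetric in the two ends: positions 0 and length-1 are both at distance 0.
    """
    if not 0 <= position < chrom.length:
        raise CoordinateError(
            f"position {position} outside {chrom.name} (length {chrom.length})"
        )
    return min(position, chrom.length - 1 - position)


def is_subtelomeric(
    interval: GenomicInterval,
    assembly: GenomeAssembly,
    threshold: int,
    *,
    reference_point: str = "start",
) -> bool:
    """Whether an interval lies within ``threshold`` bp of a chromosome end.

    The interval's reference point (its start by default; "midpoint" also
    supported) must be strictly closer than ``threshold`` to either end.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    chrom = assembly[interval.chrom]
    if interval.end > chrom.length:
        raise CoordinateError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} "
            f"extends past chromosome length {chrom.length}"
        )
    if reference_point == "start":
        point = interval.start
    elif reference_point == "midpoint":
        point = (interval.start + interval.end - 1) // 2
    else:
        raise ValueError(f"unknown reference_point {reference_point!r}")
    return distance_to_nearest_end(point, chrom) < threshold


def arm_of(position: int, chrom: ChromosomeRecord) -> str:
    """Assign a position to the ``left`` or ``right`` chromosome arm.

    The exact midpoint goes left (deterministic tie rule).
    """
    if not 0 <= position < chrom.length:
        raise CoordinateError(
            f"position {position} outside {chrom.name} (length {chrom.length})"
        )
    return "left" if 2 * position <= chrom.length else "right"


# Flank-window defaults in bp: promoter +/-2 kb around the TSS, 5' windows
# 2-10 kb and 10-100 kb upstream, 3' windows 0-10 kb and 10-100 kb downstream,
# gene desert strictly beyond 100 kb from the nearest gene.
PROMOTER_RADIUS = 2_000
PROXIMAL_BP = 10_000
DISTAL_BP = 100_000


def _flank_category(distance: int, side: str,
                    promoter_radius: int, proximal: int, distal: int):
    """Category for an intergenic position ``distance`` bp from its nearest
    gene on the given gene-relative side ('upstream' or 'downstream')."""
    if side == "upstream":
        if distance < promoter_radius:
            # upstream distance equals TSS distance, so these positions are
            # promoters and are caught earlier; defensive fallthrough
            return GenomicCategory.INTERGENIC_OTHER
        if distance < proximal:
            return GenomicCategory.FIVE_PRIME_PROXIMAL
        if distance <= distal:
            return GenomicCategory.FIVE_PRIME_DISTAL
    else:
        if distance < proximal:
            return GenomicCategory.THREE_PRIME_PROXIMAL
        if distance <= distal:
            return GenomicCategory.THREE_PRIME_DISTAL
    return GenomicCategory.INTERGENIC_OTHER


def _gene_side_and_distance(pos: int, gene: GeneModel) -> tuple[str, int]:
    """Gene-relative side and bp distance from an intergenic position to the
    gene body edge (0-based inclusive last base)."""
    if pos < gene.body.start:
        gap = gene.body.start - pos
        genomic_side = "left"
    else:
        gap = pos - (gene.body.end - 1)
        genomic_side = "right"
    if gene.strand == "+":
        side = "upstream" if genomic_side == "left" else "downstream"
    else:
        side = "upstream" if genomic_side == "right" else "downstream"
    return side, gap


class GeneCategoryIndex:
    """Interval-indexed classifier assigning every genomic position exactly one
    :class:`GenomicCategory`.

    Precedence: promoter (within ``promoter_radius`` of any TSS, both sides,
    strand-agnostic) > exon > intron > strand-aware flank windows of the
    nearest gene > gene desert (> ``distal`` bp from every gene).  Positions
    within ``distal`` of a gene but outside every named window fall into
    ``intergenic_other``.
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        *,
        promoter_radius: int = PROMOTER_RADIUS,
        proximal: int = PROXIMAL_BP,
        distal: int = DISTAL_BP,
    ):
        self.genes = list(genes)
        self.promoter_radius = promoter_radius
        self.proximal = proximal
        self.distal = distal
        self._exons: dict[str, IntervalTree] = {}
        self._bodies: dict[str, IntervalTree] = {}
        self._tss: dict[str, np.ndarray] = {}
        self._edges: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.body.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            self._bodies[chrom] = IntervalTree.from_tuples(
                (g.body.start, g.body.end, g) for g in gs
            )
            exon_tuples = [
                (ex.start, ex.end, g.id) for g in gs for ex in g.exons
            ]
            self._exons[chrom] = (
                IntervalTree.from_tuples(exon_tuples) if exon_tuples else IntervalTree()
            )
            self._tss[chrom] = np.sort(np.array([g.tss for g in gs], dtype=np.int64))
            # genes sorted by start for nearest-gene search
            order = sorted(gs, key=lambda g: (g.body.start, g.body.end, g.id))
            starts = np.array([g.body.start for g in order], dtype=np.int64)
            self._edges[chrom] = (starts, np.array(order, dtype=object))

    def _nearest_gene(self, chrom: str, pos: int) -> tuple[GeneModel, int] | None:
        entry = self._edges.get(chrom)
        if entry is None:
            return None
        starts, order = entry
        i = int(np.searchsorted(starts, pos))
        best: tuple[int, int, str, GeneModel] | None = None
        # scan a neighbourhood around the insertion point; gene bodies may
        # overlap, so look a few genes in both directions
        for j in range(max(0, i - 4), min(len(order), i + 4)):
            g = order[j]
            if g.body.start <= pos < g.body.end:
                d = 0
            elif pos < g.body.start:
                d = g.body.start - pos
            else:
                d = pos - (g.body.end - 1)
            tss_d = abs(pos - g.tss)
            key = (d, tss_d, g.id, g)
            if best is None or key[:3] < best[:3]:
                best = key
        if best is None:
            return None
        return best[3], best[0]

    def classify(self, chrom: str, pos: int) -> GenomicCategory:
        tss = self._tss.get(chrom)
        if tss is not None and tss.size:
            i = int(np.searchsorted(tss, pos))
            for j in (i - 1, i):
                if 0 <= j < tss.size and abs(pos - int(tss[j])) < self.promoter_radius:
                    return GenomicCategory.PROMOTER
        exons = self._exons.get(chrom)
        if exons is not None and exons.overlaps(pos):
            return GenomicCategory.EXON
        bodies = self._bodies.get(chrom)
        if bodies is not None and bodies.overlaps(pos):
            return GenomicCategory.INTRON
        nearest = self._nearest_gene(chrom, pos)
        if nearest is None:
            return GenomicCategory.GENE_DESERT
        gene, d = nearest
        if d > self.distal:
            return GenomicCategory.GENE_DESERT
        side, gap = _gene_side_and_distance(pos, gene)
        return _flank_category(gap, side, self.promoter_radius, self.proximal,
                               self.distal)

    def classify_many(self, chrom: str, positions: Iterable[int]) -> list[GenomicCategory]:
        return [self.classify(chrom, p) for p in positions]


def classify_genomic_category(
    position: int,
    chrom: str,
    genes: Sequence[GeneModel] | GeneCategoryIndex,
) -> GenomicCategory:
    """Classify one position; builds a throwaway index when given a raw gene
    list (use :class:`GeneCategoryIndex` directly for many queries)."""
    index = genes if isinstance(genes, GeneCategoryIndex) else GeneCategoryIndex(genes)
    return index.classify(chrom, position)
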