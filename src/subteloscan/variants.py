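"""Variant spectra relative to a wild-type baseline.

Case variant calls are normalised against the matched wild-type sample by
exact-allele subtraction, then tallied into gene-relative genomic categories
(promoter, 5'/3' proximal and distal flanks, exon, intron, gene desert) and
into single-base-substitution classes, optionally collapsed to the
pyrimidine-reference convention.  Copy-number segments are filtered on read
depth (strictly greater than the cutoff).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .genome import (
    CATEGORY_ORDER,
    GeneCategoryIndex,
    GenomeAssembly,
    GenomicCategory,
    GenomicInterval,
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
NUCLEOTIDES = ("A", "C", "G", "T")

#: the 12 directional substitution classes, reference > alternate
SBS_CLASSES = tuple(
    f"{r}>{a}" for r in NUCLEOTIDES for a in NUCLEOTIDES if r != a
)
#: the 6 pyrimidine-reference collapsed classes
SBS_COLLAPSED = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass(frozen=True)
class VariantRecord:
    """One SNV or indel call in the 1-based VCF frame."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def vtype(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def pos0(self) -> int:
        """0-based leftmost affected base."""
        return self.pos - 1


@dataclass(frozen=True)
class CNVSegment:
    interval: GenomicInterval
    ratio: float  # copy-number fold change vs control
    depth: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("CNV ratio must be > 0")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


def subtract_baseline(
    case: Iterable[VariantRecord],
    control: Iterable[VariantRecord],
    *,
    match: str = "allele",
) -> list[VariantRecord]:
    """Case variants with no matching control (wild-type) variant.

    ``match='allele'`` requires identical (chrom, pos, ref, alt);
    ``match='position'`` matches on (chrom, pos) only, tolerating indel
    representation drift between callers.
    """
    if match == "allele":
        seen = {v.key for v in control}
        return [v for v in case if v.key not in seen]
    if match == "position":
        seen = {(v.chrom, v.pos) for v in control}
        return [v for v in case if (v.chrom, v.pos) not in seen]
    raise ValueError(f"unknown match mode {match!r}")


def variant_category_counts(
    variants: Iterable[VariantRecord],
    index: GeneCategoryIndex,
    assembly: GenomeAssembly,
) -> tuple[pd.DataFrame, int]:
    """Count variants per (genomic category x variant type).

    Each variant is classified at its leftmost affected base.  Returns the
    category-by-{SNV, indel} count matrix (all categories present, zero
    filled) and the number of variants skipped for lying on chromosomes
    absent from the assembly.
    """
    counts = pd.DataFrame(
        0,
        index=pd.Index([c.value for c in CATEGORY_ORDER], name="category"),
        columns=["SNV", "indel"],
    )
    skipped = 0
    for v in variants:
        if v.chrom not in assembly:
            skipped += 1
            continue
        cat = index.classify(v.chrom, v.pos0)
        counts.loc[cat.value, v.vtype] += 1
    if skipped:
        warnings.warn(f"{skipped} variants on unknown chromosomes skipped")
    return counts, skipped


def classify_sbs(ref: str, alt: str, *, collapse: bool = False) -> str:
    """Directional substitution class ``ref>alt``; with ``collapse=True``,
    purine-reference classes are mapped to their reverse complement so every
    class has a pyrimidine (C or T) reference."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"ambiguity codes not supported: {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if collapse and ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def sbs_spectrum(
    variants: Iterable[VariantRecord], *, collapse: bool = False
) -> pd.Series:
    """SBS class counts over the SNVs in ``variants`` (indels ignored)."""
    classes = SBS_COLLAPSED if collapse else SBS_CLASSES
    counts = pd.Series(0, index=pd.Index(classes, name="sbs_class"))
    for v in variants:
        if v.vtype == "SNV":
            counts[classify_sbs(v.ref, v.alt, collapse=collapse)] += 1
    return counts


def filter_cnv_segments(
    segments: Sequence[CNVSegment], min_depth: float = 10.0
) -> list[CNVSegment]:
    """Keep segments with depth strictly greater than ``min_depth``
    (low-confidence regions removed); order preserved."""
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    return [s for s in segments if s.depth > min_depth]


def read_cnv_segments(path) -> list[CNVSegment]:
    """Read a CNV segment TSV (chrom, start, end, ratio, depth)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        CNVSegment(
            GenomicInterval(r.chrom, int(r.start), int(r.end)),
            float(r.ratio),
            float(r.depth),
        )
        for r in df.itertuples()
    ]
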