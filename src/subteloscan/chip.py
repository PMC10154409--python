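"""Telomeric-repeat read quantification and H3K9me3 peak classification.

A read is telomeric when, after trying all six phase offsets of the TTAGGG
hexamer on the forward strand and six on the reverse complement, whole repeat
units matching with at most ``max_mismatches_per_unit`` mismatches cover at
least ``min_coverage_fraction`` of the read.  This aligner-free rule replaces
mapping reads to a (TTAGGG)n reference, whose seed parameters do not transfer
between aligners.  Telomeric abundance is reported per million total reads.

Peaks that lose the H3K9me3 heterochromatin mark are classified by whether
they overlap a retrotransposon copy and whether they lie in the subtelomere,
and the flanking-gene metagene reports the median expression log2 fold change
of genes around peaks at growing window sizes.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import GeneModel, GenomeAssembly, GenomicInterval, is_subtelomeric
from .retro import reverse_complement
from .te_enrichment import TEInstanceRecord

_BASE_CODE = {65: 0, 67: 1, 71: 2, 84: 3, 78: 4}  # A C G T N


@dataclass(frozen=True)
class TelomericReadParams:
    repeat_unit: str = "TTAGGG"
    min_coverage_fraction: float = 0.7
    max_mismatches_per_unit: int = 0

    def __post_init__(self) -> None:
        if len(self.repeat_unit) != 6:
            raise ValueError("repeat unit must be a hexamer")
        if not 0 < self.min_coverage_fraction <= 1:
            raise ValueError("coverage fraction must be in (0, 1]")


@dataclass(frozen=True)
class PeakRecord:
    interval: GenomicInterval
    direction: str  # "decreased" or "increased"
    log2fc: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("decreased", "increased"):
            raise ValueError(f"bad peak direction {self.direction!r}")


_TRANSLATE = bytes(_BASE_CODE.get(i, 4) for i in range(256))


def _seq_to_codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii").translate(_TRANSLATE),
                         dtype=np.uint8)


def _best_repeat_coverage(codes: np.ndarray, unit: np.ndarray,
                          max_mm: int) -> float:
    """Best fraction of the read covered by in-frame whole repeat units over
    the 6 phase offsets, for one strand."""
    u = unit.size
    n = codes.size
    best = 0.0
    for offset in range(u):
        n_units = (n - offset) // u
        if n_units == 0:
            continue
        block = codes[offset : offset + n_units * u].reshape(n_units, u)
        mism = (block != unit[None, :]).sum(axis=1)
        matched = int((mism <= max_mm).sum())
        best = max(best, matched * u / n)
    return best


def is_telomeric_read(sequence: str,
                      params: TelomericReadParams = TelomericReadParams()) -> bool:
    """Phase-aware telomeric-repeat classification of one read."""
    seq = sequence.upper()
    if len(seq) < len(params.repeat_unit):
        return False
    unit = _seq_to_codes(params.repeat_unit)
    for s in (seq, reverse_complement(seq)):
        cov = _best_repeat_coverage(_seq_to_codes(s), unit,
                                    params.max_mismatches_per_unit)
        if cov >= params.min_coverage_fraction:
            return True
    return False


def classify_telomeric_batch(
    sequences: Sequence[str],
    params: TelomericReadParams = TelomericReadParams(),
) -> np.ndarray:
    """Vectorised telomeric classification; groups reads by length so each
    (strand, phase) test is one array comparison."""
    result = np.zeros(len(sequences), dtype=bool)
    unit = _seq_to_codes(params.repeat_unit)
    u = unit.size
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(sequences):
        by_len.setdefault(len(s), []).append(i)
    for length, idxs in by_len.items():
        if length < u:
            continue
        mat = np.empty((len(idxs), length), dtype=np.uint8)
        for row, i in enumerate(idxs):
            mat[row] = _seq_to_codes(sequences[i].upper())
        rc = np.empty_like(mat)
        comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
        rc[:] = comp[mat[:, ::-1]]
        hit = np.zeros(len(idxs), dtype=bool)
        for strand_mat in (mat, rc):
            for offset in range(u):
                n_units = (length - offset) // u
                if n_units == 0:
                    continue
                block = strand_mat[:, offset : offset + n_units * u].reshape(
                    len(idxs), n_units, u
                )
                mism = (block != unit[None, None, :]).sum(axis=2)
                matched = (mism <= params.max_mismatches_per_unit).sum(axis=1)
                hit |= matched * u / length >= params.min_coverage_fraction
        result[np.array(idxs)] = hit
    return result


def telomeric_read_rate(
    reads: Iterable[tuple[str, str]],
    params: TelomericReadParams = TelomericReadParams(),
    *,
    batch_size: int = 50_000,
) -> tuple[int, int, float, list[str]]:
    """Count telomeric reads in a stream of (id, sequence).

    Returns (telomeric_count, total_count, per_million, telomeric_ids); the
    rate is normalised to the total number of reads in the sample.
    """
    n_telo = 0
    n_total = 0
    telo_ids: list[str] = []
    ids: list[str] = []
    seqs: list[str] = []

    def flush():
        nonlocal n_telo
        if not seqs:
            return
        hits = classify_telomeric_batch(seqs, params)
        n_telo += int(hits.sum())
        telo_ids.extend(i for i, h in zip(ids, hits) if h)
        ids.clear()
        seqs.clear()

    for rid, seq in reads:
        ids.append(rid)
        seqs.append(seq)
        n_total += 1
        if len(seqs) >= batch_size:
            flush()
    flush()
    if n_total == 0:
        raise ValueError("empty read stream")
    return n_telo, n_total, n_telo / n_total * 1e6, telo_ids


def classify_peaks(
    peaks: Sequence[PeakRecord],
    te_annotation: Sequence[TEInstanceRecord],
    assembly: GenomeAssembly,
    subtelomere_threshold: int,
) -> dict[str, int]:
    """Tally peaks by retrotransposon overlap (any overlap, >= 1 bp) and
    subtelomere membership (peak start within the threshold).

    The two labels are independent; their conjunction is the
    subtelomeric-retrotransposon class, and the four exclusive 2x2 cells
    always sum to the number of peaks.
    """
    trees: dict[str, IntervalTree] = {}
    for te in te_annotation:
        trees.setdefault(te.locus.chrom, IntervalTree()).addi(
            te.locus.start, te.locus.end
        )
    on_te = subtel = both = neither = 0
    for p in peaks:
        tree = trees.get(p.interval.chrom)
        hits_te = bool(tree is not None
                       and tree.overlap(p.interval.start, p.interval.end))
        hits_sub = is_subtelomeric(p.interval, assembly, subtelomere_threshold)
        on_te += hits_te
        subtel += hits_sub
        both += hits_te and hits_sub
        neither += not hits_te and not hits_sub
    n = len(peaks)
    return {
        "total": n,
        "on_retrotransposon": on_te,
        "subtelomeric": subtel,
        "subtelomeric_retrotransposon": both,
        "other": neither,
        "te_only": on_te - both,
        "subtelomeric_only": subtel - both,
        "subtelomeric_percent": 100.0 * subtel / n if n else 0.0,
    }


def metagene_flanking_fc(
    peaks: Sequence[PeakRecord],
    genes: Sequence[GeneModel],
    gene_log2fc: Mapping[str, float],
    windows: Sequence[int],
) -> pd.DataFrame:
    """Median expression log2FC of genes flanking peaks, by peak direction,
    genomic side (5' = left of the peak start, 3' = right of the peak end)
    and window size.

    For window w, a gene contributes on a side when its TSS lies within
    (0, w] bp of the peak boundary on that side; a gene may contribute to
    several peaks.  Cells with no genes are left missing.
    """
    if list(windows) != sorted(windows):
        raise ValueError("windows must be ascending")
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        if g.id in gene_log2fc:
            tss_by_chrom.setdefault(g.body.chrom, []).append((g.tss, g.id))
    for chrom in tss_by_chrom:
        tss_by_chrom[chrom].sort()
    arrays = {
        c: (np.array([t for t, _ in v]), [gid for _, gid in v])
        for c, v in tss_by_chrom.items()
    }
    rows = []
    for direction in ("decreased", "increased"):
        dir_peaks = [p for p in peaks if p.direction == direction]
        for side in ("5prime", "3prime"):
            for w in windows:
                values: list[float] = []
                for p in dir_peaks:
                    entry = arrays.get(p.interval.chrom)
                    if entry is None:
                        continue
                    tss, gids = entry
                    if side == "5prime":
                        lo, hi = p.interval.start - w, p.interval.start  # (0, w] left
                        i0 = int(np.searchsorted(tss, lo, side="left"))
                        i1 = int(np.searchsorted(tss, hi, side="left"))
                    else:
                        last = p.interval.end - 1
                        lo, hi = last + 1, last + w  # (0, w] right of last base
                        i0 = int(np.searchsorted(tss, lo, side="left"))
                        i1 = int(np.searchsorted(tss, hi, side="right"))
                    values.extend(gene_log2fc[gids[j]] for j in range(i0, i1))
                rows.append(
                    {
                        "direction": direction,
                        "side": side,
                        "window_bp": int(w),
                        "n_genes": len(values),
                        "median_log2fc": (
                            statistics.median(values) if values else float("nan")
                        ),
                    }
                )
    return pd.DataFrame(rows)
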