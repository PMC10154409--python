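"""Subtelomeric enrichment of differentially expressed TE instances.

The analysis asks whether transposable-element copies that change expression
after telomere shortening sit closer to chromosome ends than chance predicts.
Instances passing the differential-expression filters (|fold change| above a
cutoff, p below a cutoff, and at least a minimum number of uniquely mapped
reads) are split into subtelomere-adjacent and non-adjacent sets at each
distance threshold; the expected adjacent count comes from the genomic density
of the superfamily's background instances, and significance is a two-sided
Fisher exact test on the DE-vs-background by adjacent-vs-not 2x2 table, with
Benjamini-Hochberg adjustment across the whole threshold scan.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeAssembly, GenomicInterval, is_subtelomeric

# DE filter defaults: fold change > 1.5, p < 0.05, >= 5 uniquely mapped reads.
DEFAULT_FC_CUTOFF = 1.5
DEFAULT_P_CUTOFF = 0.05
DEFAULT_MIN_READS = 5


@dataclass(frozen=True)
class TEInstanceRecord:
    id: str
    locus: GenomicInterval
    family: str
    superfamily: str

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("family must be non-empty")


@dataclass(frozen=True)
class EnrichmentResult:
    superfamily: str
    direction: str
    threshold: int
    observed: int
    expected: float
    odds_ratio: float
    p_value: float
    adjusted_p: float = float("nan")
    n_de: int = 0
    n_background: int = 0


def filter_de_instances(
    table: pd.DataFrame,
    *,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    min_reads: int = DEFAULT_MIN_READS,
    direction: str = "up",
) -> set[str]:
    """Instance ids passing the DE filters in the stated direction.

    ``table`` columns: instance_id, log2fc, pvalue, unique_reads.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if fc_cutoff <= 0 or p_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    if table["instance_id"].duplicated().any():
        raise ValueError("duplicate instance ids in DE table")
    log2_cut = math.log2(fc_cutoff)
    fc = table["log2fc"].to_numpy(float)
    keep = (
        (table["unique_reads"].to_numpy() >= min_reads)
        & (table["pvalue"].to_numpy(float) < p_cutoff)
        & ((fc > log2_cut) if direction == "up" else (fc < -log2_cut))
    )
    return set(table.loc[keep, "instance_id"])


def expressed_instances(table: pd.DataFrame, min_reads: int = DEFAULT_MIN_READS) -> set[str]:
    """Instance ids surviving the unique-read coverage filter (the default
    background universe for the 2x2 test)."""
    return set(table.loc[table["unique_reads"] >= min_reads, "instance_id"])


def split_by_distance(
    instances: Iterable[TEInstanceRecord],
    assembly: GenomeAssembly,
    threshold: int,
) -> tuple[set[TEInstanceRecord], set[TEInstanceRecord]]:
    """Partition instances into (subtelomere-adjacent, non-adjacent) sets."""
    adjacent, non_adjacent = set(), set()
    for te in instances:
        if is_subtelomeric(te.locus, assembly, threshold):
            adjacent.add(te)
        else:
            non_adjacent.add(te)
    return adjacent, non_adjacent


def expected_subtelomeric_count(
    n_de: int, n_background_subtelomeric: int, n_background_total: int
) -> float:
    """DE instances expected in the subtelomere by chance, from the genomic
    density of the background set."""
    if n_background_total <= 0:
        raise ValueError("background total must be > 0")
    if not 0 <= n_background_subtelomeric <= n_background_total:
        raise ValueError("inconsistent background counts")
    return n_de * n_background_subtelomeric / n_background_total


def _hypergeom_pmf_numerators(n_row1: int, n_row2: int, n_col1: int) -> list[int]:
    """Integer numerators of the hypergeometric pmf over all k (common
    denominator C(N, n_col1)); exact arithmetic, no floats."""
    lo = max(0, n_col1 - n_row2)
    hi = min(n_row1, n_col1)
    return [
        math.comb(n_row1, k) * math.comb(n_row2, n_col1 - k)
        for k in range(lo, hi + 1)
    ], lo


def fisher_enrichment(
    de_sub: int, de_nonsub: int, bg_sub: int, bg_nonsub: int
) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table [[de_sub, de_nonsub],
    [bg_sub, bg_nonsub]].

    Returns ``(odds_ratio, p)``.  The p-value is the probability-mass form of
    the two-sided test: the sum, over all tables with the same margins, of
    hypergeometric probabilities no larger than the observed table's.  Exact
    integer arithmetic makes the result identical to full enumeration.
    """
    cells = (de_sub, de_nonsub, bg_sub, bg_nonsub)
    if any(c < 0 for c in cells):
        raise ValueError(f"negative count in table {cells}")
    if de_nonsub * bg_sub == 0:
        odds_ratio = math.inf if de_sub * bg_nonsub > 0 else math.nan
    else:
        odds_ratio = (de_sub * bg_nonsub) / (de_nonsub * bg_sub)
    n_row1, n_row2 = de_sub + de_nonsub, bg_sub + bg_nonsub
    n_col1 = de_sub + bg_sub
    n_total = n_row1 + n_row2
    if n_total == 0:
        return odds_ratio, 1.0
    if n_total <= 2_000:
        # exact integer enumeration (identical to full fixed-margin oracle)
        numerators, lo = _hypergeom_pmf_numerators(n_row1, n_row2, n_col1)
        observed = numerators[de_sub - lo]
        total = math.comb(n_total, n_col1)
        p = sum(v for v in numerators if v <= observed) / total
    else:
        # log-space pmf for large tables; 1e-12 relative tie tolerance
        lo = max(0, n_col1 - n_row2)
        hi = min(n_row1, n_col1)
        ks = np.arange(lo, hi + 1)
        lg = math.lgamma
        log_pmf = np.array(
            [
                lg(n_row1 + 1) - lg(k + 1) - lg(n_row1 - k + 1)
                + lg(n_row2 + 1) - lg(n_col1 - k + 1)
                - lg(n_row2 - n_col1 + k + 1)
                for k in ks
            ]
        ) + (lg(n_col1 + 1) + lg(n_total - n_col1 + 1) - lg(n_total + 1))
        log_obs = log_pmf[de_sub - lo]
        p = float(np.exp(log_pmf[log_pmf <= log_obs + 1e-12]).sum())
    return odds_ratio, min(1.0, p)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (delegates to scipy's FDR control)."""
    if len(p_values) == 0:
        return np.array([])
    return stats.false_discovery_control(np.asarray(p_values, float), method="bh")


def enrichment_scan(
    table: pd.DataFrame,
    instances: Sequence[TEInstanceRecord],
    assembly: GenomeAssembly,
    thresholds: Sequence[int],
    *,
    directions: Sequence[str] = ("up", "down"),
    superfamilies: Sequence[str] | None = None,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    min_reads: int = DEFAULT_MIN_READS,
    background: str = "expressed",
) -> list[EnrichmentResult]:
    """Fisher enrichment for every (superfamily x direction x threshold).

    ``background`` selects the 2x2 universe: ``"expressed"`` (instances
    passing the coverage filter, the default) or ``"annotated"`` (every
    annotated instance of the superfamily).  BH adjustment is applied across
    the whole scan.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    if background not in ("expressed", "annotated"):
        raise ValueError(f"unknown background {background!r}")
    by_id = {te.id: te for te in instances}
    annotated_superfamilies = {te.superfamily for te in instances}
    if superfamilies is None:
        superfamilies = sorted(annotated_superfamilies)
    expressed = expressed_instances(table, min_reads)

    results: list[EnrichmentResult] = []
    for superfamily in superfamilies:
        if superfamily not in annotated_superfamilies:
            warnings.warn(f"superfamily {superfamily!r} absent from annotation; skipped")
            continue
        sf_ids = {i for i, te in by_id.items() if te.superfamily == superfamily}
        universe = sf_ids if background == "annotated" else (sf_ids & expressed)
        for direction in directions:
            de_ids = (
                filter_de_instances(
                    table, fc_cutoff=fc_cutoff, p_cutoff=p_cutoff,
                    min_reads=min_reads, direction=direction,
                )
                & sf_ids
            )
            bg_ids = universe - de_ids
            de_tes = [by_id[i] for i in de_ids if i in by_id]
            bg_tes = [by_id[i] for i in bg_ids]
            for threshold in thresholds:
                de_sub, de_non = split_by_distance(de_tes, assembly, threshold)
                bg_sub, bg_non = split_by_distance(bg_tes, assembly, threshold)
                if len(bg_tes) == 0:
                    expected = 0.0
                else:
                    expected = expected_subtelomeric_count(
                        len(de_tes), len(bg_sub), len(bg_tes)
                    )
                odds_ratio, p = fisher_enrichment(
                    len(de_sub), len(de_non), len(bg_sub), len(bg_non)
                )
                results.append(
                    EnrichmentResult(
                        superfamily=superfamily,
                        direction=direction,
                        threshold=int(threshold),
                        observed=len(de_sub),
                        expected=expected,
                        odds_ratio=odds_ratio,
                        p_value=p,
                        n_de=len(de_tes),
                        n_background=len(bg_tes),
                    )
                )
    adjusted = benjamini_hochberg([r.p_value for r in results])
    return [
        EnrichmentResult(**{**r.__dict__, "adjusted_p": float(a)})
        for r, a in zip(results, adjusted)
    ]


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "superfamily": r.superfamily,
                "direction": r.direction,
                "threshold_bp": r.threshold,
                "n_de": r.n_de,
                "n_background": r.n_background,
                "observed": r.observed,
                "expected": r.expected,
                "odds_ratio": r.odds_ratio,
                "pvalue": r.p_value,
                "padj": r.adjusted_p,
            }
            for r in results
        ]
    )
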