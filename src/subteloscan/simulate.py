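"""Synthetic data with planted, recoverable ground truth.

Every input the pipeline consumes can be generated here at miniature scale:
a small genome (five chromosomes, 5-20 Mb) with non-overlapping gene models
and TE instances placed with a controllable telomere-proximity bias; a
differential-expression table whose up-labels carry a controllable
subtelomeric enrichment factor; ChIP-style reads with a known telomeric
fraction; Hi-C valid pairs from a distance-decay model with a controllable
subtelomeric anchor boost; and paired case/control variant and insertion
sets sharing a known baseline.

Distance thresholds quoted at native mouse scale (1 Mb subtelomere, 100 kb
Hi-C exclusion, 5-60 Mb window ladder) are scaled by the ratio of the
miniature genome's median chromosome length to the mouse median (~130 Mb),
so the proportions of the analyses are preserved.

Each sub-simulator draws from its own generator spawned from the master
seed, so adding one simulator never perturbs another, and all emitted files
are byte-identical across runs with the same seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .genome import (
    ChromosomeRecord,
    GenomeAssembly,
    GeneCategoryIndex,
    GeneModel,
    GenomicCategory,
    GenomicInterval,
    distance_to_nearest_end,
)
from .retro import ConsensusLibrary, InsertionCall, reverse_complement
from .te_enrichment import TEInstanceRecord
from .variants import VariantRecord

#: median mouse chromosome length used for proportional threshold scaling
MOUSE_MEDIAN_CHROM_BP = 130_000_000

DEFAULT_CHROM_LENGTHS = {
    "chr1": 20_000_000,
    "chr2": 16_000_000,
    "chr3": 12_000_000,
    "chr4": 8_000_000,
    "chr5": 5_000_000,
}

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TEFamilySpec:
    name: str
    superfamily: str
    copies: int = 300
    telomere_bias: float = 1.0  # rho >= 1

    def __post_init__(self) -> None:
        if self.telomere_bias < 1:
            raise ValueError("telomere_bias must be >= 1")


@dataclass
class DESpec:
    fraction_up: float = 0.05
    fraction_down: float = 0.05
    enrichment_factor: float = 1.0  # up-label multiplier for subtelomeric TEs
    expressed_fraction: float = 0.9  # fraction with >= 5 unique reads


@dataclass
class ReadSpec:
    n_reads: int = 100_000
    read_length: int = 125
    telomeric_fraction: float = 0.01
    substitution_rate: float = 0.0


@dataclass
class PairSpec:
    n_pairs: int = 100_000
    alpha: float = 1.5            # distance-decay exponent
    boost: float = 1.0            # beta >= 1, subtelomeric anchor up-weight
    boost_zone_bp: int | None = None  # defaults to the scaled 5 Mb window
    trans_fraction: float = 0.1
    min_distance: int = 1_000

    def __post_init__(self) -> None:
        if self.boost < 1:
            raise ValueError("boost must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass
class VariantSpec:
    n_baseline: int = 300
    n_case: int = 500
    indel_fraction: float = 0.2
    category_weights: dict = field(
        default_factory=lambda: {
            "promoter": 0.10,
            "five_prime_proximal": 0.05,
            "five_prime_distal": 0.10,
            "exon": 0.15,
            "intron": 0.30,
            "three_prime_proximal": 0.05,
            "three_prime_distal": 0.10,
            "gene_desert": 0.15,
        }
    )


@dataclass
class InsertionSpec:
    n_case: int = 60
    n_shared: int = 40
    substitution_rate: float = 0.05
    min_length: int = 200
    max_length: int = 600
    family_mix: dict = field(
        default_factory=lambda: {
            "L1MdTf_I": 0.35,
            "L1MdA_I": 0.25,
            "L1MdGf_I": 0.20,
            "IAPEY3_I": 0.12,
            "ERVB4_1B": 0.08,
        }
    )


@dataclass
class SimulationConfig:
    seed: int = 0
    chromosome_lengths: dict = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    gene_density_per_mb: float = 2.0
    gene_length: int = 20_000
    exons_per_gene: int = 3
    subtelomere_bp: int | None = None  # defaults to the scaled 1 Mb threshold
    te_families: list = field(
        default_factory=lambda: [
            TEFamilySpec("L1MdTf_I", "LINE", 400),
            TEFamilySpec("L1MdA_I", "LINE", 300),
            TEFamilySpec("IAPEY3_I", "LTR", 300),
            TEFamilySpec("ERVB4_1B", "LTR", 200),
            TEFamilySpec("B1_Mus1", "SINE", 300),
        ]
    )
    de: DESpec = field(default_factory=DESpec)
    reads: ReadSpec = field(default_factory=ReadSpec)
    pairs: PairSpec = field(default_factory=PairSpec)
    variants: VariantSpec = field(default_factory=VariantSpec)
    insertions: InsertionSpec = field(default_factory=InsertionSpec)

    # -- scaling ---------------------------------------------------------
    @property
    def scale_factor(self) -> float:
        lengths = sorted(self.chromosome_lengths.values())
        return float(np.median(lengths)) / MOUSE_MEDIAN_CHROM_BP

    def scaled(self, native_bp: int) -> int:
        """Miniature-genome equivalent of a native mouse-scale threshold."""
        return max(1, round(native_bp * self.scale_factor))

    @property
    def subtelomere_threshold(self) -> int:
        return (self.subtelomere_bp if self.subtelomere_bp is not None
                else self.scaled(1_000_000))

    def assembly(self) -> GenomeAssembly:
        return GenomeAssembly(
            ChromosomeRecord(n, l) for n, l in self.chromosome_lengths.items()
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        for key, sub in (("de", DESpec), ("reads", ReadSpec), ("pairs", PairSpec),
                         ("variants", VariantSpec), ("insertions", InsertionSpec)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "te_families" in d:
            d["te_families"] = [
                TEFamilySpec(**f) if isinstance(f, dict) else f
                for f in d["te_families"]
            ]
        return cls(**d)


def planted_config(seed: int = 0) -> SimulationConfig:
    """A configuration with signal planted in every channel: 5x subtelomeric
    up-enrichment of LINE/LTR elements, 1% telomeric reads, a 2x Hi-C
    subtelomeric anchor boost, and case-specific variants and insertions on
    top of a shared baseline."""
    cfg = SimulationConfig(seed=seed)
    cfg.de = DESpec(enrichment_factor=5.0)
    cfg.pairs = PairSpec(boost=2.0)
    for fam in cfg.te_families:
        if fam.superfamily in ("LINE", "LTR"):
            fam.telomere_bias = 2.0
    return cfg


def _rngs(seed: int, n: int = 8) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        # substitute with one of the three other bases
        shift = rng.integers(1, 4, size=int(hit.sum()))
        code = np.searchsorted(BASES, arr[hit])
        arr[hit] = BASES[(code + shift) % 4]
    return arr.tobytes().decode()


# ------------------------------------------------------------------- genome

@dataclass
class SimulatedGenome:
    config: SimulationConfig
    assembly: GenomeAssembly
    genes: list
    te_instances: list
    te_subtelomeric: dict  # instance id -> bool at the config threshold


def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> SimulatedGenome:
    """Genes placed uniformly without overlap; TE starts drawn from a mixture
    putting probability proportional to the family's telomere bias rho on the
    subtelomeric zones of each chromosome."""
    rng = rng if rng is not None else _rngs(config.seed)[0]
    assembly = config.assembly()
    threshold = config.subtelomere_threshold

    genes: list[GeneModel] = []
    glen = config.gene_length
    for chrom in assembly:
        n_genes = int(round(config.gene_density_per_mb * chrom.length / 1e6))
        if n_genes * glen > 0.6 * chrom.length:
            raise ValueError(f"gene density infeasible on {chrom.name}")
        starts = np.sort(rng.integers(0, chrom.length - glen, size=n_genes))
        prev_end = -1
        for gi, s in enumerate(starts):
            if s <= prev_end:
                continue  # greedy drop keeps genes non-overlapping
            strand = "+" if rng.random() < 0.5 else "-"
            body = GenomicInterval(chrom.name, int(s), int(s) + glen, strand)
            # three exons at fixed relative offsets within the body
            n_ex = config.exons_per_gene
            exons = []
            ex_len = glen // (2 * n_ex)
            for e in range(n_ex):
                ex_start = int(s) + e * (glen // n_ex)
                exons.append(
                    GenomicInterval(chrom.name, ex_start, ex_start + ex_len, strand)
                )
            genes.append(GeneModel(f"gene_{chrom.name}_{gi}", body, tuple(exons)))
            prev_end = int(s) + glen
    tes: list[TEInstanceRecord] = []
    te_subtelomeric: dict[str, bool] = {}
    chrom_lengths = np.array([c.length for c in assembly], dtype=float)
    chrom_prob = chrom_lengths / chrom_lengths.sum()
    counter = 0
    for fam in config.te_families:
        rho = fam.telomere_bias
        for _ in range(fam.copies):
            ci = int(rng.choice(len(chrom_prob), p=chrom_prob))
            chrom = assembly.chromosomes[ci]
            L = chrom.length
            zone = min(threshold, L // 2)
            s_frac = 2 * zone / L
            q = rho * s_frac / (rho * s_frac + (1 - s_frac))
            if rng.random() < q:
                off = int(rng.integers(0, zone))
                start = off if rng.random() < 0.5 else L - zone + off
            else:
                start = int(rng.integers(zone, L - zone))
            te_len = int(rng.integers(300, 3000))
            end = min(start + te_len, L)
            tid = f"te_{counter}"
            counter += 1
            tes.append(
                TEInstanceRecord(
                    tid,
                    GenomicInterval(chrom.name, start, end,
                                    "+" if rng.random() < 0.5 else "-"),
                    fam.name,
                    fam.superfamily,
                )
            )
            te_subtelomeric[tid] = (
                distance_to_nearest_end(start, chrom) < threshold
            )
    return SimulatedGenome(config, assembly, genes, tes, te_subtelomeric)


# ----------------------------------------------------------------- DE table

def simulate_de_table(
    genome: SimulatedGenome,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Differential-expression table with planted up/down labels.

    Expressed instances (>= 5 unique reads) get an up-label with probability
    ``fraction_up`` away from the subtelomere and ``enrichment_factor`` times
    that (capped at 1) inside it; labelled rows draw log2FC and p that pass
    the fold-change/p filters, unlabelled rows draw values that fail them.
    """
    cfg = genome.config
    de = cfg.de
    rng = rng if rng is not None else _rngs(cfg.seed)[1]
    p_up_sub = min(1.0, de.enrichment_factor * de.fraction_up)
    rows = []
    labels: dict[str, str] = {}
    for te in genome.te_instances:
        expressed = rng.random() < de.expressed_fraction
        unique_reads = int(rng.integers(5, 120)) if expressed else int(rng.integers(0, 5))
        label = "none"
        if expressed:
            u = rng.random()
            p_up = p_up_sub if genome.te_subtelomeric[te.id] else de.fraction_up
            if u < p_up:
                label = "up"
            elif u < p_up + de.fraction_down:
                label = "down"
        if label == "up":
            log2fc = np.log2(1.5) + float(rng.exponential(0.7)) + 1e-6
            pvalue = float(rng.uniform(1e-8, 0.049))
        elif label == "down":
            log2fc = -(np.log2(1.5) + float(rng.exponential(0.7)) + 1e-6)
            pvalue = float(rng.uniform(1e-8, 0.049))
        else:
            log2fc = float(rng.uniform(-0.5, 0.5))
            pvalue = float(rng.uniform(0.05, 1.0))
        labels[te.id] = label
        rows.append(
            {
                "instance_id": te.id,
                "family": te.family,
                "superfamily": te.superfamily,
                "chrom": te.locus.chrom,
                "start": te.locus.start,
                "end": te.locus.end,
                "log2fc": round(log2fc, 6),
                "pvalue": pvalue,
                "unique_reads": unique_reads,
            }
        )
    return pd.DataFrame(rows), labels


def simulate_enrichment_table(
    n_background: int,
    n_de: int,
    subtelomere_fraction: float,
    enrichment_factor: float,
    rng: np.random.Generator,
) -> tuple[int, int, int, int]:
    """Draw one (de_sub, de_nonsub, bg_sub, bg_nonsub) replicate.

    Background instances are subtelomeric with probability
    ``subtelomere_fraction``; DE instances with the factor-weighted
    probability rho*f / (rho*f + 1 - f).  Used by the calibration and power
    studies.
    """
    f = subtelomere_fraction
    p_de = enrichment_factor * f / (enrichment_factor * f + (1 - f))
    de_sub = int(rng.binomial(n_de, p_de))
    bg_sub = int(rng.binomial(n_background, f))
    return de_sub, n_de - de_sub, bg_sub, n_background - bg_sub


# -------------------------------------------------------------------- reads

def simulate_reads(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], set[str]]:
    """Reads with a planted telomeric fraction.

    Telomeric reads are phase-randomised (TTAGGG)n tracts on either strand
    with the configured per-base substitution rate; background reads are
    uniform random.  Returns (reads, true_telomeric_ids).
    """
    spec = config.reads
    rng = rng if rng is not None else _rngs(config.seed)[2]
    unit = "TTAGGG"
    L = spec.read_length
    tract = unit * (L // 6 + 2)
    reads: list[tuple[str, str]] = []
    truth: set[str] = set()
    telo = rng.random(spec.n_reads) < spec.telomeric_fraction
    for i in range(spec.n_reads):
        rid = f"read_{i}"
        if telo[i]:
            off = int(rng.integers(0, 6))
            seq = tract[off : off + L]
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            seq = _mutate(rng, seq, spec.substitution_rate)
            truth.add(rid)
        else:
            seq = _random_seq(rng, L)
        reads.append((rid, seq))
    return reads, truth


# -------------------------------------------------------------- valid pairs

def simulate_valid_pairs(
    config: SimulationConfig,
    assembly: GenomeAssembly | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], dict]:
    """Hi-C valid-pair lines from a distance-decay contact model.

    The anchor end of every pair falls in a terminal boost zone with odds
    ``boost`` times the neutral (length-proportional) odds, uniformly within
    the chosen stratum, so the planted boost is exactly the case/control
    odds ratio of zone-anchored pair fractions (see
    :func:`subteloscan.hic.estimate_boost`).  Cis partners sit at a
    truncated power-law distance s^(-alpha) from the anchor, trans partners
    are uniform on another chromosome.  Returns (allValidPairs lines, truth
    summary).
    """
    spec = config.pairs
    rng = rng if rng is not None else _rngs(config.seed)[3]
    assembly = assembly if assembly is not None else config.assembly()
    zone = (spec.boost_zone_bp if spec.boost_zone_bp is not None
            else config.scaled(5_000_000))
    lengths = np.array([c.length for c in assembly], dtype=np.int64)
    chrom_prob = lengths / lengths.sum()
    n = spec.n_pairs
    # concatenated zone and non-zone segments across the genome
    zone_segs: list[tuple[int, int, int]] = []  # (chrom index, start, end)
    mid_segs: list[tuple[int, int, int]] = []
    for ci, c in enumerate(assembly):
        z = min(zone, c.length // 2)
        zone_segs += [(ci, 0, z), (ci, c.length - z, c.length)]
        mid_segs.append((ci, z, c.length - z))

    def _segment_draw(segs, size):
        seg_len = np.array([e - s for _, s, e in segs], dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(seg_len)])
        off = (rng.random(size) * cum[-1]).astype(np.int64)
        seg_i = np.searchsorted(cum, off, side="right") - 1
        ci = np.array([segs[i][0] for i in seg_i], dtype=np.int64)
        pos = np.array([segs[i][1] for i in seg_i]) + (off - cum[seg_i])
        return ci, pos

    total_len = int(lengths.sum())
    S = sum(e - s for _, s, e in zone_segs) / total_len
    q_zone = spec.boost * S / (spec.boost * S + (1 - S))
    in_zone = rng.random(n) < q_zone
    ci1 = np.zeros(n, dtype=np.int64)
    pos1 = np.zeros(n, dtype=np.int64)
    idx_z = np.flatnonzero(in_zone)
    idx_m = np.flatnonzero(~in_zone)
    if idx_z.size:
        ci1[idx_z], pos1[idx_z] = _segment_draw(zone_segs, idx_z.size)
    if idx_m.size:
        ci1[idx_m], pos1[idx_m] = _segment_draw(mid_segs, idx_m.size)
    L1 = lengths[ci1]
    is_trans = rng.random(n) < spec.trans_fraction
    ci2 = ci1.copy()
    pos2 = np.zeros(n, dtype=np.int64)
    # trans partners: another chromosome, uniform position
    idx_t = np.flatnonzero(is_trans)
    if idx_t.size:
        other = rng.choice(len(lengths), size=idx_t.size, p=chrom_prob)
        same = other == ci1[idx_t]
        while same.any():
            other[same] = rng.choice(len(lengths), size=int(same.sum()),
                                     p=chrom_prob)
            same = other == ci1[idx_t]
        ci2[idx_t] = other
        pos2[idx_t] = (rng.random(idx_t.size) * lengths[other]).astype(np.int64)
    # cis partners: power-law distance, redrawn until in bounds
    idx_c = np.flatnonzero(~is_trans)
    dmin = spec.min_distance
    alpha = spec.alpha
    pending = idx_c.copy()
    for _ in range(200):
        if pending.size == 0:
            break
        Lp = lengths[ci1[pending]]
        uu = rng.random(pending.size)
        if abs(alpha - 1.0) < 1e-12:
            d = (dmin * np.power(Lp / dmin, uu)).astype(np.int64)
        else:
            a1 = 1.0 - alpha
            d = np.power(
                dmin ** a1 + uu * (np.power(Lp.astype(float), a1) - dmin ** a1),
                1.0 / a1,
            ).astype(np.int64)
        sign = np.where(rng.random(pending.size) < 0.5, 1, -1)
        cand = pos1[pending] + sign * d
        ok = (cand >= 0) & (cand < Lp)
        pos2[pending[ok]] = cand[ok]
        pending = pending[~ok]
    if pending.size:  # pathological leftovers: uniform fallback
        pos2[pending] = (rng.random(pending.size)
                         * lengths[ci1[pending]]).astype(np.int64)
    names = assembly.names
    strands = np.where(rng.random((n, 2)) < 0.5, "+", "-")
    lines = [
        f"pair_{i}\t{names[ci1[i]]}\t{pos1[i] + 1}\t{strands[i, 0]}\t"
        f"{names[ci2[i]]}\t{pos2[i] + 1}\t{strands[i, 1]}\t"
        f"{abs(int(pos2[i]) - int(pos1[i])) if ci1[i] == ci2[i] else 0}\t"
        f"frag_a\tfrag_b"
        for i in range(n)
    ]
    left = pos1 * 2 <= L1
    truth = {
        "boost": spec.boost,
        "boost_zone_bp": int(zone),
        "n_pairs": int(n),
        "n_trans": int(is_trans.sum()),
        "anchor_in_zone": int(in_zone.sum()),
        "anchor_arm_counts": {
            "left": int(left.sum()),
            "right": int(n - left.sum()),
        },
    }
    return lines, truth


# ------------------------------------------------- variants and insertions

#: family -> (superfamily, consensus length); synthetic stand-ins for the
#: repeat consensus library, generated as seeded random sequences
SYNTHETIC_CONSENSUS_SPECS = {
    "L1MdTf_I": ("LINE", 7_000),
    "L1MdA_I": ("LINE", 6_500),
    "L1MdGf_I": ("LINE", 6_000),
    "IAPEY3_I": ("LTR", 5_000),
    "ERVB4_1B": ("LTR", 4_500),
    "B1_Mus1": ("SINE", 150),
}


def synthetic_consensus_library(seed: int = 1234) -> ConsensusLibrary:
    """Synthetic consensus library: seeded random sequences under mouse TE
    family names with realistic lengths.  A stand-in for a curated repeat
    library; sequence content is random, only lengths and names are real."""
    rng = np.random.Generator(np.random.PCG64(seed))
    return ConsensusLibrary(
        {name: _random_seq(rng, length)
         for name, (_, length) in SYNTHETIC_CONSENSUS_SPECS.items()}
    )


def _positions_for_categories(
    wanted: list[str],
    genome: SimulatedGenome,
    index: GeneCategoryIndex,
    rng: np.random.Generator,
    max_draws: int = 2_000_000,
) -> list[tuple[str, int]]:
    """Rejection-sample one genomic position per requested category label."""
    assembly = genome.assembly
    lengths = np.array([c.length for c in assembly], dtype=np.int64)
    chrom_prob = lengths / lengths.sum()
    names = assembly.names
    need: dict[str, int] = {}
    for w in wanted:
        need[w] = need.get(w, 0) + 1
    found: dict[str, list[tuple[str, int]]] = {w: [] for w in need}
    draws = 0
    batch = 4096
    while any(len(found[w]) < need[w] for w in need) and draws < max_draws:
        ci = rng.choice(len(lengths), size=batch, p=chrom_prob)
        pos = (rng.random(batch) * lengths[ci]).astype(np.int64)
        draws += batch
        for c, p in zip(ci, pos):
            cat = index.classify(names[c], int(p)).value
            if cat in need and len(found[cat]) < need[cat]:
                found[cat].append((names[c], int(p)))
    out: list[tuple[str, int]] = []
    for w in wanted:
        if found[w]:
            out.append(found[w].pop())
        else:
            raise RuntimeError(
                f"could not place a variant in category {w!r}; "
                "increase gene density or max_draws"
            )
    return out


def simulate_variants_and_insertions(
    config: SimulationConfig,
    genome: SimulatedGenome,
    library: ConsensusLibrary,
    rng: np.random.Generator | None = None,
):
    """Paired case/control variant and insertion sets sharing a baseline.

    Returns ``(case_records, control_records, truth)`` where records are
    (chrom, pos1, id, ref, alt, info) VCF rows and truth maps variant ids to
    planted categories and insertion ids to planted families.
    """
    rng = rng if rng is not None else _rngs(config.seed)[4]
    vspec, ispec = config.variants, config.insertions
    assembly = genome.assembly
    index = GeneCategoryIndex(genome.genes)
    lengths = np.array([c.length for c in assembly], dtype=np.int64)
    chrom_prob = lengths / lengths.sum()
    names = assembly.names

    weights = dict(vspec.category_weights)
    total_w = sum(weights.values())
    if abs(total_w - 1.0) > 1e-9:
        import warnings

        warnings.warn("category weights do not sum to 1; normalising")
        weights = {k: v / total_w for k, v in weights.items()}

    def draw_variant(vid: str, chrom: str, pos0: int) -> tuple:
        ref = "ACGT"[int(rng.integers(0, 4))]
        if rng.random() < vspec.indel_fraction:
            ins = rng.random() < 0.5
            if ins:
                alt = ref + _random_seq(rng, int(rng.integers(1, 6)))
            else:
                alt = ref
                ref = ref + _random_seq(rng, int(rng.integers(1, 6)))
            return (chrom, pos0 + 1, vid, ref, alt, "DP=50")
        alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
        return (chrom, pos0 + 1, vid, ref, alt, "DP=50")

    case_rows, control_rows = [], []
    truth = {"variant_categories": {}, "insertion_families": {},
             "baseline_variant_ids": [], "baseline_insertion_ids": []}

    # shared baseline variants at uniform positions, present in both samples
    ci = rng.choice(len(lengths), size=vspec.n_baseline, p=chrom_prob)
    pos = (rng.random(vspec.n_baseline) * lengths[ci]).astype(np.int64)
    for i in range(vspec.n_baseline):
        vid = f"base_var_{i}"
        row = draw_variant(vid, names[ci[i]], int(pos[i]))
        case_rows.append(row)
        control_rows.append(row)
        truth["baseline_variant_ids"].append(vid)

    # case-specific variants placed per planted category weights
    cats = list(weights)
    probs = np.array([weights[c] for c in cats])
    chosen = [cats[i] for i in rng.choice(len(cats), size=vspec.n_case, p=probs)]
    placed = _positions_for_categories(chosen, genome, index, rng)
    for i, ((chrom, pos0), cat) in enumerate(zip(placed, chosen)):
        vid = f"case_var_{i}"
        case_rows.append(draw_variant(vid, chrom, pos0))
        truth["variant_categories"][vid] = cat

    # insertions: shared baseline (jittered in control) + case-specific
    fams = list(ispec.family_mix)
    fam_p = np.array([ispec.family_mix[f] for f in fams])
    fam_p = fam_p / fam_p.sum()

    def draw_insertion(iid: str, shared: bool):
        fam = fams[int(rng.choice(len(fams), p=fam_p))]
        consensus = library.entries[fam]
        max_len = min(ispec.max_length, len(consensus))
        ilen = int(rng.integers(ispec.min_length, max_len + 1))
        start = int(rng.integers(0, len(consensus) - ilen + 1))
        seq = consensus[start : start + ilen]
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        seq = _mutate(rng, seq, ispec.substitution_rate)
        c = int(rng.choice(len(lengths), p=chrom_prob))
        p0 = int(rng.integers(0, lengths[c]))
        info = f"SVTYPE=INS;SVLEN={ilen};SVINSSEQ={seq}"
        row = (names[c], p0 + 1, iid, "N", "<INS>", info)
        return row, fam, (names[c], p0 + 1)

    for i in range(ispec.n_shared):
        iid = f"base_ins_{i}"
        row, fam, (chrom, pos1) = draw_insertion(iid, shared=True)
        case_rows.append(row)
        jitter = int(rng.integers(-50, 51))
        ctl_pos = max(1, pos1 + jitter)
        control_rows.append((chrom, ctl_pos, iid, "N", "<INS>", row[5]))
        truth["baseline_insertion_ids"].append(iid)
    for i in range(ispec.n_case):
        iid = f"case_ins_{i}"
        row, fam, _ = draw_insertion(iid, shared=False)
        case_rows.append(row)
        truth["insertion_families"][iid] = fam

    def sort_key(row):
        return (names.index(row[0]), row[1], row[2])

    case_rows.sort(key=sort_key)
    control_rows.sort(key=sort_key)
    return case_rows, control_rows, truth


# ----------------------------------------------------------------- full run

def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write a self-contained synthetic dataset directory and return paths.

    Emits chrom.sizes, genes.bed12, te.bed, de_table.tsv, reads.fastq.gz,
    pairs.allValidPairs, case.vcf, control.vcf, consensus.fa, truth.json and
    config.yaml, all reproducible byte-for-byte from the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rngs = _rngs(config.seed)
    genome = simulate_genome(config, rngs[0])
    de_table, de_labels = simulate_de_table(genome, rngs[1])
    reads, telo_ids = simulate_reads(config, rngs[2])
    pair_lines, pair_truth = simulate_valid_pairs(config, genome.assembly, rngs[3])
    library = synthetic_consensus_library()
    case_rows, control_rows, vi_truth = simulate_variants_and_insertions(
        config, genome, library, rngs[4]
    )

    paths = {
        "chrom_sizes": outdir / "chrom.sizes",
        "genes": outdir / "genes.bed12",
        "te_bed": outdir / "te.bed",
        "de_table": outdir / "de_table.tsv",
        "reads": outdir / "reads.fastq.gz",
        "pairs": outdir / "pairs.allValidPairs",
        "case_vcf": outdir / "case.vcf",
        "control_vcf": outdir / "control.vcf",
        "consensus": outdir / "consensus.fa",
        "truth": outdir / "truth.json",
        "config": outdir / "config.yaml",
    }
    sio.write_chrom_sizes(genome.assembly, paths["chrom_sizes"])
    sio.write_bed12(genome.genes, paths["genes"])
    sio.write_bed6(
        ((te.locus, te.family, "0") for te in genome.te_instances),
        paths["te_bed"],
    )
    de_table.to_csv(paths["de_table"], sep="\t", index=False)
    sio.write_fastq(reads, paths["reads"])
    with open(paths["pairs"], "w") as fh:
        fh.write("\n".join(pair_lines) + "\n")
    sio.write_vcf(case_rows, genome.assembly, paths["case_vcf"])
    sio.write_vcf(control_rows, genome.assembly, paths["control_vcf"])
    sio.write_fasta(sorted(library.entries.items()), paths["consensus"])
    truth = {
        "seed": config.seed,
        "subtelomere_threshold_bp": config.subtelomere_threshold,
        "te_subtelomeric": genome.te_subtelomeric,
        "de_labels": de_labels,
        "telomeric_read_ids": sorted(telo_ids),
        "pairs": pair_truth,
        **vi_truth,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
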