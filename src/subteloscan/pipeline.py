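"""End-to-end pipeline: simulate (or load) a dataset, run every analysis
stage in dependency order, and write tidy TSV tables plus a provenance log.

Output tables never embed timestamps, so identical configs and seeds yield
byte-identical tables; wall-clock provenance lives only in ``report.json``.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as sio
from .chip import PeakRecord, TelomericReadParams, classify_peaks, \
    metagene_flanking_fc, telomeric_read_rate
from .genome import GeneCategoryIndex, GenomicInterval
from .hic import arm_window_counts, center_window_counts, parse_valid_pairs, \
    percent_normalize
from .retro import ConsensusLibrary, classify_all, insertion_burden_test, \
    insertion_site_spectrum, subtract_baseline_sv
from .simulate import SimulationConfig, simulate_all
from .te_enrichment import TEInstanceRecord, enrichment_scan, results_frame
from .variants import sbs_spectrum, subtract_baseline, variant_category_counts


@dataclass
class RunConfig:
    """Parameters of a full synthetic-data pipeline run."""

    seed: int = 0
    outdir: str = "subteloscan_run"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # native mouse-scale thresholds, scaled onto the miniature genome
    enrichment_thresholds_native: tuple = (1_000_000, 20_000_000, 50_000_000)
    hic_windows_native: tuple = (5_000_000, 10_000_000, 20_000_000,
                                 30_000_000, 60_000_000)
    hic_exclusion_native: int = 100_000
    fc_cutoff: float = 1.5
    p_cutoff: float = 0.05
    min_reads: int = 5
    kmer: int = 15
    min_identity: float = 0.5
    sv_tolerance: int = 100
    metagene_windows_native: tuple = (100_000, 500_000, 1_000_000,
                                      5_000_000, 10_000_000)
    collapse_sbs: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.sim, SimulationConfig):
            self.sim = SimulationConfig.from_dict(self.sim)
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _provenance(config: RunConfig) -> dict:
    params = config.to_dict()
    params.pop("outdir", None)  # output location is not a parameter
    return {
        "tool": f"subteloscan {__version__}",
        "seed": config.seed,
        "config_hash": sio.config_hash(params),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a dataset and run every analysis stage on it.

    Returns a report dict with stage table paths and provenance; raises on
    the first stage failure.
    """
    outdir = Path(config.outdir)
    datadir = outdir / "data"
    tabledir = outdir / "tables"
    tabledir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    started = datetime.datetime.now().isoformat()

    paths = simulate_all(config.sim, datadir)
    assembly = sio.read_chrom_sizes(paths["chrom_sizes"])
    genes = sio.read_bed12(paths["genes"])
    index = GeneCategoryIndex(genes)
    scaled = config.sim.scaled

    # --- TE enrichment ---------------------------------------------------
    de_table = pd.read_csv(paths["de_table"], sep="\t")
    instances = [
        TEInstanceRecord(
            r.instance_id,
            GenomicInterval(r.chrom, int(r.start), int(r.end)),
            r.family,
            r.superfamily,
        )
        for r in de_table.itertuples()
    ]
    thresholds = sorted(scaled(t) for t in config.enrichment_thresholds_native)
    enr = enrichment_scan(
        de_table, instances, assembly, thresholds,
        fc_cutoff=config.fc_cutoff, p_cutoff=config.p_cutoff,
        min_reads=config.min_reads,
    )
    sio.write_table(results_frame(enr), tabledir / "te_enrichment.tsv", prov)

    # --- variant spectra -------------------------------------------------
    case_vars, case_ins, _ = sio.read_vcf_minimal(paths["case_vcf"])
    ctl_vars, ctl_ins, _ = sio.read_vcf_minimal(paths["control_vcf"])
    somatic = subtract_baseline(case_vars, ctl_vars)
    cat_counts, _ = variant_category_counts(somatic, index, assembly)
    sio.write_table(cat_counts.reset_index(),
                    tabledir / "variant_categories.tsv", prov)
    sbs = sbs_spectrum(somatic, collapse=config.collapse_sbs)
    sio.write_table(sbs.rename("count").reset_index(),
                    tabledir / "sbs_spectrum.tsv", prov)

    # --- retrotransposition ----------------------------------------------
    library = ConsensusLibrary.from_fasta(paths["consensus"])
    new_ins = subtract_baseline_sv(case_ins, ctl_ins, config.sv_tolerance)
    with_seq = [c for c in new_ins if c.sequence]
    assignments = classify_all(with_seq, library, k=config.kmer,
                               identity_threshold=config.min_identity)
    sio.write_table(assignments, tabledir / "insertion_assignments.tsv", prov)
    fam_counts = (assignments["family"].value_counts().rename_axis("family")
                  .rename("count").reset_index())
    sio.write_table(fam_counts, tabledir / "insertion_families.tsv", prov)
    spectrum = insertion_site_spectrum(with_seq, index, assembly)
    sio.write_table(spectrum, tabledir / "insertion_site_spectrum.tsv", prov)
    burden_p = insertion_burden_test(len(new_ins), len(ctl_ins))

    # --- telomeric reads and peaks ---------------------------------------
    n_telo, n_total, per_million, _ = telomeric_read_rate(
        sio.read_sequences(paths["reads"])
    )
    telo_df = pd.DataFrame(
        [{"sample": "synthetic", "telomeric_reads": n_telo,
          "total_reads": n_total, "per_million": per_million}]
    )
    sio.write_table(telo_df, tabledir / "telomeric_reads.tsv", prov)

    # derive a decreased-peak set from subtelomeric TE loci to exercise the
    # peak classifier on the synthetic annotation
    te_named = sio.read_bed6_named(paths["te_bed"])
    te_instances = [
        TEInstanceRecord(f"te{i}", iv, name, "NA")
        for i, (iv, name, _score) in enumerate(te_named)
    ]
    peaks = [
        PeakRecord(te.locus, "decreased" if i % 2 == 0 else "increased",
                   log2fc=-1.0 if i % 2 == 0 else 1.0)
        for i, te in enumerate(te_instances[: max(50, len(te_instances) // 4)])
    ]
    peak_counts = classify_peaks(peaks, te_instances, assembly,
                                 scaled(1_000_000))
    sio.write_table(pd.DataFrame([peak_counts]),
                    tabledir / "peak_classes.tsv", prov)
    gene_fc = {g.id: 0.0 for g in genes}
    meta = metagene_flanking_fc(
        peaks, genes, gene_fc,
        sorted(scaled(w) for w in config.metagene_windows_native),
    )
    sio.write_table(meta, tabledir / "metagene.tsv", prov)

    # --- Hi-C -------------------------------------------------------------
    pairs, stats = parse_valid_pairs(paths["pairs"], assembly)
    windows = sorted(scaled(w) for w in config.hic_windows_native)
    exclusion = scaled(config.hic_exclusion_native)
    counts = arm_window_counts(pairs, assembly, windows, exclusion)
    counts = percent_normalize(counts, stats.n_pairs)
    sio.write_table(counts, tabledir / "hic_arm_windows.tsv", prov)
    centers = percent_normalize(
        center_window_counts(pairs, assembly, windows), stats.n_pairs
    )
    sio.write_table(centers, tabledir / "hic_center_windows.tsv", prov)

    report = {
        "provenance": {**prov, "started": started,
                       "finished": datetime.datetime.now().isoformat()},
        "data": paths,
        "tables": sorted(str(p) for p in tabledir.glob("*.tsv")),
        "summary": {
            "n_te_instances": len(instances),
            "n_somatic_variants": len(somatic),
            "n_new_insertions": len(new_ins),
            "insertion_burden_p": burden_p,
            "telomeric_per_million": per_million,
            "n_valid_pairs": stats.n_pairs,
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
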