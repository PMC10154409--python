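"""Shared plumbing for the analysis drivers: one planted synthetic dataset
under scratch/simdata, regenerated on demand, plus the results directory."""

from pathlib import Path

from subteloscan import io as sio
from subteloscan.simulate import planted_config, simulate_all

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "simdata"
RESULTS = ROOT / "results"
SEED = 11


def dataset() -> dict:
    """Paths of the planted dataset, simulating it if absent."""
    marker = SCRATCH / "truth.json"
    if not marker.exists():
        simulate_all(planted_config(SEED), SCRATCH)
    return {p.name.split(".")[0]: str(p) for p in SCRATCH.iterdir()} | {
        "chrom_sizes": str(SCRATCH / "chrom.sizes"),
        "genes": str(SCRATCH / "genes.bed12"),
        "te_bed": str(SCRATCH / "te.bed"),
        "de_table": str(SCRATCH / "de_table.tsv"),
        "reads": str(SCRATCH / "reads.fastq.gz"),
        "pairs": str(SCRATCH / "pairs.allValidPairs"),
        "case_vcf": str(SCRATCH / "case.vcf"),
        "control_vcf": str(SCRATCH / "control.vcf"),
        "consensus": str(SCRATCH / "consensus.fa"),
        "truth": str(SCRATCH / "truth.json"),
    }


def write_result(df, name: str, **provenance) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    sio.write_table(df, path, {"seed": SEED, **provenance})
    return path
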