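"""Format readers and writers.

Text inputs may be gzip-compressed; compression is detected from the ``.gz``
suffix.  All readers yield the package's internal 0-based half-open frame;
VCF positions are converted from the 1-based VCF frame on ingest.  Output
tables are tidy TSV with a ``#``-prefixed provenance comment block.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam
from Bio import SeqIO

from .genome import ChromosomeRecord, GenomeAssembly, GenomicInterval, GeneModel


class FormatError(ValueError):
    """A malformed input file."""


def open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # fixed mtime so same-seed reruns are byte-identical
            gz = gzip.GzipFile(path, "wb", mtime=0)
            return _io.TextIOWrapper(gz, encoding="utf-8") if "t" in mode else gz
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- chrom.sizes

def read_chrom_sizes(path: str | Path) -> GenomeAssembly:
    """Read a UCSC-style two-column ``chrom<TAB>length`` file."""
    records = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                records.append(ChromosomeRecord(fields[0], int(fields[1])))
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
    if not records:
        raise FormatError(f"{path}: no chromosomes")
    return GenomeAssembly(records)


def write_chrom_sizes(assembly: GenomeAssembly, path: str | Path) -> None:
    with open_text(path, "wt") as fh:
        for c in assembly:
            fh.write(f"{c.name}\t{c.length}\n")


# ------------------------------------------------------------------------ BED

def read_bed6(path: str | Path) -> list[GenomicInterval]:
    """Read BED6 (name/score optional beyond column 3) into intervals.

    The name field is carried on the returned tuple list by
    :func:`read_bed6_named` when callers need it.
    """
    return [iv for iv, _name, _score in read_bed6_named(path)]


def read_bed6_named(path: str | Path) -> list[tuple[GenomicInterval, str, str]]:
    out = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
                strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
                iv = GenomicInterval(f[0], start, end, strand)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
            name = f[3] if len(f) > 3 else "."
            score = f[4] if len(f) > 4 else "0"
            out.append((iv, name, score))
    return out


def write_bed6(
    records: Iterable[tuple[GenomicInterval, str, str]], path: str | Path
) -> None:
    with open_text(path, "wt") as fh:
        for iv, name, score in records:
            strand = iv.strand if iv.strand in "+-" else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n")


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Read BED12 gene models, reconstructing exons from block columns."""
    genes = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED columns")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(starts) != n_blocks:
                    raise ValueError("block count mismatch")
                body = GenomicInterval(chrom, start, end, strand)
                exons = tuple(
                    GenomicInterval(chrom, start + bs, start + bs + sz, strand)
                    for bs, sz in zip(starts, sizes)
                )
                genes.append(GeneModel(name, body, exons))
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
    return genes


def write_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open_text(path, "wt") as fh:
        for g in genes:
            b = g.body
            exons = sorted(g.exons, key=lambda e: e.start) or (b,)
            sizes = ",".join(str(len(e)) for e in exons) + ","
            starts = ",".join(str(e.start - b.start) for e in exons) + ","
            fh.write(
                f"{b.chrom}\t{b.start}\t{b.end}\t{g.id}\t0\t{b.strand}\t"
                f"{b.start}\t{b.end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )


# ------------------------------------------------------------------------ VCF

def read_vcf_minimal(path: str | Path):
    """Read a VCF into SNV/indel and insertion-call streams.

    Returns ``(variants, insertions, n_unclassifiable)`` where variants are
    :class:`~subteloscan.variants.VariantRecord` and insertions are
    :class:`~subteloscan.retro.InsertionCall`.  SVTYPE=INS records take their
    inserted sequence from the ALT allele or INFO ``SVINSSEQ``; symbolic
    insertions without a sequence are retained but counted unclassifiable.
    """
    from .retro import InsertionCall
    from .variants import VariantRecord

    variants: list[VariantRecord] = []
    insertions: list[InsertionCall] = []
    n_unclassifiable = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else None
            if alt is None:
                continue
            svtype = rec.info.get("SVTYPE") if "SVTYPE" in rec.info else None
            if svtype == "INS":
                seq = None
                if alt and not alt.startswith("<"):
                    seq = alt[1:] if alt[0] == rec.ref[0] and len(alt) > 1 else alt
                elif "SVINSSEQ" in rec.info:
                    v = rec.info["SVINSSEQ"]
                    seq = v[0] if isinstance(v, tuple) else v
                if seq:
                    insertions.append(
                        InsertionCall(rec.chrom, rec.pos, seq.upper(), id=rec.id)
                    )
                else:
                    n_unclassifiable += 1
                    insertions.append(InsertionCall(rec.chrom, rec.pos, None, id=rec.id))
                continue
            if alt.startswith("<"):
                continue
            depth = rec.info.get("DP") if "DP" in rec.info else None
            variants.append(
                VariantRecord(rec.chrom, rec.pos, rec.ref.upper(), alt.upper(),
                              depth=depth)
            )
    return variants, insertions, n_unclassifiable


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=SVINSSEQ,Number=1,Type=String,Description="Inserted sequence">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(records: Iterable[tuple], assembly: GenomeAssembly,
              path: str | Path) -> None:
    """Write minimal VCF records given as (chrom, pos1, id, ref, alt, info)."""
    with open_text(path, "wt") as fh:
        fh.write(VCF_HEADER)
        for c in assembly:
            fh.write(f"##contig=<ID={c.name},length={c.length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos1, rid, ref, alt, info in records:
            fh.write(f"{chrom}\t{pos1}\t{rid}\t{ref}\t{alt}\t.\tPASS\t{info}\n")


# ---------------------------------------------------------------- FASTA/FASTQ

def read_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from FASTA or FASTQ, optionally gzipped."""
    path = Path(path)
    stem = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if stem.endswith(("fastq", "fq")) else "fasta"
    with open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq).upper()


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open_text(path, "wt") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open_text(path, "wt") as fh:
        for name, seq in entries:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# --------------------------------------------------------------------- tables

def write_table(df: pd.DataFrame, path: str | Path,
                provenance: dict | None = None) -> None:
    """Write a tidy TSV with a '#'-prefixed provenance comment block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False, lineterminator="\n", float_format="%.6g")
    with open_text(path, "wt") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write(buf.getvalue())


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping."""
    import json

    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
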