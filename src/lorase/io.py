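"""Shared format readers/writers and run configuration.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based conventions of VCF and GTF happens only here, at the file
boundary. TSV schemas (column order and names) are frozen so downstream
tooling can rely on them.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .counting import Annotation, TranscriptModel
from .phasing import VariantSet

__all__ = [
    "write_fasta",
    "write_phased_vcf",
    "write_gtf",
    "read_gtf",
    "read_alignments",
    "write_alignments",
    "write_counts",
    "read_counts",
    "write_calls",
    "read_calls",
    "parse_config_file",
    "apply_chr_alias",
    "write_run_log",
    "GENE_COUNT_COLUMNS",
    "CALL_COLUMNS",
]

GENE_COUNT_COLUMNS = [
    "feature_id", "chrom", "strand", "biotype", "is_x_linked",
    "maternal", "paternal", "untagged", "ambiguous", "snp_overlap_reads",
]
CALL_COLUMNS = GENE_COUNT_COLUMNS + ["ratio", "informative", "category"]


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_phased_vcf(
    variants: VariantSet, contig_lengths: Mapping[str, int], path, sample: str = "F1"
) -> None:
    """Single-sample VCF v4.2 with phased GT 0|1 (maternal = REF first)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.maternal_base}\t{v.paternal_base}"
                f"\t.\tPASS\t.\tGT\t0|1\n"
            )


def write_gtf(annotation: Annotation, path) -> None:
    """GTF with gene / transcript / exon features (1-based closed)."""
    with open(path, "w") as fh:
        for gene in annotation.genes.values():
            attrs = (
                f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
            )
            fh.write(
                f"{gene.chrom}\tlorase\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )
            for tx in annotation.transcripts_of(gene.gene_id):
                tattrs = attrs + f' transcript_id "{tx.transcript_id}";'
                fh.write(
                    f"{tx.chrom}\tlorase\ttranscript\t{tx.start + 1}\t{tx.end}\t.\t"
                    f"{tx.strand}\t.\t{tattrs}\n"
                )
                for start, end in tx.exons:
                    fh.write(
                        f"{tx.chrom}\tlorase\texon\t{start + 1}\t{end}\t.\t"
                        f"{tx.strand}\t.\t{tattrs}\n"
                    )


def _gtf_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for part in raw.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path, x_chrom: str = "chrX") -> Annotation:
    """Parse exon features into transcript models; gene extents are
    rebuilt as the exon union over transcripts."""
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    biotypes: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                if len(fields) >= 9 and fields[2] == "gene":
                    attrs = _gtf_attributes(fields[8])
                    if "gene_id" in attrs and "gene_biotype" in attrs:
                        biotypes[attrs["gene_id"]] = attrs["gene_biotype"]
                continue
            attrs = _gtf_attributes(fields[8])
            tx_id = attrs["transcript_id"]
            exons.setdefault(tx_id, []).append((int(fields[3]) - 1, int(fields[4])))
            meta[tx_id] = (attrs["gene_id"], fields[0], fields[6])
            if "gene_biotype" in attrs:
                biotypes.setdefault(attrs["gene_id"], attrs["gene_biotype"])
    transcripts = [
        TranscriptModel(tx_id, gene, chrom, strand, exons[tx_id])
        for tx_id, (gene, chrom, strand) in meta.items()
    ]
    return Annotation.from_transcripts(transcripts, biotypes, x_chrom=x_chrom)


def read_alignments(path) -> tuple[list[pysam.AlignedSegment], pysam.AlignmentHeader]:
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        header = fh.header
        records = list(fh)
    return records, header


def write_alignments(records: Iterable[pysam.AlignedSegment], header, path) -> None:
    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as fh:
        for rec in records:
            fh.write(rec)


def write_counts(table: pd.DataFrame, path) -> None:
    cols = [c for c in GENE_COUNT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table.to_csv(path, sep="\t", index=False, columns=cols)


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_calls(calls: pd.DataFrame, path) -> None:
    cols = [c for c in CALL_COLUMNS if c in calls.columns]
    cols += [c for c in calls.columns if c not in cols]
    calls.to_csv(path, sep="\t", index=False, columns=cols)


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def parse_config_file(path) -> dict[str, str]:
    """key=value configuration; '#' starts a comment."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: expected key=value, got {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def apply_chr_alias(name: str, alias: Mapping[str, str] | None) -> str:
    return alias.get(name, name) if alias else name


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_run_log(outdir, stage: str, params: Mapping, inputs: Iterable[str] = ()) -> str:
    """Machine-readable record of a pipeline stage invocation."""
    from . import __version__

    log = {
        "stage": stage,
        "version": __version__,
        "python": platform.python_version(),
        "parameters": {k: str(v) for k, v in dict(params).items()},
        "input_digests": {str(p): _digest(p) for p in inputs if Path(p).is_file()},
    }
    path = Path(outdir) / f"runlog_{stage}.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return str(path)
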