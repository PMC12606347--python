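"""Stranded union-mode gene counting and isoform-level allelic counting.

Gene-level counting follows union semantics: a read counts toward a gene
only when the set of annotated genes its aligned blocks overlap (strand
matched, when stranded) is a singleton; overlapping several genes makes
it ambiguous, overlapping none leaves it unassigned. Counting each
haplotype stream separately yields per-gene maternal/paternal/untagged
counts, the raw material for allelic ratios.

Isoform-level counting targets loci like the imprinted Gnas cluster,
where overlapping isoforms of opposite allelic status share 3' exons and
differ by their first exon: a read is attributed to the unique transcript
whose first exon hosts the read's 5' end and whose splice chain is
compatible with the read's block chain.

All intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .phasing import VariantSet

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "Annotation",
    "GeneIndex",
    "NO_FEATURE",
    "AMBIGUOUS",
    "UNASSIGNED",
    "merge_intervals",
    "read_blocks",
    "assign_read_to_gene",
    "count_alleles",
    "snp_overlap_read_count",
    "allelic_count_table",
    "assign_read_to_isoform",
    "count_isoform_alleles",
]

NO_FEATURE = "__no_feature__"
AMBIGUOUS = "__ambiguous__"
UNASSIGNED = "__unassigned__"

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of half-open intervals as a sorted, non-overlapping list."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


@dataclass
class TranscriptModel:
    """One transcript: ordered exons on one strand of one chromosome."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]  # genomic order

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def first_exon(self) -> Interval:
        """The 5'-most exon by strand."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def introns(self) -> list[Interval]:
        return [(e1[1], e2[0]) for e1, e2 in zip(self.exons, self.exons[1:])]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class GeneModel:
    """A gene as the merged exon union over its transcripts."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    biotype: str = "coding"
    is_x_linked: bool = False

    def __post_init__(self) -> None:
        self.exons = merge_intervals(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class Annotation:
    """Gene and transcript models keyed by id."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    @classmethod
    def from_transcripts(
        cls,
        transcripts: Iterable[TranscriptModel],
        biotypes: Mapping[str, str] | None = None,
        x_chrom: str = "chrX",
    ) -> "Annotation":
        """Build gene models as exon unions over their transcripts."""
        ann = cls()
        for tx in transcripts:
            ann.transcripts[tx.transcript_id] = tx
        by_gene: dict[str, list[TranscriptModel]] = {}
        for tx in ann.transcripts.values():
            by_gene.setdefault(tx.gene_id, []).append(tx)
        for gene_id, txs in by_gene.items():
            chroms = {t.chrom for t in txs}
            strands = {t.strand for t in txs}
            if len(chroms) != 1 or len(strands) != 1:
                raise ValueError(f"{gene_id}: transcripts disagree on chrom/strand")
            ann.genes[gene_id] = GeneModel(
                gene_id=gene_id,
                chrom=txs[0].chrom,
                strand=txs[0].strand,
                exons=[e for t in txs for e in t.exons],
                biotype=(biotypes or {}).get(gene_id, "coding"),
                is_x_linked=txs[0].chrom == x_chrom,
            )
        return ann

    def transcripts_of(self, gene_id: str) -> list[TranscriptModel]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]


class GeneIndex:
    """Per-chromosome interval tree over gene exon unions."""

    def __init__(self, annotation: Annotation):
        self._trees: dict[str, IntervalTree] = {}
        self._genes = annotation.genes
        for gene in annotation.genes.values():
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            for start, end in gene.exons:
                tree.addi(start, end, gene.gene_id)

    def overlapping(self, chrom: str, blocks: Sequence[Interval], strand: str | None) -> set[str]:
        """Gene ids whose exons overlap any block (strand-matched if given)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        hits: set[str] = set()
        for start, end in blocks:
            for iv in tree.overlap(start, end):
                hits.add(iv.data)
        if strand is not None:
            hits = {g for g in hits if self._genes[g].strand == strand}
        return hits


def read_blocks(record: pysam.AlignedSegment) -> list[Interval]:
    """Reference intervals consumed by aligned (M/=/X) CIGAR ops."""
    blocks: list[Interval] = []
    cigar = record.cigartuples or []
    rpos = record.reference_start
    for op, ln in cigar:
        if op in (0, 7, 8):
            if blocks and blocks[-1][1] == rpos:
                blocks[-1] = (blocks[-1][0], rpos + ln)
            else:
                blocks.append((rpos, rpos + ln))
            rpos += ln
        elif op in (2, 3):
            rpos += ln
    # merge across deletions: D ops keep blocks contiguous on reference
    return merge_intervals(blocks)


def _read_strand(record: pysam.AlignedSegment) -> str:
    return "-" if record.is_reverse else "+"


def assign_read_to_gene(
    record: pysam.AlignedSegment, index: GeneIndex, stranded: bool = True
) -> str:
    """Union-mode gene assignment for one aligned read.

    Returns the gene id when exactly one (strand-matched) gene is
    overlapped, else :data:`NO_FEATURE` or :data:`AMBIGUOUS`.
    """
    strand = _read_strand(record) if stranded else None
    hits = index.overlapping(record.reference_name, read_blocks(record), strand)
    if not hits:
        return NO_FEATURE
    if len(hits) > 1:
        return AMBIGUOUS
    return next(iter(hits))


_STREAMS = ("maternal", "paternal", "untagged")


def count_alleles(
    maternal: Iterable[pysam.AlignedSegment],
    paternal: Iterable[pysam.AlignedSegment],
    untagged: Iterable[pysam.AlignedSegment],
    annotation: Annotation,
    stranded: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene maternal/paternal/untagged counts from the split streams.

    Every annotated gene gets a row (zeros kept). ``ambiguous`` counts, per
    gene, reads whose overlap set included that gene but was not a
    singleton; totals for ambiguous and no-feature reads are returned in
    the summary dict. Chromosomes present in the alignments but absent
    from the annotation raise a ValueError naming the offenders.
    """
    index = GeneIndex(annotation)
    known_chroms = {g.chrom for g in annotation.genes.values()}
    counts = {
        gid: {"maternal": 0, "paternal": 0, "untagged": 0, "ambiguous": 0}
        for gid in annotation.genes
    }
    summary = {"no_feature": 0, "ambiguous": 0}
    offenders: set[str] = set()
    for stream_name, stream in zip(_STREAMS, (maternal, paternal, untagged)):
        for rec in stream:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name not in known_chroms:
                offenders.add(rec.reference_name)
                continue
            strand = _read_strand(rec) if stranded else None
            hits = index.overlapping(rec.reference_name, read_blocks(rec), strand)
            if not hits:
                summary["no_feature"] += 1
            elif len(hits) > 1:
                summary["ambiguous"] += 1
                for gid in hits:
                    counts[gid]["ambiguous"] += 1
            else:
                counts[next(iter(hits))][stream_name] += 1
    if offenders:
        raise ValueError(
            "alignment chromosomes missing from annotation: " + ", ".join(sorted(offenders))
        )
    rows = []
    for gid, gene in annotation.genes.items():
        c = counts[gid]
        rows.append(
            {
                "feature_id": gid,
                "chrom": gene.chrom,
                "strand": gene.strand,
                "biotype": gene.biotype,
                "is_x_linked": gene.is_x_linked,
                "maternal": c["maternal"],
                "paternal": c["paternal"],
                "untagged": c["untagged"],
                "ambiguous": c["ambiguous"],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "feature_id", "chrom", "strand", "biotype", "is_x_linked",
            "maternal", "paternal", "untagged", "ambiguous",
        ],
    )
    return table, summary


def snp_overlap_read_count(
    stream_union: Iterable[pysam.AlignedSegment],
    variants: VariantSet,
    annotation: Annotation,
    stranded: bool = True,
) -> pd.Series:
    """Per-gene count of gene-assigned reads covering >= 1 phased SNV.

    This is the informativeness denominator: a gene is later deemed
    informative only if enough of its reads actually overlap a variant.
    Counted at the read level (a read covering three SNVs contributes one).
    """
    index = GeneIndex(annotation)
    counts = {gid: 0 for gid in annotation.genes}
    for rec in stream_union:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        gid = assign_read_to_gene(rec, index, stranded=stranded)
        if gid in (NO_FEATURE, AMBIGUOUS):
            continue
        covers = any(
            variants.in_interval(rec.reference_name, start, end)
            for start, end in read_blocks(rec)
        )
        if covers:
            counts[gid] += 1
    return pd.Series(counts, name="snp_overlap_reads")


def allelic_count_table(
    maternal: Sequence[pysam.AlignedSegment],
    paternal: Sequence[pysam.AlignedSegment],
    untagged: Sequence[pysam.AlignedSegment],
    annotation: Annotation,
    variants: VariantSet,
    stranded: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Gene counts joined with the SNP-overlap informativeness column."""
    table, summary = count_alleles(maternal, paternal, untagged, annotation, stranded)
    snp = snp_overlap_read_count(
        list(maternal) + list(paternal) + list(untagged), variants, annotation, stranded
    )
    table = table.merge(
        snp.rename_axis("feature_id").reset_index(), on="feature_id", how="left"
    )
    table["snp_overlap_reads"] = table["snp_overlap_reads"].fillna(0).astype(int)
    return table, summary


def _blocks_within(blocks: Sequence[Interval], exons: Sequence[Interval], tol: int) -> bool:
    padded = merge_intervals([(max(0, s - tol), e + tol) for s, e in exons])
    for bs, be in blocks:
        if not any(s <= bs and be <= e for s, e in padded):
            return False
    return True


def _introns_match(blocks: Sequence[Interval], tx: TranscriptModel, tol: int) -> bool:
    tx_introns = tx.introns
    for (b1, b2) in zip(blocks, blocks[1:]):
        gap = (b1[1], b2[0])
        if not any(
            abs(gap[0] - i[0]) <= tol and abs(gap[1] - i[1]) <= tol for i in tx_introns
        ):
            return False
    return True


def assign_read_to_isoform(
    record: pysam.AlignedSegment,
    transcripts: Sequence[TranscriptModel],
    tss_tolerance: int = 50,
) -> str:
    """First-exon-anchored isoform assignment within one locus.

    The read's 5'-most aligned base (by strand) must fall inside a
    transcript's first exon (padded by ``tss_tolerance``), every read
    block must lie within that transcript's exons, and every skipped
    intron must match a transcript intron within tolerance. Exactly one
    compatible transcript wins; none or several yields
    :data:`UNASSIGNED`.
    """
    if not transcripts:
        return UNASSIGNED
    blocks = read_blocks(record)
    if not blocks:
        return UNASSIGNED
    strand = _read_strand(record)
    five_prime = blocks[0][0] if strand == "+" else blocks[-1][1] - 1
    candidates = []
    for tx in transcripts:
        if tx.strand != strand or tx.chrom != record.reference_name:
            continue
        fs, fe = tx.first_exon
        if not (fs - tss_tolerance <= five_prime < fe + tss_tolerance):
            continue
        if not _blocks_within(blocks, tx.exons, tss_tolerance):
            continue
        if not _introns_match(blocks, tx, tss_tolerance):
            continue
        candidates.append(tx.transcript_id)
    if len(candidates) == 1:
        return candidates[0]
    return UNASSIGNED


def count_isoform_alleles(
    maternal: Iterable[pysam.AlignedSegment],
    paternal: Iterable[pysam.AlignedSegment],
    untagged: Iterable[pysam.AlignedSegment],
    transcripts: Sequence[TranscriptModel],
    tss_tolerance: int = 50,
) -> pd.DataFrame:
    """Per-isoform allelic counts for one multi-isoform locus.

    Only reads overlapping the locus exon union on the locus strand are
    considered; each is attributed to an isoform or to the UNASSIGNED row,
    so assigned + unassigned equals the locus-assigned read count.
    """
    if not transcripts:
        raise ValueError("count_isoform_alleles requires at least one transcript")
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) != 1:
        raise ValueError("transcripts must share one locus")
    chrom = transcripts[0].chrom
    strand = transcripts[0].strand
    union = merge_intervals(e for t in transcripts for e in t.exons)
    counts: dict[str, dict[str, int]] = {
        t.transcript_id: {s: 0 for s in _STREAMS} for t in transcripts
    }
    counts[UNASSIGNED] = {s: 0 for s in _STREAMS}
    for stream_name, stream in zip(_STREAMS, (maternal, paternal, untagged)):
        for rec in stream:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name != chrom or _read_strand(rec) != strand:
                continue
            blocks = read_blocks(rec)
            if not any(s < be and bs < e for bs, be in blocks for s, e in union):
                continue
            tid = assign_read_to_isoform(rec, transcripts, tss_tolerance)
            counts[tid][stream_name] += 1
    rows = []
    for t in transcripts:
        c = counts[t.transcript_id]
        rows.append({"transcript_id": t.transcript_id, "gene_id": t.gene_id, **c})
    rows.append({"transcript_id": UNASSIGNED, "gene_id": transcripts[0].gene_id,
                 **counts[UNASSIGNED]})
    return pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "maternal", "paternal", "untagged"]
    )
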