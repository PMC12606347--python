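"""Haplotype assignment of spliced long reads from phased exonic SNVs.

A read is assigned to the maternal or paternal haplotype by majority vote
over the phased heterozygous SNVs its alignment covers: each covered SNV
whose query base matches one parental allele (at sufficient base quality)
casts one vote; ties — including reads covering no SNV — leave the read
untagged. Tagged alignments can then be split into maternal / paternal /
untagged streams, mirroring the haplotag-then-split stage of phasing
toolchains used for F1-hybrid allele-specific expression.

Conventions: variant positions are 0-based reference coordinates; the
maternal allele is whichever allele the phased genotype lists first
(GT ``0|1`` means maternal = REF, paternal = ALT).
"""

from __future__ import annotations

import enum
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "PhasedVariant",
    "VariantSet",
    "VariantLoadReport",
    "VcfFormatError",
    "Haplotype",
    "HaplotypeTag",
    "load_phased_variants",
    "read_alleles",
    "tag_read",
    "haplotag",
    "split",
    "HP_MATERNAL",
    "HP_PATERNAL",
]

# integer haplotype tag values written to the HP aux field
HP_MATERNAL = 1
HP_PATERNAL = 2
VOTE_TAG = "PC"  # "maternal,paternal,mismatch" vote counts

_BASES = frozenset("ACGT")


class VcfFormatError(ValueError):
    """Raised for a structurally unusable phased VCF (no sample, bad GT)."""


@dataclass(frozen=True)
class PhasedVariant:
    """One biallelic exonic SNV with known parental alleles."""

    chrom: str
    pos: int  # 0-based reference coordinate
    maternal_base: str
    paternal_base: str

    def __post_init__(self) -> None:
        if self.maternal_base not in _BASES or self.paternal_base not in _BASES:
            raise ValueError(f"non-ACGT allele at {self.chrom}:{self.pos}")
        if self.maternal_base == self.paternal_base:
            raise ValueError(f"homozygous variant at {self.chrom}:{self.pos}")

    def swapped(self) -> "PhasedVariant":
        """Variant with the parental alleles exchanged."""
        return PhasedVariant(self.chrom, self.pos, self.paternal_base, self.maternal_base)


class VariantSet:
    """Phased SNVs indexed per chromosome for fast interval queries."""

    def __init__(self, variants: Iterable[PhasedVariant]):
        by_chrom: dict[str, list[PhasedVariant]] = {}
        seen: set[tuple[str, int]] = set()
        for v in variants:
            key = (v.chrom, v.pos)
            if key in seen:
                raise ValueError(f"duplicate variant at {v.chrom}:{v.pos}")
            seen.add(key)
            by_chrom.setdefault(v.chrom, []).append(v)
        self._by_chrom: dict[str, tuple[np.ndarray, list[PhasedVariant]]] = {}
        for chrom, vs in by_chrom.items():
            vs.sort(key=lambda v: v.pos)
            self._by_chrom[chrom] = (np.array([v.pos for v in vs], dtype=np.int64), vs)

    def __len__(self) -> int:
        return sum(len(vs) for _, vs in self._by_chrom.values())

    def __iter__(self) -> Iterator[PhasedVariant]:
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom][1]

    @property
    def chromosomes(self) -> set[str]:
        return set(self._by_chrom)

    def in_interval(self, chrom: str, start: int, end: int) -> list[PhasedVariant]:
        """Variants with start <= pos < end on ``chrom``, in position order."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        positions, vs = entry
        lo = int(np.searchsorted(positions, start, side="left"))
        hi = int(np.searchsorted(positions, end, side="left"))
        return vs[lo:hi]

    def swapped(self) -> "VariantSet":
        return VariantSet(v.swapped() for v in self)


@dataclass
class VariantLoadReport:
    """Bookkeeping of records accepted and skipped while loading a VCF."""

    n_loaded: int = 0
    skipped: dict[str, int] = field(default_factory=dict)

    def skip(self, reason: str) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + 1


def load_phased_variants(vcf_path: str) -> tuple[VariantSet, VariantLoadReport]:
    """Load biallelic phased SNVs from a single-sample VCF.

    The first (only) sample's phased genotype orders the alleles as
    maternal|paternal. Indels, multi-allelic sites, unphased or homozygous
    genotypes, and duplicated positions are skipped and tallied in the
    returned report; a VCF without a sample column raises
    :class:`VcfFormatError`.
    """
    report = VariantLoadReport()
    variants: "OrderedDict[tuple[str, int], PhasedVariant]" = OrderedDict()
    with pysam.VariantFile(vcf_path) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise VcfFormatError(f"{vcf_path}: phased sample column required")
        sample = samples[0]
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                report.skip("multiallelic")
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                report.skip("indel")
                continue
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or len(gt) != 2 or None in gt:
                raise VcfFormatError(f"{vcf_path}: malformed GT at {rec.chrom}:{rec.pos}")
            if not call.phased:
                report.skip("unphased")
                continue
            if gt[0] == gt[1]:
                report.skip("homozygous")
                continue
            if set(gt) != {0, 1}:
                report.skip("multiallelic")
                continue
            alleles = (ref, alt)
            key = (rec.chrom, rec.pos - 1)  # VCF is 1-based
            if key in variants:
                report.skip("duplicate")
                warnings.warn(f"duplicate variant at {rec.chrom}:{rec.pos}; first record wins")
                continue
            variants[key] = PhasedVariant(
                rec.chrom, rec.pos - 1, alleles[gt[0]], alleles[gt[1]]
            )
            report.n_loaded += 1
    return VariantSet(variants.values()), report


class Haplotype(enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    UNTAGGED = "untagged"


@dataclass(frozen=True)
class HaplotypeTag:
    """Outcome of SNV voting for one read (all its alignment records)."""

    label: Haplotype
    maternal_votes: int
    paternal_votes: int
    mismatch_votes: int


def read_alleles(
    record: pysam.AlignedSegment, variants: VariantSet
) -> list[tuple[PhasedVariant, str | None, int | None]]:
    """Observed query base (and quality) at every variant under the alignment.

    Walks the CIGAR once: variants under aligned (M/=/X) ops report the
    query base at that reference position; variants under deletions report
    a gap (``None``); variants under skipped introns (N) are not reported
    at all. Soft-clipped and inserted bases never align to a reference
    position and so never report.
    """
    out: list[tuple[PhasedVariant, str | None, int | None]] = []
    cigar = record.cigartuples
    if cigar is None:
        return out
    seq = record.query_sequence
    quals = record.query_qualities
    rpos = record.reference_start
    qpos = 0
    chrom = record.reference_name
    for op, ln in cigar:
        if op in (0, 7, 8):  # M, =, X consume both
            for v in variants.in_interval(chrom, rpos, rpos + ln):
                qi = qpos + (v.pos - rpos)
                base = seq[qi] if seq is not None else None
                qual = int(quals[qi]) if quals is not None else None
                out.append((v, base, qual))
            rpos += ln
            qpos += ln
        elif op in (1, 4):  # I, S consume query only
            qpos += ln
        elif op == 2:  # D: reference position exists but no query base
            for v in variants.in_interval(chrom, rpos, rpos + ln):
                out.append((v, None, None))
            rpos += ln
        elif op == 3:  # N: skipped intron, variant not observed
            rpos += ln
        # H (5) and P (6) consume neither
    return out


def _is_secondary(rec: pysam.AlignedSegment) -> bool:
    return rec.is_secondary


def tag_read(
    records: Sequence[pysam.AlignedSegment],
    variants: VariantSet,
    min_base_quality: int = 0,
) -> HaplotypeTag:
    """Vote over all primary/supplementary records of one read.

    Each covered SNV with base quality >= ``min_base_quality`` votes for
    the parental allele its query base matches; bases matching neither
    allele accrue mismatch votes and never break ties. A strict majority
    assigns the label; ties (including 0-0) leave the read untagged.
    """
    if not records:
        raise ValueError("tag_read requires at least one alignment record")
    m = p = x = 0
    for rec in records:
        if _is_secondary(rec):
            continue
        for variant, base, qual in read_alleles(rec, variants):
            if base is None:
                continue
            if qual is not None and qual < min_base_quality:
                continue
            if base == variant.maternal_base:
                m += 1
            elif base == variant.paternal_base:
                p += 1
            else:
                x += 1
    if m > p:
        label = Haplotype.MATERNAL
    elif p > m:
        label = Haplotype.PATERNAL
    else:
        label = Haplotype.UNTAGGED
    return HaplotypeTag(label, m, p, x)


def haplotag(
    alignments: Iterable[pysam.AlignedSegment],
    variants: VariantSet,
    min_base_quality: int = 0,
) -> tuple[list[pysam.AlignedSegment], pd.DataFrame]:
    """Tag every read's records with its voted haplotype.

    Votes are pooled across a read's primary and supplementary records;
    secondary records neither vote nor receive a tag. Returns the records
    in input order (mutated in place: HP tag 1=maternal / 2=paternal plus
    a vote-count text tag; untagged records carry no HP tag) and a
    per-label, per-chromosome summary table.
    """
    records = list(alignments)
    groups: "OrderedDict[str, list[pysam.AlignedSegment]]" = OrderedDict()
    for rec in records:
        if rec.is_unmapped or _is_secondary(rec):
            continue
        groups.setdefault(rec.query_name, []).append(rec)

    missing = {
        rec.reference_name
        for rec in records
        if not rec.is_unmapped and rec.reference_name not in variants.chromosomes
    }
    if missing:
        warnings.warn(
            "no phased variants on chromosome(s) %s; reads there stay untagged"
            % ", ".join(sorted(missing))
        )

    tags: dict[str, HaplotypeTag] = {
        name: tag_read(recs, variants, min_base_quality) for name, recs in groups.items()
    }
    rows = []
    for name, recs in groups.items():
        tag = tags[name]
        for rec in recs:
            if tag.label is Haplotype.MATERNAL:
                rec.set_tag("HP", HP_MATERNAL)
            elif tag.label is Haplotype.PATERNAL:
                rec.set_tag("HP", HP_PATERNAL)
            elif rec.has_tag("HP"):
                rec.set_tag("HP", None)
            rec.set_tag(
                VOTE_TAG,
                f"{tag.maternal_votes},{tag.paternal_votes},{tag.mismatch_votes}",
            )
        rows.append(
            {
                "read_id": name,
                "chrom": recs[0].reference_name,
                "label": tag.label.value,
                "n_votes": tag.maternal_votes + tag.paternal_votes,
            }
        )
    per_read = pd.DataFrame(rows, columns=["read_id", "chrom", "label", "n_votes"])
    if per_read.empty:
        summary = pd.DataFrame(columns=["label", "chrom", "n_reads", "n_votes_mean"])
    else:
        summary = (
            per_read.groupby(["label", "chrom"], as_index=False)
            .agg(n_reads=("read_id", "size"), n_votes_mean=("n_votes", "mean"))
        )
    return records, summary


def split(
    tagged: Iterable[pysam.AlignedSegment],
) -> tuple[list[pysam.AlignedSegment], list[pysam.AlignedSegment], list[pysam.AlignedSegment]]:
    """Partition tagged records into (maternal, paternal, untagged) streams."""
    maternal: list[pysam.AlignedSegment] = []
    paternal: list[pysam.AlignedSegment] = []
    untagged: list[pysam.AlignedSegment] = []
    for rec in tagged:
        hp = rec.get_tag("HP") if rec.has_tag("HP") else None
        if hp == HP_MATERNAL:
            maternal.append(rec)
        elif hp == HP_PATERNAL:
            paternal.append(rec)
        else:
            untagged.append(rec)
    return maternal, paternal, untagged
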