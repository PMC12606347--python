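"""Synthetic F1-hybrid long-read dataset with known allelic truth.

Emulates the design used to map allele-specific expression in a
polymorphic mouse cross: two inbred parental genomes differing at exonic
SNVs, a daughter F1 whose reads can be assigned to a parent by those
SNVs, and a skewed X-inactivation setup in which the maternal X is forced
active so paternal X reads diagnose inactive-X expression.

The generator builds a small diploid genome (the reference is the
maternal haplotype; the paternal haplotype substitutes the alternate base
at each SNV), multi-exon gene models, and spliced read alignments drawn
per gene from its true maternal fraction:

* autosomal genes are biallelic (0.5), imprinted (0 or 1) or
  strain-biased (0.8 / 0.2 by default);
* with skewed XCI, X-linked genes are fully maternal except a
  paternal-only Xist-like gene and a configurable number of escape genes
  (default maternal fraction 0.67);
* an optional imprinted-cluster locus carries four isoforms with distinct
  first exons sharing 3' exons — biallelic, maternal-only, paternal-only
  and silent — emulating the Gnas cluster;
* optional antisense gene pairs overlap exonically on opposite strands,
  the case that defeats unstranded counting.

Reads are emitted directly as spliced alignments (exon match blocks,
intron skips), so haplotagging and counting are exercised without any
aligner in the loop. Every read has a truth row (gene, transcript,
haplotype of origin). All outputs are deterministic given the config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .counting import Annotation, TranscriptModel
from .phasing import PhasedVariant, VariantSet

__all__ = [
    "SimConfig",
    "SimulationSizeError",
    "SimGenome",
    "SimTruth",
    "build_genome",
    "simulate_reads",
    "write_fixtures",
    "simulate_dataset",
    "simulate_short_read_counts",
    "GNAS_GENE_ID",
    "GNAS_ISOFORMS",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

GNAS_GENE_ID = "geneGnasL"
# isoform name -> (true maternal fraction, fixed depth, biotype)
GNAS_ISOFORMS: dict[str, tuple[float, int, str]] = {
    "gsa_like": (0.5, 215, "coding"),
    "nesp_like": (1.0, 6, "coding"),
    "ex1a_like": (0.0, 26, "noncoding"),
    "nespas_like": (0.0, 0, "noncoding"),
}

_CLASS_FRACTIONS = {
    "biallelic": 0.5,
    "maternal_imprinted": 1.0,
    "paternal_imprinted": 0.0,
}


class SimulationSizeError(ValueError):
    """A chromosome is too short for the requested gene layout."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic F1-hybrid dataset.

    Depths are negative-binomial per gene (mean ``depth_mean``, dispersion
    ``depth_dispersion`` = NB size; larger means closer to Poisson), SNVs
    per exon are Poisson(``snp_per_exon_rate``), and substitution errors
    hit each read base independently with ``base_error_rate``.
    """

    seed: int = 0
    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 400_000),
        ("chr2", 400_000),
        ("chrX", 400_000),
    )
    n_genes: int = 20  # per chromosome, before special loci
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (150, 300)
    intron_length: tuple[int, int] = (200, 600)
    intergenic_gap: tuple[int, int] = (500, 1500)
    snp_per_exon_rate: float = 2.0
    depth_mean: float = 60.0
    depth_dispersion: float = 8.0
    base_error_rate: float = 1e-4  # HiFi-like Q40 default
    gene_class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "biallelic": 0.60,
            "maternal_imprinted": 0.10,
            "paternal_imprinted": 0.10,
            "maternal_strain_bias": 0.10,
            "paternal_strain_bias": 0.10,
        }
    )
    strain_bias_fraction: float = 0.8
    xci_skewed: bool = True
    escape_gene_count: int = 2
    escape_maternal_fraction: float = 0.67
    include_gnas_like: bool = True
    antisense_pair_count: int = 1
    noncoding_fraction: float = 0.1  # of ordinary genes
    x_chrom: str = "chrX"

    def validate(self) -> None:
        total = sum(self.gene_class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"gene_class_fractions sums to {total}, not 1")
        if not (0.0 <= self.base_error_rate <= 0.05):
            raise ValueError("base_error_rate must lie in [0, 0.05]")
        if self.n_genes < 0 or self.escape_gene_count < 0 or self.antisense_pair_count < 0:
            raise ValueError("counts must be non-negative")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"{name}: non-positive length")
        if self.exons_per_gene[0] < 1 or self.exons_per_gene[0] > self.exons_per_gene[1]:
            raise ValueError("invalid exons_per_gene range")
        if self.depth_mean < 0 or self.depth_dispersion <= 0:
            raise ValueError("invalid depth model")
        if self.xci_skewed and self.n_genes > 0:
            if self.escape_gene_count + 1 > self.n_genes:
                raise ValueError("chrX needs room for the Xist-like gene plus escape genes")


@dataclass
class _TranscriptPlan:
    transcript_id: str
    gene_id: str
    maternal_fraction: float
    depth: int
    status: str


@dataclass
class SimGenome:
    """Reference sequences, phased SNVs and annotation of the simulation."""

    config: SimConfig
    sequences: dict[str, str]
    variants: VariantSet
    annotation: Annotation
    plans: list[_TranscriptPlan]

    @property
    def header(self) -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [
                    {"SN": name, "LN": length}
                    for name, length in self.config.chromosomes
                ],
            }
        )


@dataclass
class SimTruth:
    """Ground truth: per-gene parameters, per-isoform status, per-read origin."""

    genes: pd.DataFrame
    isoforms: pd.DataFrame
    reads: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["read_id", "gene_id", "transcript_id", "haplotype"]
        )
    )


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _gene_structure(
    rng: np.random.Generator, cfg: SimConfig, cursor: int
) -> tuple[list[tuple[int, int]], int]:
    """Sample exon intervals for one gene starting after ``cursor``."""
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_exons)
    intron_lens = (
        rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1, size=n_exons - 1)
        if n_exons > 1
        else np.array([], dtype=int)
    )
    gap = int(rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1))
    start = cursor + gap
    exons = []
    pos = start
    for i, ln in enumerate(exon_lens):
        exons.append((pos, pos + int(ln)))
        pos += int(ln)
        if i < len(intron_lens):
            pos += int(intron_lens[i])
    return exons, pos


def _autosomal_class(rng: np.random.Generator, cfg: SimConfig) -> tuple[str, float]:
    names = list(cfg.gene_class_fractions)
    probs = np.array([cfg.gene_class_fractions[n] for n in names], dtype=float)
    label = str(rng.choice(names, p=probs / probs.sum()))
    if label in _CLASS_FRACTIONS:
        frac = _CLASS_FRACTIONS[label]
    elif label == "maternal_strain_bias":
        frac = cfg.strain_bias_fraction
    elif label == "paternal_strain_bias":
        frac = 1.0 - cfg.strain_bias_fraction
    else:
        raise ValueError(f"unknown gene class {label!r}")
    return label, frac


def _nb_depth(rng: np.random.Generator, cfg: SimConfig) -> int:
    size = cfg.depth_dispersion
    if cfg.depth_mean == 0:
        return 0
    p = size / (size + cfg.depth_mean)
    return int(rng.negative_binomial(size, p))


def build_genome(config: SimConfig) -> tuple[SimGenome, SimTruth]:
    """Lay out genes, draw SNVs, and fix each gene's allelic truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_len = dict(config.chromosomes)

    transcripts: list[TranscriptModel] = []
    biotypes: dict[str, str] = {}
    plans: list[_TranscriptPlan] = []
    gene_rows: list[dict] = []
    iso_rows: list[dict] = []

    def add_gene(
        gene_id: str,
        chrom: str,
        strand: str,
        exons: list[tuple[int, int]],
        label: str,
        frac: float,
        biotype: str,
        depth: int,
    ) -> None:
        tx_id = f"{gene_id}.t1"
        transcripts.append(TranscriptModel(tx_id, gene_id, chrom, strand, exons))
        biotypes[gene_id] = biotype
        plans.append(_TranscriptPlan(tx_id, gene_id, frac, depth, label))
        gene_rows.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "strand": strand,
                "class": label,
                "true_maternal_fraction": frac,
                "biotype": biotype,
                "is_x_linked": chrom == config.x_chrom,
            }
        )
        iso_rows.append(
            {
                "transcript_id": tx_id,
                "gene_id": gene_id,
                "allelic_status": label,
                "true_maternal_fraction": frac,
                "depth": depth,
            }
        )

    for chrom, length in config.chromosomes:
        cursor = 0
        is_x = chrom == config.x_chrom
        for i in range(config.n_genes):
            exons, cursor = _gene_structure(rng, config, cursor)
            strand = str(rng.choice(["+", "-"]))
            if cursor >= length:
                raise SimulationSizeError(
                    f"{chrom}: gene layout exceeds length {length} at gene {i + 1}"
                )
            if is_x and config.xci_skewed:
                if i == 0:
                    label, frac, biotype = "xist_like", 0.0, "noncoding"
                elif i <= config.escape_gene_count:
                    label, frac = "xci_escape", config.escape_maternal_fraction
                    biotype = "coding"
                else:
                    label, frac, biotype = "xci_subject", 1.0, "coding"
            else:
                label, frac = _autosomal_class(rng, config)
                biotype = "noncoding" if rng.random() < config.noncoding_fraction else "coding"
            add_gene(
                f"gene_{chrom}_{i:03d}", chrom, strand, exons, label, frac,
                biotype, _nb_depth(rng, config),
            )

        if chrom == config.chromosomes[0][0]:
            if config.include_gnas_like:
                cursor = _add_gnas_locus(rng, config, chrom, cursor, transcripts,
                                         biotypes, plans, gene_rows, iso_rows)
            for j in range(config.antisense_pair_count):
                cursor = _add_antisense_pair(rng, config, chrom, cursor, j, add_gene)
            if cursor >= length:
                raise SimulationSizeError(f"{chrom}: special loci exceed length {length}")

    # reference sequences (the maternal haplotype)
    sequences = {name: _random_seq(rng, length) for name, length in config.chromosomes}

    # exonic SNVs per gene union; first record wins at shared positions
    annotation = Annotation.from_transcripts(transcripts, biotypes, x_chrom=config.x_chrom)
    variants: dict[tuple[str, int], PhasedVariant] = {}
    for gene in annotation.genes.values():
        seq = sequences[gene.chrom]
        for start, end in gene.exons:
            k = int(rng.poisson(config.snp_per_exon_rate))
            if k == 0:
                continue
            k = min(k, end - start)
            offsets = np.sort(rng.choice(end - start, size=k, replace=False))
            for off in offsets:
                pos = start + int(off)
                if (gene.chrom, pos) in variants:
                    continue
                ref = seq[pos].decode()
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                variants[(gene.chrom, pos)] = PhasedVariant(gene.chrom, pos, ref, alt)

    genome = SimGenome(
        config=config,
        sequences={name: arr.tobytes().decode() for name, arr in sequences.items()},
        variants=VariantSet(variants.values()),
        annotation=annotation,
        plans=plans,
    )
    truth = SimTruth(
        genes=pd.DataFrame(
            gene_rows,
            columns=["gene_id", "chrom", "strand", "class", "true_maternal_fraction",
                     "biotype", "is_x_linked"],
        ),
        isoforms=pd.DataFrame(
            iso_rows,
            columns=["transcript_id", "gene_id", "allelic_status",
                     "true_maternal_fraction", "depth"],
        ),
    )
    return genome, truth


def _add_gnas_locus(rng, config, chrom, cursor, transcripts, biotypes, plans,
                    gene_rows, iso_rows) -> int:
    """Four overlapping isoforms with distinct first exons sharing 3' exons."""
    exons, cursor = _gene_structure(
        rng, replace(config, exons_per_gene=(6, 6)), cursor
    )
    shared = exons[4:]  # common 3' exons
    order = ["nesp_like", "nespas_like", "ex1a_like", "gsa_like"]  # 5' -> 3' starts
    depth_total_m = 0.0
    depth_total = 0
    for i, name in enumerate(order):
        frac, depth, biotype = GNAS_ISOFORMS[name]
        tx = TranscriptModel(name, GNAS_GENE_ID, chrom, "+", [exons[i]] + shared)
        transcripts.append(tx)
        plans.append(_TranscriptPlan(name, GNAS_GENE_ID, frac, depth, name))
        iso_rows.append(
            {
                "transcript_id": name,
                "gene_id": GNAS_GENE_ID,
                "allelic_status": {0.5: "biallelic", 1.0: "maternal_only"}.get(
                    frac, "silent" if depth == 0 else "paternal_only"
                ),
                "true_maternal_fraction": frac,
                "depth": depth,
            }
        )
        depth_total_m += frac * depth
        depth_total += depth
    biotypes[GNAS_GENE_ID] = "coding"
    gene_rows.append(
        {
            "gene_id": GNAS_GENE_ID,
            "chrom": chrom,
            "strand": "+",
            "class": "gnas_like",
            # depth-weighted mean over expressed isoforms
            "true_maternal_fraction": depth_total_m / depth_total if depth_total else math.nan,
            "biotype": "coding",
            "is_x_linked": False,
        }
    )
    return cursor


def _add_antisense_pair(rng, config, chrom, cursor, idx, add_gene) -> int:
    """A sense host gene with a single-exon antisense gene inside it."""
    exons, cursor = _gene_structure(
        rng, replace(config, exons_per_gene=(max(3, config.exons_per_gene[0]),
                                             max(3, config.exons_per_gene[1]))),
        cursor,
    )
    host_id = f"gene_{chrom}_host{idx}"
    anti_id = f"gene_{chrom}_anti{idx}"
    add_gene(host_id, chrom, "+", exons, "biallelic", 0.5, "coding",
             _nb_depth(rng, config))
    # antisense exon coincides with the host's second exon (Peg13-in-Trappc9 style)
    add_gene(anti_id, chrom, "-", [exons[1]], "paternal_imprinted", 0.0,
             "noncoding", _nb_depth(rng, config))
    return cursor


def _spliced_cigar(exons: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    cigar: list[tuple[int, int]] = []
    for i, (start, end) in enumerate(exons):
        if i:
            cigar.append((3, start - exons[i - 1][1]))  # N
        cigar.append((0, end - start))  # M
    return cigar


def simulate_reads(
    genome: SimGenome, truth: SimTruth, config: SimConfig | None = None
) -> tuple[list[pysam.AlignedSegment], pd.DataFrame]:
    """Draw spliced reads per transcript from its true maternal fraction.

    Each read takes its covered SNV bases from the drawn haplotype
    (reference base for maternal, alternate for paternal), then per-base
    substitution errors. Records come back coordinate-sorted;
    ``truth.reads`` is filled with one row per read.
    """
    cfg = config or genome.config
    rng = np.random.default_rng(cfg.seed + 1)  # separate stream from build_genome
    header = genome.header
    records: list[pysam.AlignedSegment] = []
    truth_rows: list[dict] = []
    counter = 0
    for plan in genome.plans:
        tx = genome.annotation.transcripts[plan.transcript_id]
        seq = genome.sequences[tx.chrom]
        exon_seqs = [seq[s:e] for s, e in tx.exons]
        covered = [genome.variants.in_interval(tx.chrom, s, e) for s, e in tx.exons]
        cigar = _spliced_cigar(tx.exons)
        length = sum(e - s for s, e in tx.exons)
        for _ in range(plan.depth):
            hap = "M" if rng.random() < plan.maternal_fraction else "P"
            bases = bytearray("".join(exon_seqs), "ascii")
            if hap == "P":
                offset = 0
                for (s, e), vs in zip(tx.exons, covered):
                    for v in vs:
                        bases[offset + (v.pos - s)] = ord(v.paternal_base)
                    offset += e - s
            if cfg.base_error_rate > 0:
                hits = np.flatnonzero(rng.random(length) < cfg.base_error_rate)
                for i in hits:
                    old = chr(bases[i])
                    bases[i] = ord(str(rng.choice([b for b in "ACGT" if b != old])))
            read_id = f"r{counter:07d}"
            counter += 1
            rec = pysam.AlignedSegment(header)
            rec.query_name = read_id
            rec.flag = 16 if tx.strand == "-" else 0
            rec.reference_id = header.get_tid(tx.chrom)
            rec.reference_start = tx.start
            rec.mapping_quality = 60
            rec.cigartuples = cigar
            rec.query_sequence = bases.decode()
            rec.query_qualities = pysam.qualitystring_to_array("I" * length)  # Q40
            records.append(rec)
            truth_rows.append(
                {
                    "read_id": read_id,
                    "gene_id": plan.gene_id,
                    "transcript_id": plan.transcript_id,
                    "haplotype": hap,
                }
            )
    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name))
    reads = pd.DataFrame(
        truth_rows, columns=["read_id", "gene_id", "transcript_id", "haplotype"]
    )
    truth.reads = reads
    return records, reads


def write_fixtures(
    genome: SimGenome,
    records: Sequence[pysam.AlignedSegment],
    truth: SimTruth,
    outdir,
) -> dict[str, str]:
    """Write FASTA / VCF / GTF / sorted SAM / truth TSVs; returns the paths."""
    from pathlib import Path

    from . import io as lio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": str(out / "reference.fa"),
        "vcf": str(out / "variants.vcf"),
        "gtf": str(out / "annotation.gtf"),
        "sam": str(out / "alignments.sam"),
        "truth_reads": str(out / "truth_reads.tsv"),
        "truth_genes": str(out / "truth_genes.tsv"),
        "truth_isoforms": str(out / "truth_isoforms.tsv"),
    }
    lio.write_fasta(genome.sequences, paths["fasta"])
    lio.write_phased_vcf(genome.variants, dict(genome.config.chromosomes), paths["vcf"])
    lio.write_gtf(genome.annotation, paths["gtf"])
    with pysam.AlignmentFile(paths["sam"], "w", header=genome.header) as sam:
        for rec in records:
            sam.write(rec)
    truth.reads.to_csv(paths["truth_reads"], sep="\t", index=False)
    truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    truth.isoforms.to_csv(paths["truth_isoforms"], sep="\t", index=False)
    return paths


def simulate_dataset(config: SimConfig, outdir=None):
    """Convenience: build genome, simulate reads, optionally write files."""
    genome, truth = build_genome(config)
    records, _ = simulate_reads(genome, truth, config)
    paths = write_fixtures(genome, records, truth, outdir) if outdir is not None else None
    return genome, truth, records, paths


def simulate_short_read_counts(
    truth: SimTruth,
    seed: int,
    depth_mean: float = 300.0,
    depth_dispersion: float = 8.0,
) -> pd.DataFrame:
    """Short-read-style allelic count table resampled from the same truth.

    Stands in for an external short-read pipeline's output: per gene an
    independent negative-binomial depth and a binomial maternal draw at
    the gene's true fraction, with every read assumed SNV-overlapping.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for row in truth.genes.itertuples(index=False):
        frac = row.true_maternal_fraction
        if math.isnan(frac):
            frac = 0.5
        p = depth_dispersion / (depth_dispersion + depth_mean)
        n = int(rng.negative_binomial(depth_dispersion, p)) if depth_mean > 0 else 0
        m = int(rng.binomial(n, frac)) if n else 0
        rows.append(
            {
                "feature_id": row.gene_id,
                "chrom": row.chrom,
                "is_x_linked": row.is_x_linked,
                "biotype": row.biotype,
                "maternal": m,
                "paternal": n - m,
                "untagged": 0,
                "ambiguous": 0,
                "snp_overlap_reads": n,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "chrom", "is_x_linked", "biotype", "maternal",
                 "paternal", "untagged", "ambiguous", "snp_overlap_reads"],
    )
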