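#!/usr/bin/env python
"""Per-isoform allelic counts at the simulated imprinted cluster.

The locus carries four overlapping isoforms with distinct first exons
sharing 3' exons: a biallelic coding isoform, a maternal-only isoform, a
paternal-only isoform and a silent one. First-exon-anchored assignment
recovers allele-specific counts per isoform; the table goes to
results/isoform_counts.tsv.
"""

import argparse
from pathlib import Path

from lorase import io as lio
from lorase.counting import count_isoform_alleles
from lorase.simulate import GNAS_GENE_ID

parser = argparse.ArgumentParser()
parser.add_argument("--simdir", type=Path, default=Path("scratch/sim"))
parser.add_argument("--phasedir", type=Path, default=Path("scratch/phasing"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
parser.add_argument("--locus", default=GNAS_GENE_ID)
args = parser.parse_args()

annotation = lio.read_gtf(args.simdir / "annotation.gtf")
streams = [
    lio.read_alignments(args.phasedir / f"alignments.{name}.sam")[0]
    for name in ("maternal", "paternal", "untagged")
]
transcripts = annotation.transcripts_of(args.locus)
iso = count_isoform_alleles(*streams, transcripts)
iso.to_csv(args.outdir / "isoform_counts.tsv", sep="\t", index=False)

print(iso.to_string(index=False))
expressed = iso[(iso.maternal + iso.paternal) > 0]
expressed = expressed[expressed.transcript_id != "__unassigned__"]
print(f"\n{len(expressed)} expressed isoforms with allele-specific information")
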