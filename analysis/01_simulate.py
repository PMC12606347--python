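#!/usr/bin/env python
"""Simulate the synthetic F1-hybrid long-read dataset.

Writes reference FASTA, phased VCF, GTF, coordinate-sorted SAM and truth
tables under results/sim/, and prints what the genome contains. All later
analysis steps start from these files.
"""

import argparse
from pathlib import Path

from lorase.simulate import SimConfig, simulate_dataset

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("scratch/sim"))
args = parser.parse_args()

config = SimConfig(seed=args.seed)
genome, truth, records, paths = simulate_dataset(config, args.outdir)

print(f"chromosomes : {', '.join(f'{n} ({l} bp)' for n, l in config.chromosomes)}")
print(f"genes       : {len(truth.genes)} "
      f"({truth.genes['class'].value_counts().to_dict()})")
print(f"phased SNVs : {len(genome.variants)}")
print(f"reads       : {len(truth.reads)} spliced alignments")
print(f"outputs     : {', '.join(Path(p).name for p in paths.values())} -> {args.outdir}")
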