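# Methods

## Problem setting and model

In an F1 hybrid between two polymorphic inbred strains, each autosome
carries one maternal and one paternal haplotype distinguished by known
exonic SNVs. We model allele-specific expression per feature (gene or
isoform) as a binomial process: each sequenced molecule originates from
the maternal haplotype with probability θ (the true maternal fraction)
and from the paternal haplotype with probability 1 − θ. Imprinted genes
have θ ∈ {0, 1}, biallelic genes θ = 0.5, strain-biased genes an
intermediate θ. The observed allelic ratio r = m/(m + p) over tagged
reads is the maximum-likelihood estimate of θ, with standard error
√(θ(1 − θ)/n); all recovery tests in this package are phrased as
3-SE binomial bounds on |r − θ|.

The maternal haplotype is identified with the reference genome and the
paternal haplotype with the alternate allele at every phased SNV
(matching a cross in which the maternal strain is the reference strain).
The phased genotype `0|1` therefore reads maternal|paternal.

## Haplotagging

A read's records (primary plus supplementary; secondary alignments are
ignored) are walked once through their CIGARs. Every phased SNV under an
aligned (M/=/X) op contributes the query base at that reference position;
SNVs under deletions are observed as gaps and SNVs under skipped introns
(N) are not observed at all. A base equal to the maternal allele with
quality ≥ `min_base_quality` votes maternal, a paternal base paternal;
anything else is a mismatch vote. The label is the strict majority of
maternal vs paternal votes; ties — including zero votes — leave the read
untagged, and mismatch votes never break ties. This simple deterministic
voter replaces the likelihood machinery of general-purpose phasing tools;
for HiFi-grade data, where a single confidently sequenced SNV suffices to
identify the allele, the two coincide in practice, and the voter is
verified against a brute-force per-base alignment expansion on fuzzed
spliced reads. `min_base_quality` defaults to 0 because HiFi base
qualities are uniformly high; raise it for noisier chemistries.

Mis-tagging requires at least ⌈k/2⌉ of a read's k covered SNVs to be
corrupted *toward the other allele* (probability e/3 per base at
substitution rate e), so the mis-tag rate is bounded by the tail of
Binomial(k, e/3); the test suite checks simulated data against this
bound.

## Counting

Gene-level counting uses stranded union semantics: the set of annotated
genes whose merged exon unions overlap any aligned block of the read,
restricted to the read's strand, must be a singleton; otherwise the read
is ambiguous (overlap ≥ 2) or unassigned (overlap 0). Ambiguous reads are
excluded from all allelic tables. Strandedness is taken directly from the
alignment flag, appropriate for orientation-resolved full-length cDNA
reads; it is what resolves antisense gene pairs (a noncoding gene sitting
antisense inside a host gene's exons) that confound unstranded short-read
counting. Gene exon unions are always rebuilt from transcript exons; gene
records in the GTF are not trusted for extents.

The informativeness denominator is the number of gene-assigned reads
covering ≥ 1 phased SNV, counted at the read level. It is computed on
reads after union-mode assignment (ambiguous reads do not contribute).

Isoform-level counting serves loci where overlapping isoforms share 3′
exons but differ in their first exon (the *Gnas*-cluster architecture).
A read is attributed to the unique transcript satisfying all of: the
read's 5′-most aligned base (by strand) lies within the transcript's
first exon padded by `tss_tolerance` (default 50 bp); every aligned block
lies within the transcript's padded exons; every skipped intron matches a
transcript intron with both boundaries within tolerance. No unique
transcript → unassigned, so assigned + unassigned always equals the
locus read count. The 50 bp default absorbs minor TSS heterogeneity
without letting distinct first exons (separated by introns ≥ 200 bp in
the simulator, and typically kilobases in real annotations) collide.

## Classification and XCI escape

Features with ≥ `min_informative_reads` SNV-overlapping reads (default
10; 20 recommended for short-read tables, reflecting the shorter reads'
lower per-read SNV coverage) are classified by hard cutoffs with
boundaries on the allele-specific side: r ≥ 0.7 maternal, r ≤ 0.3
paternal, else biallelic. Features with no tagged reads have an undefined
ratio and are never classified biallelic. No significance testing is
attached — the cutoff scheme is deliberately the simple, reproducible
rule used in hybrid ASE screens; add replicates and a binomial test
downstream if calibrated error rates are needed.

Escape detection assumes a fully skewed XCI design with the maternal X
active (the situation engineered by deleting the *Xist* A-repeat on the
maternal allele, so the paternal X is always inactivated). For every
informative X-linked gene: ratio > `xci_subject_ratio` (default 0.9) →
subject to XCI; ratio ≤ `low_cut` → inactive-X-only expression (the
*Xist*-like signature); otherwise escape candidate if ≥
`min_inactive_reads` (default 2) paternal reads support inactive-X
expression, a floor that suppresses single-read artefacts. The 0.9
subject boundary is exposed as a parameter because reasonable analyses
may prefer a stricter or looser definition of "essentially monoallelic".

## Concordance

Two call tables are joined on features informative in both. Reported:
Venn counts of biallelic and allele-specific labels, direction agreement
among features allele-specific in both tables, and Pearson correlation of
the ratios (two-sided p from the t transform with n − 2 df, via
scipy), optionally repeated over a user-supplied subset such as known
imprinted genes. Undefined correlations (fewer than 3 shared features, or
zero variance) are reported as null rather than raising.

## Synthetic data generator

The generator emulates the study design the package targets: a small
diploid genome (three 400 kb chromosomes, one of them X) whose reference
is the maternal haplotype; Poisson(2) exonic SNVs per exon; 20 multi-exon
genes per chromosome (3–6 exons of 150–300 bp, introns 200–600 bp);
negative-binomial per-gene depth (mean 60, dispersion 8 — the NB spread
is an assumption, chosen so the informativeness filter is actually
exercised by low-depth genes); per-base substitution error 1e-4
(HiFi-like Q40). Autosomal genes draw a class from {biallelic 0.6,
maternal-imprinted 0.1, paternal-imprinted 0.1, maternal-bias 0.1,
paternal-bias 0.1} with θ = 0.5 / 1 / 0 / 0.8 / 0.2. With skewed XCI, X
genes are fully maternal except one paternal-only *Xist*-like noncoding
gene and two escape genes at θ = 0.67 (near the canonical escape-gene
observation of roughly two-thirds active-X expression). The
imprinted-cluster locus carries four isoforms with distinct first exons
sharing two 3′ exons — biallelic (depth 215), maternal-only (6),
paternal-only (26), silent (0); these depths are fixed, not NB-drawn, so
the locus reproduces the expression pattern it emulates deterministically.
One antisense pair (noncoding single-exon gene on the opposite strand
inside a biallelic host's second exon) exercises stranded counting.

Reads are emitted directly as spliced alignments — exon-length match
blocks separated by intron skips at the transcript's true position — so
tagging and counting are tested without mapping error; every read gets a
truth row (gene, transcript, haplotype). Consequently the simulation does
not model alignment artefacts, truncated or internally primed cDNAs,
poly-A tails, supplementary/chimeric splits, or realistic HiFi error
profiles; passing recovery tests demonstrates correctness of the
tagging/counting/classification logic under the binomial model, not
robustness to mapping error. The short-read-style comparison table is a
binomial resampling of the same truth at higher depth — it stands in for
an external short-read ASE pipeline's output table, not for short-read
alignment itself.

Determinism: one `numpy` Generator seeded from `SimConfig.seed` drives
genome construction and a second (seed + 1) drives read drawing; byte
reproducibility of all output files is under test.

## Numerical and interface choices

- Coordinates are 0-based half-open internally; conversion happens only
  at the VCF (1-based) and GTF (1-based closed) boundaries.
- Duplicate VCF positions: first record wins with a warning; indels,
  multi-allelic and unphased records are skipped and tallied.
- Chromosome names must match exactly between inputs; a `--chr-alias`
  style mapping is available in the IO layer rather than silent prefix
  stripping. Alignments on chromosomes absent from the annotation raise
  an explicit error listing the offenders; chromosomes absent from the
  variant set produce a warning and untagged reads.
- TSV schemas (column order and names) are frozen; every stage writes a
  JSON run log with parameters and input digests.
- Problem sizes in the test-suite simulations (10–40 genes per
  chromosome, depths 25–200, 10,000 fuzzed reads for the oracle
  equivalence) were chosen to give the statistical assertions ≥ 100
  genes where fractions are asserted, while keeping the whole suite in
  the tens of seconds.

## Known limitations

- The voter has no likelihood model: at high error rates with few SNVs a
  quality-aware model would mis-tag less. Documented divergence from
  general phasing tools.
- Union counting discards multi-gene reads entirely; no rescue by
  fractional assignment.
- Isoform assignment requires a distinct first exon; isoforms differing
  only internally are reported unassigned rather than guessed.
- Escape detection is specific to the fully skewed maternal-active
  design; balanced XCI would require a different (mixture) model.
- The hard-cutoff classifier has no error control; borderline genes
  fluctuate with depth, which the concordance module makes visible but
  does not correct.
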