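"""Haplotagging: VCF loading, CIGAR-walk allele extraction, voting, splitting."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from conftest import make_header, make_read, oracle_alleles, oracle_vote, random_spliced_read
from lorase import phasing as ph
from lorase.phasing import (
    Haplotype,
    PhasedVariant,
    VariantSet,
    VcfFormatError,
    load_phased_variants,
    read_alleles,
    split,
    tag_read,
)


def write_vcf(path, body_lines, sample="F1"):
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=100000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    )
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if sample:
        cols += f"\tFORMAT\t{sample}"
    path.write_text(header + cols + "\n" + "".join(l + "\n" for l in body_lines))


class TestLoadPhasedVariants:
    def test_filters_and_bookkeeping(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        write_vcf(vcf, [
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1",
            "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1|0",
            "chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t0|1",
            "chr1\t400\t.\tAT\tA\t.\tPASS\t.\tGT\t0|1",   # indel
            "chr1\t500\t.\tT\tC\t.\tPASS\t.\tGT\t0/1",    # unphased
        ])
        variants, report = load_phased_variants(str(vcf))
        assert len(variants) == 3
        assert report.n_loaded == 3
        assert report.skipped == {"indel": 1, "unphased": 1}

    def test_gt_order_defines_parental_alleles(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        write_vcf(vcf, ["chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1|0"])
        variants, _ = load_phased_variants(str(vcf))
        v = next(iter(variants))
        assert v.pos == 199  # 0-based
        assert (v.maternal_base, v.paternal_base) == ("T", "C")

    def test_empty_body_ok(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        write_vcf(vcf, [])
        variants, report = load_phased_variants(str(vcf))
        assert len(variants) == 0 and report.n_loaded == 0

    def test_missing_sample_is_format_error(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        write_vcf(vcf, [], sample=None)
        with pytest.raises(VcfFormatError):
            load_phased_variants(str(vcf))

    def test_duplicate_position_first_wins(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        write_vcf(vcf, [
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1",
            "chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0|1",
        ])
        with pytest.warns(UserWarning, match="duplicate"):
            variants, report = load_phased_variants(str(vcf))
        assert len(variants) == 1
        assert next(iter(variants)).paternal_base == "G"
        assert report.skipped == {"duplicate": 1}


class TestReadAlleles:
    header = make_header()

    def test_variant_in_intron_not_reported(self):
        vs = VariantSet([PhasedVariant("chr1", 120, "A", "G")])
        rec = make_read(self.header, "chr1", 100, [(0, 10), (3, 100), (0, 10)], "A" * 20)
        assert read_alleles(rec, vs) == []

    def test_variant_at_last_base_of_exon_block(self):
        vs = VariantSet([PhasedVariant("chr1", 109, "A", "G")])
        seq = "C" * 9 + "G" + "C" * 10
        rec = make_read(self.header, "chr1", 100, [(0, 10), (3, 50), (0, 10)], seq)
        [(v, base, qual)] = read_alleles(rec, vs)
        assert (v.pos, base, qual) == (109, "G", 40)

    def test_soft_clip_offsets_query_index(self):
        # 5S10M, variant at block offset 3 -> query index 8
        vs = VariantSet([PhasedVariant("chr1", 103, "A", "G")])
        seq = "T" * 5 + "AAA" + "G" + "A" * 6
        rec = make_read(self.header, "chr1", 100, [(4, 5), (0, 10)], seq)
        [(v, base, _)] = read_alleles(rec, vs)
        assert base == seq[8] == "G"

    def test_deletion_yields_gap_entry(self):
        vs = VariantSet([PhasedVariant("chr1", 105, "A", "G")])
        rec = make_read(self.header, "chr1", 100, [(0, 5), (2, 3), (0, 5)], "A" * 10)
        [(v, base, qual)] = read_alleles(rec, vs)
        assert base is None and qual is None

    @given(st.integers(0, 2**32 - 1))
    def test_matches_per_base_expansion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rec = random_spliced_read(rng, self.header)
        span = rec.reference_end - rec.reference_start
        positions = rng.choice(span, size=min(10, span), replace=False)
        vs = VariantSet([
            PhasedVariant("chr1", rec.reference_start + int(p), "A", "G")
            for p in positions
        ])
        got = [(v.pos, b, q) for v, b, q in read_alleles(rec, vs) if b is not None]
        expect = [(v.pos, b, q) for v, b, q in oracle_alleles(rec, vs)]
        assert got == expect


class TestTagRead:
    header = make_header()

    def _read_over(self, variants, bases, start=100):
        """One read with an M block covering the given variants."""
        end = max(v.pos for v in variants) + 1
        seq = list("A" * (end - start))
        for v, b in zip(sorted(variants, key=lambda v: v.pos), bases):
            seq[v.pos - start] = b
        return make_read(self.header, "chr1", start, [(0, end - start)], "".join(seq))

    def test_single_snv_suffices(self):
        v = PhasedVariant("chr1", 150, "C", "T")
        rec = self._read_over([v], ["C"])
        tag = tag_read([rec], VariantSet([v]))
        assert tag.label is Haplotype.MATERNAL
        assert (tag.maternal_votes, tag.paternal_votes) == (1, 0)

    def test_tie_is_untagged(self):
        vs = [PhasedVariant("chr1", 150 + i, "C", "T") for i in range(4)]
        rec = self._read_over(vs, ["C", "C", "T", "T"])
        tag = tag_read([rec], VariantSet(vs))
        assert tag.label is Haplotype.UNTAGGED
        assert (tag.maternal_votes, tag.paternal_votes) == (2, 2)

    def test_no_covered_variant_untagged(self):
        vs = VariantSet([PhasedVariant("chr1", 5000, "C", "T")])
        rec = make_read(self.header, "chr1", 100, [(0, 50)], "A" * 50)
        tag = tag_read([rec], vs)
        assert tag.label is Haplotype.UNTAGGED
        assert (tag.maternal_votes, tag.paternal_votes) == (0, 0)

    def test_mismatch_votes_never_break_ties(self):
        vs = [PhasedVariant("chr1", 150, "C", "T"), PhasedVariant("chr1", 160, "C", "T")]
        rec = self._read_over(vs, ["G", "G"])  # neither allele
        tag = tag_read([rec], VariantSet(vs))
        assert tag.label is Haplotype.UNTAGGED
        assert tag.mismatch_votes == 2

    def test_low_quality_bases_excluded(self):
        v = PhasedVariant("chr1", 110, "C", "T")
        seq = "A" * 10 + "C" + "A" * 9
        rec = make_read(make_header(), "chr1", 100, [(0, 20)], seq, quals=[5] * 20)
        assert tag_read([rec], VariantSet([v]), min_base_quality=10).label is Haplotype.UNTAGGED
        assert tag_read([rec], VariantSet([v]), min_base_quality=0).label is Haplotype.MATERNAL

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            tag_read([], VariantSet([]))

    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_voter(self, seed):
        rng = np.random.default_rng(seed)
        rec = random_spliced_read(rng, self.header)
        span = rec.reference_end - rec.reference_start
        k = int(rng.integers(1, 12))
        positions = rng.choice(span, size=min(k, span), replace=False)
        variants = []
        for p in positions:
            mat, pat = rng.choice(list("ACGT"), size=2, replace=False)
            variants.append(PhasedVariant("chr1", rec.reference_start + int(p), mat, pat))
        vs = VariantSet(variants)
        tag = tag_read([rec], vs)
        label, m, p = oracle_vote([rec], vs)
        assert (tag.label, tag.maternal_votes, tag.paternal_votes) == (label, m, p)

    @given(st.integers(0, 2**32 - 1))
    def test_allele_swap_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        rec = random_spliced_read(rng, self.header)
        span = rec.reference_end - rec.reference_start
        positions = rng.choice(span, size=min(6, span), replace=False)
        variants = []
        for p in positions:
            mat, pat = rng.choice(list("ACGT"), size=2, replace=False)
            variants.append(PhasedVariant("chr1", rec.reference_start + int(p), mat, pat))
        vs = VariantSet(variants)
        tag = tag_read([rec], vs)
        swapped = tag_read([rec], vs.swapped())
        flip = {Haplotype.MATERNAL: Haplotype.PATERNAL,
                Haplotype.PATERNAL: Haplotype.MATERNAL,
                Haplotype.UNTAGGED: Haplotype.UNTAGGED}
        assert swapped.label is flip[tag.label]
        assert (swapped.maternal_votes, swapped.paternal_votes) == (
            tag.paternal_votes, tag.maternal_votes)
        assert swapped.mismatch_votes == tag.mismatch_votes


class TestHaplotagAndSplit:
    def test_noiseless_tags_equal_truth(self, noiseless_sim):
        genome, truth, records = noiseless_sim
        tagged, _ = ph.haplotag(records, genome.variants)
        hap = dict(zip(truth.reads.read_id, truth.reads.haplotype))
        n_checked = 0
        for rec in tagged:
            covered = any(
                v for v, b, _ in ph.read_alleles(rec, genome.variants) if b is not None
            )
            if covered:
                assert rec.get_tag("HP") == (1 if hap[rec.query_name] == "M" else 2)
                n_checked += 1
            else:
                assert not rec.has_tag("HP")
        assert n_checked > 1000

    def test_no_variants_means_all_untagged(self, noiseless_sim):
        genome, truth, records = noiseless_sim
        with pytest.warns(UserWarning, match="untagged"):
            tagged, summary = ph.haplotag(records, VariantSet([]))
        assert all(not r.has_tag("HP") for r in tagged)
        assert set(summary.label) <= {"untagged"}

    def test_supplementary_record_inherits_group_tag(self):
        header = make_header()
        v = PhasedVariant("chr1", 110, "C", "T")
        seq = "A" * 10 + "C" + "A" * 9
        primary = make_read(header, "chr1", 100, [(0, 20)], seq, name="rA")
        supp = make_read(header, "chr1", 5000, [(0, 10)], "A" * 10, name="rA",
                         flag_extra=0x800)
        tagged, _ = ph.haplotag([primary, supp], VariantSet([v]))
        assert all(r.get_tag("HP") == 1 for r in tagged)

    def test_secondary_records_do_not_vote(self):
        header = make_header()
        v = PhasedVariant("chr1", 110, "C", "T")
        seq = "A" * 10 + "T" + "A" * 9  # paternal base, but on a secondary record
        primary = make_read(header, "chr1", 5000, [(0, 10)], "A" * 10, name="rA")
        secondary = make_read(header, "chr1", 100, [(0, 20)], seq, name="rA",
                              flag_extra=0x100)
        tag = tag_read([primary, secondary], VariantSet([v]))
        assert tag.label is Haplotype.UNTAGGED

    def test_split_partitions_and_conserves(self, noiseless_sim):
        genome, _, records = noiseless_sim
        tagged, _ = ph.haplotag(records, genome.variants)
        m, p, u = split(tagged)
        assert len(m) + len(p) + len(u) == len(tagged)
        ids = sorted(r.query_name for r in m + p + u)
        assert ids == sorted(r.query_name for r in tagged)

    def test_maternal_stream_contains_only_truth_maternal(self, noiseless_sim, noiseless_streams):
        _, truth, _ = noiseless_sim
        m, p, _ = noiseless_streams
        hap = dict(zip(truth.reads.read_id, truth.reads.haplotype))
        assert all(hap[r.query_name] == "M" for r in m)
        assert all(hap[r.query_name] == "P" for r in p)

    def test_mistag_rate_bounded_by_binomial_model(self):
        """With error rate e, a read with k covered SNVs mis-tags only if
        >= ceil(k/2) of them are corrupted toward the other allele
        (probability e/3 per base); the empirical rate must stay within
        3 SE of that bound."""
        from lorase.simulate import SimConfig, build_genome, simulate_reads

        e = 0.02
        cfg = SimConfig(seed=13, n_genes=15, depth_mean=80, base_error_rate=e,
                        include_gnas_like=False, antisense_pair_count=0)
        genome, truth = build_genome(cfg)
        records, reads = simulate_reads(genome, truth)
        tagged, _ = ph.haplotag(records, genome.variants)
        hap = dict(zip(reads.read_id, reads.haplotype))
        n = mistags = 0
        bound_sum = 0.0
        for rec in tagged:
            if not rec.has_tag("HP"):
                continue
            k = sum(1 for _, b, _ in ph.read_alleles(rec, genome.variants) if b is not None)
            n += 1
            bound_sum += stats.binom.sf(math.ceil(k / 2) - 1, k, e / 3)
            got = "M" if rec.get_tag("HP") == 1 else "P"
            mistags += got != hap[rec.query_name]
        bound = bound_sum / n
        assert mistags / n <= bound + 3 * math.sqrt(max(bound * (1 - bound), 1e-12) / n)
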