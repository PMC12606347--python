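import numpy as np
import pysam
import pytest
from hypothesis import HealthCheck, settings

from lorase import phasing as ph
from lorase.simulate import SimConfig, build_genome, simulate_reads

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_header(chroms=(("chr1", 100_000),)):
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": n, "LN": ln} for n, ln in chroms]}
    )


def make_read(header, chrom, start, cigar, seq, name="read1", reverse=False,
              quals=None, flag_extra=0):
    """Construct an aligned segment from explicit CIGAR and query sequence."""
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.flag = (16 if reverse else 0) | flag_extra
    rec.reference_id = header.get_tid(chrom)
    rec.reference_start = start
    rec.mapping_quality = 60
    rec.cigartuples = cigar
    rec.query_sequence = seq
    if quals is None:
        quals = [40] * len(seq)
    rec.query_qualities = quals
    return rec


def random_spliced_read(rng, header, chrom="chr1", name="fuzz", max_start=5_000):
    """A random alignment mixing S/M/I/D/N ops with a random query sequence."""
    start = int(rng.integers(0, max_start))
    n_ops = int(rng.integers(1, 8))
    cigar = []
    ops = []
    prev = None
    for _ in range(n_ops):
        op = int(rng.choice([0, 1, 2, 3]))
        if op == prev or (prev in (2, 3) and op in (2, 3)):
            op = 0
        ops.append(op)
        prev = op
    if ops[0] != 0:
        ops.insert(0, 0)
    if ops[-1] != 0:
        ops.append(0)
    if rng.random() < 0.3:
        cigar.append((4, int(rng.integers(1, 10))))
    for op in ops:
        ln = int(rng.integers(1, 40)) if op != 3 else int(rng.integers(20, 200))
        cigar.append((op, ln))
    if rng.random() < 0.3:
        cigar.append((4, int(rng.integers(1, 10))))
    qlen = sum(ln for op, ln in cigar if op in (0, 1, 4))
    seq = "".join(rng.choice(list("ACGT"), size=qlen))
    return make_read(header, chrom, start, cigar, seq, name=name)


def oracle_alleles(rec, variants):
    """Per-base expansion oracle for the base observed at each variant."""
    pairs = dict(
        (rpos, qpos)
        for qpos, rpos in rec.get_aligned_pairs(matches_only=True)
    )
    out = []
    chrom = rec.reference_name
    for v in sorted(variants.in_interval(chrom, rec.reference_start, rec.reference_end),
                    key=lambda v: v.pos):
        if v.pos in pairs:
            qi = pairs[v.pos]
            out.append((v, rec.query_sequence[qi], rec.query_qualities[qi]))
    return out


def oracle_vote(records, variants, min_bq=0):
    """Brute-force voter over the per-base expansion."""
    m = p = 0
    for rec in records:
        if rec.is_secondary:
            continue
        for v, base, q in oracle_alleles(rec, variants):
            if q < min_bq:
                continue
            if base == v.maternal_base:
                m += 1
            elif base == v.paternal_base:
                p += 1
    if m > p:
        return ph.Haplotype.MATERNAL, m, p
    if p > m:
        return ph.Haplotype.PATERNAL, m, p
    return ph.Haplotype.UNTAGGED, m, p


@pytest.fixture(scope="session")
def noiseless_config():
    return SimConfig(seed=11, n_genes=10, base_error_rate=0.0)


@pytest.fixture(scope="session")
def noiseless_sim(noiseless_config):
    genome, truth = build_genome(noiseless_config)
    records, _ = simulate_reads(genome, truth)
    return genome, truth, records


@pytest.fixture(scope="session")
def noiseless_streams(noiseless_sim):
    genome, truth, records = noiseless_sim
    tagged, _ = ph.haplotag(records, genome.variants)
    return ph.split(tagged)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
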