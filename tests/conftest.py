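import random
import re

import pysam
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def write_bam(path, reads, chrom="chr1", length=10_000, sort_order="coordinate"):
    """Write read dicts (name, flag, pos1, cigar, seq, quals, mapq[, nh,
    mate_pos1]) to an indexed coordinate-sorted BAM."""
    header = {
        "HD": {"VN": "1.6", "SO": sort_order},
        "SQ": [{"SN": chrom, "LN": length}],
    }
    ordered = sorted(reads, key=lambda r: r["pos1"]) if sort_order == "coordinate" else reads
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in ordered:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = r["name"]
            a.flag = r["flag"]
            a.reference_id = 0
            a.reference_start = r["pos1"] - 1
            a.mapping_quality = r["mapq"]
            a.cigarstring = r["cigar"]
            a.query_sequence = r["seq"]
            a.query_qualities = r["quals"]
            if r["flag"] & 0x1:
                a.next_reference_id = 0
                a.next_reference_start = r.get("mate_pos1", r["pos1"]) - 1
            if "nh" in r:
                a.set_tag("NH", r["nh"])
            bam.write(a)
    if sort_order == "coordinate":
        pysam.index(str(path))
    return path


def random_reads(rng: random.Random, n_reads: int, chrom="chr1"):
    """Messy random fixture: pairs and singles with mixed flags, MAPQs,
    qualities, CIGAR shapes and NH tags, over a ~200 bp window."""
    reads = []
    i = 0
    while len(reads) < n_reads:
        paired = rng.random() < 0.7
        name = f"r{i}"
        i += 1

        def one(flag_extra, pos1, mate_pos1):
            length = rng.randint(8, 20)
            cigar_kind = rng.random()
            if cigar_kind < 0.6:
                cigar = f"{length}M"
            elif cigar_kind < 0.75:
                a = length // 2
                cigar = f"{a}M2D{length - a}M"
            elif cigar_kind < 0.9:
                a = max(1, length // 2)
                cigar = f"{a}M3N{length - a}M"
            else:
                clip = rng.randint(1, 3)
                cigar = f"{clip}S{length - clip}M"
                length += 0  # seq length includes the clip below
            seq_len = sum(int(n) for n, _op in re.findall(r"(\d+)([MIS=X])", cigar))
            flag = flag_extra
            if rng.random() < 0.15:
                flag |= 0x400  # duplicate
            if rng.random() < 0.1:
                flag |= 0x100  # secondary
            if rng.random() < 0.08:
                flag |= 0x800  # supplementary
            return {
                "name": name,
                "flag": flag,
                "chrom": chrom,
                "pos1": pos1,
                "cigar": cigar,
                "seq": "".join(rng.choice("ACGTN") for _ in range(seq_len)),
                "quals": [rng.randint(5, 45) for _ in range(seq_len)],
                "mapq": rng.choice([0, 30, 60, 60]),
                "nh": rng.choice([1, 1, 1, 2]),
                "mate_pos1": mate_pos1,
            }

        if paired:
            proper = 0x2 if rng.random() < 0.8 else 0
            p1 = rng.randint(1, 180)
            p2 = p1 + rng.randint(0, 15)  # often-overlapping mates
            reads.append(one(0x1 | proper | 0x40, p1, p2))
            reads.append(one(0x1 | proper | 0x80, p2, p1))
        else:
            reads.append(one(0x0, rng.randint(1, 180), 0))
    return reads[:n_reads]


@pytest.fixture
def bam_factory(tmp_path):
    def make(reads, name="sample.bam", **kw):
        return write_bam(tmp_path / name, reads, **kw)

    return make
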