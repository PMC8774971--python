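"""Independent brute-force oracles the implementation is checked against.

Everything here is written from first principles (integer hypergeometric
enumeration, explicit CIGAR walking, explicit step-up loops) and shares no
code with the package internals.
"""

from __future__ import annotations

import re
from itertools import combinations
from math import comb

# ---------------------------------------------------------------------------
# pileup: per-read, per-position brute force over SAM-style read dicts
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_MATE_UNMAPPED = 0x8
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_DUP = 0x400
FLAG_SUPPLEMENTARY = 0x800


def _aligned_bases(read):
    """Yield (refpos1, base, qual) for M/=/X cigar ops of one read dict."""
    pos = read["pos1"]
    qpos = 0
    for n, op in _CIGAR_RE.findall(read["cigar"]):
        n = int(n)
        if op in "M=X":
            for i in range(n):
                yield pos + i, read["seq"][qpos + i], read["quals"][qpos + i]
            pos += n
            qpos += n
        elif op in "DN":
            pos += n
        elif op in "IS":
            qpos += n
        # H/P consume nothing we track


def pileup_bruteforce(reads, min_base_quality=30, min_mapping_quality=60,
                      exclude_duplicates=True, exclude_multimappers=True,
                      require_concordant_pairs=True):
    """Expected per-position base counts for a list of read dicts.

    Read dicts carry: name, flag, chrom, pos1, cigar, seq, quals, mapq and
    optionally nh.  A fragment whose mates both cover a position counts
    once, keeping the higher-quality base (read1 on ties).
    """
    passing = []
    for r in reads:
        flag = r["flag"]
        if exclude_duplicates and (flag & FLAG_DUP):
            continue
        if r["mapq"] < min_mapping_quality:
            continue
        if require_concordant_pairs and not (flag & FLAG_PROPER):
            continue
        if exclude_multimappers:
            if flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
                continue
            if r.get("nh", 1) > 1:
                continue
        passing.append(r)

    # group mapped-pair mates by (chrom, name); singles stand alone
    fragments = {}
    singles = []
    for r in passing:
        if (r["flag"] & FLAG_PAIRED) and not (r["flag"] & FLAG_MATE_UNMAPPED):
            fragments.setdefault((r["chrom"], r["name"]), []).append(r)
        else:
            singles.append(r)

    counts = {}

    def add(chrom, contribs):
        for pos, (base, q) in contribs.items():
            key = (chrom, pos)
            slot = counts.setdefault(key, {"A": 0, "C": 0, "G": 0, "T": 0, "qsum": 0.0})
            if base in "ACGT":
                slot[base] += 1
                slot["qsum"] += q

    for r in singles:
        contrib = {}
        for pos, base, q in _aligned_bases(r):
            if q >= min_base_quality and base in "ACGT":
                contrib[pos] = (base, q)
        add(r["chrom"], contrib)

    for (chrom, _name), mates in fragments.items():
        # read1 first so it wins quality ties
        mates.sort(key=lambda r: bool(r["flag"] & FLAG_READ2))
        merged = {}
        for r in mates:
            for pos, base, q in _aligned_bases(r):
                if q < min_base_quality or base not in "ACGT":
                    continue
                if pos not in merged or q > merged[pos][1]:
                    merged[pos] = (base, q)
        add(chrom, merged)
    return counts


# ---------------------------------------------------------------------------
# Fisher exact: full-table enumeration with integer arithmetic
# ---------------------------------------------------------------------------


def fisher_enumeration(k1, n1, k2, n2):
    """Two-sided Fisher p by enumerating every table with the observed
    margins; exact rational arithmetic, then one final division."""
    k = k1 + k2
    lo, hi = max(0, k - n2), min(k, n1)
    weights = {x: comb(n1, x) * comb(n2, k - x) for x in range(lo, hi + 1)}
    total = sum(weights.values())
    obs = weights[k1]
    return sum(w for w in weights.values() if w <= obs) / total


# ---------------------------------------------------------------------------
# Benjamini–Hochberg: explicit step-up with running minimum
# ---------------------------------------------------------------------------


def bh_stepup_oracle(pvals, m_total):
    """Adjusted p-values in input order, computed by the textbook step-up:
    walk ranks from largest to smallest keeping the running minimum."""
    indexed = sorted(range(len(pvals)), key=lambda i: pvals[i])
    adj_sorted = [None] * len(pvals)
    running = 1.0
    for rank in range(len(pvals), 0, -1):
        i = indexed[rank - 1]
        running = min(running, pvals[i] * m_total / rank)
        adj_sorted[rank - 1] = running
    out = [None] * len(pvals)
    for rank, i in enumerate(indexed):
        out[i] = adj_sorted[rank]
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum: exact enumeration of group assignments
# ---------------------------------------------------------------------------


def ranksum_enumeration(x, y):
    """Exact two-sided rank-sum p for tie-free samples by enumerating all
    C(n1+n2, n1) equally likely assignments of the pooled ranks."""
    n1, n2 = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) // 2
    u_low = min(u_obs, n1 * n2 - u_obs)
    count = 0
    total = 0
    for grp in combinations(range(1, n1 + n2 + 1), n1):
        u = sum(grp) - n1 * (n1 + 1) // 2
        total += 1
        if u <= u_low or u >= n1 * n2 - u_low:
            count += 1
    return min(1.0, count / total)
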