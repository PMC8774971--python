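"""Pileup-based de novo detection of candidate RNA-editing positions.

A-to-I editing shows up in RNA-Seq as A→G mismatches against the genome
(inosine is read as guanosine).  Without matched DNA, every position whose
filtered read stack contains a non-reference base is a candidate; genetic
variation is removed downstream by the filter cascade.  The read and base
filters mirror the de novo calling settings of REDItools-style analysis:
minimum base quality 30, minimum mapping quality 60, duplicates and
multi-mappers excluded, concordant pairs only, and a single read sufficing
for both coverage and variant support.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pysam

from .formats_io import CodingAnnotation, complement_base, complement_substitution

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclass(frozen=True)
class FilterConfig:
    """Read- and base-level filters applied before counting.

    Defaults correspond to: base quality ≥ 30 (-q), mapping quality ≥ 60
    (-m, unique mapping for hisat2-style aligners), coverage ≥ 1 read (-c),
    variant support ≥ 1 read (-v), duplicates excluded (-d), multi-hit
    reads excluded (-e), concordant pairs only (-p).
    """

    min_base_quality: int = 30
    min_mapping_quality: int = 60
    min_coverage: int = 1
    min_variant_reads: int = 1
    exclude_duplicates: bool = True
    exclude_multimappers: bool = True
    require_concordant_pairs: bool = True

    def __post_init__(self):
        for name in ("min_base_quality", "min_mapping_quality", "min_coverage",
                     "min_variant_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class BaseDistribution:
    """Filtered base counts at one position."""

    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0
    quality_sum: float = 0.0

    @property
    def coverage(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def mean_quality(self) -> float:
        cov = self.coverage
        return round(self.quality_sum / cov, 2) if cov else 0.0

    def count(self, base: str) -> int:
        return (self.a, self.c, self.g, self.t)[_BASE_INDEX[base]]

    def _add(self, base_idx: int, quality: int):
        if base_idx == 0:
            self.a += 1
        elif base_idx == 1:
            self.c += 1
        elif base_idx == 2:
            self.g += 1
        else:
            self.t += 1
        self.quality_sum += quality


@dataclass(frozen=True)
class SiteCall:
    """One candidate edited position.

    ``substitutions`` are ref→alt codes on the annotated strand (forward
    reference reading until :func:`assign_strand` resolves the strand);
    ``frequency`` is variant reads / coverage for the principal (most
    supported) substitution.
    """

    chrom: str
    position: int  # 1-based
    strand: str  # '+', '-' or '?' (unknown)
    reference_base: str
    distribution: BaseDistribution
    substitutions: tuple
    frequency: float
    is_a_to_i: bool
    gene: Optional[str] = None

    def replace(self, **kw) -> "SiteCall":
        return dataclasses.replace(self, **kw)

    @property
    def site(self) -> Tuple[str, int]:
        return (self.chrom, self.position)


def _classify_a_to_i(strand: str, substitutions) -> bool:
    return strand in ("+", "-") and "AG" in substitutions


def _read_passes(read, config: FilterConfig) -> bool:
    if read.is_unmapped:
        return False
    if config.exclude_duplicates and read.is_duplicate:
        return False
    if read.mapping_quality < config.min_mapping_quality:
        return False
    if config.require_concordant_pairs and not read.is_proper_pair:
        return False
    if config.exclude_multimappers:
        if read.is_secondary or read.is_supplementary:
            return False
        try:
            if read.get_tag("NH") > 1:
                return False
        except KeyError:
            pass
    return True


def _read_contributions(read, config: FilterConfig, bounds=None):
    """(pos1 -> (base_idx, quality)) for aligned, quality-passing bases.

    Insertions, deletions and reference skips contribute nothing
    (``matches_only`` drops unaligned pairs); N bases are ignored.
    """
    seq = read.query_sequence
    quals = read.query_qualities
    out = {}
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        q = quals[qpos]
        if q < config.min_base_quality:
            continue
        idx = _BASE_INDEX.get(seq[qpos].upper())
        if idx is None:
            continue
        pos1 = rpos + 1
        if bounds is not None and not (bounds[0] <= pos1 <= bounds[1]):
            continue
        out[pos1] = (idx, q)
    return out


def _merge_mates(first, second):
    """One fragment covering a position contributes once: the higher-quality
    base wins; on a quality tie the first mate's base is kept."""
    merged = dict(first)
    for pos, (idx, q) in second.items():
        if pos not in merged or q > merged[pos][1]:
            merged[pos] = (idx, q)
    return merged


def accumulate_pileup(
    alignments,
    region: Optional[Tuple[str, int, int]] = None,
    config: Optional[FilterConfig] = None,
) -> Dict[Tuple[str, int], BaseDistribution]:
    """Count filtered bases per genomic position.

    Parameters
    ----------
    alignments
        Path to a coordinate-sorted SAM/BAM (indexed if ``region`` is
        given), or an open :class:`pysam.AlignmentFile`.
    region
        Optional (chrom, start1, end1) interval, 1-based inclusive.
    config
        Filter thresholds; defaults to :class:`FilterConfig`.

    Returns
    -------
    dict mapping (chrom, 1-based position) → :class:`BaseDistribution`.
    """
    config = config or FilterConfig()
    own = not isinstance(alignments, pysam.AlignmentFile)
    af = pysam.AlignmentFile(str(alignments)) if own else alignments
    try:
        so = (af.header.to_dict().get("HD") or {}).get("SO")
        if so != "coordinate":
            raise ValueError(
                "alignments are not coordinate-sorted; run `samtools sort` "
                "(and `samtools index`) first"
            )
        if region is not None:
            chrom, start1, end1 = region
            try:
                reads = af.fetch(chrom, start1 - 1, end1)
            except ValueError as exc:
                raise ValueError(
                    f"region queries need an index; run `samtools index` ({exc})"
                ) from None
            bounds = (start1, end1)
        else:
            reads = af.fetch(until_eof=True)
            bounds = None

        counts: Dict[Tuple[str, int], BaseDistribution] = {}
        # reads buffered until their (potentially overlapping) mate arrives
        pending: Dict[Tuple[str, str], dict] = {}

        def commit(chrom, contrib):
            for pos, (idx, q) in contrib.items():
                dist = counts.get((chrom, pos))
                if dist is None:
                    dist = counts[(chrom, pos)] = BaseDistribution()
                dist._add(idx, q)

        for read in reads:
            if not _read_passes(read, config):
                continue
            contrib = _read_contributions(read, config, bounds)
            chrom = read.reference_name
            paired_same_chrom = (
                read.is_paired
                and not read.mate_is_unmapped
                and read.next_reference_id == read.reference_id
            )
            if not paired_same_chrom:
                commit(chrom, contrib)
                continue
            key = (chrom, read.query_name)
            mate = pending.pop(key, None)
            if mate is None:
                pending[key] = (contrib, read.is_read2)
            else:
                mate_contrib, mate_is_read2 = mate
                if mate_is_read2 and not read.is_read2:
                    first, second = contrib, mate_contrib
                else:
                    first, second = mate_contrib, contrib
                commit(chrom, _merge_mates(first, second))
        for (chrom, _), (contrib, _r2) in pending.items():
            commit(chrom, contrib)
        return counts
    finally:
        if own:
            af.close()


def _reference_base(reference, chrom: str, pos1: int) -> str:
    """Fetch one reference base; accepts pyfaidx.Fasta or a plain mapping."""
    if isinstance(reference, Mapping):
        return reference[chrom][pos1 - 1].upper()
    return str(reference[chrom][pos1 - 1 : pos1]).upper()


def call_sites(
    pileup: Mapping[Tuple[str, int], BaseDistribution],
    reference,
    config: Optional[FilterConfig] = None,
) -> List[SiteCall]:
    """Emit a call for every position with sufficient coverage and at least
    one non-reference base with sufficient support.

    Substitutions are listed in descending count order (alphabetical on
    ties); the reported frequency belongs to the principal substitution.
    Positions whose reference base is N are skipped.
    """
    config = config or FilterConfig()
    calls: List[SiteCall] = []
    for (chrom, pos), dist in sorted(pileup.items()):
        cov = dist.coverage
        if cov < config.min_coverage:
            continue
        ref = _reference_base(reference, chrom, pos)
        if ref not in _BASE_INDEX:
            logger.debug("skipping %s:%d: reference base %r", chrom, pos, ref)
            continue
        variants = [
            (dist.count(alt), alt)
            for alt in _BASES
            if alt != ref and dist.count(alt) >= config.min_variant_reads
        ]
        if not variants:
            continue
        variants.sort(key=lambda x: (-x[0], x[1]))
        subs = tuple(ref + alt for _, alt in variants)
        freq = variants[0][0] / cov
        calls.append(
            SiteCall(
                chrom=chrom, position=pos, strand="?", reference_base=ref,
                distribution=dist, substitutions=subs, frequency=freq,
                is_a_to_i=False,
            )
        )
    return calls


def assign_strand(call: SiteCall, annotation: CodingAnnotation) -> SiteCall:
    """Resolve a call's strand from the annotated gene strand.

    On a −-strand gene the observed forward-reference substitutions are
    complemented (T→C becomes A→G) so that A-to-I events read as AG on
    the transcribed strand.  Positions overlapped by genes on both
    strands, or by none, stay unknown and carry ``is_a_to_i=False``.
    """
    gene, strand = annotation.strand_at(call.chrom, call.position)
    if strand is None:
        return call.replace(strand="?", gene=None, is_a_to_i=False)
    if strand == "-":
        subs = tuple(complement_substitution(s) for s in call.substitutions)
        ref = complement_base(call.reference_base)
    else:
        subs = call.substitutions
        ref = call.reference_base
    return call.replace(
        strand=strand, gene=gene, substitutions=subs, reference_base=ref,
        is_a_to_i=_classify_a_to_i(strand, subs),
    )


def call_sample(
    alignments,
    reference,
    annotation: Optional[CodingAnnotation] = None,
    config: Optional[FilterConfig] = None,
    region: Optional[Tuple[str, int, int]] = None,
) -> List[SiteCall]:
    """Pileup → threshold calling → strand assignment for one sample."""
    config = config or FilterConfig()
    pileup = accumulate_pileup(alignments, region=region, config=config)
    calls = call_sites(pileup, reference, config)
    if annotation is not None:
        calls = [assign_strand(c, annotation) for c in calls]
    return calls
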