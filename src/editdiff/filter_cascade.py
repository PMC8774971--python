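"""Filtering of candidate calls into the two analysis branches.

The cascade runs strand/A-to-I classification → coding restriction → SNV
exclusion → known-site split.  The individual filters commute, so the
order is fixed purely for reproducible logs.  Its product feeds two
branches: sites matched to the known-editing catalog go to per-site
differential testing; the full coding A-to-I set goes to the per-sample
editing-burden comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

from .formats_io import CodingAnnotation, KnownEditingCatalog, SnvCatalog
from .site_caller import SiteCall

logger = logging.getLogger(__name__)


@dataclass
class FilteredSiteSets:
    """The two branches: all coding A-to-I calls, and the subset matching
    the known-editing catalog (position + substitution compatible)."""

    coding_a_to_i: List[SiteCall] = field(default_factory=list)
    known_matched: List[SiteCall] = field(default_factory=list)


def exclude_snv_positions(
    calls: List[SiteCall],
    snvs: SnvCatalog,
    allele_aware: bool = False,
) -> List[SiteCall]:
    """Drop calls at catalogued SNV positions (input order preserved).

    Positional by default: a position listed in the catalog is treated as
    genetic variation regardless of alleles.  With ``allele_aware`` a call
    survives unless its principal ref→alt pair matches a catalogued allele
    pair.
    """
    if not allele_aware:
        return [c for c in calls if (c.chrom, c.position) not in snvs]
    out = []
    for c in calls:
        sub = c.substitutions[0] if c.substitutions else "NN"
        if not snvs.matches(c.chrom, c.position, sub[0], sub[1], allele_aware=True):
            out.append(c)
    return out


def restrict_coding_a_to_i(
    calls: List[SiteCall], annotation: CodingAnnotation
) -> List[SiteCall]:
    """Keep A-to-I calls inside protein-coding regions, attaching the gene
    name.  Calls without a resolved strand (``is_a_to_i`` false) drop out."""
    out = []
    for c in calls:
        if not c.is_a_to_i:
            continue
        gene, strand = annotation.strand_at(c.chrom, c.position)
        if gene is None:
            continue
        out.append(c if c.gene == gene else c.replace(gene=gene))
    return out


def split_by_known(
    calls: List[SiteCall], known: KnownEditingCatalog
) -> FilteredSiteSets:
    """Partition calls by known-editing-catalog membership.

    A match requires the catalog entry at (chrom, pos) to carry a
    compatible substitution (AG after strand resolution); an entry whose
    strand conflicts with the call's assigned strand is treated as
    unmatched with a warning.
    """
    matched = []
    for c in calls:
        entry = known.get(c.chrom, c.position)
        if entry is None:
            continue
        strand, subst = entry
        if c.strand in ("+", "-") and strand != c.strand:
            logger.warning(
                "known-site strand %s conflicts with assigned strand %s at %s:%d; "
                "treating as unmatched", strand, c.strand, c.chrom, c.position,
            )
            continue
        if subst not in c.substitutions:
            continue
        matched.append(c)
    return FilteredSiteSets(coding_a_to_i=list(calls), known_matched=matched)


def apply_filter_cascade(
    calls: List[SiteCall],
    annotation: CodingAnnotation,
    snvs: SnvCatalog,
    known: KnownEditingCatalog,
    allele_aware_snv: bool = False,
) -> FilteredSiteSets:
    """Run the full cascade on strand-assigned calls."""
    coding = restrict_coding_a_to_i(calls, annotation)
    non_snv = exclude_snv_positions(coding, snvs, allele_aware=allele_aware_snv)
    return split_by_known(non_snv, known)
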