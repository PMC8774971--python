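"""Cohort-level orchestration: per-sample calling + filtering into
profiles, then the differential and burden analyses."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from .diff_stats import (
    BurdenResult,
    ContingencyRecord,
    SampleProfile,
    burden_per_sample,
    differential_table,
)
from .filter_cascade import FilteredSiteSets, apply_filter_cascade
from .formats_io import CodingAnnotation, KnownEditingCatalog, SnvCatalog
from .site_caller import FilterConfig, call_sample


def mapped_read_count(bam_path) -> int:
    """Number of mapped reads (the burden library-size normaliser)."""
    with pysam.AlignmentFile(str(bam_path)) as af:
        try:
            return af.mapped
        except ValueError:  # no index: count
            return sum(1 for r in af.fetch(until_eof=True) if not r.is_unmapped)


def process_sample(
    bam_path,
    reference,
    annotation: CodingAnnotation,
    snvs: SnvCatalog,
    known: KnownEditingCatalog,
    config: Optional[FilterConfig] = None,
) -> Tuple[FilteredSiteSets, int]:
    """Call and filter one sample; returns its two site sets and the
    mapped-read count."""
    calls = call_sample(bam_path, reference, annotation, config)
    sets = apply_filter_cascade(calls, annotation, snvs, known)
    return sets, mapped_read_count(bam_path)


def build_profiles(
    samples: Sequence[Tuple[str, str, FilteredSiteSets, int]],
) -> Tuple[List[SampleProfile], List[SampleProfile]]:
    """(known-matched profiles, all-coding-site profiles) from processed
    samples given as (sample_id, group, site sets, library size)."""
    matched, full = [], []
    for sample_id, group, sets, library in samples:
        matched.append(
            SampleProfile(sample_id, group, {c.site for c in sets.known_matched}, library)
        )
        full.append(
            SampleProfile(sample_id, group, {c.site for c in sets.coding_a_to_i}, library)
        )
    return matched, full


def run_cohort(
    profiles_matched: Sequence[SampleProfile],
    profiles_all: Sequence[SampleProfile],
    genes: Optional[Dict] = None,
    method: str = "bh",
) -> Tuple[List[ContingencyRecord], BurdenResult]:
    """Differential table over the union of matched sites, plus the
    editing-burden comparison over the full site sets."""
    tested = sorted(set().union(*(p.edited_sites for p in profiles_matched)) or set())
    records = differential_table(
        profiles_matched, tested, m_total=len(tested), genes=genes, method=method
    )
    burden = burden_per_sample(profiles_all)
    return records, burden
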