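"""Statistical core: per-site differential editing and cohort editing burden.

Per site, the number of samples carrying the edit is tabulated for each
cohort and compared with the two-sided Fisher exact test; p-values are
corrected by the Benjamini–Hochberg step-up over the full tested site set.
Per sample, the count of detected A-to-I sites (raw and per million mapped
reads) is compared between cohorts with the two-sided Wilcoxon rank-sum
(Mann–Whitney) test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

Site = Tuple[str, int]

CONTROL = "control"
CASE = "case"


@dataclass
class SampleProfile:
    """One sample's group label, detected edited-site set and library size
    (mapped-read count, the burden normaliser)."""

    sample_id: str
    group: str  # 'control' or 'case'
    edited_sites: Set[Site] = field(default_factory=set)
    library_size: int = 0

    def __post_init__(self):
        if self.group not in (CONTROL, CASE):
            raise ValueError(f"unknown group label {self.group!r} (use 'control'/'case')")


@dataclass(frozen=True)
class ContingencyRecord:
    """One differential-editing table row: edited/total per group with the
    Fisher p and its multiplicity-adjusted value."""

    gene: str
    chrom: str
    position: int
    k_control: int
    n_control: int
    k_case: int
    n_case: int
    p_fisher: float
    p_adjusted: float


@dataclass
class BurdenResult:
    """Per-sample editing burden and the between-group comparison.

    ``table`` has one row per sample: group, raw site count, normalized
    count (sites per million mapped reads).  Both the raw-count and the
    normalized-count rank-sum p are reported.
    """

    table: pd.DataFrame
    median_raw: Dict[str, float]
    median_normalized: Dict[str, float]
    p_raw: float
    p_normalized: float


def build_contingency(
    profiles: Sequence[SampleProfile], site: Site
) -> Tuple[int, int, int, int]:
    """(k_control, n_control, k_case, n_case) for one site.

    A sample counts as edited iff the site survived its calling and
    filtering (one variant read suffices under the default thresholds).
    """
    site = (site[0], int(site[1]))
    k = {CONTROL: 0, CASE: 0}
    n = {CONTROL: 0, CASE: 0}
    for p in profiles:
        n[p.group] += 1
        if site in p.edited_sites:
            k[p.group] += 1
    if n[CONTROL] == 0 or n[CASE] == 0:
        raise ValueError("need at least one sample per group")
    return k[CONTROL], n[CONTROL], k[CASE], n[CASE]


def fisher_exact_two_sided(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for k1/n1 vs k2/n2 edited samples.

    Exact under the hypergeometric null with fixed margins; two-sided by
    summing the probabilities of all tables whose point probability does
    not exceed that of the observed table (the R ``fisher.test``
    convention).
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError(f"impossible counts: {k1}/{n1}, {k2}/{n2}")
    if n1 + n2 == 0:
        raise ValueError("both groups empty")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_adjust(p_values: Sequence[float], m_total: Optional[int] = None) -> List[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``m_total`` is the size of the full tested set; it may exceed
    ``len(p_values)`` when only the m smallest p-values are supplied (the
    caller must guarantee they are the smallest).  adjusted_i =
    min over ranks j ≥ i of (p_(j) × m_total / j), clamped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m_total is None else int(m_total)
    if m < len(p):
        raise ValueError(f"m_total={m} smaller than the number of p-values ({len(p)})")
    if p.size == 0:
        return []
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out.tolist()


def bonferroni_adjust(p_values: Sequence[float], m_total: Optional[int] = None) -> List[float]:
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m_total is None else int(m_total)
    if m < len(p):
        raise ValueError(f"m_total={m} smaller than the number of p-values ({len(p)})")
    return np.minimum(1.0, p * m).tolist()


def differential_table(
    profiles: Sequence[SampleProfile],
    sites: Iterable[Site],
    m_total: Optional[int] = None,
    genes: Optional[Mapping[Site, str]] = None,
    method: str = "bh",
) -> List[ContingencyRecord]:
    """Per-site contingency analysis over the tested site set.

    One record per site with its Fisher p and adjusted p (BH by default,
    Bonferroni via ``method='bonferroni'``); adjusted over ``m_total``
    tests (default: the number of sites supplied).  Records are sorted by
    adjusted p ascending, ties by raw p, then (chrom, position).
    """
    site_list = sorted({(c, int(p)) for c, p in sites})
    if not site_list:
        return []
    counts = [build_contingency(profiles, s) for s in site_list]
    pvals = [fisher_exact_two_sided(*c) for c in counts]
    adjust = {"bh": bh_adjust, "bonferroni": bonferroni_adjust}[method]
    padj = adjust(pvals, m_total if m_total is not None else len(site_list))
    genes = genes or {}
    records = [
        ContingencyRecord(
            gene=genes.get(s, "?"), chrom=s[0], position=s[1],
            k_control=c[0], n_control=c[1], k_case=c[2], n_case=c[3],
            p_fisher=p, p_adjusted=q,
        )
        for s, c, p, q in zip(site_list, counts, pvals, padj)
    ]
    records.sort(key=lambda r: (r.p_adjusted, r.p_fisher, r.chrom, r.position))
    return records


def wilcoxon_rank_sum(
    values_control: Sequence[float], values_case: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact enumeration when the combined sample is small (≤ 25) and free of
    ties; otherwise the normal approximation with tie and continuity
    correction.
    """
    x = list(values_control)
    y = list(values_case)
    if not x or not y:
        raise ValueError("both groups must be non-empty")
    pooled = x + y
    no_ties = len(set(pooled)) == len(pooled)
    if no_ties and len(pooled) <= 25:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def burden_per_sample(profiles: Sequence[SampleProfile]) -> BurdenResult:
    """Editing burden per sample and its between-group comparison.

    Raw burden is the size of a sample's detected site set; normalized
    burden is sites per million mapped reads (raw × 1e6 / library size).
    """
    for p in profiles:
        if p.library_size <= 0:
            raise ValueError(f"sample {p.sample_id}: library size must be positive")
    table = pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in profiles],
            "group": [p.group for p in profiles],
            "raw_count": [len(p.edited_sites) for p in profiles],
            "library_size": [p.library_size for p in profiles],
        }
    )
    table["normalized_count"] = table["raw_count"] * 1e6 / table["library_size"]
    by = table.groupby("group")
    ctrl = table[table.group == CONTROL]
    case = table[table.group == CASE]
    return BurdenResult(
        table=table,
        median_raw=by["raw_count"].median().to_dict(),
        median_normalized=by["normalized_count"].median().to_dict(),
        p_raw=wilcoxon_rank_sum(ctrl.raw_count, case.raw_count),
        p_normalized=wilcoxon_rank_sum(ctrl.normalized_count, case.normalized_count),
    )
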