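import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from editdiff.diff_stats import (
    SampleProfile,
    bh_adjust,
    bonferroni_adjust,
    build_contingency,
    burden_per_sample,
    differential_table,
    fisher_exact_two_sided,
    wilcoxon_rank_sum,
)

from .oracles import bh_stepup_oracle, fisher_enumeration, ranksum_enumeration

# the six cohort contingency tables used throughout:
# (k_control, n_control, k_case, n_case)
COHORT_TABLES = [
    (38, 44, 11, 29),
    (30, 44, 6, 29),
    (9, 44, 18, 29),
    (37, 44, 14, 29),
    (27, 44, 7, 29),
    (30, 44, 9, 29),
]
# exact two-sided Fisher p for these tables, frozen from the integer
# enumeration oracle and independently confirmed with R fisher.test
COHORT_FISHER_P = [2.7652e-05, 1.0155e-04, 4.7625e-04, 1.6724e-03, 2.1005e-03, 3.6515e-03]


def _profiles(site, k1, n1, k2, n2):
    profs = []
    for i in range(n1):
        profs.append(SampleProfile(f"c{i}", "control", {site} if i < k1 else set(), 10))
    for i in range(n2):
        profs.append(SampleProfile(f"p{i}", "case", {site} if i < k2 else set(), 10))
    return profs


class TestBuildContingency:
    def test_cohort_counts(self):
        site = ("chr19", 14482881)
        profs = _profiles(site, 38, 44, 11, 29)
        assert build_contingency(profs, site) == (38, 44, 11, 29)

    def test_absent_site(self):
        profs = _profiles(("chr1", 5), 3, 4, 2, 3)
        assert build_contingency(profs, ("chr1", 99)) == (0, 4, 0, 3)

    def test_ubiquitous_site(self):
        site = ("chr1", 5)
        profs = _profiles(site, 4, 4, 3, 3)
        assert build_contingency(profs, site) == (4, 4, 3, 3)

    def test_group_must_be_known_label(self):
        with pytest.raises(ValueError):
            SampleProfile("x", "patients", set(), 10)


class TestFisher:
    @pytest.mark.parametrize("table,expected", list(zip(COHORT_TABLES, COHORT_FISHER_P)))
    def test_cohort_tables(self, table, expected):
        assert fisher_exact_two_sided(*table) == pytest.approx(expected, rel=1e-3)

    def test_identical_proportions_give_p_one(self):
        assert fisher_exact_two_sided(5, 10, 5, 10) == pytest.approx(1.0)

    def test_tiny_table_enumeration(self):
        # margins (2,2|2,2): tables have probability 1/6, 4/6, 1/6;
        # observed (2,0) has 1/6, so the two-sided sum is 1/3
        assert fisher_exact_two_sided(2, 2, 0, 2) == pytest.approx(1 / 3)

    def test_matches_enumeration_for_all_small_margins(self):
        """Exhaustive agreement with full-table enumeration, n1+n2 <= 12."""
        for n1 in range(1, 12):
            for n2 in range(1, 13 - n1):
                for k1 in range(n1 + 1):
                    for k2 in range(n2 + 1):
                        assert fisher_exact_two_sided(k1, n1, k2, n2) == pytest.approx(
                            fisher_enumeration(k1, n1, k2, n2), rel=1e-9, abs=1e-12
                        ), (k1, n1, k2, n2)

    @given(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
    )
    def test_label_symmetry(self, k1, d1, k2, d2):
        n1, n2 = k1 + d1, k2 + d2
        if n1 == 0 or n2 == 0:
            return
        assert fisher_exact_two_sided(k1, n1, k2, n2) == pytest.approx(
            fisher_exact_two_sided(k2, n2, k1, n1)
        )

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(5, 4, 1, 2)


class TestBHAdjust:
    def test_six_smallest_of_160(self):
        # the printed cohort p-value column, adjusted over 160 tested sites
        p = [3.00e-5, 1.00e-4, 4.80e-4, 1.67e-3, 2.10e-3, 3.65e-3]
        expected = [4.80e-3, 8.00e-3, 2.56e-2, 6.68e-2, 6.72e-2, 9.73e-2]
        got = bh_adjust(p, m_total=160)
        for g, e in zip(got, expected):
            assert g == pytest.approx(e, rel=1e-3)

    def test_single_p_identity(self):
        assert bh_adjust([0.5], m_total=1) == [0.5]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_stepup_oracle_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=20).tolist()
        assert bh_adjust(p, m_total=20) == pytest.approx(bh_stepup_oracle(p, 20))
        # with a larger total test count (only the smallest p's supplied)
        assert bh_adjust(p, m_total=37) == pytest.approx(bh_stepup_oracle(p, 37))

    def test_matches_statsmodels_when_full_set_supplied(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(42)
        p = rng.uniform(size=50)
        ours = bh_adjust(p.tolist())
        theirs = multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs.tolist())

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_and_bounded(self, p):
        adj = bh_adjust(p)
        assert all(a >= raw - 1e-12 and a <= 1.0 for a, raw in zip(adj, p))
        order = np.argsort(p, kind="stable")
        resorted = [adj[i] for i in order]
        assert all(x <= y + 1e-12 for x, y in zip(resorted, resorted[1:]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bh_adjust([1.5])
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2], m_total=1)

    def test_bonferroni_option(self):
        assert bonferroni_adjust([0.01, 0.4], m_total=10) == pytest.approx([0.1, 1.0])


class TestDifferentialTable:
    def test_cohort_rows_among_null_background(self):
        """The six strong contingency tables embedded among 154 null sites
        reproduce their exact Fisher p's; BH runs over all 160 records."""
        genes = ["GIPC1", "GRIA2", "PLIN4", "GABRA3", "GRIK2", "GRIK1"]
        merged = []
        n1, n2 = 44, 29
        for i in range(n1):
            sites = {("chr1", j + 1) for j, t in enumerate(COHORT_TABLES) if i < t[0]}
            sites |= {("chrN", 100 + j) for j in range(154) if i < 20}
            merged.append(SampleProfile(f"c{i}", "control", sites, 10))
        for i in range(n2):
            sites = {("chr1", j + 1) for j, t in enumerate(COHORT_TABLES) if i < t[2]}
            sites |= {("chrN", 100 + j) for j in range(154) if i < 13}
            merged.append(SampleProfile(f"p{i}", "case", sites, 10))
        all_sites = [("chr1", j + 1) for j in range(6)] + [("chrN", 100 + j) for j in range(154)]
        gene_map = {("chr1", j + 1): g for j, g in enumerate(genes)}
        records = differential_table(merged, all_sites, m_total=160, genes=gene_map)
        assert len(records) == 160
        top = records[:6]
        assert [r.gene for r in top] == genes
        for r, p_exp in zip(top, COHORT_FISHER_P):
            assert r.p_fisher == pytest.approx(p_exp, rel=1e-3)
            # BH over the 160 tested records, computed from the exact p's
        ranks = [1, 2, 3, 4, 5, 6]
        for r, p_exp, rank in zip(top, COHORT_FISHER_P, ranks):
            assert r.p_adjusted == pytest.approx(
                min(1.0, p_exp * 160 / rank), rel=1e-2
            )

    def test_identical_proportions_all_p_one(self):
        profs = _profiles(("chr1", 5), 3, 6, 2, 4)
        for p in profs:
            p.edited_sites = {("chr1", 5)} if p.sample_id in {"c0", "c1", "p0"} else set()
        # 2/6 vs 1/4 -> p = 1 for this balanced configuration
        recs = differential_table(profs, [("chr1", 5)])
        assert recs[0].p_fisher == pytest.approx(1.0)
        assert recs[0].p_adjusted == pytest.approx(1.0)

    def test_single_site_adjusted_equals_raw(self):
        profs = _profiles(("chr1", 5), 4, 5, 1, 5)
        recs = differential_table(profs, [("chr1", 5)], m_total=1)
        assert recs[0].p_adjusted == pytest.approx(recs[0].p_fisher)


class TestWilcoxon:
    def test_exact_small_sample(self):
        # 2 of the C(6,3)=20 rank assignments are as extreme -> p = 0.1
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_matches_enumeration_oracle(self):
        x, y = [1.2, 3.4, 0.5, 7.7], [2.2, 5.1, 6.3]
        assert wilcoxon_rank_sum(x, y) == pytest.approx(ranksum_enumeration(x, y))

    def test_identical_multisets_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 2, 3], [1, 2, 2, 3]) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_label_symmetry(self):
        x, y = [3.0, 1.0, 4.0, 1.5], [2.0, 6.0, 5.0]
        assert wilcoxon_rank_sum(x, y) == pytest.approx(wilcoxon_rank_sum(y, x))

    def test_null_rejection_rate_calibrated(self):
        """30 vs 30 null samples, 1000 replicates: rejection rate at
        alpha = 0.05 stays within binomial 99% bounds of 0.05."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            rejections += wilcoxon_rank_sum(x.tolist(), y.tolist()) < 0.05
        rate = rejections / n_rep
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / n_rep)
        assert 0.05 - half_width <= rate <= 0.05 + half_width


class TestBurden:
    def test_normalization_arithmetic(self):
        profs = [
            SampleProfile("c0", "control", {("c", i) for i in range(500)}, 50_000_000),
            SampleProfile("p0", "case", set(), 1_000_000),
        ]
        res = burden_per_sample(profs)
        row = res.table.set_index("sample_id")
        assert row.loc["c0", "normalized_count"] == pytest.approx(10.0)
        assert row.loc["p0", "raw_count"] == 0
        assert row.loc["p0", "normalized_count"] == 0.0

    def test_library_size_scales_normalized_counts(self):
        sites = {("c", i) for i in range(100)}
        profs = [
            SampleProfile("c0", "control", sites, 1_000_000),
            SampleProfile("c1", "control", sites, 2_000_000),
            SampleProfile("p0", "case", sites, 1_000_000),
        ]
        res = burden_per_sample(profs)
        t = res.table.set_index("sample_id")
        assert t.loc["c0", "normalized_count"] == pytest.approx(
            2 * t.loc["c1", "normalized_count"]
        )

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            burden_per_sample([SampleProfile("x", "case", set(), 0),
                               SampleProfile("y", "control", set(), 5)])
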