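"""Pairwise F_ST, top-quantile extraction and stock-specific SNP rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import naive_fst
from poolscan.fst import (
    FstTable,
    fixed_differentiation,
    fst_per_site,
    pairwise_scan,
    site_fst,
    stock_specific_snps,
    summary_matrix,
    top_quantile,
)
from poolscan.io import CountMatrix, PoolPanel
from poolscan.sites import FilterConfig, merge_by_stock
from poolscan.simulate import SimulationConfig, simulate_dataset


class TestSiteFst:
    def test_disjoint_fixation_gives_one(self):
        assert site_fst([10, 0, 0, 0], [0, 10, 0, 0]) == pytest.approx(1.0)

    def test_identical_pools_give_exact_sampling_correction(self):
        # duplicating a pool doubles the coverage, so the C/(C-1) correction
        # shrinks pi_total relative to pi_within by exactly 1/(2(C-1)):
        # F_ST of identical polymorphic pools is -1/(2(C-1)), never positive
        C = 20
        assert site_fst([12, 8, 0, 0], [12, 8, 0, 0]) == pytest.approx(
            -1.0 / (2 * (C - 1)), abs=1e-12
        )

    def test_known_value(self):
        val = site_fst([15, 5, 0, 0], [5, 15, 0, 0])
        assert val == pytest.approx(0.230263, abs=1e-6)

    def test_combined_monomorphic_undefined(self):
        assert np.isnan(site_fst([10, 0, 0, 0], [20, 0, 0, 0]))

    @given(
        a=st.lists(st.integers(0, 200), min_size=4, max_size=4),
        b=st.lists(st.integers(0, 200), min_size=4, max_size=4),
    )
    def test_symmetry_relabeling_and_oracle(self, a, b):
        x, y = site_fst(a, b), site_fst(b, a)
        expected = naive_fst(a, b)
        if np.isnan(expected):
            assert np.isnan(x)
            return
        assert x == pytest.approx(y, abs=1e-12)
        assert x == pytest.approx(expected, abs=1e-12)
        # relabeling bases changes nothing
        assert site_fst(a[::-1], b[::-1]) == pytest.approx(x, abs=1e-12)
        assert x <= 1.0 + 1e-12

    @given(st.lists(st.integers(0, 100), min_size=4, max_size=4), st.integers(2, 80))
    def test_duplicated_and_disjoint_pools_across_coverages(self, counts, cov):
        C = sum(counts)
        v = site_fst(counts, counts)
        if C >= 2 and not np.isnan(v):
            # duplicated identical pools: exactly the -1/(2(C-1)) correction
            assert v == pytest.approx(-1.0 / (2 * (C - 1)), abs=1e-9)
        assert site_fst([cov, 0, 0, 0], [0, cov, 0, 0]) == pytest.approx(1.0)


def two_stock_matrix(rows_a, rows_b):
    n = len(rows_a)
    counts = np.zeros((n, 2, 6), dtype=np.int64)
    counts[:, 0, :4] = rows_a
    counts[:, 1, :4] = rows_b
    return CountMatrix(
        chrom=np.array(["LG1"] * n, dtype=object),
        pos=1 + np.arange(n, dtype=np.int64) * 10,
        ref=np.array(["A"] * n, dtype=object),
        counts=counts,
        panel=PoolPanel(["A", "B"], ["A", "B"], [24, 24]),
    )


class TestPairwiseScan:
    def test_row_count_equals_snp_count_and_matches_brute_force(self, rng):
        rows_a = rng.integers(0, 30, size=(120, 4))
        rows_b = rng.integers(0, 30, size=(120, 4))
        m = two_stock_matrix(rows_a, rows_b)
        filters = FilterConfig(min_coverage=20, min_count=10)
        tables = pairwise_scan(m, filters=filters, caps=np.array([np.inf, np.inf]))
        t = tables[frozenset(("A", "B"))]
        # brute force: per-site two-pass
        expected = {}
        for i in range(120):
            a, b = rows_a[i], rows_b[i]
            comb = a + b
            minor = sorted(comb)[-2]
            if min(a.sum(), b.sum()) < 20 or minor < 10:
                continue
            v = naive_fst(a, b)
            if not np.isnan(v):
                expected[int(m.pos[i])] = v
        assert set(t.table["pos"]) == set(expected)
        for _, row in t.table.iterrows():
            assert row["fst"] == pytest.approx(expected[row["pos"]], abs=1e-12)

    def test_zero_drift_pair_mean_near_zero_and_drift_monotonicity(self):
        def mean_fst(F, seed):
            cfg = SimulationConfig(
                n_stocks=2, pools_per_stock=4, n_sites=4000, drift_F=F,
                seq_error=0.0, seed=seed,
            )
            _, matrix = simulate_dataset(cfg)
            sm = merge_by_stock(matrix)
            tables = pairwise_scan(sm, filters=FilterConfig())
            return tables[frozenset(("stock1", "stock2"))].genome_mean

        near_zero = mean_fst(0.0, 21)
        drifted = mean_fst(0.1, 21)
        assert abs(near_zero) < 0.01
        assert drifted > near_zero + 0.02

    def test_empty_pair_gives_missing_mean(self):
        m = two_stock_matrix(np.zeros((5, 4), int), np.zeros((5, 4), int))
        tables = pairwise_scan(m, filters=FilterConfig(), caps=np.array([np.inf] * 2))
        t = tables[frozenset(("A", "B"))]
        assert t.n_snps == 0 and np.isnan(t.genome_mean)


def table_from_values(values, stock_a="A", stock_b="B"):
    n = len(values)
    return FstTable(
        stock_a=stock_a,
        stock_b=stock_b,
        table=pd.DataFrame(
            {
                "chrom": ["LG1"] * n,
                "pos": np.arange(1, n + 1),
                "fst": values,
                "pi_within": np.zeros(n),
                "pi_total": np.ones(n),
            }
        ),
    )


class TestFixedDifferentiation:
    def test_strict_threshold_count(self):
        count, hits = fixed_differentiation(table_from_values([0.7, 0.6, 0.66]), 0.65)
        assert count == 2
        assert set(hits["fst"]) == {0.7, 0.66}

    def test_threshold_one_empty(self):
        count, _ = fixed_differentiation(table_from_values([0.7, 0.9, 1.0]), 1.0)
        assert count == 0

    def test_simulated_fixed_differences_recovered(self):
        # alt fixed in A, absent in B, no sequencing error: F_ST = 1 > 0.65
        rows_a = np.tile([0, 30, 0, 0], (20, 1))
        rows_b = np.tile([30, 0, 0, 0], (20, 1))
        m = two_stock_matrix(rows_a, rows_b)
        tables = pairwise_scan(m, filters=FilterConfig(), caps=np.array([np.inf] * 2))
        count, hits = fixed_differentiation(tables[frozenset(("A", "B"))])
        assert count == 20
        np.testing.assert_allclose(hits["fst"], 1.0)


class TestTopQuantile:
    def test_distinct_values_top_permille_is_maximum(self, rng):
        vals = rng.permutation(np.linspace(0, 0.999, 1000))
        top = top_quantile(table_from_values(vals), 0.001)
        assert len(top.snps) == 1
        (snp,) = top.snps
        assert vals[snp[1] - 1] == vals.max()

    def test_q_one_returns_entire_table(self):
        top = top_quantile(table_from_values([0.1, 0.2, 0.3]), 1.0)
        assert len(top.snps) == 3

    def test_all_tied_values_all_returned(self):
        top = top_quantile(table_from_values([0.5] * 7), 0.001)
        assert len(top.snps) == 7


class TestStockSpecific:
    def toy_sets(self, assignments):
        """Build TopSnpSets for stocks A,B,C from {pair: snp set}."""
        from poolscan.fst import TopSnpSet

        return {
            frozenset(pair): TopSnpSet(pair[0], pair[1], 0.01, 0.0, set(snps))
            for pair, snps in assignments.items()
        }

    def test_snp_in_every_comparison_of_one_stock_is_specific(self):
        x = ("LG1", 5)
        sets = self.toy_sets(
            {("A", "B"): {x}, ("A", "C"): {x}, ("B", "C"): set()}
        )
        out = stock_specific_snps(sets, ["A", "B", "C"])
        assert out["A"] == [x]
        assert out["B"] == [] and out["C"] == []

    def test_snp_in_single_comparison_is_candidate_for_neither(self):
        x = ("LG1", 5)
        sets = self.toy_sets(
            {("A", "B"): {x}, ("A", "C"): set(), ("B", "C"): set()}
        )
        out = stock_specific_snps(sets, ["A", "B", "C"])
        assert out == {"A": [], "B": [], "C": []}

    def test_shared_candidate_not_specific(self):
        # x is a candidate for both A and B -> specific to neither
        x = ("LG1", 5)
        sets = self.toy_sets(
            {("A", "B"): {x}, ("A", "C"): {x}, ("B", "C"): {x}}
        )
        out = stock_specific_snps(sets, ["A", "B", "C"])
        assert out == {"A": [], "B": [], "C": []}

    def test_union_rule(self):
        x = ("LG1", 5)
        sets = self.toy_sets(
            {("A", "B"): {x}, ("A", "C"): set(), ("B", "C"): set()}
        )
        out = stock_specific_snps(sets, ["A", "B", "C"], rule="union")
        # x is in a comparison involving both A and B -> candidate for both
        assert out == {"A": [], "B": [], "C": []}

    def test_missing_pair_listed_in_error(self):
        sets = self.toy_sets({("A", "B"): set()})
        with pytest.raises(ValueError, match="missing"):
            stock_specific_snps(sets, ["A", "B", "C"])


def test_summary_matrix_layout():
    tables = {
        frozenset(("A", "B")): table_from_values([0.7, 0.1], "A", "B"),
    }
    mat = summary_matrix(tables, ["A", "B"])
    assert mat.loc["B", "A"] == pytest.approx(0.4)  # mean below diagonal
    assert mat.loc["A", "B"] == 1  # fixed-diff count above
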