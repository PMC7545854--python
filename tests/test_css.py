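"""Composite selection signal: ranks, Z, p, outliers, block localization."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given
from hypothesis import strategies as hs

from helpers import naive_css, naive_fractional_ranks
from poolscan.css import (
    compute_css,
    css_score,
    fractional_ranks,
    map_to_blocks,
    rank_to_z,
    top_css,
)
from poolscan.io import HaplotypeBlock


class TestFractionalRanks:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            fractional_ranks([0.1, 0.4, 0.2, 0.3]), [0.2, 0.8, 0.4, 0.6]
        )

    def test_all_tied_values_average_to_half(self):
        np.testing.assert_allclose(fractional_ranks([0.3, 0.3, 0.3]), [0.5] * 3)

    def test_maximum_maps_inside_open_interval(self):
        r = fractional_ranks(np.arange(100, dtype=float))
        assert r.max() == pytest.approx(100 / 101)
        assert (r > 0).all() and (r < 1).all()

    @given(hs.lists(hs.floats(0, 1, width=32), min_size=1, max_size=50))
    def test_matches_naive_sorting_oracle(self, values):
        np.testing.assert_allclose(
            fractional_ranks(values), naive_fractional_ranks(values), atol=1e-12
        )


class TestRankToZ:
    def test_median_maps_to_zero(self):
        assert rank_to_z(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_quantile_value(self):
        assert rank_to_z(0.8) == pytest.approx(0.841621, abs=1e-6)

    @given(hs.floats(0.001, 0.999))
    def test_antisymmetry(self, r):
        assert rank_to_z(r) == pytest.approx(-rank_to_z(1 - r), abs=1e-9)

    @pytest.mark.parametrize("r", [0.0, 1.0, -0.1, 1.5])
    def test_out_of_open_interval_rejected(self, r):
        with pytest.raises(ValueError):
            rank_to_z(r)


def z_frame(z_by_comparison):
    return pd.DataFrame(z_by_comparison)


class TestCssScore:
    def test_single_comparison_median_snp(self):
        res = css_score(z_frame({"c1": [0.0]}))
        row = res.table.iloc[0]
        assert row["p"] == pytest.approx(0.5)
        assert row["css"] == pytest.approx(0.301030, abs=1e-6)

    def test_four_comparisons_mean_one(self):
        res = css_score(z_frame({f"c{i}": [1.0] for i in range(4)}))
        row = res.table.iloc[0]
        assert row["p"] == pytest.approx(0.022750, abs=1e-6)
        assert row["css"] == pytest.approx(1.643052, abs=1e-4)

    def test_complete_policy_drops_missing(self):
        z = z_frame({"c1": [1.0, np.nan], "c2": [0.5, 0.5]})
        res = css_score(z, policy="complete")
        assert res.n_snps == 1

    def test_available_policy_scales_by_own_m(self):
        z = z_frame({"c1": [1.0, np.nan], "c2": [1.0, 1.0]})
        res = css_score(z, policy="available")
        p0, p1 = res.table["p"]
        assert p0 == pytest.approx(st.norm.sf(1.0 * np.sqrt(2)))
        assert p1 == pytest.approx(st.norm.sf(1.0))

    def test_null_p_values_uniform(self, rng):
        """10,000 null SNPs over 4 independent comparisons: p is uniform
        (KS < 0.02) and the alpha=0.05 exceedance rate is calibrated."""
        n = 10_000
        tables = {
            f"c{i}": pd.DataFrame(
                {
                    "chrom": ["LG1"] * n,
                    "pos": np.arange(1, n + 1),
                    "fst": rng.uniform(size=n),
                }
            )
            for i in range(4)
        }
        res = compute_css(tables)
        p = res.table["p"].to_numpy()
        assert abs((p < 0.05).mean() - 0.05) <= 0.01
        assert st.kstest(p, "uniform").statistic < 0.02

    def test_monotone_transform_invariance(self, rng):
        """CSS is rank-based: any strictly monotone transform of each
        comparison's F_ST values leaves the scores unchanged."""
        n = 200
        base = {
            f"c{i}": pd.DataFrame(
                {
                    "chrom": ["LG1"] * n,
                    "pos": np.arange(1, n + 1),
                    "fst": rng.uniform(size=n),
                }
            )
            for i in range(3)
        }
        transformed = {
            name: t.assign(fst=np.exp(3.0 * t["fst"]) - 0.5)
            for name, t in base.items()
        }
        a = compute_css(base).table["css"]
        b = compute_css(transformed).table["css"]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_matches_naive_oracle_on_small_input(self, rng):
        n = 100
        tables = {
            f"c{i}": pd.DataFrame(
                {
                    "chrom": ["LG1"] * n,
                    "pos": np.arange(1, n + 1),
                    "fst": rng.uniform(size=n),
                }
            )
            for i in range(4)
        }
        res = compute_css(tables)
        oracle = naive_css(
            {
                name: dict(zip(zip(t["chrom"], t["pos"]), t["fst"]))
                for name, t in tables.items()
            }
        )
        assert len(oracle) == res.n_snps
        for snp, (zbar, p, css) in oracle.items():
            row = res.table.loc[snp]
            assert row["z_mean"] == pytest.approx(zbar, abs=1e-9)
            assert row["p"] == pytest.approx(p, abs=1e-9)
            assert row["css"] == pytest.approx(css, abs=1e-9)


class TestTopCss:
    def css_from_values(self, values):
        n = len(values)
        table = pd.DataFrame(
            {"css": values, "p": 10.0 ** -np.asarray(values)},
            index=pd.MultiIndex.from_arrays(
                [["LG1"] * n, np.arange(1, n + 1)], names=["chrom", "pos"]
            ),
        )
        from poolscan.css import CssResult

        return CssResult(table=table, comparisons=["c"])

    def test_distinct_values_top_permille_is_maximum(self, rng):
        vals = rng.permutation(np.linspace(0, 5, 1000))
        out = top_css(self.css_from_values(vals), 0.001)
        assert len(out) == 1
        (snp,) = out
        assert vals[snp[1] - 1] == vals.max()

    def test_median_split(self):
        out = top_css(self.css_from_values(np.arange(10.0)), 0.5)
        assert len(out) == 5

    def test_outlier_floor_dominates_non_outliers(self, rng):
        vals = rng.uniform(size=500)
        res = self.css_from_values(vals)
        out = top_css(res, 0.01)
        others = set(res.table.index) - out
        out_min = min(res.table.loc[s, "css"] for s in out)
        assert all(res.table.loc[s, "css"] <= out_min for s in others)


class TestMapToBlocks:
    def block(self, start, end, chrom="LG1"):
        return HaplotypeBlock(chrom, start, end, block_id=f"b{start}")

    def test_block_with_six_snps_and_outlier_reported(self):
        snps = [("LG1", p) for p in range(101, 107)]
        out = map_to_blocks({snps[0]}, snps, [self.block(100, 200)])
        (e,) = out
        assert e.snp_count == 6 and e.outlier_count == 1 and e.reported

    def test_block_with_five_snps_not_reported(self):
        snps = [("LG1", p) for p in range(101, 106)]
        out = map_to_blocks({snps[0]}, snps, [self.block(100, 200)])
        assert out[0].snp_count == 5 and not out[0].reported

    def test_block_without_outlier_not_reported(self):
        snps = [("LG1", p) for p in range(101, 111)]
        out = map_to_blocks(set(), snps, [self.block(100, 200)])
        assert out[0].snp_count == 10 and not out[0].reported

    def test_snp_at_half_open_end_excluded(self):
        out = map_to_blocks(set(), [("LG1", 200)], [self.block(100, 200)])
        assert out[0].snp_count == 0

    def test_overlapping_blocks_each_count_the_snp(self):
        snps = [("LG1", 150)]
        out = map_to_blocks(set(), snps, [self.block(100, 200), self.block(140, 260)])
        assert [e.snp_count for e in out] == [1, 1]

    def test_output_sorted_by_position(self):
        blocks = [self.block(300, 400), self.block(0, 100)]
        out = map_to_blocks(set(), [], blocks)
        assert [e.block.start for e in out] == [0, 300]
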