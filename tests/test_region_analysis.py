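import numpy as np
import pandas as pd
import pytest

from conftest import make_expression, make_gene_table
from rer_scan.core_io import SampleMetadata
from rer_scan.region_analysis import (
    RegionExpressionMatrix,
    cluster_regions,
    gene_density_test,
    neighbor_correlation_count,
    region_mean_expression,
    subtype_association,
)
from rer_scan.region_calling import RERRegion


def make_region(region_id, genes, start=0, end=100):
    return RERRegion(
        region_id=region_id, chrom="chr1", start=start, end=end,
        member_genes=tuple(genes), significant_genes=tuple(genes),
        span_sig=end - start, window_n=10,
    )


class TestRegionMeanExpression:
    def test_single_gene_region_equals_gene_z_profile(self, rng):
        genes = make_gene_table(4)
        values = rng.normal(size=(4, 10))
        expr = make_expression(genes, values)
        rem = region_mean_expression([make_region("r1", ["g0_2"])], expr)
        x = values[2]
        expected = (x - x.mean()) / x.std()
        np.testing.assert_allclose(rem.data.loc["r1"], expected, atol=1e-12)

    def test_region_row_mean_is_zero_without_missing_data(self, rng):
        genes = make_gene_table(6)
        expr = make_expression(genes, rng.normal(size=(6, 20)))
        rem = region_mean_expression(
            [make_region("r1", ["g0_0", "g0_1", "g0_2"])], expr
        )
        assert abs(rem.data.loc["r1"].mean()) < 1e-9

    def test_opposite_profiles_cancel(self, rng):
        genes = make_gene_table(2)
        profile = rng.normal(size=12)
        expr = make_expression(genes, np.vstack([profile, -profile]))
        rem = region_mean_expression([make_region("r1", ["g0_0", "g0_1"])], expr)
        np.testing.assert_allclose(rem.data.loc["r1"], 0.0, atol=1e-12)

    def test_missing_cells_excluded_from_mean(self, rng):
        genes = make_gene_table(2)
        values = rng.normal(size=(2, 10))
        values[1, 0] = np.nan
        expr = make_expression(genes, values)
        rem = region_mean_expression([make_region("r1", ["g0_0", "g0_1"])], expr)
        z0 = (values[0] - values[0].mean()) / values[0].std()
        assert rem.data.loc["r1"].iloc[0] == pytest.approx(z0[0])

    def test_region_with_no_present_genes_named(self, rng):
        genes = make_gene_table(2)
        expr = make_expression(genes, rng.normal(size=(2, 5)))
        with pytest.raises(KeyError, match="ghost"):
            region_mean_expression([make_region("ghost", ["nope"])], expr)

    def test_rows_follow_their_samples(self, rng):
        genes = make_gene_table(3)
        expr = make_expression(genes, rng.normal(size=(3, 8)))
        region = make_region("r1", ["g0_0", "g0_1"])
        rem = region_mean_expression([region], expr)
        from rer_scan.core_io import ExpressionMatrix

        perm = rng.permutation(8)
        shuffled = ExpressionMatrix(expr.data.iloc[:, perm])
        rem2 = region_mean_expression([region], shuffled)
        pd.testing.assert_series_equal(
            rem.data.loc["r1"].sort_index(), rem2.data.loc["r1"].sort_index()
        )


class TestClusterRegions:
    def _orthogonal_rem(self, rng, n_per_group=3, noise=0.3):
        """Three region groups, each activated in its own sample block."""
        samples = [f"s{j}" for j in range(60)]
        rows = {}
        labels = {}
        for g in range(3):
            for i in range(n_per_group):
                rid = f"r{g}_{i}"
                row = rng.normal(0, noise, size=60)
                row[g * 20 : (g + 1) * 20] += 2.0
                rows[rid] = row
                labels[rid] = g
        data = pd.DataFrame(rows, index=samples).T
        return RegionExpressionMatrix(data), labels

    def test_recovers_orthogonal_groups_exactly(self, rng):
        rem, truth = self._orthogonal_rem(rng)
        result = cluster_regions(rem, k=3)
        # adjusted Rand index must be 1: identical partitions up to relabeling
        from itertools import combinations

        def pairs(labels):
            return {
                frozenset(p)
                for p in combinations(sorted(labels), 2)
                if labels[p[0]] == labels[p[1]]
            }

        assert pairs(result.region_labels) == pairs(truth)

    def test_k_equals_region_count_gives_singletons(self, rng):
        rem, _ = self._orthogonal_rem(rng)
        result = cluster_regions(rem, k=len(rem.data))
        assert len(set(result.region_labels.values())) == len(rem.data)

    def test_duplicate_rows_co_cluster(self, rng):
        rem, _ = self._orthogonal_rem(rng)
        data = rem.data.copy()
        data.loc["dup"] = data.loc["r0_0"]
        result = cluster_regions(RegionExpressionMatrix(data), k=3)
        assert result.region_labels["dup"] == result.region_labels["r0_0"]

    def test_invalid_k_rejected(self, rng):
        rem, _ = self._orthogonal_rem(rng)
        with pytest.raises(ValueError, match="k must be"):
            cluster_regions(rem, k=1)
        with pytest.raises(ValueError, match="k must be"):
            cluster_regions(rem, k=100)


class TestSubtypeAssociation:
    def _rem(self, values_by_sample):
        data = pd.DataFrame({"r1": values_by_sample}).T
        data.columns = [f"s{j}" for j in range(len(values_by_sample))]
        return RegionExpressionMatrix(data)

    def _meta(self, labels):
        return SampleMetadata(
            pd.DataFrame(
                {"sample_id": [f"s{j}" for j in range(len(labels))], "group_label": labels}
            )
        )

    def test_separated_triples_give_exact_p(self):
        # {1,2,3} vs {10,11,12}: the most extreme of C(6,3)=20 rank splits,
        # two-sided exact p = 2/20 = 0.1
        rem = self._rem([1, 2, 3, 10, 11, 12])
        meta = self._meta(["a"] * 3 + ["b"] * 3)
        p = subtype_association(rem, meta, "a", "b").loc["r1", "p"]
        assert p == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        rem = self._rem([1, 2, 3, 4, 1, 2, 3, 4])
        meta = self._meta(["a"] * 4 + ["b"] * 4)
        p = subtype_association(rem, meta, "a", "b").loc["r1", "p"]
        assert p == pytest.approx(1.0)

    def test_symmetric_in_group_exchange(self, rng):
        values = list(rng.normal(size=30))
        rem = self._rem(values)
        meta = self._meta(["a"] * 15 + ["b"] * 15)
        ab = subtype_association(rem, meta, "a", "b").loc["r1", "p"]
        ba = subtype_association(rem, meta, "b", "a").loc["r1", "p"]
        assert ab == pytest.approx(ba)

    def test_strong_shift_highly_significant(self, rng):
        values = np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])
        rem = self._rem(list(values))
        meta = self._meta(["a"] * 50 + ["b"] * 50)
        p = subtype_association(rem, meta, "a", "b").loc["r1", "p"]
        assert p < 0.001

    def test_empty_group_rejected(self, rng):
        rem = self._rem(list(rng.normal(size=6)))
        meta = self._meta(["a"] * 6)
        with pytest.raises(ValueError, match="samples"):
            subtype_association(rem, meta, "a", "b")


class TestNeighborCorrelationCount:
    def test_shared_profile_counts_all_20(self, rng):
        genes = make_gene_table(41)
        profile = rng.normal(size=30)
        expr = make_expression(
            genes, profile[None, :] + rng.normal(scale=0.01, size=(41, 30))
        )
        assert neighbor_correlation_count("g0_20", expr, genes, k=20, alpha=0.05) == 20

    def test_chromosome_end_gene_bounded_by_available_neighbors(self, rng):
        genes = make_gene_table(41)
        profile = rng.normal(size=30)
        expr = make_expression(
            genes, profile[None, :] + rng.normal(scale=0.01, size=(41, 30))
        )
        assert neighbor_correlation_count("g0_0", expr, genes, k=20, alpha=0.05) == 10

    def test_null_gene_counts_near_alpha_k(self, rng):
        genes = make_gene_table(41)
        counts = []
        for _ in range(30):
            expr = make_expression(genes, rng.normal(size=(41, 50)))
            counts.append(neighbor_correlation_count("g0_20", expr, genes, 20, 0.05))
        # binomial(20, 0.05) expectation = 1
        assert 0.2 < np.mean(counts) < 2.5

    def test_unknown_gene_rejected(self, rng):
        genes = make_gene_table(5)
        expr = make_expression(genes, rng.normal(size=(5, 10)))
        with pytest.raises(KeyError):
            neighbor_correlation_count("nope", expr, genes)


class TestGeneDensityTest:
    def test_whole_genome_region_gives_global_density_and_p_near_one(self):
        genes = make_gene_table(100, spacing=10_000)  # 1 Mb chromosome
        region = make_region("all", ["g0_0"], start=0, end=1_000_000)
        density, p = gene_density_test(
            [region], genes, {"chr1": 1_000_000}, n_permutations=200, seed=0
        )
        assert density == pytest.approx(100.0)  # 100 genes / 1 Mb
        assert p > 0.9

    def test_dense_placement_detected(self, rng):
        # gene map with a dense decile: 150 genes packed in [0, 100kb),
        # 50 genes spread over the remaining 900 kb
        starts = np.concatenate(
            [
                np.sort(rng.choice(100_000, size=150, replace=False)),
                100_000 + np.sort(rng.choice(900_000 - 1000, size=50, replace=False)),
            ]
        )
        df = pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(200)],
                "chrom": "chr1",
                "start": starts,
                "end": starts + 500,
            }
        )
        from rer_scan.core_io import GeneTable

        genes = GeneTable.from_frame(df)
        region = make_region("dense", ["G0"], start=0, end=100_000)
        _, p = gene_density_test(
            [region], genes, {"chr1": 1_000_000}, n_permutations=1000, seed=1
        )
        assert p <= 0.01

    def test_p_respects_add_one_bounds(self, rng):
        genes = make_gene_table(50, spacing=10_000)
        region = make_region("r", ["g0_0"], start=0, end=50_000)
        for seed in range(3):
            _, p = gene_density_test(
                [region], genes, {"chr1": 500_000}, n_permutations=99, seed=seed
            )
            assert 1 / 100 <= p <= 1.0

    def test_oversized_region_rejected(self):
        genes = make_gene_table(10, spacing=1000)
        region = make_region("big", ["g0_0"], start=0, end=100_000)
        with pytest.raises(ValueError, match="exceeds"):
            gene_density_test([region], genes, {"chr1": 10_000}, 10, 0)
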