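import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import ucrtile as u


def make_regions(n, strand_cycle=("+", "-")):
    return [
        u.UCRegion(f"r{i}", "chr1", 1000 + 10000 * i, 1300 + 10000 * i,
                   "intronic", f"G{i}", strand_cycle[i % len(strand_cycle)])
        for i in range(n)
    ]


def transcript_frame(regions, n_arrays=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = {
        f"{r.id}:{c}": rng.normal(size=n_arrays)
        for r in regions for c in ("plus", "minus")
    }
    return pd.DataFrame(rows).T


class TestReorientMerge:
    def test_shape_and_value_conservation(self):
        regions = make_regions(6)
        values = transcript_frame(regions)
        out = u.reorient_merge(values, regions)
        assert out.shape == (6, 2 * values.shape[1])
        assert np.isclose(np.sort(out.to_numpy().ravel()),
                          np.sort(values.to_numpy().ravel())).all()

    def test_minus_host_strand_routes_minus_container_to_sense_block(self):
        regions = make_regions(2)          # r0 on +, r1 on -
        values = transcript_frame(regions)
        out = u.reorient_merge(values, regions)
        F = values.shape[1]
        assert np.allclose(out.loc["r0"][:F], values.loc["r0:plus"])
        assert np.allclose(out.loc["r1"][:F], values.loc["r1:minus"])
        assert np.allclose(out.loc["r1"][F:], values.loc["r1:plus"])

    def test_intergenic_region_uses_plus_as_sense(self):
        region = u.UCRegion("rI", "chr1", 1000, 1300, "intergenic")
        values = transcript_frame([region])
        values.index = ["rI:plus", "rI:minus"]
        out = u.reorient_merge(values, [region])
        F = values.shape[1]
        assert np.allclose(out.loc["rI"][:F], values.loc["rI:plus"])

    def test_deterministic(self):
        regions = make_regions(5)
        values = transcript_frame(regions)
        assert u.reorient_merge(values, regions).equals(
            u.reorient_merge(values, regions))

    def test_missing_host_strand_rejected(self):
        region = u.UCRegion("rX", "chr1", 1000, 1300, "unclassified")
        values = transcript_frame([make_regions(1)[0]])
        values.index = ["rX:plus", "rX:minus"]
        with pytest.raises(ValueError, match="rX"):
            u.reorient_merge(values, [region])


class TestSpearmanDistance:
    def test_identical_rows_distance_zero(self):
        df = pd.DataFrame([[1, 2, 3, 4], [2, 4, 6, 8]], index=["a", "b"])
        d = u.spearman_distance(df)
        assert np.isclose(d.loc["a", "b"], 0.0)

    def test_reversed_ranking_distance_two(self):
        df = pd.DataFrame([[1, 2, 3, 4], [4, 3, 2, 1]], index=["a", "b"])
        assert np.isclose(u.spearman_distance(df).loc["a", "b"], 2.0)

    def test_matches_hand_rank_oracle(self):
        df = pd.DataFrame([[10, 30, 20, 40],
                           [1, 4, 2, 3],
                           [5, 5, 7, 9]], index=["a", "b", "c"])
        d = u.spearman_distance(df)
        for i, j in itertools.combinations(df.index, 2):
            ri = rankdata(df.loc[i])
            rj = rankdata(df.loc[j])
            rho = np.corrcoef(ri, rj)[0, 1]
            assert np.isclose(d.loc[i, j], 1.0 - rho, atol=1e-12)

    def test_invariant_under_monotone_row_transform(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(4, 8)))
        warped = df.copy()
        warped.iloc[0] = np.exp(warped.iloc[0])
        warped.iloc[1] = warped.iloc[1] ** 3
        assert np.allclose(u.spearman_distance(df), u.spearman_distance(warped))

    def test_constant_row_rejected(self):
        df = pd.DataFrame([[1, 1, 1, 1], [1, 2, 3, 4]], index=["flat", "b"])
        with pytest.raises(ValueError, match="flat"):
            u.spearman_distance(df)


class TestWardCluster:
    @staticmethod
    def planted_blocks(n_per_block=10, n_features=24, noise=0.1, seed=0):
        rng = np.random.default_rng(seed)
        p1 = rng.normal(size=n_features)
        p2 = rng.normal(size=n_features)
        rows, index = [], []
        for b, pattern in enumerate((p1, p2)):
            for i in range(n_per_block):
                rows.append(pattern + rng.normal(0, noise, n_features))
                index.append(f"b{b}_{i}")
        truth = [i.split("_")[0] for i in index]
        return pd.DataFrame(rows, index=index), truth

    def test_two_planted_blocks_recovered_exactly(self):
        df, truth = self.planted_blocks()
        result = u.ward_cluster(u.spearman_distance(df), k=2)
        groups = {}
        for rid, lab in result.labels.items():
            groups.setdefault(lab, set()).add(rid.split("_")[0])
        assert all(len(g) == 1 for g in groups.values())
        assert len(groups) == 2

    def test_k_equals_n_gives_singletons(self):
        df, _ = self.planted_blocks(n_per_block=3)
        result = u.ward_cluster(u.spearman_distance(df), k=len(df))
        assert result.labels.nunique() == len(df)

    def test_row_permutation_invariance_up_to_relabeling(self):
        df, _ = self.planted_blocks(n_per_block=5, seed=2)
        d = u.spearman_distance(df)
        perm = np.random.default_rng(0).permutation(len(df))
        dp = d.iloc[perm, perm]
        a = u.ward_cluster(d, k=2).labels
        b = u.ward_cluster(dp, k=2).labels
        pairs = {(a[i], b[i]) for i in df.index}
        assert len(pairs) == 2  # bijection between labelings

    def test_k_larger_than_n_rejected(self):
        df, _ = self.planted_blocks(n_per_block=2)
        with pytest.raises(ValueError):
            u.ward_cluster(u.spearman_distance(df), k=10)


def brute_hypergeom_over(k, N, K, n):
    """P(X >= k) by exhaustive enumeration of draws."""
    total = math.comb(N, n)
    return sum(math.comb(K, x) * math.comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / total


def brute_hypergeom_under(k, N, K, n):
    total = math.comb(N, n)
    return sum(math.comb(K, x) * math.comb(N - K, n - x)
               for x in range(max(0, n - (N - K)), k + 1)) / total


class TestEnrichment:
    def labels(self, assignment):
        return pd.Series(assignment,
                         index=[f"r{i}" for i in range(len(assignment))])

    def test_matches_bruteforce_on_small_universe(self):
        labels = self.labels([1, 1, 1, 1, 2, 2, 2, 2, 2, 2, 2, 2])
        annotation = {"setA": {"r0", "r1", "r2", "r5"}}
        out = u.cluster_enrichment(labels, annotation)
        for _, row in out.iterrows():
            N, K = 12, 4
            n, k = row["cluster_size"], row["overlap"]
            assert np.isclose(row["p_over"], brute_hypergeom_over(k, N, K, n),
                              atol=1e-9)
            assert np.isclose(row["p_under"], brute_hypergeom_under(k, N, K, n),
                              atol=1e-9)

    def test_cluster_equal_to_annotation_hits_minimum_p(self):
        labels = self.labels([1, 1, 1, 2, 2, 2, 2, 2, 2])
        annotation = {"setA": {"r0", "r1", "r2"}}
        out = u.cluster_enrichment(labels, annotation)
        row = out[(out["cluster"] == 1)].iloc[0]
        assert np.isclose(row["p_over"], 1.0 / math.comb(9, 3), atol=1e-12)

    def test_annotation_equal_to_universe_gives_p_one_both_tails(self):
        labels = self.labels([1, 1, 2, 2])
        annotation = {"all": {"r0", "r1", "r2", "r3"}}
        out = u.cluster_enrichment(labels, annotation)
        assert np.allclose(out["p_over"], 1.0)
        assert np.allclose(out["p_under"], 1.0)

    def test_complement_consistency(self):
        labels = self.labels([1, 1, 1, 2, 2, 2, 2, 1, 2, 2])
        members = {"r0", "r3", "r4", "r7"}
        complement = set(labels.index) - members
        out = u.cluster_enrichment(labels, {"A": members, "notA": complement})
        a = out[out["annotation"] == "A"].set_index("cluster")
        na = out[out["annotation"] == "notA"].set_index("cluster")
        for c in a.index:
            assert np.isclose(a.loc[c, "p_over"], na.loc[c, "p_under"], atol=1e-12)

    def test_disjoint_annotation_skipped_with_warning(self, caplog):
        import logging
        labels = self.labels([1, 2])
        with caplog.at_level(logging.WARNING):
            out = u.cluster_enrichment(labels, {"ghost": {"zz"}})
        assert out.empty
        assert "ghost" in caplog.text
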