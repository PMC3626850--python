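import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ucrtile as u
from ucrtile import preprocess as prep
from ucrtile.diffexpr import DEConfig, de_filter


class TestFolds:
    def test_identical_conditions_give_unit_folds(self, tucr_factory):
        tm = tucr_factory({"t1": [5.0] * 12})
        folds = u.per_repeat_folds(tm)
        assert np.allclose(folds, 1.0)

    def test_log2_difference_of_one_gives_fold_two(self, tucr_factory):
        samples = u.simulate.make_sample_sheet()
        vals = [3.0 if t == "ATRA" else 2.0 for t in samples["treatment"]]
        tm = tucr_factory({"t1": vals})
        assert np.allclose(u.per_repeat_folds(tm), 2.0)

    def test_unmatched_repeat_rejected(self, tucr_factory):
        tm = tucr_factory({"t1": np.arange(12.0)})
        tm.samples = tm.samples.iloc[:-1]
        tm.values = tm.values.iloc[:, :-1]
        with pytest.raises(ValueError, match="SH-SY5Y"):
            u.per_repeat_folds(tm)

    @pytest.mark.parametrize("pair, expected", [
        ((2.0, 2.0), 2.0),
        ((1.0, 4.0), 2.0),
        ((3.0, 3.0), 3.0),
    ])
    def test_line_fold_is_geometric_mean(self, pair, expected):
        cols = pd.MultiIndex.from_tuples(
            [("A", 1), ("A", 2)], names=["cell_line", "repeat"])
        rf = pd.DataFrame([pair], index=["t"], columns=cols)
        lf = u.per_line_folds(rf)
        assert np.isclose(lf.loc["t", "A"], expected)

    def test_nonpositive_fold_rejected(self):
        cols = pd.MultiIndex.from_tuples(
            [("A", 1), ("A", 2)], names=["cell_line", "repeat"])
        rf = pd.DataFrame([(0.0, 2.0)], index=["t"], columns=cols)
        with pytest.raises(ValueError):
            u.per_line_folds(rf)


class TestDEFilter:
    def test_published_up_row(self):
        verdict = de_filter([1.41, 2.86, 3.38])
        assert verdict["direction"] == "up"
        assert verdict["lines_passing"] == 2
        assert verdict["passes"]

    def test_published_down_row(self):
        verdict = de_filter([0.40, 0.37, 0.99])
        assert verdict["direction"] == "down"
        assert verdict["lines_passing"] == 2
        assert verdict["passes"]

    def test_subthreshold_folds_fail(self):
        assert not de_filter([1.2, 1.3, 1.4])["passes"]

    def test_mixed_directions_without_majority_fail(self):
        verdict = de_filter([2.0, 0.5, 1.0])
        assert verdict["ambiguous"]
        assert not verdict["passes"]

    def test_repeat_criterion_enforced(self):
        # 3 lines pass but only 3 of 6 repeats do
        verdict = de_filter([2.0, 2.0, 2.0],
                            repeat_folds=[4.0, 1.0, 4.0, 1.0, 4.0, 1.0])
        assert verdict["repeats_passing"] == 3
        assert not verdict["passes"]
        ok = de_filter([2.0, 2.0, 2.0],
                       repeat_folds=[4.0, 1.0, 4.0, 4.0, 4.0, 1.0])
        assert ok["passes"]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        folds = np.exp2(rng.normal(0, 1, size=(200, 3)))
        counts = []
        for thr in (1.2, 1.5, 2.0, 3.0):
            cfg = DEConfig(fold_threshold=thr)
            counts.append(sum(de_filter(f, cfg)["passes"] for f in folds))
        assert counts == sorted(counts, reverse=True)

    def test_direction_symmetry_under_inversion(self):
        rng = np.random.default_rng(1)
        folds = np.exp2(rng.normal(0, 1, size=(100, 3)))
        for f in folds:
            v, vinv = de_filter(f), de_filter(1.0 / f)
            assert v["passes"] == vinv["passes"]
            assert v["lines_passing"] == vinv["lines_passing"]
            if v["passes"]:
                assert {v["direction"], vinv["direction"]} == {"up", "down"}


class TestTTest:
    def test_equal_conditions_give_p_one(self, tucr_factory):
        tm = tucr_factory({"t1": [4.0] * 12})
        assert u.ttest_treated_vs_untreated(tm).loc["t1"] == 1.0

    def test_constant_nonzero_shift_gives_p_zero_with_warning(self, tucr_factory,
                                                              caplog):
        samples = u.simulate.make_sample_sheet()
        vals = [5.0 if t == "ATRA" else 4.0 for t in samples["treatment"]]
        tm = tucr_factory({"t1": vals})
        import logging
        with caplog.at_level(logging.WARNING):
            p = u.ttest_treated_vs_untreated(tm)
        assert p.loc["t1"] == 0.0
        assert "zero-variance" in caplog.text

    def test_matches_textbook_paired_oracle(self, tucr_factory):
        diffs = np.array([1.0, 1.2, 0.8, 1.1, 0.9, 1.0])
        samples = u.simulate.make_sample_sheet()
        pair_keys = sorted(set(zip(samples["cell_line"], samples["repeat"])))
        base = {k: 3.0 + 0.2 * i for i, k in enumerate(pair_keys)}
        vals = []
        for aid, row in samples.iterrows():
            k = (row["cell_line"], row["repeat"])
            vals.append(base[k] + (diffs[pair_keys.index(k)]
                                   if row["treatment"] == "ATRA" else 0.0))
        tm = tucr_factory({"t1": vals})
        p = u.ttest_treated_vs_untreated(tm).loc["t1"]
        tstat = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
        oracle = 2 * stats.t.sf(abs(tstat), df=len(diffs) - 1)
        assert np.isclose(p, oracle, atol=1e-12)

    def test_unpaired_option(self, tucr_factory):
        rng = np.random.default_rng(4)
        tm = tucr_factory({"t1": rng.normal(5, 1, 12)})
        p_paired = u.ttest_treated_vs_untreated(tm, paired=True).loc["t1"]
        p_unpaired = u.ttest_treated_vs_untreated(tm, paired=False).loc["t1"]
        assert 0 < p_paired <= 1 and 0 < p_unpaired <= 1
        assert not np.isclose(p_paired, p_unpaired)


class TestBuildTable:
    def test_alpha_zero_empties_table(self, small_dataset, small_preprocessed):
        _, tucrs = small_preprocessed
        expressed = u.call_expressed(tucrs)
        table = u.build_de_table(expressed, small_dataset.regions,
                                 DEConfig(alpha=1e-300))
        assert table.empty

    def test_up_block_precedes_down_block_sorted_by_p(self, small_dataset,
                                                      small_preprocessed):
        _, tucrs = small_preprocessed
        expressed = u.call_expressed(tucrs)
        table = u.build_de_table(expressed, small_dataset.regions)
        dirs = list(table["direction"])
        if "up" in dirs and "down" in dirs:
            assert dirs.index("down") > max(i for i, d in enumerate(dirs)
                                            if d == "up")
        for _, block in table.groupby("direction"):
            assert block["p_value"].is_monotonic_increasing

    def test_noiseless_simulation_recovers_planted_set_exactly(self):
        cfg = u.SimConfig(n_regions=40, n_de_up=4, n_de_down=4,
                          de_log2fold_range=(1.0, 2.0),
                          noise_sd=0.0, line_sd=0.0, repeat_sd=0.0,
                          array_sd=0.0, probe_affinity_sd=0.0,
                          outlier_prob=0.0, seed=11)
        ds = u.simulate_dataset(cfg)
        m = prep.log2_transform(ds.intensities)
        m = prep.smooth_tracks(m, ds.probes)
        tucrs = prep.summarize_tucrs(m, ds.probes)
        table = u.build_de_table(tucrs, ds.regions)
        metrics = u.evaluate_de_calls(table, ds.truth)
        assert metrics["recall"] == 1.0
        assert metrics["fdp"] == 0.0
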